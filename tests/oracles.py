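"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the mathematical definitions with literal loops
(per voxel, per atlas, per ROI) and stay independent of the vectorized
implementations they check.
"""

import numpy as np


def selection_factor_loop(subject_masks, atlas_masks, roi_names, atlas_index):
    """Literal per-voxel per-ROI product of membership agreements."""
    shape = subject_masks[roi_names[0]].shape
    w = np.zeros(shape, dtype=bool)
    for p in np.ndindex(shape):
        agree = True
        for roi in roi_names:
            if bool(subject_masks[roi][p]) != bool(atlas_masks[atlas_index][roi][p]):
                agree = False
                break
        w[p] = agree
    return w


def synthesize_loop(subject_masks, atlas_masks, cts, roi_names, air_mask):
    """Literal per-voxel selected-mean / fallback-mean / air-override synthesis."""
    n = len(cts)
    shape = cts[0].shape
    out = np.zeros(shape)
    for p in np.ndindex(shape):
        selected = []
        for i in range(n):
            agree = True
            for roi in roi_names:
                if bool(subject_masks[roi][p]) != bool(atlas_masks[i][roi][p]):
                    agree = False
                    break
            if agree:
                selected.append(cts[i][p])
        if selected:
            out[p] = sum(selected) / len(selected)
        else:
            out[p] = sum(ct[p] for ct in cts) / n
        if air_mask[p]:
            out[p] = -1000.0
    return out


def gamma_loop(ref, ev, dose_percent, distance_mm, spacing_mm, substeps=30):
    """Exhaustive fine-grid 2D local gamma for small dose maps."""
    h, w = ref.shape
    step = distance_mm / substeps
    radius = 3.0 * distance_mm
    delta = dose_percent / 100.0
    gamma = np.zeros((h, w))

    def ref_interp(y_mm, x_mm):
        fi = y_mm / spacing_mm[0]
        fj = x_mm / spacing_mm[1]
        if fi < 0 or fj < 0 or fi > h - 1 or fj > w - 1:
            return None
        i0, j0 = int(fi), int(fj)
        i1, j1 = min(i0 + 1, h - 1), min(j0 + 1, w - 1)
        di, dj = fi - i0, fj - j0
        return (ref[i0, j0] * (1 - di) * (1 - dj) + ref[i1, j0] * di * (1 - dj)
                + ref[i0, j1] * (1 - di) * dj + ref[i1, j1] * di * dj)

    n_off = int(radius / step)
    for i in range(h):
        for j in range(w):
            best = np.inf
            for oi in range(-n_off, n_off + 1):
                for oj in range(-n_off, n_off + 1):
                    dy, dx = oi * step, oj * step
                    d2 = dy * dy + dx * dx
                    if d2 > radius * radius:
                        continue
                    r = ref_interp(i * spacing_mm[0] + dy, j * spacing_mm[1] + dx)
                    if r is None or r <= 0:
                        continue
                    g2 = (ev[i, j] - r) ** 2 / (delta * r) ** 2 + d2 / distance_mm ** 2
                    best = min(best, g2)
            gamma[i, j] = np.sqrt(best)
    return gamma


def dx_order_statistics(doses, x):
    """Dx from explicitly sorted doses with linear rank interpolation."""
    doses = sorted(doses)  # ascending
    n = len(doses)
    q = 1.0 - x / 100.0
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return doses[lo] * (1 - frac) + doses[hi] * frac
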