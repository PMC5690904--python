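"""Shared fixtures: phantom subjects and the leave-one-out cohort run.

The 10-subject leave-one-out run is expensive (90 deformable registrations),
so it is computed once per session at the default cohort conditions with the
dose and localization stages disabled (those are covered by dedicated,
smaller tests) and shared by every test that needs cohort-level results.
"""

import warnings

import numpy as np
import pytest

from sctforge.evaluation import LOOConfig, run_leave_one_out
from sctforge.phantom import PhantomSpec, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def subject0(default_spec):
    return generate_subject(default_spec, 0)


@pytest.fixture(scope="session")
def subject1(default_spec):
    return generate_subject(default_spec, 1)


@pytest.fixture(scope="session")
def tiny_spec():
    """Coarse cohort for smoke tests: 8 mm voxels keep everything fast."""
    return PhantomSpec(grid_shape=(32, 32, 24), spacing_mm=(8.0, 8.0, 8.0), seed=3)


@pytest.fixture(scope="session")
def loo_report(default_spec):
    """Leave-one-out over the default 10-subject cohort (HU + Dice stages)."""
    cohort = generate_cohort(default_spec, 10)
    cfg = LOOConfig(
        atlas_counts=(5, 6, 7, 8, 9),
        include_dose=False,
        include_localization=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_leave_one_out(cohort, cfg, seed=1)
    assert not report.config_echo["errors"], report.config_echo["errors"]
    return report


def random_selection_instance(rng, shape=(16, 16, 16), n_atlases=None, n_rois=6):
    """A random small synthesis instance for oracle comparisons."""
    from sctforge.atlaslib import ROIMaskSet
    from sctforge.sct import SelectionInput
    from sctforge.volume import Volume3D

    roi_names = ["air", "bone", "bladder", "prostate", "rectum", "skin"][:n_rois]
    n = n_atlases or int(rng.integers(3, 10))
    subject_masks = ROIMaskSet(
        {name: rng.random(shape) < 0.4 for name in roi_names}
    )
    cts = [
        Volume3D(rng.uniform(-1000, 1500, shape), (1, 1, 1), (0, 0, 0), "CT")
        for _ in range(n)
    ]
    atlas_masks = [
        ROIMaskSet({name: rng.random(shape) < 0.4 for name in roi_names})
        for _ in range(n)
    ]
    air = rng.random(shape) < 0.1
    return SelectionInput(
        subject_masks=subject_masks,
        deformed_atlas_cts=cts,
        deformed_atlas_masks=atlas_masks,
        roi_selection_set=tuple(roi_names),
        air_mask=air,
    )
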