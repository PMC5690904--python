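"""HU reports, dose proxy, gamma index, DVH metrics, localization, orchestration."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import dx_order_statistics, gamma_loop
from sctforge.atlaslib import ROIMaskSet
from sctforge.evaluation import (
    Beam,
    LOOConfig,
    compare_localization,
    default_beams,
    dose_proxy,
    dvh_curve,
    dvh_parameters,
    gamma_2d_local,
    hu_error_report,
    run_leave_one_out,
    soft_tissue_mask,
)
from sctforge.phantom import PhantomSpec, generate_cohort
from sctforge.registration import RigidTransform
from sctforge.volume import Volume3D


class TestHUErrorReport:
    def test_identity_gives_zero_errors(self, subject0):
        rep = hu_error_report(subject0.ct, subject0.ct, subject0.roi_masks)
        for roi, (mean, sd, n) in rep.per_roi.items():
            assert mean == 0.0 and sd == 0.0 and n > 0
        assert rep.quantiles[0.9] == 0.0

    def test_offset_confined_to_prostate(self, subject0):
        shifted = subject0.ct.values.copy()
        shifted[subject0.roi_masks["prostate"]] += 10.0
        sct = subject0.ct.with_values(shifted)
        rep = hu_error_report(sct, subject0.ct, subject0.roi_masks)
        assert rep.per_roi["prostate"][0] == pytest.approx(10.0)
        assert rep.per_roi["prostate"][1] == pytest.approx(0.0)
        assert rep.per_roi["bladder"][0] == pytest.approx(0.0)
        assert rep.per_roi["soft_tissue"][0] == pytest.approx(0.0)

    def test_cumulative_histogram_reaches_one(self, subject0):
        rng_vals = subject0.ct.values + np.random.default_rng(0).normal(
            0, 20, subject0.ct.values.shape)
        rep = hu_error_report(subject0.ct.with_values(rng_vals), subject0.ct,
                              subject0.roi_masks)
        abs_err, cum = rep.cumulative_abs_histogram
        assert cum[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cum) >= 0)
        assert np.all(np.diff(abs_err) >= 0)

    def test_soft_tissue_excludes_organs(self, subject0):
        soft = soft_tissue_mask(subject0.roi_masks)
        for roi in ("bone", "bladder", "prostate", "rectum", "air"):
            assert not (soft & subject0.roi_masks[roi]).any()
        assert np.all(subject0.roi_masks["skin"][soft])


class TestDoseProxy:
    def _water_phantom(self, n=32):
        vol = Volume3D(np.zeros((n, n, n)), (2.0, 2.0, 2.0), (0, 0, 0), "CT")
        ptv = np.zeros((n, n, n), bool)
        ptv[12:20, 12:20, 12:20] = True
        return vol, ptv

    def test_uniform_water_exponential_depth_dose(self):
        vol, ptv = self._water_phantom()
        mu = 0.005
        field = np.ones(vol.values.shape, bool)
        dose = dose_proxy(vol, [Beam(0.0, field)], ptv, mu_water_per_mm=mu,
                          prescription_gy=10.0)
        # half-value depth: dose ratio across Delta-y equals exp(-mu*Delta)
        prof = dose.values[16, :, 16]
        ratio = prof[20] / prof[10]
        assert ratio == pytest.approx(np.exp(-mu * 10 * 2.0), rel=1e-6)

    def test_deterministic(self, subject0):
        ptv = subject0.roi_masks["prostate"]
        beams = default_beams(ptv, n_beams=3)
        d1 = dose_proxy(subject0.ct, beams, ptv)
        d2 = dose_proxy(subject0.ct, beams, ptv)
        assert np.array_equal(d1.values, d2.values)

    def test_prescription_normalization(self, subject0):
        ptv = subject0.roi_masks["prostate"]
        dose = dose_proxy(subject0.ct, default_beams(ptv, 3), ptv,
                          prescription_gy=79.2)
        assert dose.values[ptv].mean() == pytest.approx(79.2)

    def test_empty_field_mask_rejected(self):
        vol, ptv = self._water_phantom()
        with pytest.raises(ValueError, match="field"):
            dose_proxy(vol, [Beam(0.0, np.zeros(vol.values.shape, bool))], ptv)


class TestGamma:
    def _toy_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        y, x = np.mgrid[0:11, 0:11]
        ref = 10.0 * np.exp(-((y - 5) ** 2 + (x - 5) ** 2) / 20.0) + 1.0
        ev = ref * (1.0 + rng.uniform(-0.03, 0.03, ref.shape))
        return ref, ev

    def test_identical_pair_passes_everywhere(self):
        ref, _ = self._toy_pair()
        res = gamma_2d_local(ref, ref, 2.0, 2.0, (1.0, 1.0))
        assert res.pass_rate == 1.0
        assert np.allclose(res.gamma_map, 0.0, atol=1e-12)

    def test_boundary_dose_difference_gives_gamma_one(self):
        # flat reference, one evaluated point at exactly +2% under 2%/2mm
        ref = np.full((9, 9), 50.0)
        ev = ref.copy()
        ev[4, 4] = 51.0
        res = gamma_2d_local(ref, ev, 2.0, 2.0, (1.0, 1.0))
        assert res.gamma_map[4, 4] == pytest.approx(1.0, abs=1e-6)
        assert res.pass_rate == 1.0

    def test_matches_bruteforce_oracle_on_toy_maps(self):
        # oracle substeps chosen so both implementations search the same
        # distance/10 node lattice; agreement is then near machine precision
        ref, ev = self._toy_pair(3)
        res = gamma_2d_local(ref, ev, 2.0, 2.0, (1.0, 1.0))
        oracle = gamma_loop(ref, ev, 2.0, 2.0, (1.0, 1.0), substeps=10)
        assert np.isfinite(res.gamma_map).all()
        np.testing.assert_allclose(res.gamma_map, oracle, rtol=1e-6, atol=1e-9)

    def test_pass_rate_monotone_in_criteria(self):
        ref, ev = self._toy_pair(4)
        ev = ev * 1.015  # push some points near the criterion
        tight = gamma_2d_local(ref, ev, 1.0, 1.0, (1.0, 1.0)).pass_rate
        loose = gamma_2d_local(ref, ev, 2.0, 2.0, (1.0, 1.0)).pass_rate
        assert tight <= loose

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gamma_2d_local(np.zeros((5, 5)), np.ones((5, 5)), 2.0, 2.0)

    def test_low_dose_voxels_excluded_from_pass_rate(self):
        ref = np.ones((9, 9))
        ref[0, 0] = 100.0  # everything else falls below the 10% cutoff
        res = gamma_2d_local(ref, ref, 2.0, 2.0, (1.0, 1.0))
        assert res.evaluated.sum() == 1


class TestDVH:
    def _roi_dose(self, values):
        values = np.asarray(values, dtype=float)
        vol = Volume3D(values.reshape(-1, 1, 1), (1, 1, 1), (0, 0, 0), "DOSE")
        roi = np.ones(vol.values.shape, bool)
        return vol, roi

    def test_uniform_dose_gives_dx_equal_everywhere(self):
        vol, roi = self._roi_dose(np.full(50, 42.0))
        dx = dvh_parameters(vol, roi, [99, 95, 50, 5, 1])
        assert all(v == pytest.approx(42.0) for v in dx.values())

    def test_linear_doses_match_rank_interpolation(self):
        doses = np.arange(1.0, 101.0)
        vol, roi = self._roi_dose(doses)
        dx = dvh_parameters(vol, roi, [99, 50])
        assert dx[99.0] == pytest.approx(1.99)
        assert dx[50.0] == pytest.approx(50.5)

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(5)
        doses = rng.uniform(0, 80, 100)
        vol, roi = self._roi_dose(doses)
        for x in (99, 95, 50, 40, 5, 1):
            assert dvh_parameters(vol, roi, [x])[float(x)] == pytest.approx(
                dx_order_statistics(doses, x))

    def test_dx_non_increasing_in_x(self):
        rng = np.random.default_rng(6)
        vol, roi = self._roi_dose(rng.uniform(0, 80, 200))
        xs = [1, 5, 40, 50, 95, 99]
        vals = [dvh_parameters(vol, roi, [x])[float(x)] for x in xs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_curve_consistent_with_dx(self):
        rng = np.random.default_rng(7)
        doses = rng.uniform(0, 80, 500)
        vol, roi = self._roi_dose(doses)
        curve = dvh_curve(vol, roi, n_bins=400)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        # Dx read off the curve agrees within one bin width
        bin_w = curve.dose_bins[1] - curve.dose_bins[0]
        d50 = dvh_parameters(vol, roi, [50])[50.0]
        idx = np.searchsorted(-curve.volume_fraction, -0.5)
        assert abs(curve.dose_bins[min(idx, len(curve.dose_bins) - 1)] - d50) <= 2 * bin_w

    def test_empty_roi_rejected(self):
        vol, _ = self._roi_dose(np.ones(10))
        with pytest.raises(ValueError):
            dvh_parameters(vol, np.zeros(vol.values.shape, bool), [50])


class TestCompareLocalization:
    def test_identical_transforms_zero_difference(self):
        t = RigidTransform((1, 2, 3), (0.5, -0.5, 0.1))
        assert compare_localization(t, t) == (0.0, (0.0, 0.0, 0.0))

    def test_unit_translation_difference(self):
        a = RigidTransform((1, 0, 0), (0, 0, 0))
        b = RigidTransform((0, 0, 0), (0, 0, 0))
        dt, drot = compare_localization(a, b)
        assert dt == pytest.approx(1.0)
        assert drot == (0.0, 0.0, 0.0)

    def test_convention_mismatch_rejected(self):
        a = RigidTransform((0, 0, 0), (0, 0, 0))
        b = RigidTransform((0, 0, 0), (0, 0, 0), convention="other")
        with pytest.raises(ValueError):
            compare_localization(a, b)


class TestLeaveOneOut:
    def _tiny_cohort(self):
        spec = PhantomSpec(grid_shape=(32, 32, 24), spacing_mm=(8, 8, 8), seed=5)
        return generate_cohort(spec, 2)

    def test_two_subject_boundary_runs_single_atlas(self):
        cohort = self._tiny_cohort()
        cfg = LOOConfig(include_dose=False, include_localization=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_leave_one_out(cohort, cfg, seed=0)
        assert rep.soft_p90.subject.nunique() == 2
        assert not rep.config_echo["errors"]

    def test_same_seed_reproduces_aggregates(self):
        cohort = self._tiny_cohort()
        cfg = LOOConfig(include_dose=False, include_localization=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_leave_one_out(cohort, cfg, seed=2)
            b = run_leave_one_out(cohort, cfg, seed=2)
        pd.testing.assert_frame_equal(a.hu, b.hu)
        pd.testing.assert_frame_equal(a.dice, b.dice)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            run_leave_one_out(self._tiny_cohort()[:1], LOOConfig(), 0)

    def test_report_files_written(self, tmp_path, loo_report):
        loo_report.save(tmp_path / "out")
        for name in ("summary_hu.csv", "summary_dice.csv", "summary_dice_sweep.csv",
                     "report.json"):
            assert (tmp_path / "out" / name).exists()
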