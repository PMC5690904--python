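"""Voxel selection and synthesis: closed-form cases, oracle match, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_selection_instance
from oracles import selection_factor_loop, synthesize_loop
from sctforge.atlaslib import ROIMaskSet
from sctforge.registration import DVF
from sctforge.sct import (
    SelectionInput,
    direct_mean_sct,
    selection_factor,
    synthesize_sct,
)
from sctforge.volume import Volume3D


def _voxel_instance(w_flags, ct_values, subject_in_prostate=True):
    """1-voxel instance with per-atlas agreement controlled by w_flags."""
    shape = (1, 1, 1)
    roi_names = ("prostate",)
    subject = ROIMaskSet({"prostate": np.full(shape, subject_in_prostate)})
    cts, masks = [], []
    for w, v in zip(w_flags, ct_values):
        cts.append(Volume3D(np.full(shape, float(v)), (1, 1, 1), (0, 0, 0), "CT"))
        member = subject_in_prostate if w else not subject_in_prostate
        masks.append(ROIMaskSet({"prostate": np.full(shape, member)}))
    return SelectionInput(subject, cts, masks, roi_names,
                          air_mask=np.zeros(shape, bool))


class TestSelectionFactor:
    def test_identical_masks_select_everywhere(self):
        rng = np.random.default_rng(0)
        inst = random_selection_instance(rng, shape=(8, 8, 8), n_atlases=1)
        inst.deformed_atlas_masks[0] = ROIMaskSet(dict(inst.subject_masks.masks))
        assert selection_factor(inst, 0).all()

    def test_single_roi_disagreement_deselects(self):
        inst = _voxel_instance([False], [100.0])
        assert not selection_factor(inst, 0).any()

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(1)
        inst = random_selection_instance(rng, shape=(8, 8, 8))
        for i in range(inst.n_atlases):
            oracle = selection_factor_loop(
                inst.subject_masks.masks,
                [m.masks for m in inst.deformed_atlas_masks],
                list(inst.roi_selection_set), i)
            assert np.array_equal(selection_factor(inst, i), oracle)

    def test_missing_roi_rejected(self):
        rng = np.random.default_rng(2)
        inst = random_selection_instance(rng, shape=(4, 4, 4), n_atlases=2)
        with pytest.raises(KeyError, match="femoral"):
            SelectionInput(inst.subject_masks, inst.deformed_atlas_cts,
                           inst.deformed_atlas_masks,
                           roi_selection_set=("femoral",))

    def test_atlas_index_out_of_range(self):
        rng = np.random.default_rng(3)
        inst = random_selection_instance(rng, shape=(4, 4, 4), n_atlases=2)
        with pytest.raises(IndexError):
            selection_factor(inst, 5)


class TestSynthesize:
    def test_selected_mean_branch(self):
        inst = _voxel_instance([True, True, False], [100.0, 200.0, 999.0])
        sct, diag = synthesize_sct(inst)
        assert sct.values[0, 0, 0] == pytest.approx(150.0)
        assert diag.selected_count[0, 0, 0] == 2
        assert diag.fallback_fraction == 0.0

    def test_fallback_mean_branch(self):
        inst = _voxel_instance([False, False, False], [100.0, 200.0, 999.0])
        sct, diag = synthesize_sct(inst)
        assert sct.values[0, 0, 0] == pytest.approx(433.0, abs=0.5)
        assert diag.fallback_fraction == 1.0

    def test_air_override_wins_over_any_atlas_value(self):
        rng = np.random.default_rng(4)
        inst = random_selection_instance(rng, shape=(8, 8, 8))
        assert inst.air_mask.any()
        sct, _ = synthesize_sct(inst)
        assert np.all(sct.values[inst.air_mask] == -1000.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        inst = random_selection_instance(rng, shape=(8, 8, 8))
        sct, _ = synthesize_sct(inst)
        oracle = synthesize_loop(
            inst.subject_masks.masks,
            [m.masks for m in inst.deformed_atlas_masks],
            [ct.values for ct in inst.deformed_atlas_cts],
            list(inst.roi_selection_set), inst.air_mask)
        assert np.array_equal(sct.values, oracle)

    def test_empty_atlas_list_rejected(self):
        with pytest.raises(ValueError):
            SelectionInput(ROIMaskSet({"a": np.zeros((2, 2, 2), bool)}), [], [],
                           roi_selection_set=("a",))


class TestSynthesisInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_selection_instance(rng, shape=(5, 5, 5),
                                         n_atlases=int(rng.integers(1, 6)),
                                         n_rois=int(rng.integers(1, 5)))
        sct, _ = synthesize_sct(inst)
        oracle = synthesize_loop(
            inst.subject_masks.masks,
            [m.masks for m in inst.deformed_atlas_masks],
            [ct.values for ct in inst.deformed_atlas_cts],
            list(inst.roi_selection_set), inst.air_mask)
        assert np.array_equal(sct.values, oracle)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_range_property(self, seed):
        # both branches are means, so non-air output is bounded by the
        # per-voxel min/max over atlases
        rng = np.random.default_rng(seed)
        inst = random_selection_instance(rng, shape=(6, 6, 6))
        sct, _ = synthesize_sct(inst)
        stack = np.stack([ct.values for ct in inst.deformed_atlas_cts])
        non_air = ~inst.air_mask
        assert np.all(sct.values[non_air] >= stack.min(axis=0)[non_air] - 1e-9)
        assert np.all(sct.values[non_air] <= stack.max(axis=0)[non_air] + 1e-9)

    def test_atlas_order_invariance(self):
        rng = np.random.default_rng(6)
        inst = random_selection_instance(rng, shape=(6, 6, 6), n_atlases=5)
        sct, _ = synthesize_sct(inst)
        perm = [4, 2, 0, 3, 1]
        inst2 = SelectionInput(
            inst.subject_masks,
            [inst.deformed_atlas_cts[i] for i in perm],
            [inst.deformed_atlas_masks[i] for i in perm],
            inst.roi_selection_set, inst.air_mask)
        sct2, _ = synthesize_sct(inst2)
        assert np.allclose(sct.values, sct2.values)

    def test_self_atlas_identity(self, subject0):
        # sole atlas = the subject's own matched pair, zero DVF: the output
        # reproduces the subject CT exactly outside the air mask
        inst = SelectionInput(
            subject_masks=subject0.roi_masks,
            deformed_atlas_cts=[subject0.ct],
            deformed_atlas_masks=[subject0.roi_masks],
            air_mask=subject0.roi_masks["air"])
        sct, diag = synthesize_sct(inst)
        outside_air = ~subject0.roi_masks["air"]
        assert np.array_equal(sct.values[outside_air], subject0.ct.values[outside_air])
        assert diag.fallback_fraction == 0.0


class TestDirectMean:
    def test_single_atlas_is_identity_plus_air(self):
        rng = np.random.default_rng(7)
        ct = Volume3D(rng.uniform(-500, 500, (5, 5, 5)), (1, 1, 1), (0, 0, 0), "CT")
        air = rng.random((5, 5, 5)) < 0.2
        out = direct_mean_sct([ct], air)
        assert np.array_equal(out.values[~air], ct.values[~air])
        assert np.all(out.values[air] == -1000.0)

    def test_symmetric_values_average_to_zero(self):
        shape = (3, 3, 3)
        cts = [Volume3D(np.full(shape, v), (1, 1, 1), (0, 0, 0), "CT")
               for v in (-1000.0, 1000.0)]
        out = direct_mean_sct(cts, np.zeros(shape, bool))
        assert np.all(out.values == 0.0)

    def test_equals_selection_fallback_where_nothing_selected(self):
        inst = _voxel_instance([False, False], [10.0, 50.0])
        sct, _ = synthesize_sct(inst)
        dm = direct_mean_sct(inst.deformed_atlas_cts, inst.air_mask)
        assert np.array_equal(sct.values, dm.values)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            direct_mean_sct([], np.zeros((2, 2, 2), bool))
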