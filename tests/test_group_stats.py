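"""Paired voxel statistics: t-map correctness, VOIs, resampling."""

import numpy as np
import pytest
from scipy import stats as sps

from fdgkin.group_stats import (
    PairedMapSet,
    define_vois,
    fdr_correct,
    paired_tmap,
    resample_pmap,
    voi_test,
)
from fdgkin.phantom import make_atlas

DIMS = (8, 8, 4)


def make_set(saline, insulin, n=None):
    saline = np.asarray(saline, float)
    insulin = np.asarray(insulin, float)
    subjects = tuple(f"s{i}" for i in range(saline.shape[0]))
    return PairedMapSet(saline, insulin, subjects, (0.4, 0.4, 0.8), np.eye(4))


def null_set(n_subj=4, seed=0, shape=DIMS):
    rng = np.random.default_rng(seed)
    base = 0.5 + 0.1 * rng.random(shape)
    sal = base + rng.normal(0, 0.02, (n_subj,) + shape)
    ins = base + rng.normal(0, 0.02, (n_subj,) + shape)
    return make_set(sal, ins)


class TestPairedTmap:
    def test_identical_maps_null_identity(self):
        maps = np.tile(np.linspace(0.2, 0.8, np.prod(DIMS)).reshape(DIMS), (4, 1, 1, 1))
        pm = paired_tmap(make_set(maps, maps.copy()))
        assert np.all(pm.t[pm.defined] == 0.0)
        assert np.all(pm.p[pm.defined] == 1.0)

    def test_textbook_example(self):
        # per-subject differences [2, 0, 2, 0] -> t = sqrt(3), df = 3
        sal = np.zeros((4, 1, 1, 1)) + [[[[1.0]]], [[[1.0]]], [[[1.0]]], [[[1.0]]]]
        ins = sal - np.array([2.0, 0.0, 2.0, 0.0]).reshape(4, 1, 1, 1)
        pm = paired_tmap(make_set(sal, ins))
        expected_t = np.sqrt(3.0)
        expected_p = 2 * sps.t.sf(expected_t, 3)  # ~0.1817
        assert pm.t[0, 0, 0] == pytest.approx(expected_t, rel=1e-12)
        assert pm.p[0, 0, 0] == pytest.approx(expected_p, rel=1e-12)
        assert pm.df == 3

    def test_label_swap_negates_t_preserves_p(self):
        ms = null_set(6, seed=3)
        pm = paired_tmap(ms)
        swapped = paired_tmap(make_set(ms.insulin, ms.saline))
        assert np.array_equal(np.nan_to_num(swapped.t), -np.nan_to_num(pm.t))
        assert np.allclose(swapped.p, pm.p, equal_nan=True)

    def test_undefined_subject_voxel_excluded(self):
        ms = null_set(4)
        ms.saline[2, 0, 0, 0] = np.nan
        pm = paired_tmap(ms)
        assert not pm.defined[0, 0, 0]
        assert np.isnan(pm.p[0, 0, 0])

    def test_zero_variance_nonzero_mean_flagged(self):
        sal = np.full((4, 2, 1, 1), 1.0)
        ins = np.full((4, 2, 1, 1), 0.9)
        pm = paired_tmap(make_set(sal, ins))
        assert pm.n_degenerate == 2
        assert np.all(pm.p[pm.defined] > 0.0)

    def test_requires_three_subjects(self):
        ms = null_set(2)
        with pytest.raises(ValueError):
            paired_tmap(ms)

    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(12)
        shape = (13, 13, 12)  # ~2000 voxels
        base = 0.5 * np.ones(shape)
        sal = base + rng.normal(0, 0.02, (8,) + shape)
        ins = base + rng.normal(0, 0.02, (8,) + shape)
        pm = paired_tmap(make_set(sal, ins))
        frac = float((pm.p[pm.defined] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestDefineVois:
    def test_uniform_p_one_gives_empty_list(self):
        maps = np.tile(np.full(DIMS, 0.5), (4, 1, 1, 1))
        pm = paired_tmap(make_set(maps, maps.copy()))
        assert define_vois(pm) == []

    def test_single_planted_cluster_recovered(self):
        pm = paired_tmap(null_set(6, seed=5))
        pm.p[:] = 1.0
        pm.sign[:] = 1.0
        pm.p[2:4, 2:4, 1:3] = 1e-4  # 2x2x2 block
        vois = define_vois(pm, alpha=0.05, min_voxels=4)
        assert len(vois) == 1
        assert vois[0].n_voxels == 8
        assert vois[0].direction == "saline>insulin"
        assert np.array_equal(np.argwhere(vois[0].voxels).min(axis=0), [2, 2, 1])

    def test_min_voxels_threshold(self):
        pm = paired_tmap(null_set(6, seed=5))
        pm.p[:] = 1.0
        pm.sign[:] = 1.0
        pm.p[0, 0, 0:3] = 1e-4  # 3 voxels < min_voxels=4
        assert define_vois(pm, min_voxels=4) == []
        assert len(define_vois(pm, min_voxels=3)) == 1

    def test_direction_split(self):
        pm = paired_tmap(null_set(6, seed=5))
        pm.p[:] = 1.0
        pm.p[0:2, 0:2, 0:2] = 1e-4
        pm.sign[0:2, 0:2, 0:2] = 1.0
        pm.p[5:7, 5:7, 1:3] = 1e-4
        pm.sign[5:7, 5:7, 1:3] = -1.0
        vois = define_vois(pm)
        assert {v.direction for v in vois} == {"saline>insulin", "insulin>saline"}

    def test_named_by_dominant_atlas_region(self):
        atlas = make_atlas(dims=(12, 12, 6), n_regions=4, seed=3)
        shape = atlas.label_volume.shape
        rng = np.random.default_rng(0)
        base = 0.5 + 0.1 * rng.random(shape)
        sal = base + rng.normal(0, 0.01, (5,) + shape)
        pm = paired_tmap(make_set(sal, sal + rng.normal(0, 0.01, sal.shape)))
        pm.p[:] = 1.0
        pm.sign[:] = 1.0
        label = atlas.tissue_labels[1]
        pm.p[atlas.mask(label)] = 1e-5
        vois = define_vois(pm, atlas=atlas)
        assert len(vois) == 1
        assert vois[0].name == atlas.names[label]


class TestVoiTest:
    def _voi(self, shape=DIMS):
        from fdgkin.group_stats import VOI

        vox = np.zeros(shape, bool)
        vox[1:3, 1:3, 1:3] = True
        return VOI("test", vox, "saline>insulin", int(vox.sum()))

    def test_identical_conditions_null(self):
        maps = np.tile(np.full(DIMS, 0.5), (4, 1, 1, 1))
        s = voi_test(self._voi(), make_set(maps, maps.copy()))
        assert s.t == 0.0
        assert s.p == 1.0

    def test_constant_shift_degenerate_branch(self):
        maps = np.tile(np.full(DIMS, 0.5), (4, 1, 1, 1))
        s = voi_test(self._voi(), make_set(maps, maps - 0.1))
        assert s.degenerate
        assert s.p < 1e-300

    def test_subject_with_all_nan_voi_dropped(self):
        ms = null_set(5)
        ms.saline[1][self._voi().voxels] = np.nan
        s = voi_test(self._voi(), ms)
        assert s.subjects_dropped == ("s1",)
        assert s.df == 3  # 4 remaining subjects

    def test_effect_detected(self):
        rng = np.random.default_rng(9)
        base = 0.5 * np.ones(DIMS)
        sal = base + rng.normal(0, 0.01, (8,) + DIMS)
        ins = 0.7 * base + rng.normal(0, 0.01, (8,) + DIMS)
        s = voi_test(self._voi(), make_set(sal, ins))
        assert s.p < 0.05
        assert 0.6 <= s.ratio <= 0.8


class TestResamplePmap:
    def _pmap(self):
        return paired_tmap(null_set(5, seed=8))

    def test_identity_spacing_preserves_values(self):
        pm = self._pmap()
        res = resample_pmap(pm, pm.voxel_dims)
        assert res.p.shape == pm.p.shape
        assert np.allclose(res.p, np.where(pm.defined, pm.p, 1.0))
        assert res.presentation_only

    def test_constant_map_stays_constant(self):
        pm = self._pmap()
        pm.p[:] = 0.37
        pm.defined[:] = True
        res = resample_pmap(pm, (0.1, 0.1, 0.1))
        assert np.allclose(res.p, 0.37)

    def test_midpoint_linear_interpolation(self):
        pm = self._pmap()
        pm.p[:] = 1.0
        pm.defined[:] = True
        pm.p[0, 0, 0] = 0.2
        pm.p[1, 0, 0] = 0.4
        res = resample_pmap(pm, (0.2, 0.4, 0.8))  # halves x spacing
        assert res.p[1, 0, 0] == pytest.approx(0.3)

    def test_source_statistics_untouched(self):
        pm = self._pmap()
        t_before = pm.t.copy()
        resample_pmap(pm, (0.1, 0.1, 0.1))
        assert np.array_equal(np.nan_to_num(pm.t), np.nan_to_num(t_before))

    def test_bad_spacing_rejected(self):
        pm = self._pmap()
        with pytest.raises(ValueError):
            resample_pmap(pm, (0.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            resample_pmap(pm, (100.0, 100.0, 100.0))


def test_fdr_is_monotone_and_bounded():
    pm = paired_tmap(null_set(6, seed=10))
    adj = fdr_correct(pm)
    ok = np.isfinite(adj)
    assert np.all(adj[ok] >= pm.p[ok] - 1e-15)
    assert np.all(adj[ok] <= 1.0)
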