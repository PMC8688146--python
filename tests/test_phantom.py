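"""Phantom generator contracts: geometry, determinism, noise scaling."""

import numpy as np
import pytest

from fdgkin.kinetic_model import FrameSchedule, KineticParams, frame_average, frame_averaged_tac
from fdgkin.phantom import (
    INSULIN,
    SALINE,
    GroundTruth,
    SizingError,
    StudyDesign,
    make_atlas,
    noise_scale_for_fraction,
    simulate_cohort,
    simulate_plasma_input,
    simulate_subject_scan,
)


@pytest.fixture(scope="module")
def atlas():
    return make_atlas(dims=(20, 20, 10), n_regions=8, seed=1)


@pytest.fixture(scope="module")
def design():
    return StudyDesign.of_size(4)


@pytest.fixture(scope="module")
def truth(atlas, design):
    return GroundTruth.default(atlas, design, seed=1)


class TestMakeAtlas:
    def test_construction_contract(self, atlas):
        labels = set(np.unique(atlas.label_volume)) - {0}
        assert len(labels) == 9  # 8 tissue + blood pool
        for lab in labels:
            assert (atlas.label_volume == lab).sum() >= 8 or atlas.names[lab] == "blood_pool"
        assert (atlas.blood_mask.sum()) >= 4
        # blood pool disjoint from tissue
        assert not (atlas.blood_mask & atlas.tissue_mask).any()

    def test_deterministic_given_seed(self):
        a = make_atlas(dims=(20, 20, 10), n_regions=8, seed=1)
        b = make_atlas(dims=(20, 20, 10), n_regions=8, seed=1)
        assert np.array_equal(a.label_volume, b.label_volume)
        c = make_atlas(dims=(20, 20, 10), n_regions=8, seed=2)
        assert not np.array_equal(a.label_volume, c.label_volume)

    def test_infeasible_packing_raises(self):
        with pytest.raises(SizingError):
            make_atlas(dims=(2, 2, 1), n_regions=8)
        with pytest.raises(SizingError):
            make_atlas(dims=(6, 6, 4), n_regions=30)

    def test_regions_are_connected(self, atlas):
        from scipy import ndimage

        for lab in atlas.tissue_labels:
            _, n = ndimage.label(atlas.mask(lab))
            assert n == 1


class TestPlasmaSimulation:
    def test_zero_amplitudes_zero_curve(self):
        cp = simulate_plasma_input({"a1": 0.0, "a2": 0.0, "a3": 0.0})
        assert np.all(cp(np.linspace(0, 43, 50)) == 0)

    def test_default_shape_contract(self):
        cp = simulate_plasma_input()
        t = np.linspace(0, 43, 20001)
        assert cp(0.0) == 0.0
        assert t[np.argmax(cp(t))] < 2.0  # peak < 120 s


class TestSubjectScan:
    def test_no_uptake_no_noise_gives_zero_tissue(self, atlas, design, schedule, feng):
        zero = KineticParams(0.0, 0.1, 0.05, 0.0)
        params = {
            atlas.names[l]: {SALINE: zero, INSULIN: zero} for l in atlas.tissue_labels
        }
        truth0 = GroundTruth(params, {s: 1.0 for s in design.subjects}, sc=0.0)
        img = simulate_subject_scan(atlas, truth0, SALINE, feng, schedule, seed=0)
        assert np.all(img.data[atlas.tissue_mask] == 0.0)

    def test_blood_pool_pv_mixing_identity(self, atlas, truth, schedule, feng):
        img = simulate_subject_scan(atlas, truth, SALINE, feng, schedule, seed=0)
        cp_frames = frame_average(feng, schedule)
        blood_vals = img.data[atlas.blood_mask]
        assert blood_vals == pytest.approx(np.tile(0.6 * cp_frames, (blood_vals.shape[0], 1)))

    def test_noiseless_tac_matches_forward_model_bitwise(self, atlas, truth, schedule, feng):
        img = simulate_subject_scan(atlas, truth, SALINE, feng, schedule, seed=0)
        label = atlas.tissue_labels[2]
        name = atlas.names[label]
        expected = frame_averaged_tac(truth.region_params[name][SALINE], feng, schedule)
        voxel_tacs = img.data[atlas.mask(label)]
        assert np.array_equal(voxel_tacs, np.tile(expected, (voxel_tacs.shape[0], 1)))

    def test_deterministic_given_seed(self, atlas, truth, schedule, feng):
        t = GroundTruth(truth.region_params, truth.subject_effects, sc=1.0)
        a = simulate_subject_scan(atlas, t, SALINE, feng, schedule, seed=5)
        b = simulate_subject_scan(atlas, t, SALINE, feng, schedule, seed=5)
        c = simulate_subject_scan(atlas, t, SALINE, feng, schedule, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_unknown_condition_raises(self, atlas, truth, schedule, feng):
        with pytest.raises(KeyError):
            simulate_subject_scan(atlas, truth, "vehicle", feng, schedule, seed=0)

    def test_noise_variance_matches_model(self, atlas, design, schedule, feng):
        # empirical per-frame variance over replicate voxels ~ Sc*C/dt within 10%
        p = KineticParams(0.1, 0.2, 0.05, 0.005)
        params = {atlas.names[l]: {SALINE: p, INSULIN: p} for l in atlas.tissue_labels}
        sc = 2.0
        t = GroundTruth(params, {s: 1.0 for s in design.subjects}, sc=sc)
        img = simulate_subject_scan(atlas, t, SALINE, feng, schedule, seed=3)
        clean = frame_averaged_tac(p, feng, schedule)
        resid = img.data[atlas.tissue_mask] - clean  # all tissue voxels share one TAC
        assert resid.shape[0] >= 1000
        emp_var = resid.var(axis=0)
        model_var = sc * clean / schedule.durations_s
        late = slice(5, None)  # skip near-zero early frames
        assert np.all(np.abs(emp_var[late] / model_var[late] - 1.0) < 0.10)


class TestCohort:
    def test_null_cohort_has_identical_truth_maps(self, atlas, design, schedule, feng):
        truth = GroundTruth.default(atlas, design, effect_regions={}, seed=1)
        res = simulate_cohort(design, atlas, truth, feng, schedule, seed=1)
        s, i = res.true_cecp[SALINE], res.true_cecp[INSULIN]
        assert np.array_equal(np.nan_to_num(s), np.nan_to_num(i))

    def test_scan_count(self, atlas, truth, design, schedule, feng):
        res = simulate_cohort(design, atlas, truth, feng, schedule, seed=1)
        assert len(res.images) == 8  # 4 subjects x 2 conditions

    def test_k1_effect_scales_cecp_exactly(self, atlas, design, schedule, feng):
        truth = GroundTruth.default(atlas, design, effect_regions={"MBH": 0.7}, seed=1)
        res = simulate_cohort(design, atlas, truth, feng, schedule, seed=1)
        mbh = atlas.mask(next(k for k, v in atlas.names.items() if v == "MBH"))
        ratio = res.true_cecp[INSULIN][mbh] / res.true_cecp[SALINE][mbh]
        assert ratio == pytest.approx(np.full(int(mbh.sum()), 0.7), rel=1e-12)
        other = atlas.tissue_mask & ~mbh
        assert res.true_cecp[INSULIN][other] == pytest.approx(res.true_cecp[SALINE][other])


def test_noise_scale_helper_sets_mean_cv(schedule, feng):
    p = KineticParams(0.1, 0.2, 0.05, 0.005)
    sc = noise_scale_for_fraction(p, feng, schedule, 0.05)
    tac = frame_averaged_tac(p, feng, schedule)
    cv = np.sqrt(sc / (tac * schedule.durations_s))
    use = tac > 0.05 * tac.max()
    assert cv[use].mean() == pytest.approx(0.05, rel=1e-12)
    # long late frames are less noisy than short early ones
    assert cv[use][-1] < cv[use][0]
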