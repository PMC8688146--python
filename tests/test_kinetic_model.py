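"""Forward-model correctness: closed forms against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdgkin.kinetic_model import (
    FrameSchedule,
    KineticParams,
    TissueCurve,
    UndefinedRatioError,
    ce_cp,
    forward_tac,
    frame_average,
    frame_averaged_tac,
    impulse_response,
)
from fdgkin.plasma import FengInput, SampledInput

from conftest import ode_tissue_curve

rates = st.floats(min_value=0.0, max_value=0.5, allow_nan=False)


class TestImpulseResponse:
    def test_no_influx_is_identically_zero(self):
        terms = impulse_response(KineticParams(0.0, 0.2, 0.05, 0.01))
        assert all(c == 0 for c, _, _ in terms)

    def test_irreversible_case_hand_algebra(self):
        # k4 = 0: alpha1 = 0, alpha2 = k2+k3; B1 = k1 k3/(k2+k3), B2 = k1 k2/(k2+k3)
        terms = impulse_response(KineticParams(0.1, 0.2, 0.05, 0.0))
        (b1, a1, p1), (b2, a2, p2) = terms
        assert (p1, p2) == (0, 0)
        assert a1 == pytest.approx(0.0, abs=1e-15)
        assert a2 == pytest.approx(0.25)
        assert b1 == pytest.approx(0.02)
        assert b2 == pytest.approx(0.08)

    def test_amplitudes_sum_to_k1(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = KineticParams(*rng.uniform(0.01, 0.5, 4))
            terms = impulse_response(p)
            total = sum(c for c, _, pw in terms if pw == 0)
            assert total == pytest.approx(p.k1, rel=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-0.1, 0.2, 0.05, 0.0)


class TestForwardTac:
    def test_zero_input_gives_zero_tissue(self, schedule):
        plasma = FengInput(a1=0.0, a2=0.0, a3=0.0)
        tac = forward_tac(KineticParams(0.1, 0.2, 0.05, 0.01), plasma, schedule.mid_min)
        assert np.all(tac.values == 0.0)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_ode_oracle_parametric(self, schedule, seed):
        plasma = FengInput() if seed == 1 else FengInput(a1=120.0, a2=8.0, a3=2.0, lam1=2.0, lam2=0.3, lam3=0.02)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            p = KineticParams(
                rng.uniform(0.01, 0.3), rng.uniform(0.05, 0.5),
                rng.uniform(0.01, 0.2), rng.uniform(0.0, 0.05),
            )
            ana = forward_tac(p, plasma, schedule.mid_min).values
            ode = ode_tissue_curve(p, plasma, schedule.mid_min)
            assert np.max(np.abs(ana - ode)) / np.max(np.abs(ode)) < 1e-5

    def test_matches_ode_oracle_sampled(self, schedule, feng):
        plasma = SampledInput(schedule.mid_min, feng(schedule.mid_min))
        p = KineticParams(0.1, 0.2, 0.05, 0.005)
        t = np.linspace(0.5, 40.0, 60)
        ana = forward_tac(p, plasma, t).values
        ode = ode_tissue_curve(p, plasma, t)
        assert np.max(np.abs(ana - ode)) / np.max(np.abs(ode)) < 1e-5

    def test_constant_input_patlak_slope(self):
        # with Cp == 1 and k4 = 0, dC_T/dt tends to the net influx k1 k3/(k2+k3)
        p = KineticParams(0.1, 0.2, 0.05, 0.0)
        plasma = SampledInput(np.array([1.0, 1000.0]), np.array([1.0, 1.0]))
        t = np.array([200.0, 201.0])
        v = forward_tac(p, plasma, t).values
        slope = (v[1] - v[0]) / 1.0
        assert slope == pytest.approx(0.02, abs=1e-4)

    def test_k4_to_zero_continuity(self, schedule, feng):
        base = forward_tac(KineticParams(0.1, 0.2, 0.05, 0.0), feng, schedule.mid_min).values
        for k4 in (1e-6, 1e-9, 1e-12):
            v = forward_tac(KineticParams(0.1, 0.2, 0.05, k4), feng, schedule.mid_min).values
            assert np.max(np.abs(v - base)) < max(50 * k4, 1e-8)

    @pytest.mark.parametrize("k2_offset", [0.0, 5e-7, 2e-6])
    def test_repeated_root_branch_accuracy(self, schedule, feng, k2_offset):
        # k3 = 0, k2 = k4 is an exactly repeated root; check both the
        # degenerate branch and its immediate neighbourhood against the ODE
        p = KineticParams(0.1, 0.1 + k2_offset, 0.0, 0.1)
        ana = forward_tac(p, feng, schedule.mid_min).values
        ode = ode_tissue_curve(p, feng, schedule.mid_min)
        assert np.max(np.abs(ana - ode)) < 1e-8

    @settings(deadline=None, max_examples=25)
    @given(k1=rates, k2=rates, k3=rates, k4=st.floats(0.0, 0.05))
    def test_nonnegative_output(self, k1, k2, k3, k4):
        p = KineticParams(k1, k2, k3, k4)
        t = np.linspace(0.0, 43.0, 40)
        vals = forward_tac(p, FengInput(), t).values
        assert np.all(vals >= -1e-10)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        vals = frame_average(lambda t: np.full_like(np.asarray(t, float), 2.5), schedule)
        assert vals == pytest.approx(np.full(len(schedule), 2.5), rel=1e-12)

    def test_linear_curve_first_frame_midpoint(self):
        sched = FrameSchedule(((0.0, 30.0),))
        # rises linearly 0 -> 30 over the frame: mean is 15
        vals = frame_average(lambda t: t * 60.0, sched)
        assert vals[0] == pytest.approx(15.0, rel=1e-12)

    def test_conserves_total_integral(self, schedule, feng):
        p = KineticParams(0.1, 0.2, 0.05, 0.005)
        vals = frame_averaged_tac(p, feng, schedule)
        total = float(vals @ schedule.durations_min)
        from scipy.integrate import quad

        ref, _ = quad(lambda t: float(forward_tac(p, feng, [t]).values[0]), 0.0,
                      schedule.ends_min[-1], limit=400)
        assert total == pytest.approx(ref, rel=1e-8)

    def test_tissue_curve_input(self, schedule):
        curve = TissueCurve(np.linspace(0, 43, 200), np.linspace(0, 43, 200) ** 0)
        vals = frame_average(curve, schedule)
        assert vals == pytest.approx(np.ones(len(schedule)))

    def test_schedule_beyond_curve_support_rejected(self, schedule):
        short = TissueCurve(np.linspace(0, 20, 50), np.ones(50))
        with pytest.raises(ValueError, match="support"):
            frame_average(short, schedule)


class TestCeCp:
    @pytest.mark.parametrize(
        "k,lc,expected",
        [
            ((0.1, 0.2, 0.0, 0.0), 0.26, 0.5),  # k3=0 reduces to k1/k2
            ((0.10, 0.20, 0.052, 0.0), 0.26, 0.25),  # 0.1/(0.2 + 0.2)
        ],
    )
    def test_known_values(self, k, lc, expected):
        assert ce_cp(KineticParams(*k), lc) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_k1(self):
        p1 = KineticParams(0.1, 0.2, 0.05, 0.01)
        p2 = KineticParams(0.2, 0.2, 0.05, 0.01)
        assert ce_cp(p2) == pytest.approx(2.0 * ce_cp(p1), rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            ce_cp(KineticParams(0.1, 0.0, 0.0, 0.01))


class TestFrameSchedule:
    def test_default_matches_protocol(self, schedule):
        assert len(schedule) == 25
        assert schedule.ends_s[-1] == pytest.approx(2580.0)
        d = schedule.durations_s
        assert list(d[:12]) == [30.0] * 12
        assert list(d[12:15]) == [60.0] * 3
        assert list(d[15:18]) == [120.0] * 3
        assert list(d[18:]) == [240.0] * 7

    def test_rejects_overlap_and_gap(self):
        with pytest.raises(ValueError):
            FrameSchedule(((0.0, 30.0), (20.0, 60.0)))
        with pytest.raises(ValueError):
            FrameSchedule(((0.0, 30.0), (40.0, 60.0)))
        with pytest.raises(ValueError):
            FrameSchedule(((10.0, 10.0),))
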