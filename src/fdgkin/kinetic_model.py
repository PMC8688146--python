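"""Two-tissue-compartment (2TC) forward model for [18F]FDG.

The model has a free-tracer compartment exchanging with plasma (rates ``k1``,
``k2``) and a phosphorylated compartment (``k3``, ``k4``)::

    dC_free/dt  = k1·Cp − (k2 + k3)·C_free + k4·C_bound
    dC_bound/dt = k3·C_free − k4·C_bound

Total tissue activity ``C_T = C_free + C_bound`` responds to a unit impulse
in plasma with ``h(t) = B1·e^{−α1 t} + B2·e^{−α2 t}`` where::

    α1,2 = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4)] / 2
    B1   = k1·(k3 + k4 − α1)/(α2 − α1)
    B2   = k1·(α2 − k3 − k4)/(α2 − α1)

so that ``B1 + B2 = k1``.  When the two roots coincide the degenerate limit
``h(t) = k1·e^{−αt}·(1 + (k3 + k4 − α)·t)`` is used.

Glucose transport is summarized by the tissue-to-plasma glucose ratio
``Ce/Cp = k1/(k2 + k3/LC)`` with a lumped-constant-type factor ``LC`` that
defaults to 0.26.

Units: rate constants per minute (``k1`` in ml·cm⁻³·min⁻¹), times in minutes,
concentrations in kBq·ml⁻¹.  Frame schedules are specified in seconds (as on
disk) and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._conv import conv_terms, lin_conv_frame_sums, lin_conv_values
from .plasma import FengInput, PlasmaInput, SampledInput

__all__ = [
    "KineticParams",
    "FrameSchedule",
    "TissueCurve",
    "LC_DEFAULT",
    "impulse_response",
    "forward_tac",
    "frame_average",
    "frame_averaged_tac",
    "ce_cp",
]

LC_DEFAULT = 0.26
#: threshold on |α2 − α1| (min⁻¹) below which the repeated-root form is used;
#: below it the two-exponential closed form loses precision to cancellation
#: (error ~ eps/|α2−α1|) while the degenerate form is off by only O(|α2−α1|²)
REPEATED_ROOT_TOL = 1e-6

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


class UndefinedRatioError(ZeroDivisionError):
    """Ce/Cp denominator is zero (k2 = k3 = 0)."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the 2TC model; all nonnegative.

    k1 : ml·cm⁻³·min⁻¹ (plasma-to-tissue transport)
    k2 : min⁻¹ (efflux), k3 : min⁻¹ (phosphorylation), k4 : min⁻¹ (dephosphorylation)
    """

    k1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be nonnegative")
        s = self.k2 + self.k3 + self.k4
        if not np.isfinite(s):
            raise ValueError("rate constants must be finite")
        # discriminant is automatically nonnegative for nonnegative rates
        assert s * s - 4.0 * self.k2 * self.k4 >= -1e-12 * max(1.0, s * s)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k1, self.k2, self.k3, self.k4)


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping emission time frames, in seconds."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        f = tuple((float(a), float(b)) for a, b in self.frames)
        if not f:
            raise ValueError("schedule needs at least one frame")
        for a, b in f:
            if not b > a:
                raise ValueError("each frame must satisfy start < end")
        for (_, b0), (a1, _) in zip(f[:-1], f[1:]):
            if abs(a1 - b0) > 1e-9:
                raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frames", f)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """25-frame schedule: 12×30 s, 3×60 s, 3×120 s, 7×240 s (total 2580 s)."""
        durations = [30.0] * 12 + [60.0] * 3 + [120.0] * 3 + [240.0] * 7
        edges = np.concatenate(([0.0], np.cumsum(durations)))
        return cls(tuple(zip(edges[:-1], edges[1:])))

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], start_s: float = 0.0) -> "FrameSchedule":
        edges = start_s + np.concatenate(([0.0], np.cumsum(np.asarray(durations_s, float))))
        return cls(tuple(zip(edges[:-1], edges[1:])))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    @property
    def ends_s(self) -> np.ndarray:
        return np.array([b for _, b in self.frames])

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.starts_s + self.ends_s)

    @property
    def starts_min(self) -> np.ndarray:
        return self.starts_s / 60.0

    @property
    def ends_min(self) -> np.ndarray:
        return self.ends_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def span_min(self) -> tuple[float, float]:
        return (self.starts_min[0], self.ends_min[-1])


@dataclass(frozen=True)
class TissueCurve:
    """Sampled tissue concentration (kBq·ml⁻¹) at given times (minutes)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape:
            raise ValueError("times and values must have matching shapes")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


def impulse_response(params: KineticParams) -> list[tuple[float, float, int]]:
    """Exponential-mixture representation of the tissue impulse response.

    Returns ``(coef, alpha, p)`` terms meaning ``coef·t^p·e^{−αt}``.  In the
    generic case two ``p = 0`` terms; in the repeated-root limit
    (|α2 − α1| < ``REPEATED_ROOT_TOL``) one ``p = 0`` and one ``p = 1`` term.
    """
    k1, k2, k3, k4 = params.as_tuple()
    if k1 == 0.0:
        return [(0.0, 0.0, 0)]
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < REPEATED_ROOT_TOL:
        a = 0.5 * (a1 + a2)
        return [(k1, a, 0), (k1 * (k3 + k4 - a), a, 1)]
    b1 = k1 * (k3 + k4 - a1) / (a2 - a1)
    b2 = k1 * (a2 - k3 - k4) / (a2 - a1)
    return [(b1, a1, 0), (b2, a2, 0)]


def _exp_pairs_split(params: KineticParams, split: float = 1e-6):
    return exp_pairs_raw(*params.as_tuple(), split=split)


def exp_pairs_raw(k1: float, k2: float, k3: float, k4: float, split: float = 1e-6):
    """Impulse response as exactly two ``(B, α)`` pairs.

    Near a repeated root the two rates are symmetrically separated by
    ``split`` (min⁻¹); the resulting secant form approximates the degenerate
    limit to O(split²) while keeping the downstream sampled-input recursion a
    pure two-exponential sum.
    """
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < split:
        a = 0.5 * (a1 + a2)
        a1 = max(a - 0.5 * split, 0.0)
        a2 = a1 + split
    b1 = k1 * (k3 + k4 - a1) / (a2 - a1)
    b2 = k1 * (a2 - k3 - k4) / (a2 - a1)
    return (b1, a1), (b2, a2)


class SampledFrameModel:
    """Precomputed forward model for one (sampled plasma, schedule) pair.

    Building the merged breakpoint grid (plasma knots ∪ frame edges) once and
    reusing it across voxels/iterations is what makes voxel-wise nonlinear
    fitting against an IDIF affordable.
    """

    def __init__(self, plasma: SampledInput, schedule: FrameSchedule):
        self.schedule = schedule
        t_end = schedule.ends_min[-1]
        kt, kv = plasma.knots(t_end)
        if kt[-1] < t_end - 1e-12:
            raise ValueError("plasma input does not cover the frame schedule")
        edges = np.unique(np.concatenate([schedule.starts_min, schedule.ends_min]))
        bt = np.unique(np.concatenate([kt, edges]))
        bt = bt[(bt >= 0.0) & (bt <= t_end + 1e-12)]
        cv = np.interp(bt, kt, kv)
        self.bt = bt
        self.c0 = cv[:-1]
        self.m = np.diff(cv) / np.diff(bt)
        mids = 0.5 * (bt[:-1] + bt[1:])
        self.seg_frame = np.searchsorted(schedule.ends_min, mids, side="right").astype(np.int64)
        self.n_frames = len(schedule)
        self.durations = schedule.durations_min

    def basis(self, alpha: float) -> np.ndarray:
        """Frame means of ``e^{−αt} ⊗ Cp``."""
        sums = lin_conv_frame_sums(alpha, self.bt, self.c0, self.m, self.seg_frame, self.n_frames)
        return sums / self.durations

    def frame_means(self, params: KineticParams) -> np.ndarray:
        (b1, a1), (b2, a2) = _exp_pairs_split(params)
        return b1 * self.basis(a1) + b2 * self.basis(a2)

    def frame_means_raw(self, k1: float, k2: float, k3: float, k4: float) -> np.ndarray:
        (b1, a1), (b2, a2) = exp_pairs_raw(k1, k2, k3, k4)
        return b1 * self.basis(a1) + b2 * self.basis(a2)

    def values(self, params: KineticParams, times_min: np.ndarray) -> np.ndarray:
        times_min = np.asarray(times_min, float)
        bt = np.unique(np.concatenate([self.bt, times_min]))
        full_cv = np.interp(bt, self.bt, self._cp_at_breaks())
        c0 = full_cv[:-1]
        m = np.diff(full_cv) / np.diff(bt)
        (b1, a1), (b2, a2) = _exp_pairs_split(params)
        y = b1 * lin_conv_values(a1, bt, c0, m) + b2 * lin_conv_values(a2, bt, c0, m)
        return np.interp(times_min, bt, y)

    def _cp_at_breaks(self) -> np.ndarray:
        return np.append(self.c0, self.c0[-1] + self.m[-1] * (self.bt[-1] - self.bt[-2]))


def conv_terms_model(plasma: FengInput, schedule: FrameSchedule):
    """Fast frame-means evaluator for a parametric input.

    Precomputes the Gauss–Legendre node grid once; the returned callable maps
    raw ``(k1, k2, k3, k4)`` to frame-averaged tissue activity via the
    analytic convolution.
    """
    starts, ends = schedule.starts_min, schedule.ends_min
    half = 0.5 * (ends - starts)
    mid = 0.5 * (ends + starts)
    nodes = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    cp_terms = plasma.terms()
    n_frames = len(schedule)
    weights = _GL_WEIGHTS / 2.0

    def frame_means_raw(k1: float, k2: float, k3: float, k4: float) -> np.ndarray:
        (b1, a1), (b2, a2) = exp_pairs_raw(k1, k2, k3, k4)
        vals = conv_terms([(b1, a1, 0), (b2, a2, 0)], cp_terms, nodes)
        return vals.reshape(n_frames, -1) @ weights

    return frame_means_raw


def forward_tac(params: KineticParams, plasma: PlasmaInput, times_min) -> TissueCurve:
    """Tissue curve ``C_T(t) = (h ⊗ Cp)(t)`` at the requested times (minutes).

    Parametric inputs are convolved analytically; sampled inputs by the exact
    piecewise-linear recursion.
    """
    times_min = np.atleast_1d(np.asarray(times_min, float))
    if np.any(np.diff(times_min) < 0):
        raise ValueError("times must be nondecreasing")
    if isinstance(plasma, FengInput):
        vals = conv_terms(impulse_response(params), plasma.terms(), times_min)
    elif isinstance(plasma, SampledInput):
        sched = FrameSchedule(((0.0, max(float(times_min[-1]), 1e-6) * 60.0),))
        model = SampledFrameModel(plasma, sched)
        vals = model.values(params, times_min)
    else:
        raise TypeError(f"unsupported plasma input type: {type(plasma)!r}")
    return TissueCurve(times_min, vals)


def frame_average(curve: Callable[[np.ndarray], np.ndarray] | TissueCurve, schedule: FrameSchedule) -> np.ndarray:
    """Mean value of a continuous curve over each frame.

    ``value_i = (1/Δt_i)·∫ curve dt`` over frame i, computed with 12-point
    Gauss–Legendre quadrature per frame (exact to machine precision for
    smooth curves), so that ``Σ value_i·Δt_i`` conserves the total integral.
    """
    starts, ends = schedule.starts_min, schedule.ends_min
    if isinstance(curve, TissueCurve):
        if ends[-1] > curve.times[-1] + 1e-9 or starts[0] < curve.times[0] - 1e-9:
            raise ValueError("frame schedule extends beyond the curve's support")
    half = 0.5 * (ends - starts)
    mid = 0.5 * (ends + starts)
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = np.asarray(curve(nodes.ravel()), float).reshape(nodes.shape)
    return vals @ (_GL_WEIGHTS / 2.0)


def frame_averaged_tac(params: KineticParams, plasma: PlasmaInput, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged tissue activity — the quantity a PET frame measures."""
    if isinstance(plasma, SampledInput):
        return SampledFrameModel(plasma, schedule).frame_means(params)
    return frame_average(lambda t: forward_tac(params, plasma, t).values, schedule)


def ce_cp(params: KineticParams, lc: float = LC_DEFAULT) -> float:
    """Tissue-to-plasma glucose concentration ratio ``k1/(k2 + k3/lc)``."""
    if lc <= 0:
        raise ValueError("lumped-constant factor must be positive")
    denom = params.k2 + params.k3 / lc
    if denom <= 0:
        raise UndefinedRatioError("Ce/Cp undefined: k2 + k3/lc is zero")
    return params.k1 / denom


def cecp_from_arrays(k1, k2, k3, lc: float = LC_DEFAULT) -> np.ndarray:
    """Vectorized Ce/Cp; voxels with zero denominator become NaN."""
    denom = np.asarray(k2, float) + np.asarray(k3, float) / lc
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, np.asarray(k1, float) / denom, np.nan)
    return out
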