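"""Plasma input curves.

Two concrete representations of the tracer concentration in plasma,
``Cp(t)``, are used throughout the package:

* :class:`FengInput` — a parametric tri-exponential bolus model used by the
  phantom simulator.  It is smooth, nonnegative by construction and has a
  closed-form integral, which makes it convenient both as a forward-model
  input and as an oracle in tests.
* :class:`SampledInput` — frame-sampled concentrations, e.g. an image-derived
  input function (IDIF).  Between samples the curve is piecewise linear and
  anchored at ``Cp(0) = 0``; beyond the last sample a single-exponential tail
  fitted to the final three samples is used.

All times are **minutes** and concentrations **kBq·ml⁻¹**.  File formats use
seconds; conversion happens at the I/O boundary (see :mod:`fdgkin.interfaces`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FengInput", "SampledInput", "PlasmaInput"]


class PlasmaValidationError(ValueError):
    """Raised when plasma-curve parameters would produce an invalid Cp(t)."""


@dataclass(frozen=True)
class FengInput:
    """Tri-exponential bolus input:

    ``Cp(t) = a1·t·e^{−λ1 t} + a2·(e^{−λ2 t} − e^{−λ1 t}) + a3·(e^{−λ3 t} − e^{−λ1 t})``

    with ``λ1 ≥ λ2 ≥ λ3 > 0`` and ``a1, a2, a3 ≥ 0``, which guarantees
    ``Cp(0) = 0`` and ``Cp(t) ≥ 0`` for all ``t ≥ 0``.

    Parameters
    ----------
    a1 : bolus amplitude, kBq·ml⁻¹·min⁻¹
    a2, a3 : exponential amplitudes, kBq·ml⁻¹
    lam1, lam2, lam3 : decay rates, min⁻¹

    Defaults give a bolus peaking around 20 s at ~25 kBq·ml⁻¹ with a slowly
    decaying tail of a few kBq·ml⁻¹ over a 43-min scan.
    """

    a1: float = 200.0
    a2: float = 5.0
    a3: float = 3.5
    lam1: float = 3.0
    lam2: float = 0.5
    lam3: float = 0.012

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0:
            raise PlasmaValidationError("amplitudes must be nonnegative")
        if not (self.lam1 >= self.lam2 >= self.lam3 > 0):
            raise PlasmaValidationError("decay rates must satisfy lam1 >= lam2 >= lam3 > 0")

    def terms(self) -> list[tuple[float, float, float]]:
        """Decompose into ``(c, d, lam)`` triples meaning ``(c + d·t)·e^{−lam·t}``."""
        return [
            (-(self.a2 + self.a3), self.a1, self.lam1),
            (self.a2, 0.0, self.lam2),
            (self.a3, 0.0, self.lam3),
        ]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, d, lam in self.terms():
            out = out + (c + d * t) * np.exp(-lam * t)
        return out

    def integral(self, t0: float, t1: float) -> float:
        """Closed-form ``∫_{t0}^{t1} Cp dt`` (kBq·ml⁻¹·min)."""

        def anti(t: float) -> float:
            # antiderivative of sum (c + d*t) e^{-lam t}
            total = 0.0
            for c, d, lam in self.terms():
                total += -(c / lam + d * (t / lam + 1.0 / lam**2)) * np.exp(-lam * t)
            return total

        return anti(t1) - anti(t0)


@dataclass(frozen=True)
class SampledInput:
    """Plasma input sampled at discrete times (typically frame mid-times).

    Piecewise linear through ``(0, 0)`` and the samples; beyond the last
    sample the curve decays as a single exponential fitted (log-linearly) to
    the final three samples.  If those samples are non-positive or
    non-decreasing, a flat tail at the last value is used instead.
    """

    times: np.ndarray  # minutes, strictly increasing, > 0
    values: np.ndarray  # kBq/ml, nonnegative
    tail_rate: float = field(init=False)  # min^-1, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise PlasmaValidationError("times and values must be matching 1-D arrays")
        if t.size < 2:
            raise PlasmaValidationError("at least two samples are required")
        if not np.all(np.diff(t) > 0) or t[0] <= 0:
            raise PlasmaValidationError("times must be strictly increasing and positive")
        if np.any(v < 0):
            raise PlasmaValidationError("sampled plasma values must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "tail_rate", self._fit_tail())

    def _fit_tail(self) -> float:
        t, v = self.times[-3:], self.values[-3:]
        if len(t) < 2 or np.any(v <= 0):
            return 0.0
        slope = np.polyfit(t, np.log(v), 1)[0]
        return max(0.0, -float(slope))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        inside = np.interp(t, np.concatenate(([0.0], self.times)), np.concatenate(([0.0], self.values)))
        tail = self.values[-1] * np.exp(-self.tail_rate * np.maximum(t - self.times[-1], 0.0))
        return np.where(t <= self.times[-1], inside, tail)

    def knots(self, t_end: float, n_tail: int = 5) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear node representation on ``[0, t_end]``.

        The exponential tail (if any) is discretized with ``n_tail`` extra
        nodes; the returned polyline is what the convolution engine
        integrates against.
        """
        kt = np.concatenate(([0.0], self.times))
        kv = np.concatenate(([0.0], self.values))
        if t_end > self.times[-1]:
            extra = np.linspace(self.times[-1], t_end, n_tail + 1)[1:]
            kt = np.concatenate([kt, extra])
            kv = np.concatenate([kv, self(extra)])
        return kt, kv


PlasmaInput = FengInput | SampledInput
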