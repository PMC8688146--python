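"""Fibre-photometry ΔF/F analysis.

A two-channel recording — calcium-dependent fluorescence excited at 465 nm
and a calcium-independent isosbestic control at 405 nm — is reduced to a
single signal ``F(t) = F465(t)/F405(t)``; the ratio cancels any
multiplicative artefact (movement, slow drift) shared by both channels.
``F0`` is the median of ``F`` during the pre-event baseline (10 min in the
emulated protocol), the fractional response is
``dF/F(%) = 100·(F(t) − F0)/F0``, and the post-event response magnitude is
its trapezoidal area under the curve (AUC) in %·min over a configurable
window (default: the full 20-min post-event recording).

No photobleaching correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhotometryTrace",
    "DffTrace",
    "ratio_signal",
    "baseline_f0",
    "dff",
    "response_auc",
    "simulate_trace",
    "analyze_trace",
]


@dataclass
class PhotometryTrace:
    """Two-channel fluorescence time series (times in seconds)."""

    times: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    event_time: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.f465 = np.asarray(self.f465, float)
        self.f405 = np.asarray(self.f405, float)
        if not (self.times.shape == self.f465.shape == self.f405.shape):
            raise ValueError("channels must have the same length as times")
        b0, b1 = self.baseline_window
        if not b0 < b1 <= self.event_time:
            raise ValueError("baseline window must precede the event time")


@dataclass
class DffTrace:
    """Fractional fluorescence change in percent, with its baseline F0."""

    times: np.ndarray
    dff_percent: np.ndarray
    f0: float


def ratio_signal(trace: PhotometryTrace) -> np.ndarray:
    """``F(t) = F465(t)/F405(t)``; requires a strictly positive 405 channel."""
    if np.any(trace.f405 <= 0):
        raise ValueError("isosbestic (405 nm) channel must be strictly positive")
    return trace.f465 / trace.f405


def baseline_f0(signal: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> float:
    """Median of the signal within the baseline window (robust to spikes).

    Even sample counts use the usual mid-mean median convention.
    """
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    return float(np.median(signal[sel]))


def dff(signal: np.ndarray, f0: float, times: np.ndarray | None = None) -> DffTrace:
    """``dF/F(%) = 100·(F(t) − F0)/F0``."""
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    t = np.arange(len(signal), dtype=float) if times is None else np.asarray(times, float)
    return DffTrace(times=t, dff_percent=100.0 * (np.asarray(signal, float) - f0) / f0, f0=f0)


def response_auc(trace: DffTrace, window: tuple[float, float]) -> float:
    """Trapezoidal ``∫ dF/F dt`` over the window, in %·min (times in seconds)."""
    t0, t1 = window
    if t0 < trace.times[0] - 1e-9 or t1 > trace.times[-1] + 1e-9:
        raise ValueError("AUC window lies outside the recorded trace")
    sel = (trace.times >= t0) & (trace.times <= t1)
    return float(np.trapezoid(trace.dff_percent[sel], trace.times[sel]) / 60.0)


def simulate_trace(
    response_amplitude: float = 0.2,
    onset_tau_s: float = 30.0,
    artefact_amplitude: float = 0.1,
    bleach_tau_s: float = 3600.0,
    noise_sd: float = 0.0,
    baseline_s: float = 600.0,
    post_s: float = 1200.0,
    rate_hz: float = 20.0,
    seed: int = 0,
) -> tuple[PhotometryTrace, DffTrace]:
    """Synthetic two-channel trace with known ground-truth dF/F.

    Both channels share a multiplicative artefact (slow sinusoid times a
    gentle bleaching trend); a saturating calcium response of fractional
    amplitude ``response_amplitude`` (e.g. 0.2 → +20% plateau) is applied to
    the 465-nm channel only, starting at the event.  Additive Gaussian noise
    of standard deviation ``noise_sd`` (channel units) is drawn per channel.

    Returns the trace and the ground-truth (noise- and artefact-free)
    dF/F trace.
    """
    n = int(round((baseline_s + post_s) * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    event = baseline_s
    rng = np.random.default_rng([seed, 31])

    artefact = (1.0 + artefact_amplitude * np.sin(2 * np.pi * t / 180.0)) * np.exp(-t / bleach_tau_s)
    rise = np.clip((t - event) / onset_tau_s, 0.0, 700.0)
    response = np.where(t >= event, -np.expm1(-rise), 0.0)
    f465_0, f405_0 = 2.0, 1.0
    f465 = f465_0 * artefact * (1.0 + response_amplitude * response)
    f405 = f405_0 * artefact
    if noise_sd > 0:
        f465 = f465 + rng.normal(0.0, noise_sd, n)
        f405 = f405 + rng.normal(0.0, noise_sd, n)

    trace = PhotometryTrace(
        times=t, f465=f465, f405=f405, event_time=event, baseline_window=(0.0, event)
    )
    truth = DffTrace(times=t, dff_percent=100.0 * response_amplitude * response, f0=f465_0 / f405_0)
    return trace, truth


def analyze_trace(
    trace: PhotometryTrace, auc_window_s: float | None = None
) -> tuple[DffTrace, float]:
    """Full pipeline: ratio → median baseline F0 → dF/F(%) → post-event AUC.

    ``auc_window_s`` limits the AUC integration to that many seconds after
    the event; by default the window extends to the end of the recording.
    """
    f = ratio_signal(trace)
    f0 = baseline_f0(f, trace.times, trace.baseline_window)
    d = dff(f, f0, trace.times)
    t_end = trace.times[-1] if auc_window_s is None else trace.event_time + auc_window_s
    auc = response_auc(d, (trace.event_time, t_end))
    return d, auc
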