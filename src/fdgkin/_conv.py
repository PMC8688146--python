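"""Convolution kernels for exponential impulse responses.

The two-tissue-compartment impulse response is a sum of (at most two)
exponentials, possibly with a ``t·e^{−αt}`` term in the repeated-root limit.
This module provides exact convolution of such kernels with

* parametric exponential-mixture inputs (``(c + d·t)·e^{−λt}`` terms), via
  closed forms with series fallbacks near the removable singularity
  ``α → λ``; and
* piecewise-linear sampled inputs, via an exact per-segment recursion
  (numba-compiled) based on the stable φ-functions
  ``φ1 = (1−e^{−x})/x``, ``φ2 = (e^{−x}−1+x)/x²``, ``φ3 = (1−e^{−x}−x+x²/2)/x³``.

Everything here works in minutes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SERIES_X = 1e-3  # |x| below which series expansions replace closed forms


def conv_exp_pair(alpha: float, lam: float, t: np.ndarray):
    """Convolutions of ``t^p e^{−αt}`` (p = 0, 1) with ``s^q e^{−λs}`` (q = 0, 1).

    Returns ``(F, G, H, K)`` evaluated at each ``t``::

        F = ∫ e^{−α(t−s)} e^{−λs} ds          (p=0, q=0)
        G = ∫ e^{−α(t−s)} s e^{−λs} ds        (p=0, q=1)
        H = ∫ (t−s) e^{−α(t−s)} e^{−λs} ds    (p=1, q=0)
        K = ∫ (t−s) e^{−α(t−s)} s e^{−λs} ds  (p=1, q=1)

    Stable for any nonnegative rates, including α ≈ λ.
    """
    t = np.asarray(t, dtype=float)
    mu = alpha - lam
    x = mu * t
    ea = np.exp(-alpha * t)
    el = np.exp(-lam * t)
    small = np.abs(x) < _SERIES_X
    with np.errstate(divide="ignore", invalid="ignore"):
        F_big = (el - ea) / mu
        G_big = (t * el - F_big) / mu
        K_big = t * G_big - (t * t * el - 2.0 * G_big) / mu
    F_small = ea * t * (1.0 + x / 2 + x * x / 6 + x**3 / 24)
    G_small = ea * t * t * (0.5 + x / 3 + x * x / 8 + x**3 / 30)
    K_small = ea * t**3 * (1.0 / 6 + x / 12 + x * x / 40 + x**3 / 180)
    F = np.where(small, F_small, F_big)
    G = np.where(small, G_small, G_big)
    K = np.where(small, K_small, K_big)
    H = t * F - G
    return F, G, H, K


def conv_terms(impulse_terms, cp_terms, t: np.ndarray) -> np.ndarray:
    """Convolve an exponential-mixture impulse response with a parametric input.

    ``impulse_terms``: iterable of ``(coef, alpha, p)`` meaning
    ``coef · t^p · e^{−αt}`` with ``p ∈ {0, 1}``.
    ``cp_terms``: iterable of ``(c, d, lam)`` meaning ``(c + d·t)·e^{−λt}``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for coef, alpha, p in impulse_terms:
        if coef == 0.0:
            continue
        for c, d, lam in cp_terms:
            F, G, H, K = conv_exp_pair(alpha, lam, t)
            if p == 0:
                out = out + coef * (c * F + d * G)
            else:
                out = out + coef * (c * H + d * K)
    return out


@njit(cache=True)
def _phi123(x):
    if abs(x) < _SERIES_X:
        phi1 = 1.0 - x / 2 + x * x / 6 - x * x * x / 24
        phi2 = 0.5 - x / 6 + x * x / 24 - x * x * x / 120
        phi3 = 1.0 / 6 - x / 24 + x * x / 120 - x * x * x / 720
        e = math.exp(-x)
    else:
        e = math.exp(-x)
        phi1 = (1.0 - e) / x
        phi2 = (e - 1.0 + x) / (x * x)
        phi3 = (1.0 - e - x + x * x / 2) / (x * x * x)
    return e, phi1, phi2, phi3


@njit(cache=True)
def lin_conv_frame_sums(alpha, bt, c0, m, seg_frame, n_frames):
    """Exact ``∫ y dt`` per frame for ``y' = Cp(t) − α·y``, ``y(0) = 0``.

    ``Cp`` is piecewise linear: on segment i spanning ``[bt[i], bt[i+1]]`` it
    equals ``c0[i] + m[i]·(t − bt[i])``.  ``seg_frame[i]`` maps segment i to
    its frame.  Returns per-frame integrals of y (divide by frame durations
    for means).
    """
    acc = np.zeros(n_frames)
    y = 0.0
    for i in range(c0.shape[0]):
        dt = bt[i + 1] - bt[i]
        e, p1, p2, p3 = _phi123(alpha * dt)
        acc[seg_frame[i]] += y * dt * p1 + c0[i] * dt * dt * p2 + m[i] * dt**3 * p3
        y = y * e + c0[i] * dt * p1 + m[i] * dt * dt * p2
    return acc


@njit(cache=True)
def lin_conv_values(alpha, bt, c0, m):
    """``y = e^{−αt} ⊗ Cp`` at every breakpoint of a piecewise-linear Cp."""
    y = np.zeros(bt.shape[0])
    for i in range(c0.shape[0]):
        dt = bt[i + 1] - bt[i]
        e, p1, p2, _ = _phi123(alpha * dt)
        y[i + 1] = y[i] * e + c0[i] * dt * p1 + m[i] * dt * dt * p2
    return y
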