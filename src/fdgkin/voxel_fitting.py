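"""Voxel-by-voxel weighted nonlinear least-squares estimation of k1–k4.

Each voxel's frame-averaged time-activity curve is fitted to the 2TC forward
model by bounded least squares (trust-region reflective), minimizing

    Σᵢ wᵢ·(TACᵢ − modelᵢ)²   with wᵢ = Δtᵢ by default,

so that longer (statistically better) frames weigh more.  A fixed start plus
a configurable number of seeded log-uniform multistarts guard against local
minima; the start with the lowest weighted residual sum of squares (WRSS)
wins, ties broken by lower k4.  Non-convergence flags the voxel instead of
raising.

Identical voxel TACs (e.g. noiseless phantom regions) are fitted once and
broadcast, which makes noiseless whole-image fits essentially free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .image import DynamicImage
from .input_function import EmptyMaskError
from .kinetic_model import (
    LC_DEFAULT,
    FrameSchedule,
    SampledFrameModel,
    cecp_from_arrays,
    conv_terms_model,
)
from .plasma import FengInput, PlasmaInput, SampledInput

__all__ = ["FitConfig", "VoxelFit", "ParametricMap", "brain_mask", "fit_voxel", "fit_image"]

log = logging.getLogger(__name__)

PARAM_NAMES = ("k1", "k2", "k3", "k4")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the voxel-wise fit.

    Bounds are generous physiological ranges for FDG in brain; k4 is small
    and may optionally be fixed (``fix_k4``) for the common irreversible
    variant.  ``weight_rule`` is ``"duration"`` (default) or ``"uniform"``.
    """

    bounds: tuple[tuple[float, float], ...] = ((0.0, 2.0), (0.0, 2.0), (0.0, 2.0), (0.0, 0.2))
    init: tuple[float, ...] = (0.1, 0.1, 0.05, 0.01)
    n_multistart: int = 4
    weight_rule: str = "duration"
    ftol: float = 1e-8
    xtol: float = 1e-10
    max_nfev: int = 500
    mask_quantile: float = 0.0
    fix_k4: float | None = None
    lc: float = LC_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        for (lo, hi), x0 in zip(self.bounds, self.init):
            if not lo <= x0 <= hi:
                raise ValueError("initial values must lie within bounds")
        if self.weight_rule not in ("duration", "uniform"):
            raise ValueError("weight_rule must be 'duration' or 'uniform'")


@dataclass
class VoxelFit:
    """Result of a single-voxel fit."""

    k1: float
    k2: float
    k3: float
    k4: float
    wrss: float
    converged: bool
    n_starts: int

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4])


@dataclass
class ParametricMap:
    """Per-voxel rate constants, Ce/Cp, WRSS and convergence bookkeeping.

    Voxels outside the mask or without a converged fit are NaN.
    """

    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    k4: np.ndarray
    cecp: np.ndarray
    wrss: np.ndarray
    converged: np.ndarray  # bool volume
    mask: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray
    n_unconverged: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _frame_model(plasma: PlasmaInput, schedule: FrameSchedule):
    """Callable k-tuple -> frame means, with per-(plasma, schedule) precompute."""
    if isinstance(plasma, SampledInput):
        return SampledFrameModel(plasma, schedule).frame_means_raw
    if isinstance(plasma, FengInput):
        return conv_terms_model(plasma, schedule)
    raise TypeError(f"unsupported plasma input type: {type(plasma)!r}")


def brain_mask(
    image: DynamicImage,
    threshold_quantile: float = 0.0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels with time-integrated activity at or above the given quantile of
    the nonzero voxels' integrals; an ``exclude`` mask (e.g. blood pool) is
    removed."""
    integ = image.data @ image.schedule.durations_s
    nonzero = integ > 0
    if not nonzero.any():
        raise EmptyMaskError("image has no voxels with positive integrated activity")
    thr = np.quantile(integ[nonzero], threshold_quantile)
    mask = nonzero & (integ >= thr)
    if exclude is not None:
        mask &= ~np.asarray(exclude, bool)
    if not mask.any():
        raise EmptyMaskError("brain mask is empty")
    return mask


def _starts(config: FitConfig) -> list[np.ndarray]:
    starts = [np.asarray(config.init, float)]
    rng = np.random.default_rng([config.seed, 23])
    lows = np.array([max(lo, hi * 1e-3) for lo, hi in config.bounds])
    highs = np.array([hi for _, hi in config.bounds])
    for _ in range(config.n_multistart):
        starts.append(np.exp(rng.uniform(np.log(lows), np.log(highs))))
    return starts


def fit_voxel(
    tac: np.ndarray,
    schedule: FrameSchedule,
    plasma: PlasmaInput,
    config: FitConfig = FitConfig(),
    _model=None,
    _starts_cache=None,
) -> VoxelFit:
    """Fit one frame-averaged TAC; returns parameters and diagnostics."""
    tac = np.asarray(tac, float)
    if tac.shape != (len(schedule),):
        raise ValueError("TAC length must match the frame schedule")
    if not np.all(np.isfinite(tac)):
        raise ValueError("TAC contains non-finite values")
    model = _model if _model is not None else _frame_model(plasma, schedule)
    if config.weight_rule == "duration":
        w = schedule.durations_min
    else:
        w = np.ones(len(schedule))
    sqrt_w = np.sqrt(w)

    fix4 = config.fix_k4
    if fix4 is None:

        def residual(x):
            return sqrt_w * (model(x[0], x[1], x[2], x[3]) - tac)

        lo = np.array([b[0] for b in config.bounds])
        hi = np.array([b[1] for b in config.bounds])
        starts = _starts_cache if _starts_cache is not None else _starts(config)
    else:

        def residual(x):
            return sqrt_w * (model(x[0], x[1], x[2], fix4) - tac)

        lo = np.array([b[0] for b in config.bounds[:3]])
        hi = np.array([b[1] for b in config.bounds[:3]])
        starts = [s[:3] for s in (_starts_cache if _starts_cache is not None else _starts(config))]

    best = None
    any_converged = False
    for x0 in starts:
        res = least_squares(
            residual,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=1e-12,
            max_nfev=config.max_nfev,
        )
        wrss = float(res.cost * 2.0)
        k4 = fix4 if fix4 is not None else res.x[3]
        cand = (wrss, k4, res.x, res.status > 0)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
        any_converged = any_converged or res.status > 0
    wrss, k4, x, conv = best
    if fix4 is not None:
        x = np.append(x, fix4)
    return VoxelFit(*(float(v) for v in x), wrss=wrss, converged=bool(conv), n_starts=len(starts))


def fit_image(
    image: DynamicImage,
    plasma: PlasmaInput,
    config: FitConfig = FitConfig(),
    mask: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> ParametricMap:
    """Apply :func:`fit_voxel` over a brain mask and assemble parametric maps.

    Unmasked voxels are NaN; non-converged voxels are NaN and counted.
    Duplicate TACs are fitted once.
    """
    span = image.schedule.span_min
    if isinstance(plasma, SampledInput):
        # SampledInput extrapolates its tail, but require samples inside the scan
        if plasma.times[0] > span[1]:
            raise ValueError("plasma input does not cover the frame schedule")
    if mask is None:
        mask = brain_mask(image, config.mask_quantile, exclude=exclude)
    elif exclude is not None:
        mask = np.asarray(mask, bool) & ~np.asarray(exclude, bool)
    if not mask.any():
        raise EmptyMaskError("empty fit mask")

    model = _frame_model(plasma, image.schedule)
    starts = _starts(config)
    tacs = image.data[mask]
    uniq, inverse = np.unique(tacs, axis=0, return_inverse=True)
    log.info("fitting %d voxels (%d unique TACs)", tacs.shape[0], uniq.shape[0])

    fits = []
    for i, tac in enumerate(uniq):
        fits.append(
            fit_voxel(tac, image.schedule, plasma, config, _model=model, _starts_cache=starts)
        )
        if (i + 1) % 500 == 0:
            log.info("  %d / %d unique TACs fitted", i + 1, uniq.shape[0])

    shape = image.shape3d
    vols = {name: np.full(shape, np.nan) for name in PARAM_NAMES + ("wrss",)}
    conv = np.zeros(shape, bool)
    params_arr = np.array([f.as_array() for f in fits])[inverse]
    wrss_arr = np.array([f.wrss for f in fits])[inverse]
    conv_arr = np.array([f.converged for f in fits])[inverse]
    for j, name in enumerate(PARAM_NAMES):
        v = np.full(shape, np.nan)
        vals = params_arr[:, j].copy()
        vals[~conv_arr] = np.nan
        v[mask] = vals
        vols[name] = v
    wrss_vol = np.full(shape, np.nan)
    wrss_vol[mask] = wrss_arr
    conv[mask] = conv_arr

    cecp = cecp_from_arrays(vols["k1"], vols["k2"], vols["k3"], lc=config.lc)
    n_unconv = int(mask.sum() - conv.sum())
    if n_unconv:
        log.warning("%d voxels did not converge", n_unconv)
    return ParametricMap(
        k1=vols["k1"],
        k2=vols["k2"],
        k3=vols["k3"],
        k4=vols["k4"],
        cecp=cecp,
        wrss=wrss_vol,
        converged=conv,
        mask=np.asarray(mask, bool),
        voxel_dims=image.voxel_dims,
        affine=image.affine,
        n_unconverged=n_unconv,
    )
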