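"""Voxel-wise paired statistics on Ce/Cp maps.

The cross-over design gives every subject one saline and one insulin scan,
so condition differences are tested voxel-by-voxel with a paired two-sided
Student's t-test on the subject-wise differences (saline − insulin).  From
the resulting 3-D p-map, contiguous significant clusters become volumes of
interest (VOIs) that are re-tested at the region level on subject-mean
Ce/Cp.  A trilinear resampling of the p-map onto a finer grid is provided
for presentation only and never feeds back into inference.

No multiple-comparison correction is applied to the voxel-wise map by
default (the VOI re-test is the confirmatory step); interpret voxel-wise
p-values accordingly.  An FDR (Benjamini–Hochberg) option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .phantom import RegionAtlas

__all__ = [
    "PairedMapSet",
    "PValueMap",
    "VOI",
    "VOISummary",
    "paired_tmap",
    "define_vois",
    "voi_test",
    "resample_pmap",
    "fdr_correct",
]

log = logging.getLogger(__name__)

_MIN_P = np.finfo(float).tiny


@dataclass
class PairedMapSet:
    """Congruent per-subject Ce/Cp maps for both conditions.

    ``saline`` and ``insulin`` are stacked (subject, x, y, z) arrays; NaN
    marks undefined voxels (outside mask or non-converged fits).
    """

    saline: np.ndarray
    insulin: np.ndarray
    subjects: tuple[str, ...]
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.saline = np.asarray(self.saline, float)
        self.insulin = np.asarray(self.insulin, float)
        if self.saline.shape != self.insulin.shape:
            raise ValueError("condition map stacks must be congruent")
        if self.saline.ndim != 4 or self.saline.shape[0] != len(self.subjects):
            raise ValueError("expected (subject, x, y, z) stacks matching the subject list")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_parametric_maps(cls, subjects, saline_maps, insulin_maps) -> "PairedMapSet":
        ref = saline_maps[0]
        return cls(
            saline=np.stack([m.cecp for m in saline_maps]),
            insulin=np.stack([m.cecp for m in insulin_maps]),
            subjects=tuple(subjects),
            voxel_dims=ref.voxel_dims,
            affine=ref.affine,
        )


@dataclass
class PValueMap:
    """Voxel-wise paired t statistics.

    ``sign`` is +1 where mean(saline − insulin) > 0 (saline > insulin).
    ``defined`` marks voxels where every subject has both conditions defined.
    ``n_degenerate`` counts zero-variance voxels with nonzero mean whose p was
    set to the smallest representable value.
    """

    t: np.ndarray
    p: np.ndarray
    sign: np.ndarray
    df: int
    defined: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray
    n_degenerate: int = 0
    presentation_only: bool = False


def paired_tmap(maps: PairedMapSet) -> PValueMap:
    """Two-sided paired t-test per voxel on subject-wise condition differences."""
    n = maps.n_subjects
    if n < 3:
        raise ValueError("paired t-test requires at least 3 subjects")
    d = maps.saline - maps.insulin
    defined = np.all(np.isfinite(maps.saline), axis=0) & np.all(np.isfinite(maps.insulin), axis=0)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    df = n - 1
    shape = mean.shape

    t = np.zeros(shape)
    p = np.ones(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = sd / np.sqrt(n)
        t_raw = mean / se
    regular = defined & (sd > 0)
    t[regular] = t_raw[regular]
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df)
    p[regular] = np.minimum(p[regular], 1.0)

    degen = defined & (sd == 0) & (mean != 0)
    n_degen = int(degen.sum())
    if n_degen:
        log.warning("%d voxels have zero-variance nonzero differences", n_degen)
        t[degen] = np.sign(mean[degen]) * np.inf
        p[degen] = _MIN_P
    # zero-variance zero-mean voxels keep t=0, p=1

    t[~defined] = np.nan
    p[~defined] = np.nan
    sign = np.sign(mean)
    sign[~defined] = 0.0
    return PValueMap(
        t=t, p=p, sign=sign, df=df, defined=defined,
        voxel_dims=maps.voxel_dims, affine=maps.affine, n_degenerate=n_degen,
    )


@dataclass
class VOI:
    """Connected significant cluster, split by effect direction."""

    name: str
    voxels: np.ndarray  # boolean volume
    direction: str  # "saline>insulin" or "insulin>saline"
    n_voxels: int


_CONN6 = ndimage.generate_binary_structure(3, 1)


def define_vois(
    pmap: PValueMap,
    alpha: float = 0.05,
    min_voxels: int = 4,
    atlas: RegionAtlas | None = None,
) -> list[VOI]:
    """Connected components (6-neighbourhood) of ``p < alpha``, per direction,
    of at least ``min_voxels`` voxels, named after the dominant overlapping
    atlas region when an atlas is given."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    vois: list[VOI] = []
    sig = pmap.defined & (pmap.p < alpha)
    for sgn, direction in ((1.0, "saline>insulin"), (-1.0, "insulin>saline")):
        labels, n = ndimage.label(sig & (pmap.sign == sgn), structure=_CONN6)
        for comp in range(1, n + 1):
            vox = labels == comp
            size = int(vox.sum())
            if size < min_voxels:
                continue
            name = f"{direction}_{len(vois) + 1}"
            if atlas is not None:
                overlap = atlas.label_volume[vox]
                overlap = overlap[overlap > 0]
                if overlap.size:
                    dominant = np.bincount(overlap).argmax()
                    name = atlas.names[int(dominant)]
            vois.append(VOI(name=name, voxels=vox, direction=direction, n_voxels=size))
    return vois


@dataclass
class VOISummary:
    """Region-level paired re-test on subject-mean Ce/Cp over a VOI."""

    name: str
    direction: str
    n_voxels: int
    mean_saline: float
    mean_insulin: float
    mean_diff: float
    ratio: float  # insulin / saline
    t: float
    df: int
    p: float
    degenerate: bool = False
    subjects_dropped: tuple[str, ...] = field(default_factory=tuple)


def voi_test(voi: VOI, maps: PairedMapSet) -> VOISummary:
    """Paired two-sided t-test on per-subject VOI-mean Ce/Cp."""
    if not voi.voxels.any():
        raise ValueError("VOI is empty")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN subjects handled below
        mean_s = np.array([np.nanmean(m[voi.voxels]) for m in maps.saline])
        mean_i = np.array([np.nanmean(m[voi.voxels]) for m in maps.insulin])
    ok = np.isfinite(mean_s) & np.isfinite(mean_i)
    dropped = tuple(s for s, k in zip(maps.subjects, ok) if not k)
    if dropped:
        log.warning("VOI %s: dropping subjects with no defined voxels: %s", voi.name, dropped)
    mean_s, mean_i = mean_s[ok], mean_i[ok]
    n = len(mean_s)
    if n < 3:
        raise ValueError("fewer than 3 subjects with defined VOI values")
    d = mean_s - mean_i
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        degenerate = True
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0 else _MIN_P
    else:
        degenerate = False
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return VOISummary(
        name=voi.name,
        direction=voi.direction,
        n_voxels=voi.n_voxels,
        mean_saline=float(mean_s.mean()),
        mean_insulin=float(mean_i.mean()),
        mean_diff=float(d.mean()),
        ratio=float(mean_i.mean() / mean_s.mean()) if mean_s.mean() != 0 else np.nan,
        t=t,
        df=df,
        p=p,
        degenerate=degenerate,
        subjects_dropped=dropped,
    )


def resample_pmap(pmap: PValueMap, target_spacing: tuple[float, float, float]) -> PValueMap:
    """Trilinear resampling of the p-map onto a finer grid — presentation only.

    The source statistics are untouched; the returned map carries
    ``presentation_only=True`` and interpolated p-values (undefined source
    voxels are treated as p = 1).  Spacing must be positive and no larger
    than the volume extent.
    """
    target = np.asarray(target_spacing, float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    src = np.asarray(pmap.voxel_dims, float)
    shape = np.asarray(pmap.p.shape)
    extent = src * (shape - 1)
    if np.any(target > np.maximum(extent, src)):
        raise ValueError("target spacing exceeds the volume extent")

    filled = np.where(pmap.defined, pmap.p, 1.0)
    step = target / src  # target-grid step in source voxel units
    axes = [np.arange(0.0, shape[i] - 1 + 1e-9, step[i]) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    new_p = ndimage.map_coordinates(filled, coords, order=1, mode="nearest").reshape(
        [len(a) for a in axes]
    )
    new_sign = ndimage.map_coordinates(
        np.where(pmap.defined, pmap.sign, 0.0), coords, order=0, mode="nearest"
    ).reshape(new_p.shape)
    new_defined = (
        ndimage.map_coordinates(pmap.defined.astype(float), coords, order=0, mode="nearest")
        .reshape(new_p.shape)
        .astype(bool)
    )
    scale = np.diag(list(step) + [1.0])
    new_affine = pmap.affine @ scale
    return PValueMap(
        t=np.full(new_p.shape, np.nan),
        p=new_p,
        sign=new_sign,
        df=pmap.df,
        defined=new_defined,
        voxel_dims=tuple(target),
        affine=new_affine,
        presentation_only=True,
    )


def fdr_correct(pmap: PValueMap) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values over defined voxels (optional)."""
    p = pmap.p[pmap.defined]
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.full(pmap.p.shape, np.nan)
    vals = np.empty_like(p)
    vals[order] = np.minimum(adj, 1.0)
    out[pmap.defined] = vals
    return out
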