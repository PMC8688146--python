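"""Synthetic paired-condition dynamic PET phantom.

Generates desk-scale datasets with the statistical structure the analysis
pipeline assumes: a labelled brain-like volume of contiguous regions, a small
extracerebral blood pool whose signal mixes true blood activity with
background at a known volume fraction, per-region two-tissue-compartment
kinetics, frame-duration-scaled Gaussian noise, and a paired cross-over
design (one saline and one insulin scan per subject, with insulin reducing
``k1`` — hence Ce/Cp — in designated effect regions).

The blood-pool mixing fraction equals the 0.6 the downstream correction
assumes, so IDIF extraction followed by PV correction is exact on noiseless
phantoms; a mismatch knob (``vf_true``) exists for sensitivity studies.

Noise model: zero-mean Gaussian per voxel and frame with variance
``σ² = Sc·C/Δt`` (``Sc`` in kBq·ml⁻¹·s, ``C`` the noiseless frame value,
``Δt`` the frame duration in seconds) — the standard surrogate for
count-limited frame statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import DEFAULT_VOXEL_DIMS, DynamicImage
from .kinetic_model import (
    FrameSchedule,
    KineticParams,
    ce_cp,
    frame_average,
    frame_averaged_tac,
)
from .plasma import FengInput

__all__ = [
    "SALINE",
    "INSULIN",
    "DEFAULT_REGION_NAMES",
    "RegionAtlas",
    "GroundTruth",
    "StudyDesign",
    "CohortResult",
    "make_atlas",
    "simulate_plasma_input",
    "simulate_subject_scan",
    "simulate_cohort",
    "noise_scale_for_fraction",
]

SALINE = "saline"
INSULIN = "insulin"
CONDITIONS = (SALINE, INSULIN)

BLOOD_POOL = "blood_pool"

#: region abbreviations used for the default phantom labels
DEFAULT_REGION_NAMES = ("CP", "BNST/LPO", "MBH", "PAG", "ZI/aSNR", "pSNR", "MV", "SPV")


class SizingError(ValueError):
    """Requested volume too small to place the requested regions."""


@dataclass(frozen=True)
class RegionAtlas:
    """Integer label volume (0 = background) with a label→name map."""

    label_volume: np.ndarray
    names: dict[int, str]
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS

    def __post_init__(self) -> None:
        vol = np.asarray(self.label_volume)
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        present = set(np.unique(vol)) - {0}
        if not present <= set(self.names):
            raise ValueError("label volume contains labels missing from the name map")
        if sum(1 for n in self.names.values() if n == BLOOD_POOL) != 1:
            raise ValueError("exactly one region must be named 'blood_pool'")
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        object.__setattr__(self, "label_volume", vol)

    @property
    def blood_label(self) -> int:
        return next(k for k, v in self.names.items() if v == BLOOD_POOL)

    @property
    def tissue_labels(self) -> list[int]:
        return [k for k, v in self.names.items() if v != BLOOD_POOL]

    def mask(self, label: int) -> np.ndarray:
        return self.label_volume == label

    @property
    def blood_mask(self) -> np.ndarray:
        return self.mask(self.blood_label)

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, self.tissue_labels)


@dataclass(frozen=True)
class StudyDesign:
    """Paired cross-over design: every subject has one scan per condition."""

    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects) or not self.subjects:
            raise ValueError("subject ids must be unique and non-empty")

    @classmethod
    def of_size(cls, n: int) -> "StudyDesign":
        return cls(tuple(f"sub{i + 1:02d}" for i in range(n)))


@dataclass(frozen=True)
class GroundTruth:
    """Per-region, per-condition kinetic truth plus simulation nuisances.

    ``subject_effects`` are multiplicative per-subject factors applied to
    ``k1`` in both conditions (between-subject variability that pairing
    removes).  ``sc`` is the noise scale in kBq·ml⁻¹·s; 0 means noiseless.
    ``vf_true`` and ``background_level`` control the blood-pool mixing.
    """

    region_params: dict[str, dict[str, KineticParams]]
    subject_effects: dict[str, float]
    sc: float = 0.0
    vf_true: float = 0.6
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sc < 0:
            raise ValueError("noise scale must be nonnegative")
        if not 0 < self.vf_true <= 1:
            raise ValueError("vf_true must be in (0, 1]")
        if any(e <= 0 for e in self.subject_effects.values()):
            raise ValueError("subject effects must be positive")
        for per_cond in self.region_params.values():
            missing = set(CONDITIONS) - set(per_cond)
            if missing:
                raise ValueError(f"conditions {missing} missing from ground truth")

    @classmethod
    def default(
        cls,
        atlas: RegionAtlas,
        design: StudyDesign,
        effect_regions: dict[str, float] | None = None,
        sc: float = 0.0,
        subject_sd: float = 0.1,
        seed: int = 0,
    ) -> "GroundTruth":
        """Plausible mouse-brain FDG kinetics with an insulin effect on k1.

        ``effect_regions`` maps region names to the multiplicative k1 factor
        under insulin (default: 0.7 in "MBH" when present, i.e. a 30%
        reduction of glucose transport).  Baseline rates are drawn once per
        region from physiological ranges (k1 0.08–0.14 ml·cm⁻³·min⁻¹,
        k2 0.15–0.30, k3 0.04–0.09, k4 0.005–0.015 min⁻¹).
        """
        if effect_regions is None:
            tissue_names = [atlas.names[l] for l in atlas.tissue_labels]
            effect_regions = {"MBH": 0.7} if "MBH" in tissue_names else {}
        rng = np.random.default_rng([seed, 101])
        region_params: dict[str, dict[str, KineticParams]] = {}
        for label in atlas.tissue_labels:
            name = atlas.names[label]
            base = KineticParams(
                k1=rng.uniform(0.08, 0.14),
                k2=rng.uniform(0.15, 0.30),
                k3=rng.uniform(0.04, 0.09),
                k4=rng.uniform(0.005, 0.015),
            )
            mult = effect_regions.get(name, 1.0)
            insulin = KineticParams(base.k1 * mult, base.k2, base.k3, base.k4)
            region_params[name] = {SALINE: base, INSULIN: insulin}
        effects = {
            s: float(np.exp(rng.normal(0.0, subject_sd))) for s in design.subjects
        }
        return cls(region_params, effects, sc=sc, seed=seed)

    def true_cecp_map(self, atlas: RegionAtlas, condition: str, lc: float = 0.26) -> np.ndarray:
        """Ground-truth Ce/Cp volume (NaN outside tissue)."""
        out = np.full(atlas.label_volume.shape, np.nan)
        for label in atlas.tissue_labels:
            name = atlas.names[label]
            out[atlas.mask(label)] = ce_cp(self.region_params[name][condition], lc)
        return out


def make_atlas(
    dims: tuple[int, int, int] = (20, 20, 10),
    n_regions: int = 8,
    seed: int = 0,
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS,
    region_names: tuple[str, ...] = DEFAULT_REGION_NAMES,
    min_region_voxels: int = 8,
) -> RegionAtlas:
    """Labelled blob atlas: an ellipsoidal 'brain' split into contiguous
    regions by farthest-point-seeded nearest-seed assignment, plus a small
    blood-pool block outside the brain.

    Deterministic given ``seed``.  Raises :class:`SizingError` when the
    volume cannot host ``n_regions`` regions of ``min_region_voxels`` voxels
    plus a blood pool.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 4:
        raise SizingError("dims must be a triple with every axis >= 4")
    if n_regions < 2:
        raise ValueError("need at least two tissue regions")

    idx = np.indices(dims, dtype=float)
    center = (np.asarray(dims) - 1) / 2.0
    semi = np.asarray(dims) * 0.40
    brain = (
        ((idx[0] - center[0]) / semi[0]) ** 2
        + ((idx[1] - center[1]) / semi[1]) ** 2
        + ((idx[2] - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # blood pool: small block near a corner, strictly outside the brain
    bx, by = slice(1, min(4, dims[0] - 1)), slice(1, min(4, dims[1] - 1))
    z0 = dims[2] // 2
    bz = slice(max(z0 - 1, 0), min(z0 + 1, dims[2]))
    blood = np.zeros(dims, bool)
    blood[bx, by, bz] = True
    blood &= ~brain
    if blood.sum() < 4:
        raise SizingError("no room for a blood pool outside the brain")

    brain_vox = np.argwhere(brain)
    if len(brain_vox) < n_regions * min_region_voxels:
        raise SizingError(
            f"brain volume of {len(brain_vox)} voxels cannot host "
            f"{n_regions} regions of >= {min_region_voxels} voxels"
        )

    # farthest-point sampling of region seeds (first seed random, rest greedy)
    rng = np.random.default_rng([seed, 7])
    pts = brain_vox * np.asarray(voxel_dims)
    seeds = [rng.integers(len(pts))]
    d2 = np.sum((pts - pts[seeds[0]]) ** 2, axis=1)
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(d2))
        seeds.append(nxt)
        d2 = np.minimum(d2, np.sum((pts - pts[nxt]) ** 2, axis=1))

    dists = np.stack([np.sum((pts - pts[s]) ** 2, axis=1) for s in seeds])
    assign = np.argmin(dists, axis=0)

    labels = np.zeros(dims, dtype=np.int32)
    for i in range(n_regions):
        vox = brain_vox[assign == i]
        labels[tuple(vox.T)] = i + 1
    blood_label = n_regions + 1
    labels[blood] = blood_label

    sizes = [int((labels == i + 1).sum()) for i in range(n_regions)]
    if min(sizes) < min_region_voxels:
        raise SizingError(
            f"smallest region has {min(sizes)} voxels (< {min_region_voxels}); "
            "reduce n_regions or enlarge dims"
        )

    names = {
        i + 1: (region_names[i] if i < len(region_names) else f"R{i + 1}")
        for i in range(n_regions)
    }
    names[blood_label] = BLOOD_POOL
    return RegionAtlas(labels, names, voxel_dims)


def simulate_plasma_input(model_params: dict | None = None, seed: int = 0) -> FengInput:
    """Parametric stand-in for the in vivo plasma input.

    A tri-exponential bolus (see :class:`~fdgkin.plasma.FengInput`); the
    defaults peak before 120 s and decay over the 2580-s scan.  ``seed`` is
    accepted for interface symmetry — the curve itself is deterministic.
    """
    del seed
    return FengInput(**(model_params or {}))


def _scan_rng(seed: int, subject_index: int, condition: str) -> np.random.Generator:
    return np.random.default_rng([seed, subject_index, CONDITIONS.index(condition)])


def simulate_subject_scan(
    atlas: RegionAtlas,
    truth: GroundTruth,
    condition: str,
    plasma: FengInput,
    schedule: FrameSchedule,
    seed: int,
    subject: str | None = None,
    subject_index: int = 0,
) -> DynamicImage:
    """One dynamic scan: deterministic forward model plus seeded noise.

    Tissue voxels carry the frame-averaged 2TC response of their region
    (with the subject's multiplicative k1 effect); blood-pool voxels mix the
    frame-averaged true plasma curve with the background level at
    ``vf_true``; background voxels are zero.
    """
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    shape = atlas.label_volume.shape
    data = np.zeros(shape + (len(schedule),))

    effect = truth.subject_effects.get(subject, 1.0) if subject else 1.0
    for label in atlas.tissue_labels:
        name = atlas.names[label]
        if name not in truth.region_params:
            raise KeyError(f"ground truth missing region {name!r}")
        p = truth.region_params[name][condition]
        p_eff = KineticParams(p.k1 * effect, p.k2, p.k3, p.k4)
        data[atlas.mask(label)] = frame_averaged_tac(p_eff, plasma, schedule)

    cp_frames = frame_average(plasma, schedule)
    blood_signal = truth.vf_true * cp_frames + (1.0 - truth.vf_true) * truth.background_level
    data[atlas.blood_mask] = blood_signal

    if truth.sc > 0:
        rng = _scan_rng(seed, subject_index, condition)
        sigma = np.sqrt(truth.sc * np.maximum(data, 0.0) / schedule.durations_s)
        data = data + rng.normal(0.0, 1.0, data.shape) * sigma

    return DynamicImage(data, schedule, atlas.voxel_dims)


@dataclass
class CohortResult:
    """Paired scans per subject plus ground-truth Ce/Cp maps per condition."""

    design: StudyDesign
    images: dict[tuple[str, str], DynamicImage]  # (subject, condition) -> scan
    true_cecp: dict[str, np.ndarray]
    atlas: RegionAtlas
    truth: GroundTruth
    schedule: FrameSchedule
    plasma: FengInput = field(repr=False, default=None)

    def scans(self, condition: str) -> list[DynamicImage]:
        return [self.images[(s, condition)] for s in self.design.subjects]


def simulate_cohort(
    design: StudyDesign,
    atlas: RegionAtlas,
    truth: GroundTruth,
    plasma: FengInput,
    schedule: FrameSchedule,
    seed: int,
) -> CohortResult:
    """Paired saline/insulin scans for every subject (fresh noise per scan)."""
    images = {}
    for i, sub in enumerate(design.subjects):
        for cond in CONDITIONS:
            images[(sub, cond)] = simulate_subject_scan(
                atlas, truth, cond, plasma, schedule, seed, subject=sub, subject_index=i
            )
    true_cecp = {c: truth.true_cecp_map(atlas, c) for c in CONDITIONS}
    return CohortResult(design, images, true_cecp, atlas, truth, schedule, plasma)


def noise_scale_for_fraction(
    params: KineticParams, plasma: FengInput, schedule: FrameSchedule, fraction: float
) -> float:
    """``Sc`` giving a mean relative TAC noise of ``fraction``.

    With ``σᵢ = √(Sc·Cᵢ/Δtᵢ)`` the per-frame coefficient of variation is
    ``√(Sc/(Cᵢ·Δtᵢ))``; this solves for the ``Sc`` whose average CV over the
    informative frames (activity above 5% of the TAC maximum) equals
    ``fraction``.  Short early frames stay noisier and long late frames less
    noisy than the average, as in real framed data.
    """
    tac = frame_averaged_tac(params, plasma, schedule)
    use = tac > 0.05 * tac.max()
    inv = np.mean(1.0 / np.sqrt(tac[use] * schedule.durations_s[use]))
    return float((fraction / inv) ** 2)
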