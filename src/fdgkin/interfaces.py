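"""File formats, run configuration and provenance.

Conventions
-----------
* Images, masks and maps: NIfTI-1 (uncompressed ``.nii`` so that re-runs are
  byte-identical).  Voxel indices are 0-based; world coordinates come from
  the NIfTI affine.
* Frame schedules: TSV with columns ``frame_start_s``, ``frame_end_s``
  (seconds on disk, minutes internally for rate-constant work).
* IDIF curves: CSV ``time_s, uncorrected_kBq_ml, corrected_kBq_ml``.
* Undefined / non-converged voxels: NaN in maps; masks as uint8.
* Configuration: YAML, validated into :class:`RunConfig`; every stochastic
  stage derives its seed from the global seed plus a stage offset.
* Every written artifact set gets a ``provenance.json`` (config snapshot,
  input digests, package version, timestamp, warnings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import DynamicImage
from .input_function import IdifCurve
from .kinetic_model import FrameSchedule, ce_cp
from .phantom import CONDITIONS, GroundTruth, RegionAtlas
from .voxel_fitting import PARAM_NAMES, ParametricMap

__all__ = [
    "RunConfig",
    "read_schedule",
    "write_schedule",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_atlas",
    "write_atlas",
    "write_ground_truth",
    "write_idif",
    "read_idif",
    "write_parametric_maps",
    "read_map",
    "make_provenance",
    "file_digest",
]

MAP_QUANTITIES = PARAM_NAMES + ("cecp", "wrss")


# ---------------------------------------------------------------- schedules


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {"frame_start_s": schedule.starts_s, "frame_end_s": schedule.ends_s}
    ).to_csv(path, sep="\t", index=False)


def read_schedule(path: str | Path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_end_s"):
        if col not in df.columns:
            raise ValueError(f"schedule TSV is missing column {col!r}")
    return FrameSchedule(tuple(zip(df["frame_start_s"], df["frame_end_s"])))


# ------------------------------------------------------------------- images


def write_dynamic_image(image: DynamicImage, path_image: str | Path, path_schedule: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.data, image.affine), str(path_image))
    write_schedule(image.schedule, path_schedule)


def read_dynamic_image(path_image: str | Path, path_schedule: str | Path) -> DynamicImage:
    img = nib.load(str(path_image))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D dynamic image, got {data.ndim}-D")
    schedule = read_schedule(path_schedule)
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"image has {data.shape[3]} frames but schedule lists {len(schedule)}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data, schedule, tuple(float(z) for z in zooms), affine=img.affine)


def write_atlas(atlas: RegionAtlas, path_labels: str | Path, path_names: str | Path) -> None:
    aff = np.diag(list(atlas.voxel_dims) + [1.0])
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), aff), str(path_labels))
    Path(path_names).write_text(json.dumps({str(k): v for k, v in atlas.names.items()}, indent=1))


def read_atlas(path_labels: str | Path, path_names: str | Path) -> RegionAtlas:
    img = nib.load(str(path_labels))
    labels = np.asarray(img.dataobj).astype(np.int32)
    names = {int(k): v for k, v in json.loads(Path(path_names).read_text()).items()}
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RegionAtlas(labels, names, zooms)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for region, per_cond in truth.region_params.items():
        for cond in CONDITIONS:
            p = per_cond[cond]
            rows.append(
                dict(region=region, condition=cond, k1=p.k1, k2=p.k2, k3=p.k3, k4=p.k4,
                     cecp=ce_cp(p))
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------- IDIF curves


def write_idif(uncorrected: IdifCurve, corrected: IdifCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": uncorrected.times_min * 60.0,
            "uncorrected_kBq_ml": uncorrected.values,
            "corrected_kBq_ml": corrected.values,
        }
    ).to_csv(path, index=False)


def read_idif(path: str | Path, column: str = "corrected_kBq_ml") -> IdifCurve:
    df = pd.read_csv(path)
    return IdifCurve(np.asarray(df["time_s"]) / 60.0, np.asarray(df[column]))


# --------------------------------------------------------- parametric maps


def write_parametric_maps(pmap: ParametricMap, out_dir: str | Path, provenance: dict | None = None) -> dict[str, str]:
    """One 3-D NIfTI per quantity plus the mask and a provenance JSON.

    Returns ``{filename: sha256}`` digests of the written map files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    for name in MAP_QUANTITIES:
        path = out / f"{name}.nii"
        nib.save(nib.Nifti1Image(pmap[name], pmap.affine), str(path))
        digests[path.name] = file_digest(path)
    mask_path = out / "mask.nii"
    nib.save(nib.Nifti1Image(pmap.mask.astype(np.uint8), pmap.affine), str(mask_path))
    digests[mask_path.name] = file_digest(mask_path)
    prov = dict(provenance or {})
    prov.setdefault("n_unconverged", pmap.n_unconverged)
    prov["map_digests"] = digests
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    return digests


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


# -------------------------------------------------------------- provenance


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def make_provenance(config: dict, inputs: dict[str, str] | None = None, warnings: list[str] | None = None) -> dict:
    snapshot = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_digest": hashlib.sha256(snapshot.encode()).hexdigest(),
        "inputs": inputs or {},
        "software": {"package": "fdgkin", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "warnings": warnings or [],
    }


# ------------------------------------------------------------ run configs


def _asdict_nonrecursive(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


@dataclass(frozen=True)
class PhantomConfig:
    dims: tuple[int, int, int] = (16, 16, 8)
    n_regions: int = 8
    n_subjects: int = 8
    effect_regions: dict = field(default_factory=lambda: {"MBH": 0.7})
    noise_fraction: float = 0.05
    subject_sd: float = 0.1
    vf_true: float = 0.6
    background_level: float = 0.0


@dataclass(frozen=True)
class InputConfig:
    quantile: float = 0.95
    vf: float = 0.6
    background: float = 0.0


@dataclass(frozen=True)
class FitSection:
    n_multistart: int = 4
    weight_rule: str = "duration"
    fix_k4: float | None = None
    mask_quantile: float = 0.0
    lc: float = 0.26


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    min_voxels: int = 4


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of the end-to-end pipeline."""

    seed: int = 0
    phantom: PhantomConfig = PhantomConfig()
    input: InputConfig = InputConfig()
    fit: FitSection = FitSection()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {"phantom": PhantomConfig, "input": InputConfig, "fit": FitSection, "stats": StatsConfig}
        kwargs: dict = {}
        unknown = set(raw) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs["seed"] = int(raw.get("seed", 0))
        for name, klass in sections.items():
            sub = dict(raw.get(name, {}))
            bad = set(sub) - {f.name for f in dataclasses.fields(klass)}
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            if name == "phantom" and "dims" in sub:
                sub["dims"] = tuple(sub["dims"])
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out = {"seed": self.seed}
        for name in ("phantom", "input", "fit", "stats"):
            sub = _asdict_nonrecursive(getattr(self, name))
            if "dims" in sub:
                sub["dims"] = list(sub["dims"])
            out[name] = sub
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
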