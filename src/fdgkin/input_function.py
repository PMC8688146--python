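"""Image-derived input function (IDIF) with partial-volume correction.

The plasma input is estimated from the blood pool (aorta) visible in the
first time frame of the dynamic image.  Because the blood pool is small
relative to scanner resolution, the measured concentration is a mixture of
true blood activity and surroundings; it is corrected with a standardized
volume fraction (default 0.6)::

    Cp_corrected = (Cp_measured − (1 − vf)·background) / vf

With the default zero background this reduces to division by 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import DynamicImage
from .plasma import FengInput, PlasmaInput, SampledInput

__all__ = [
    "VF_DEFAULT",
    "IdifCurve",
    "locate_blood_pool",
    "extract_idif",
    "pvc_correct",
    "as_continuous",
]

log = logging.getLogger(__name__)

#: standardized blood-pool volume fraction
VF_DEFAULT = 0.6


class EmptyMaskError(ValueError):
    """No voxels qualify for the requested mask."""


@dataclass
class IdifCurve:
    """Frame-sampled blood-pool activity at frame mid-times (minutes).

    Unlike :class:`~fdgkin.plasma.SampledInput` this container tolerates
    negative values (possible in noisy uncorrected data); conversion to a
    proper plasma input happens in :func:`as_continuous`.
    """

    times_min: np.ndarray
    values: np.ndarray
    n_clamped: int = field(default=0)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.values = np.asarray(self.values, float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")


def locate_blood_pool(image: DynamicImage, quantile: float = 0.95) -> np.ndarray:
    """Blood-pool mask from the first-frame hotspot.

    The earliest frame is dominated by the vascular bolus, so the blood pool
    is the connected component (6-neighbourhood) of supra-threshold voxels
    that contains the first-frame maximum.  The threshold is the given
    quantile of the positive first-frame values.
    """
    if image.n_frames < 1:
        raise ValueError("image has no frames")
    f0 = image.data[..., 0]
    positive = f0[f0 > 0]
    if positive.size == 0:
        raise EmptyMaskError("first frame contains no positive voxels")
    thr = np.quantile(positive, quantile)
    candidates = f0 >= thr
    if not candidates.any():
        raise EmptyMaskError("no voxel exceeds the first-frame threshold")
    labels, _ = ndimage.label(candidates)
    peak = np.unravel_index(np.argmax(f0), f0.shape)
    mask = labels == labels[peak]
    return mask


def extract_idif(image: DynamicImage, mask: np.ndarray) -> IdifCurve:
    """Uncorrected IDIF: per-frame mean activity over the mask voxels."""
    mask = np.asarray(mask, bool)
    if mask.shape != image.shape3d:
        raise IndexError("mask shape does not match image")
    if not mask.any():
        raise EmptyMaskError("blood-pool mask is empty")
    values = image.data[mask].mean(axis=0)
    return IdifCurve(image.schedule.mid_min, values)


def pvc_correct(
    idif: IdifCurve,
    vf: float = VF_DEFAULT,
    background: float | np.ndarray = 0.0,
    tol: float = 1e-9,
) -> IdifCurve:
    """Partial-volume correction with a fixed volume fraction.

    ``corrected = (measured − (1 − vf)·background)/vf``.  Values more negative
    than ``−tol`` trigger a warning; all negative values are clamped to zero
    (count recorded on the returned curve).
    """
    if not 0.0 < vf <= 1.0:
        raise ValueError("volume fraction must be in (0, 1]")
    bg = np.broadcast_to(np.asarray(background, float), idif.values.shape)
    corrected = (idif.values - (1.0 - vf) * bg) / vf
    n_neg = int(np.sum(corrected < -tol))
    if n_neg:
        log.warning("PV correction produced %d negative values; clamping to 0", n_neg)
    corrected = np.maximum(corrected, 0.0)
    return IdifCurve(idif.times_min, corrected, n_clamped=n_neg)


def as_continuous(idif: IdifCurve) -> SampledInput:
    """Continuous plasma input from IDIF samples.

    Piecewise linear through (0, 0) and the samples, single-exponential tail
    beyond the last sample (see :class:`~fdgkin.plasma.SampledInput`).
    """
    if idif.times_min.size < 2:
        raise ValueError("need at least two IDIF samples")
    return SampledInput(idif.times_min, np.maximum(idif.values, 0.0))
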