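"""PET activity-per-volume quantification and caliper tumor volumes.

Manual ROI placement over the FDG-avid part of a tumor is replaced by a
reproducible surrogate: the largest connected component of voxels above a
fraction of the volume maximum. Activity density is total ROI activity per
ROI volume. Caliper volumes use the standard prolate-ellipsoid formula
V = (pi/6) a b^2 with a the longest dimension and b the width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = ["PETVolume", "CaliperMeasurement", "avid_roi", "activity_per_volume", "caliper_volume"]


@dataclass
class PETVolume:
    """Reconstructed PET volume: per-voxel activity (a.u.), voxel volume mm^3."""

    activity: np.ndarray
    voxel_volume_mm3: float
    injected_dose: float | None = None
    scan_delay_min: float | None = None  # provenance only; no decay correction

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.voxel_volume_mm3 <= 0:
            raise InvalidInputError("voxel_volume_mm3 must be strictly positive")
        if np.any(self.activity < 0):
            raise InvalidInputError("activity must be non-negative")


@dataclass(frozen=True)
class CaliperMeasurement:
    """Perpendicular caliper diameters (mm): a = longest dimension, b = width."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise InvalidInputError("caliper dimensions must be strictly positive")
        if self.a < self.b:
            raise InvalidInputError("'a' must be the longest dimension (a >= b)")


def avid_roi(pet: PETVolume, threshold_fraction: float = 0.4) -> np.ndarray:
    """Tracer-avid ROI: largest connected component above a max-fraction.

    Voxels with activity >= threshold_fraction * max(activity) are selected
    and the largest 26-connected component retained, mimicking an ROI drawn
    over the actively accumulating part of the tumor.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidInputError("threshold_fraction must lie in (0, 1)")
    peak = float(pet.activity.max())
    if peak <= 0:
        raise InvalidInputError("all-zero PET volume: no avid region")
    hot = pet.activity >= threshold_fraction * peak
    labels, n = ndimage.label(hot, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise InvalidInputError("no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def activity_per_volume(pet: PETVolume, roi: np.ndarray) -> float:
    """Total ROI activity divided by ROI volume (activity units per mm^3)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pet.activity.shape:
        raise InvalidInputError("ROI and PET grids differ")
    n = int(roi.sum())
    if n == 0:
        raise InvalidInputError("empty ROI")
    return float(pet.activity[roi].sum()) / (n * pet.voxel_volume_mm3)


def caliper_volume(m: CaliperMeasurement) -> float:
    """Prolate-ellipsoid tumor volume (mm^3): (pi/6) * a * b^2."""
    return (np.pi / 6.0) * m.a * m.b**2
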