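"""Whole-section immunofluorescence quantification.

One cryosection is imaged once per marker, the channels overlaid and aligned,
cropped to the tumor boundary, and necrotic/artifact regions excluded. Five
physiology metrics are then pixel-counting exercises on the viable tissue:

* hypoxic / proliferating / apoptotic fraction — percent of viable tumor
  pixels positive for EF5, Ki67 and TUNEL respectively;
* perfused-vessel fraction — percent of CD31+ (endothelium) pixels that are
  also Hoechst+ (perfusion dye), i.e. vessels functional at injection time;
* microvessel density — mean Euclidean distance of viable pixels to the
  nearest CD31+ pixel (short distance = dense vasculature);
* necrotic fraction — percent of tumor pixels inside the necrosis mask
  (necrosis outlines are a manual input, drawn against H&E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvalidInputError, UndefinedResultError

__all__ = [
    "SectionImageSet",
    "SectionMetrics",
    "align_channels",
    "viable_mask",
    "positive_fraction",
    "perfused_vessel_fraction",
    "mean_vessel_distance",
    "necrotic_fraction",
    "compute_section_metrics",
]

MARKER_CHANNELS = ("hoechst_perfusion", "cd31", "ef5", "ki67", "tunel", "counterstain")


@dataclass
class SectionImageSet:
    """Co-registered 2D marker channels plus masks for one tumor section."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    tumor_mask: np.ndarray
    necrosis_mask: np.ndarray
    artifact_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel_size_um must be strictly positive")
        shapes = {ch.shape for ch in self.channels.values()}
        shapes |= {self.tumor_mask.shape, self.necrosis_mask.shape, self.artifact_mask.shape}
        if len(shapes) != 1:
            raise InvalidInputError("all channels and masks must share one shape")
        if np.any(self.necrosis_mask & ~self.tumor_mask):
            raise InvalidInputError("necrosis mask must be a subset of the tumor mask")


@dataclass
class SectionMetrics:
    """Whole-section physiology metrics; percentages in [0, 100], distance µm.

    Metrics whose denominator is empty (e.g. perfused-vessel fraction without
    any CD31+ pixel) are ``None`` — undefined, not zero.
    """

    ef5_fraction: float
    ki67_fraction: float
    tunel_fraction: float
    perfused_vessel_fraction: float | None
    mean_vessel_distance_um: float | None
    necrotic_fraction: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape patches."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _shift_ncc_surface(
    moving: np.ndarray, reference: np.ndarray, window: int
) -> np.ndarray:
    """NCC of ``moving`` shifted by (dy, dx) against ``reference``, for all
    integer shifts in [-window, window]^2, on the overlap region."""
    size = 2 * window + 1
    surface = np.full((size, size), -np.inf)
    h, w = reference.shape
    for iy, dy in enumerate(range(-window, window + 1)):
        for ix, dx in enumerate(range(-window, window + 1)):
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            yr = slice(max(0, -dy), min(h, h - dy))
            xr = slice(max(0, -dx), min(w, w - dx))
            surface[iy, ix] = _ncc(moving[yr, xr], reference[ys, xs])
    return surface


def align_channels(
    image_set: SectionImageSet,
    reference: str = "counterstain",
    *,
    window: int = 8,
    min_peak_corr: float = 0.2,
    peak_ratio: float = 1.02,
) -> tuple[SectionImageSet, dict[str, tuple[int, int]]]:
    """Rigid integer-pixel translation of each channel onto the reference.

    For every non-reference channel the normalized cross-correlation is
    evaluated over all integer shifts within ``window`` pixels and the
    best shift applied (circular shifts are avoided: exposed borders fill
    with zeros). If the correlation peak is indistinct — absolute value
    below ``min_peak_corr``, or less than ``peak_ratio`` times the best
    correlation found away from the peak's immediate neighborhood — the
    channel is left unshifted and a warning is issued.

    Returns the aligned set and the per-channel shifts applied.
    """
    if reference not in image_set.channels:
        raise InvalidInputError(f"reference channel {reference!r} not present")
    if len(image_set.channels) < 2:
        raise InvalidInputError("at least two channels required for alignment")

    ref = np.asarray(image_set.channels[reference], dtype=float)
    new_channels: dict[str, np.ndarray] = {}
    shifts: dict[str, tuple[int, int]] = {}
    for name, chan in image_set.channels.items():
        if name == reference:
            new_channels[name] = chan
            shifts[name] = (0, 0)
            continue
        surface = _shift_ncc_surface(np.asarray(chan, dtype=float), ref, window)
        peak_flat = int(np.argmax(surface))
        py, px = np.unravel_index(peak_flat, surface.shape)
        peak = surface[py, px]
        # competitor: best correlation outside the peak's 3x3 neighborhood
        masked = surface.copy()
        masked[max(0, py - 1) : py + 2, max(0, px - 1) : px + 2] = -np.inf
        second = masked.max()
        distinct = peak >= min_peak_corr and (
            not np.isfinite(second) or second <= 0 or peak >= peak_ratio * second
        )
        if not distinct:
            warnings.warn(
                f"channel {name!r}: indistinct correlation peak, left unshifted",
                stacklevel=2,
            )
            new_channels[name] = chan
            shifts[name] = (0, 0)
            continue
        dy, dx = int(py) - window, int(px) - window
        shifted = np.zeros_like(chan)
        h, w = chan.shape
        ys = slice(max(0, dy), min(h, h + dy))
        xs = slice(max(0, dx), min(w, w + dx))
        yr = slice(max(0, -dy), min(h, h - dy))
        xr = slice(max(0, -dx), min(w, w - dx))
        shifted[ys, xs] = chan[yr, xr]
        new_channels[name] = shifted
        shifts[name] = (dy, dx)
    return replace(image_set, channels=new_channels), shifts


def viable_mask(image_set: SectionImageSet) -> np.ndarray:
    """Viable tumor tissue: tumor minus necrosis minus artifacts."""
    viable = image_set.tumor_mask & ~image_set.necrosis_mask & ~image_set.artifact_mask
    if not viable.any():
        raise InvalidInputError("viable mask is empty after exclusions")
    return viable


def positive_fraction(
    channel: np.ndarray,
    viable: np.ndarray,
    threshold: float | None = None,
) -> float:
    """Percent of viable pixels at or above the positivity threshold.

    ``threshold=None`` selects Otsu's threshold computed within the viable
    region; fixed thresholds make the metric fully deterministic.
    """
    if not viable.any():
        raise InvalidInputError("empty viable mask")
    values = channel[viable]
    if threshold is None:
        if np.ptp(values) == 0:
            return 0.0  # constant channel: Otsu undefined, nothing stands out
        threshold = threshold_otsu(values)
    return 100.0 * float((values >= threshold).sum()) / values.size


def perfused_vessel_fraction(cd31_mask: np.ndarray, hoechst_mask: np.ndarray) -> float:
    """Percent of vessel (CD31+) pixels that carry the perfusion dye."""
    if cd31_mask.shape != hoechst_mask.shape:
        raise InvalidInputError("masks must share one grid")
    n_vessel = int(cd31_mask.sum())
    if n_vessel == 0:
        raise UndefinedResultError("no CD31+ pixels: perfused fraction undefined")
    return 100.0 * float((cd31_mask & hoechst_mask).sum()) / n_vessel


def mean_vessel_distance(
    cd31_mask: np.ndarray,
    viable: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Mean Euclidean distance (µm) of viable pixels to the nearest vessel.

    Computed by the exact Euclidean distance transform of the vessel-negative
    region, scaled to microns. CD31+ pixels themselves are at distance zero.
    """
    if int(cd31_mask.sum()) == 0:
        raise UndefinedResultError("no CD31+ pixels: vessel distance undefined")
    if not viable.any():
        raise InvalidInputError("empty viable mask")
    edt = ndimage.distance_transform_edt(~cd31_mask, sampling=pixel_size_um)
    return float(edt[viable].mean())


def necrotic_fraction(necrosis_mask: np.ndarray, tumor_mask: np.ndarray) -> float:
    """Percent of tumor pixels that are necrotic."""
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        raise InvalidInputError("empty tumor mask")
    if np.any(necrosis_mask & ~tumor_mask):
        raise InvalidInputError("necrosis mask must be a subset of the tumor mask")
    return 100.0 * float(necrosis_mask.sum()) / n_tumor


def compute_section_metrics(
    image_set: SectionImageSet,
    thresholds: dict[str, float] | None = None,
    *,
    vessel_distance_includes_necrosis: bool = False,
) -> SectionMetrics:
    """All five section metrics from an aligned image set.

    ``thresholds`` maps channel names to fixed positivity thresholds;
    channels absent from the mapping use Otsu within the viable region.
    Binary vessel/perfusion masks are the thresholded cd31/hoechst channels.
    The vessel-distance average runs over viable pixels by default; the
    switch includes necrotic tissue pixels in the average instead.
    """
    thresholds = thresholds or {}
    viable = viable_mask(image_set)

    def _thr(name: str) -> float | None:
        return thresholds.get(name)

    def _binary(name: str) -> np.ndarray:
        chan = image_set.channels[name]
        thr = _thr(name)
        if thr is None:
            vals = chan[viable]
            thr = threshold_otsu(vals) if np.ptp(vals) > 0 else np.inf
        return chan >= thr

    cd31 = _binary("cd31") & image_set.tumor_mask
    hoechst = _binary("hoechst_perfusion") & image_set.tumor_mask

    try:
        pvf = perfused_vessel_fraction(cd31, hoechst)
    except UndefinedResultError:
        pvf = None
    distance_region = (
        (image_set.tumor_mask & ~image_set.artifact_mask)
        if vessel_distance_includes_necrosis
        else viable
    )
    try:
        mvd = mean_vessel_distance(cd31, distance_region, image_set.pixel_size_um)
    except UndefinedResultError:
        mvd = None

    return SectionMetrics(
        ef5_fraction=positive_fraction(image_set.channels["ef5"], viable, _thr("ef5")),
        ki67_fraction=positive_fraction(image_set.channels["ki67"], viable, _thr("ki67")),
        tunel_fraction=positive_fraction(image_set.channels["tunel"], viable, _thr("tunel")),
        perfused_vessel_fraction=pvf,
        mean_vessel_distance_um=mvd,
        necrotic_fraction=necrotic_fraction(image_set.necrosis_mask, image_set.tumor_mask),
    )
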