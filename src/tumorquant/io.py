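"""Readers/writers for the pipeline's on-disk formats.

Volumetric data travel as NIfTI-1 (world coordinates carry only the voxel
size; axis order is (x, y, z[, t]), 0-based indexing). Section channels are
multi-page TIFF, one page per channel in a documented order. Tables are CSV.
Every writer drops a JSON provenance sidecar (package version, seed, config
hash) next to its output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .errors import InvalidInputError
from .histology import MARKER_CHANNELS, SectionImageSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_section_tiff",
    "load_section_tiff",
    "write_provenance",
]


def save_volume(
    data: np.ndarray, path: str | Path, voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)
) -> None:
    """Write a 3D map/mask or 4D dynamic series as NIfTI-1."""
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    zooms = list(voxel_size[:3]) + ([1.0] if np.asarray(data).ndim == 4 else [])
    img.header.set_zooms(tuple(zooms[: np.asarray(data).ndim]))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), tuple(float(z) for z in img.header.get_zooms())


def save_section_tiff(image_set: SectionImageSet, path: str | Path) -> None:
    """Multi-page TIFF: marker channels in MARKER_CHANNELS order, then the
    tumor, necrosis and artifact masks as 0/255 pages."""
    pages = [np.asarray(image_set.channels[name], dtype=np.float32) for name in MARKER_CHANNELS]
    for m in (image_set.tumor_mask, image_set.necrosis_mask, image_set.artifact_mask):
        pages.append(np.asarray(m, dtype=np.float32) * 255.0)
    tifffile.imwrite(str(path), np.stack(pages), metadata={"axes": "CYX"})


def load_section_tiff(path: str | Path, pixel_size_um: float) -> SectionImageSet:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"section TIFF not found: {path}")
    stack = tifffile.imread(str(path))
    if stack.shape[0] != len(MARKER_CHANNELS) + 3:
        raise InvalidInputError(
            f"expected {len(MARKER_CHANNELS) + 3} pages, found {stack.shape[0]}"
        )
    channels = {name: stack[i].astype(float) for i, name in enumerate(MARKER_CHANNELS)}
    n = len(MARKER_CHANNELS)
    return SectionImageSet(
        channels=channels,
        pixel_size_um=pixel_size_um,
        tumor_mask=stack[n] > 127,
        necrosis_mask=stack[n + 1] > 127,
        artifact_mask=stack[n + 2] > 127,
    )


def write_provenance(path: str | Path, *, seed: int, config_dump: dict, extra: dict | None = None) -> None:
    """JSON sidecar recording how an output was produced."""
    from . import __version__

    blob = json.dumps(config_dump, sort_keys=True).encode()
    record = {
        "tumorquant_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config_dump,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
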