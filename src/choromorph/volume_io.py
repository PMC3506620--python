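"""Reading and writing OCT volumes, en face slabs, and masks.

Volumes are stored as multi-page TIFF stacks (one page per B-scan, each page a
depth x A-scan cross-section) with a JSON sidecar carrying the physical pixel
pitches and any per-eye metadata (group label, covariates, seed).  All writers
and readers are lossless inverses on 8-bit data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any

import imageio.v3 as iio
import numpy as np
import tifffile

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .enface import EnFaceSlab

__all__ = [
    "OctVolume",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "write_label_volume",
    "read_label_volume",
    "write_enface_image",
    "read_enface_image",
    "write_depth_map",
]


class VolumeFormatError(ValueError):
    """Raised when an on-disk volume and its sidecar disagree or are invalid."""


@dataclass
class OctVolume:
    """A 3-D OCT intensity volume with physical pitch metadata.

    ``intensities`` is indexed ``(a_scan, b_scan, depth)``: axis 0 is the fast
    (horizontal) scan direction, axis 1 the slow direction, axis 2 depth.  The
    standard macular cube is 512 A-scans x 128 B-scans over a 6 mm square, so
    the lateral pitches are anisometric (6000/512 = 11.72 um horizontally,
    6000/128 = 46.88 um vertically).
    """

    intensities: np.ndarray
    lateral_pitch_x_um: float
    lateral_pitch_y_um: float
    axial_pitch_um: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"volume must be 3-D (a_scan, b_scan, depth); got shape "
                f"{self.intensities.shape}"
            )
        if self.intensities.dtype != np.uint8:
            if self.intensities.min() < 0 or self.intensities.max() > 255:
                raise ValueError("intensities must fit in [0, 255]")
            self.intensities = self.intensities.astype(np.uint8)
        for name in ("lateral_pitch_x_um", "lateral_pitch_y_um", "axial_pitch_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_ascan(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bscan(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_axial(self) -> int:
        return self.intensities.shape[2]

    def bscan(self, j: int) -> np.ndarray:
        """Cross-sectional B-scan ``j`` as an (a_scan, depth) array."""
        return self.intensities[:, j, :]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: OctVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    Pages are B-scans: page ``j`` holds ``volume.intensities[:, j, :].T``
    (rows = depth, columns = A-scans), the orientation a B-scan is viewed in.
    """
    path = Path(path)
    pages = np.transpose(volume.intensities, (1, 2, 0))  # (b, depth, a)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "shape": list(volume.intensities.shape),
        "lateral_pitch_x_um": volume.lateral_pitch_x_um,
        "lateral_pitch_y_um": volume.lateral_pitch_y_um,
        "axial_pitch_um": volume.axial_pitch_um,
        "metadata": volume.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> OctVolume:
    """Read a volume written by :func:`write_volume`; round-trips bit-exactly."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise VolumeFormatError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("shape", "lateral_pitch_x_um", "lateral_pitch_y_um", "axial_pitch_um"):
        if key not in sidecar:
            raise VolumeFormatError(f"sidecar {sidecar_path} lacks required key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single B-scan collapses to 2-D
        pages = pages[None]
    intensities = np.transpose(pages, (2, 0, 1))  # (a, b, depth)
    expected = tuple(sidecar["shape"])
    if intensities.shape != expected:
        raise VolumeFormatError(
            f"TIFF shape {intensities.shape} disagrees with sidecar shape {expected}"
        )
    return OctVolume(
        intensities=intensities,
        lateral_pitch_x_um=float(sidecar["lateral_pitch_x_um"]),
        lateral_pitch_y_um=float(sidecar["lateral_pitch_y_um"]),
        axial_pitch_um=float(sidecar["axial_pitch_um"]),
        metadata=sidecar.get("metadata", {}),
    )


def write_label_volume(labels: np.ndarray, path: str | Path) -> Path:
    """Write a boolean vessel-label volume as a 0/1 uint8 TIFF stack."""
    path = Path(path)
    pages = np.transpose(labels.astype(np.uint8), (1, 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


def read_label_volume(path: str | Path) -> np.ndarray:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return np.transpose(pages, (2, 0, 1)).astype(bool)


def write_enface_image(slab: "EnFaceSlab | np.ndarray", path: str | Path) -> Path:
    """Export an en face slab (or bare 2-D array) as a lossless 8-bit image.

    The slab's ``image`` is indexed ``(a_scan, b_scan)``; on disk the image is
    transposed so the fast-scan (x) axis runs horizontally in a viewer.  PNG
    and TIFF are supported, chosen by the file suffix.
    """
    path = Path(path)
    image = slab if isinstance(slab, np.ndarray) else slab.image
    image = np.ascontiguousarray(np.asarray(image, dtype=np.uint8).T)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, photometric="minisblack")
    else:
        iio.imwrite(path, image, extension=path.suffix or ".png")
    return path


def read_enface_image(path: str | Path) -> np.ndarray:
    """Read an image written by :func:`write_enface_image` back to (a, b) order."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    else:
        image = iio.imread(path)
    return np.asarray(image).T


def write_depth_map(depth_map: np.ndarray, path: str | Path) -> Path:
    """Export a fractional surface depth map as a 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(depth_map, dtype=np.float32).T)
    return path
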