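"""Vessel/stroma binarization, vessel density, and vessel diameter measurement.

Vessels are hypo-reflective on en face choroidal C-scans, so a pixel is vessel
iff its intensity is at or below the threshold (strict default 65 of 255; a
loose alternative of 110 is kept as an option).  Density is the vessel-pixel
fraction over a scope — the full 6x6 mm scan or a selected 500x500 um region.
Diameters are horizontal (fast-scan axis) run lengths through the vessel
lumen, in pixels, converted to microns with the anisometric pixel pitch
(6000/512 = 11.72 um horizontally on the standard cube).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .enface import EnFaceSlab

__all__ = [
    "STRICT_THRESHOLD",
    "LOOSE_THRESHOLD",
    "VesselMask",
    "DensityResult",
    "DiameterMeasurement",
    "binarize",
    "vessel_density",
    "select_region",
    "measure_diameter",
    "map_magnified_coords",
    "component_diameters",
    "summarize_diameters",
    "pixel_pitch",
]

STRICT_THRESHOLD = 65
LOOSE_THRESHOLD = 110


@dataclass
class VesselMask:
    """Binary vessel/stroma classification of a slab at a stated threshold."""

    mask: np.ndarray
    threshold: int
    pitch_x_um: float
    pitch_y_um: float

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)


@dataclass
class DensityResult:
    density: float
    scope: Literal["full_scan", "region"]
    threshold: int
    region_origin_um: tuple[float, float] | None = None
    region_size_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


@dataclass
class DiameterMeasurement:
    center: tuple[int, int]
    diameter_px: int
    diameter_um: float


def binarize(slab: EnFaceSlab, threshold: int = STRICT_THRESHOLD) -> VesselMask:
    """Classify pixels at or below ``threshold`` as vessel (inclusive rule).

    Grayscale slabs are single-channel, so the R=G=B threshold rule of the
    original RGB formulation reduces to one comparison per pixel.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return VesselMask(
        mask=slab.image <= threshold,
        threshold=threshold,
        pitch_x_um=slab.pitch_x_um,
        pitch_y_um=slab.pitch_y_um,
    )


def _region_to_pixels(
    mask_shape: tuple[int, int],
    origin_um: tuple[float, float],
    size_um: tuple[float, float],
    pitch_x_um: float,
    pitch_y_um: float,
) -> tuple[slice, slice]:
    """Convert a micron-space rectangle to pixel slices.

    The origin maps to the top-left pixel (0-based, floor); the window spans
    ``ceil(size/pitch)`` pixels per axis — the pinned convention for, e.g.,
    a 500x500 um region at (11.72, 46.88) um pitches being 43x11 pixels.
    """
    i0 = int(np.floor(origin_um[0] / pitch_x_um))
    j0 = int(np.floor(origin_um[1] / pitch_y_um))
    wi = int(np.ceil(size_um[0] / pitch_x_um))
    wj = int(np.ceil(size_um[1] / pitch_y_um))
    if wi <= 0 or wj <= 0:
        raise ValueError("region size must be positive")
    if i0 < 0 or j0 < 0 or i0 + wi > mask_shape[0] or j0 + wj > mask_shape[1]:
        raise ValueError(
            f"region origin {origin_um} um, size {size_um} um maps to pixels "
            f"[{i0}:{i0 + wi}, {j0}:{j0 + wj}] outside the {mask_shape} grid"
        )
    return slice(i0, i0 + wi), slice(j0, j0 + wj)


def vessel_density(
    mask: VesselMask,
    region_origin_um: tuple[float, float] | None = None,
    region_size_um: tuple[float, float] | None = None,
) -> DensityResult:
    """Vessel-pixel fraction over the full scan or a micron-space region."""
    if (region_origin_um is None) != (region_size_um is None):
        raise ValueError("give both region origin and size, or neither")
    if region_origin_um is None:
        return DensityResult(
            density=float(mask.mask.mean()),
            scope="full_scan",
            threshold=mask.threshold,
        )
    si, sj = _region_to_pixels(
        mask.mask.shape, region_origin_um, region_size_um,
        mask.pitch_x_um, mask.pitch_y_um,
    )
    window = mask.mask[si, sj]
    if window.size == 0:
        raise ValueError("empty region")
    return DensityResult(
        density=float(window.mean()),
        scope="region",
        threshold=mask.threshold,
        region_origin_um=tuple(float(v) for v in region_origin_um),
        region_size_um=tuple(float(v) for v in region_size_um),
    )


def select_region(
    slab: EnFaceSlab,
    size_um: tuple[float, float] = (500.0, 500.0),
    manual_origin_um: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Pick a representative region with visible vasculature; returns its
    top-left origin in microns.

    Manual coordinates are returned verbatim.  Automatic mode scores
    non-overlapping candidate tiles by their mean absolute horizontal
    intensity gradient — the vessel/stroma alternation that makes vasculature
    "visible" — discards tiles scoring below half the best (no visible
    vasculature), and returns the tile with the *median* score among the
    rest: a representative area rather than an extreme one, so the selection
    does not systematically favor unusually sparse or dense windows.
    """
    if manual_origin_um is not None:
        return tuple(float(v) for v in manual_origin_um)
    image = slab.image.astype(np.float64)
    wi = int(np.ceil(size_um[0] / slab.pitch_x_um))
    wj = int(np.ceil(size_um[1] / slab.pitch_y_um))
    na, nb = image.shape
    if wi > na or wj > nb:
        raise ValueError(
            f"region of {size_um} um ({wi}x{wj} px) exceeds the {image.shape} slab"
        )
    grad = np.abs(np.diff(image, axis=0))
    grad = np.pad(grad, ((0, 1), (0, 0)))
    tiles = []
    for i0 in range(0, na - wi + 1, wi):
        for j0 in range(0, nb - wj + 1, wj):
            tiles.append((float(grad[i0 : i0 + wi, j0 : j0 + wj].mean()), i0, j0))
    best = max(score for score, *_ in tiles)
    visible = sorted(t for t in tiles if t[0] >= 0.5 * best)
    score, i0, j0 = visible[len(visible) // 2]
    return float(i0 * slab.pitch_x_um), float(j0 * slab.pitch_y_um)


def measure_diameter(mask: VesselMask, seed_point: tuple[int, int]) -> DiameterMeasurement:
    """Horizontal diameter through a vessel pixel.

    Scans left and right along the fast-scan axis from ``seed_point`` to the
    first stroma pixel on either side; the run length of contiguous vessel
    pixels is the diameter in pixels, converted to microns with the horizontal
    pitch.  Raises ``ValueError`` if the seed lies on stroma.
    """
    i, j = seed_point
    m = mask.mask
    if not (0 <= i < m.shape[0] and 0 <= j < m.shape[1]):
        raise ValueError(f"seed point {seed_point} outside the {m.shape} mask")
    if not m[i, j]:
        raise ValueError(f"seed point {seed_point} lies on stroma, not vessel")
    column = m[:, j]
    left = i
    while left > 0 and column[left - 1]:
        left -= 1
    right = i
    while right < column.shape[0] - 1 and column[right + 1]:
        right += 1
    diameter_px = right - left + 1
    return DiameterMeasurement(
        center=(i, j),
        diameter_px=diameter_px,
        diameter_um=diameter_px * mask.pitch_x_um,
    )


def map_magnified_coords(
    point: tuple[float, float],
    magnified_size: tuple[float, float],
    original_size: tuple[float, float],
) -> tuple[int, int]:
    """Map a point picked on a magnified display back to original-image pixels.

    Coordinates are scaled by ``original/magnified`` per axis and rounded to
    the nearest pixel — the correction applied when vessel edges are picked on
    an enlarged rendering of the C-scan.
    """
    if min(magnified_size) <= 0 or min(original_size) <= 0:
        raise ValueError("sizes must be positive")
    return tuple(
        int(round(p * o / m)) for p, m, o in zip(point, magnified_size, original_size)
    )


def component_diameters(
    mask: VesselMask,
    central_band: float = 0.5,
    min_rows: int = 1,
) -> list[DiameterMeasurement]:
    """One representative horizontal diameter per detected vessel.

    Vessels are 8-connected components of the mask.  For each component, run
    lengths are collected over the central ``central_band`` fraction of B-scan
    rows, runs touching the lateral image boundary (vessels cut off by the
    scan edge, hence not fully "visible") are dropped, and the component's
    representative diameter is the median run length — robust to occasional
    pixel-level bridging between neighboring vessels.
    """
    m = mask.mask
    labeled, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    na, nb = m.shape
    j_lo = int(round(nb * (0.5 - central_band / 2)))
    j_hi = max(int(round(nb * (0.5 + central_band / 2))), j_lo + 1)
    runs: dict[int, list[tuple[int, int]]] = {}
    for j in range(j_lo, j_hi):
        col = m[:, j]
        padded = np.concatenate([[False], col, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for s, e in zip(starts, ends):
            if s == 0 or e == na:  # clipped by the lateral boundary
                continue
            label = labeled[s, j]
            runs.setdefault(label, []).append((e - s, s))
    out: list[DiameterMeasurement] = []
    for label, rr in sorted(runs.items()):
        if len(rr) < min_rows:
            continue
        lengths = sorted(length for length, _ in rr)
        rep = lengths[len(lengths) // 2]
        # seed: any run of representative length
        seed_start = next(s for length, s in rr if length == rep)
        seed_j = next(
            j for j in range(j_lo, j_hi)
            if labeled[seed_start, j] == label and m[seed_start, j]
        )
        out.append(
            DiameterMeasurement(
                center=(seed_start + rep // 2, seed_j),
                diameter_px=rep,
                diameter_um=rep * mask.pitch_x_um,
            )
        )
    return out


def summarize_diameters(
    measurements: Sequence[DiameterMeasurement | float],
    scheme: Literal["standard", "rpd"] = "standard",
    pitch_x_um: float | None = None,
) -> tuple[float, float | None]:
    """Per-image vessel-diameter average, ``(pixels, microns)``.

    ``standard``: the mean of the largest and smallest vessel diameters (>= 2
    measurements required).  ``rpd``: for the superficial layer of eyes
    without a visible choriocapillaris, the mean of five designated
    measurements spanning large, medium, and small vessels — with exactly five
    values their plain mean, with a larger pool the min/Q1/median/Q3/max
    representatives (>= 5 required).

    Accepts either :class:`DiameterMeasurement` objects or bare pixel values
    (give ``pitch_x_um`` to get microns back for bare values).
    """
    values = [
        float(m.diameter_px) if isinstance(m, DiameterMeasurement) else float(m)
        for m in measurements
    ]
    if pitch_x_um is None:
        for m in measurements:
            if isinstance(m, DiameterMeasurement) and m.diameter_px:
                pitch_x_um = m.diameter_um / m.diameter_px
                break
    if scheme == "standard":
        if len(values) < 2:
            raise ValueError(
                "standard scheme needs at least 2 measurements "
                "(largest and smallest visible vessels)"
            )
        mean_px = (max(values) + min(values)) / 2.0
    elif scheme == "rpd":
        if len(values) < 5:
            raise ValueError(
                "rpd scheme needs at least 5 measurements "
                "(large, medium, and small vessels)"
            )
        if len(values) == 5:
            chosen = values
        else:
            chosen = list(np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0]))
        mean_px = float(np.mean(chosen))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return mean_px, (mean_px * pitch_x_um if pitch_x_um is not None else None)


def pixel_pitch(scan_width_um: float, n_samples: int) -> float:
    """Physical pixel pitch, um: scan width divided by sample count.

    The standard macular cube gives 6000/512 = 11.72 um horizontally and
    6000/128 = 46.88 um vertically.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if scan_width_um <= 0:
        raise ValueError("scan_width_um must be positive")
    return scan_width_um / n_samples
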