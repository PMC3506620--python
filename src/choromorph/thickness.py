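"""Choroidal thickness: RPE base to choroid-sclera junction on a B-scan.

The choroid-sclera junction (CSJ) is found per A-scan as the deepest sustained
intensity step below the RPE after lateral smoothing; thickness is the axial
distance from the fitted RPE base to the CSJ at a chosen column (default: the
central A-scan of the central B-scan, emulating the foveal caliper placement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rpe import RpeSurface
from .volume_io import OctVolume

__all__ = ["ThicknessResult", "CsjError", "segment_csj", "measure_thickness"]


class CsjError(RuntimeError):
    """Raised when no choroid-sclera transition can be located."""


@dataclass
class ThicknessResult:
    thickness_um: float
    a_scan_position: int
    b_scan_position: int

    def __post_init__(self) -> None:
        if self.thickness_um < 0:
            raise ValueError("thickness_um must be non-negative")


def segment_csj(
    volume: OctVolume,
    surface: RpeSurface,
    b_scan: int | None = None,
    lateral_smooth_px: int = 31,
    step_window_vox: int = 3,
    step_threshold: float = 25.0,
    min_offset_um: float = 30.0,
) -> np.ndarray:
    """Per-A-scan axial index of the choroid-sclera junction on one B-scan.

    The B-scan is smoothed laterally (boxcar of ``lateral_smooth_px`` columns)
    so vessel texture averages toward the layer mean, then for every depth the
    mean over the ``step_window_vox`` voxels below is compared with the mean
    above; the deepest position where the downward step exceeds
    ``step_threshold`` gray levels — at least ``min_offset_um`` below the RPE —
    is the junction.  The resulting depth profile is median-filtered across
    A-scans.  Raises :class:`CsjError` when no such step exists anywhere.
    """
    j = volume.n_bscan // 2 if b_scan is None else b_scan
    bscan = volume.bscan(j).astype(np.float32)  # (a_scan, depth)
    smoothed = ndimage.uniform_filter1d(bscan, lateral_smooth_px, axis=0, mode="nearest")
    smoothed = ndimage.gaussian_filter1d(smoothed, 1.0, axis=1)

    na, nz = smoothed.shape
    k = step_window_vox
    cum = np.concatenate([np.zeros((na, 1), np.float64), smoothed.cumsum(axis=1)], axis=1)
    # step[z] = mean(smoothed[z:z+k]) - mean(smoothed[z-k:z]); defined for k<=z<=nz-k
    below = (cum[:, 2 * k :] - cum[:, k:-k]) / k
    above = (cum[:, k:-k] - cum[:, : -2 * k]) / k
    step = below - above  # column m corresponds to boundary z = m + k
    z_of_col = np.arange(k, nz - k + 1)

    rpe = surface.depth_map[:, j]
    min_z = rpe + min_offset_um / volume.axial_pitch_um
    candidates = (step < -step_threshold) & (z_of_col[None, :] >= min_z[:, None])
    any_found = candidates.any(axis=1)
    if not any_found.any():
        raise CsjError(
            f"no sustained downward step below the RPE on B-scan {j} "
            f"(threshold {step_threshold} gray levels)"
        )
    # deepest qualifying step per column, refined to the local step minimum
    # (the true boundary), since partial windows just past it still qualify
    rev = candidates[:, ::-1]
    deepest = candidates.shape[1] - 1 - np.argmax(rev, axis=1)
    offsets = np.arange(-k, k + 1)
    neighborhood = np.clip(deepest[:, None] + offsets[None, :], 0, step.shape[1] - 1)
    local = np.take_along_axis(step, neighborhood, axis=1)
    deepest = neighborhood[np.arange(na), np.argmin(local, axis=1)]
    csj = z_of_col[deepest].astype(np.float64)
    if (~any_found).any():
        good = np.flatnonzero(any_found)
        csj = np.interp(np.arange(na), good, csj[good])
    csj = ndimage.median_filter(csj, size=9, mode="nearest")
    return csj


def measure_thickness(
    volume: OctVolume,
    surface: RpeSurface,
    csj: np.ndarray,
    a_scan: int | None = None,
    b_scan: int | None = None,
) -> ThicknessResult:
    """Choroidal thickness ``(CSJ - RPE base) * axial pitch`` at one column.

    Defaults to the central A-scan of the central B-scan (the foveal column of
    a fovea-centered cube).  Raises ``ValueError`` if the junction lies above
    the RPE at the measurement column.
    """
    j = volume.n_bscan // 2 if b_scan is None else b_scan
    i = volume.n_ascan // 2 if a_scan is None else a_scan
    if not 0 <= i < volume.n_ascan:
        raise ValueError(f"a_scan {i} outside [0, {volume.n_ascan})")
    rpe = float(surface.depth_map[i, j])
    junction = float(csj[i])
    if junction < rpe:
        raise ValueError(
            f"choroid-sclera junction ({junction:.1f}) lies above the RPE base "
            f"({rpe:.1f}) at a_scan {i}"
        )
    return ThicknessResult(
        thickness_um=(junction - rpe) * volume.axial_pitch_um,
        a_scan_position=i,
        b_scan_position=j,
    )
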