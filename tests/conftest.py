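"""Shared fixtures: reduced-geometry synthetic eyes.

Unit tests run on a quarter-size cube (256x64 A/B-scans over a 3 mm square,
512 axial samples over 1 mm) that preserves the standard pixel pitches
(11.72 x 46.88 x 1.95 um), so every pitch-dependent quantity behaves exactly
as at full size while generation stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from choromorph import synthetic
from choromorph.volume_io import OctVolume

SMALL_GEOMETRY = dict(
    n_ascan=256,
    n_bscan=64,
    n_axial=512,
    scan_width_um=3000.0,
    axial_depth_um=1000.0,
    rpe_base_depth_um=300.0,
)


@pytest.fixture(scope="session")
def small_geometry() -> dict:
    return dict(SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def control_eye():
    """A rendered control eye (intact choriocapillaris) plus ground truth."""
    params = synthetic.default_eye_params("control", seed=42, **SMALL_GEOMETRY)
    volume, truth = synthetic.generate_volume(params)
    return params, volume, truth


@pytest.fixture(scope="session")
def reticular_eye():
    """A rendered reticular-pseudodrusen eye (no choriocapillaris)."""
    params = synthetic.default_eye_params("reticular", seed=43, **SMALL_GEOMETRY)
    volume, truth = synthetic.generate_volume(params)
    return params, volume, truth


def make_band_volume(
    n_ascan: int = 64,
    n_bscan: int = 16,
    n_axial: int = 256,
    base_index: int = 100,
    band_vox: int = 8,
    below_value: int = 180,
    above_value: int = 30,
    axial_pitch_um: float = 1.953125,
) -> OctVolume:
    """A volume with a flat bright band whose base (first voxel below the
    band) sits at ``base_index`` — the minimal RPE phantom."""
    vol = np.full((n_ascan, n_bscan, n_axial), above_value, dtype=np.uint8)
    vol[:, :, base_index - band_vox : base_index] = 255
    vol[:, :, base_index:] = below_value
    return OctVolume(
        intensities=vol,
        lateral_pitch_x_um=11.71875,
        lateral_pitch_y_um=46.875,
        axial_pitch_um=axial_pitch_um,
    )
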