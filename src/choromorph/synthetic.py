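"""Synthetic OCT macular-cube phantoms of the choroidal vasculature.

The generator produces 3-D volumes with the geometry of a 512x128 macular cube
over a 6x6 mm grid (~2 mm of depth at ~1.95 um per axial sample) together with
voxel-level ground truth, so that every downstream stage of the morphometry
pipeline (RPE segmentation, C-scan extraction, binarization, density, diameter,
thickness, cohort statistics) can be validated against known answers.

Anatomy emulated, from inner to outer along each A-scan: a dim pre-RPE region,
a bright RPE band following a smooth dome-shaped surface, a choroid of known
thickness split into three stacked vascular zones (choriocapillaris, middle /
Sattler, outer / Haller), and homogeneous sclera.  Each zone contains straight,
parallel, hypo-reflective vessels rendered as constant-width ribbons: the
horizontal (en face) width equals the drawn caliber at every depth inside the
zone's vessel band, which makes the ground-truth density and diameter analytic
and independent of exactly where inside the band a C-scan is taken.

Cohorts emulate three clinical groups plus an advanced subgroup: controls
(epiretinal membrane, intact granular choriocapillaris), early AMD (drusen,
choriocapillaris present in ~45% of eyes), and reticular pseudodrusen with or
without advanced AMD (no granular choriocapillaris; the zone just under the
RPE carries middle-caliber vessels instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .volume_io import OctVolume

__all__ = [
    "GROUPS",
    "LayerSpec",
    "EyeParams",
    "GroundTruth",
    "default_layer_specs",
    "default_eye_params",
    "sample_eye_params",
    "generate_volume",
    "generate_cohort",
    "iter_cohort",
]

GROUPS = ("control", "early_amd", "reticular", "advanced_reticular")

#: Default rendered intensities (8-bit). Vessels are hypo-reflective lumens on
#: bright stroma; the strict threshold 65 separates them cleanly, the loose
#: threshold 110 still classifies sclera as non-vessel.
VESSEL_INTENSITY = 40
STROMA_INTENSITY = 180
RPE_INTENSITY = 255
PRE_RPE_INTENSITY = 30
SCLERA_INTENSITY = 120

#: RPE band thickness, um (the bright monolayer complex as imaged).
RPE_BAND_UM = 16.0
#: Margin between the RPE base and the top of the choriocapillaris band, um
#: (a thin Bruch's/stroma gap that keeps the RPE posterior edge a clean step).
INNER_TOP_MARGIN_UM = 6.0
#: Stroma left between the outer vessel band and the sclera so the
#: choroid-sclera junction remains a clean step, um.
CSJ_MARGIN_UM = 10.0
#: Vessels run within this angle of the slow-scan (y) axis, degrees, so the
#: horizontal caliper reads the true caliber to within ~1% (sec 15deg = 1.035).
MAX_TILT_DEG = 15.0

# Table-derived group defaults: full-scan vessel density per layer (inner,
# middle, outer, as fractions), choroidal thickness mean/SD (um), age mean/SD
# (years), and the proportion of female eyes.
_GROUP_DENSITY = {
    "control": (0.765, 0.836, 0.872),
    "early_amd": (0.722, 0.803, 0.872),
    "reticular": (0.738, 0.800, 0.859),
    "advanced_reticular": (0.738, 0.800, 0.859),
}
_GROUP_THICKNESS = {
    "control": (207.0, 42.5),
    "early_amd": (228.6, 58.4),
    "reticular": (163.4, 68.5),
    "advanced_reticular": (179.0, 99.4),
}
_GROUP_AGE = {
    "control": (61.0, 10.7),
    "early_amd": (76.7, 9.0),
    "reticular": (82.6, 7.0),
    "advanced_reticular": (84.3, 7.6),
}
_GROUP_FEMALE_FRACTION = {
    "control": 7 / 14,
    "early_amd": 4 / 11,
    "reticular": 19 / 23,
    "advanced_reticular": 8 / 10,
}
#: Probability that an early AMD eye retains a visible choriocapillaris.
EARLY_AMD_CC_PROBABILITY = 5 / 11

#: Sampled choroidal thicknesses are clamped to this range (um): thinner
#: choroids cannot hold three renderable vessel bands at the default calibers.
THICKNESS_CLAMP_UM = (130.0, 380.0)
AGE_CLAMP_YEARS = (41.0, 97.0)


@dataclass(frozen=True)
class LayerSpec:
    """One choroidal vascular zone of the phantom.

    ``vessel_diameter_um`` is the mean horizontal caliber; individual vessels
    draw their caliber from a symmetric truncated normal with the given spread
    (clipped at two spreads).  ``target_density`` is the fraction of the en
    face plane the zone's vessels should cover.  ``max_axial_extent_um`` caps
    the axial extent of the rendered vessel band; without a cap a vessel is as
    deep as it is wide and a zone thinner than one caliber is rejected.
    """

    thickness_fraction: float
    vessel_diameter_um: float
    diameter_spread_um: float
    target_density: float
    vessel_intensity: int = VESSEL_INTENSITY
    stroma_intensity: int = STROMA_INTENSITY
    max_axial_extent_um: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.thickness_fraction < 1:
            raise ValueError("thickness_fraction must lie in (0, 1)")
        if not 0 <= self.target_density <= 1:
            raise ValueError("target_density must lie in [0, 1]")
        if self.vessel_diameter_um <= 0:
            raise ValueError("vessel_diameter_um must be positive")
        if not self.vessel_intensity < self.stroma_intensity:
            raise ValueError("vessels must be darker than stroma")


def default_layer_specs(group: str) -> tuple[LayerSpec, LayerSpec, LayerSpec]:
    """Inner/middle/outer layer defaults for a clinical group.

    Calibers follow the reported averages (~50 um choriocapillaris, ~100 um
    middle, ~215 um outer vessels); densities are the group's full-scan
    per-layer averages.  Axial-extent caps keep every band renderable inside
    choroids in the observed 130-380 um thickness range.
    """
    d_in, d_mid, d_out = _GROUP_DENSITY[group]
    return (
        LayerSpec(0.25, 50.0, 8.0, d_in, max_axial_extent_um=30.0),
        LayerSpec(0.35, 100.0, 10.0, d_mid, max_axial_extent_um=60.0),
        LayerSpec(0.40, 215.0, 12.0, d_out, max_axial_extent_um=50.0),
    )


@dataclass
class EyeParams:
    """Full parameterization of one synthetic eye."""

    group: str
    age: float
    gender: str
    choroid_thickness_um: float
    rpe_curvature_um: float
    layer_specs: tuple[LayerSpec, LayerSpec, LayerSpec]
    choriocapillaris_present: bool
    seed: int
    speckle_sigma: float = 0.1
    n_ascan: int = 512
    n_bscan: int = 128
    n_axial: int = 1024
    scan_width_um: float = 6000.0
    axial_depth_um: float = 2000.0
    rpe_base_depth_um: float = 500.0
    eye_id: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be 'F' or 'M'")
        if self.choroid_thickness_um <= 0:
            raise ValueError("choroid_thickness_um must be positive")
        if len(self.layer_specs) != 3:
            raise ValueError("exactly three layer specs (inner, middle, outer)")
        if abs(sum(s.thickness_fraction for s in self.layer_specs) - 1.0) > 1e-9:
            raise ValueError("layer thickness fractions must sum to 1")
        if self.group == "control" and not self.choriocapillaris_present:
            raise ValueError("control eyes have an intact choriocapillaris")
        if self.group in ("reticular", "advanced_reticular") and self.choriocapillaris_present:
            raise ValueError("reticular eyes lack a visible choriocapillaris")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")

    @property
    def lateral_pitch_x_um(self) -> float:
        return self.scan_width_um / self.n_ascan

    @property
    def lateral_pitch_y_um(self) -> float:
        return self.scan_width_um / self.n_bscan

    @property
    def axial_pitch_um(self) -> float:
        return self.axial_depth_um / self.n_axial


@dataclass
class GroundTruth:
    """Voxel-level ground truth accompanying a generated volume.

    ``rpe_depth_map`` gives, per lateral position, the axial index of the first
    sub-RPE (choroidal) voxel, the reference the pipeline's RPE segmentation is
    judged against.  ``layer_offsets_um`` are the depths (um below the RPE
    base) of the centers of the three vessel bands: extracting a C-scan there
    is the ground-truth-driven counterpart of placing a slice manually with
    B-scan guidance.  ``per_layer_density`` is the exact fraction of the en
    face grid covered by each band (recomputable from the label volume at any
    depth inside the band); ``per_layer_mean_diameter_um`` the mean drawn
    caliber of the rendered vessels.
    """

    vessel_labels: np.ndarray
    rpe_depth_map: np.ndarray
    per_layer_density: tuple[float, float, float]
    per_layer_mean_diameter_um: tuple[float, float, float]
    layer_offsets_um: tuple[float, float, float]
    layer_bands_um: tuple[tuple[float, float], ...]
    choroid_thickness_um: float
    vessel_orientation_deg: tuple[float, float, float]


def default_eye_params(group: str, seed: int = 0, **overrides) -> EyeParams:
    """A deterministic, group-typical eye (group means, no sampling)."""
    cc = group == "control" or (group == "early_amd")
    if group in ("reticular", "advanced_reticular"):
        cc = False
    params = EyeParams(
        group=group,
        age=_GROUP_AGE[group][0],
        gender="F",
        choroid_thickness_um=_GROUP_THICKNESS[group][0],
        rpe_curvature_um=100.0,
        layer_specs=default_layer_specs(group),
        choriocapillaris_present=cc,
        seed=seed,
    )
    if overrides:
        params = replace(params, **overrides)
    return params


def sample_eye_params(
    n_per_group: Sequence[int],
    seed: int,
    **overrides,
) -> list[EyeParams]:
    """Draw per-eye parameters for a cohort from the group distributions.

    ``n_per_group`` is ``(control, early_amd, reticular, advanced_reticular)``.
    Ages and choroidal thicknesses come from the groups' reported mean +/- SD
    (clamped to physiologic/renderable ranges), gender from the groups'
    reported proportions, and choriocapillaris presence is certain in controls,
    absent in reticular eyes, and Bernoulli(5/11) in early AMD.
    """
    if len(n_per_group) != len(GROUPS):
        raise ValueError(f"n_per_group must have {len(GROUPS)} entries")
    if any(n < 0 for n in n_per_group):
        raise ValueError("cohort sizes must be non-negative")
    root = np.random.default_rng(seed)
    eyes: list[EyeParams] = []
    idx = 0
    for group, n in zip(GROUPS, n_per_group):
        for _ in range(n):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            age = float(np.clip(rng.normal(*_GROUP_AGE[group]), *AGE_CLAMP_YEARS))
            thickness = float(
                np.clip(rng.normal(*_GROUP_THICKNESS[group]), *THICKNESS_CLAMP_UM)
            )
            gender = "F" if rng.random() < _GROUP_FEMALE_FRACTION[group] else "M"
            if group == "control":
                cc = True
            elif group == "early_amd":
                cc = bool(rng.random() < EARLY_AMD_CC_PROBABILITY)
            else:
                cc = False
            params = EyeParams(
                group=group,
                age=round(age, 1),
                gender=gender,
                choroid_thickness_um=round(thickness, 1),
                rpe_curvature_um=float(rng.uniform(50.0, 150.0)),
                layer_specs=default_layer_specs(group),
                choriocapillaris_present=cc,
                seed=int(rng.integers(0, 2**31 - 1)),
                eye_id=f"eye{idx:03d}",
            )
            if overrides:
                params = replace(params, **overrides)
            eyes.append(params)
            idx += 1
    return eyes


def _rpe_surface_um(params: EyeParams) -> np.ndarray:
    """Depth (um) of the RPE base per lateral position.

    The posterior bowing of the globe is modeled as an elliptic paraboloid:
    the surface is ``rpe_curvature_um`` deeper at the scan center than at the
    corners — a smooth low-order dome of the kind the surface-fitting stage
    is designed to regularize.
    """
    x = (np.arange(params.n_ascan) + 0.5) * params.lateral_pitch_x_um
    y = (np.arange(params.n_bscan) + 0.5) * params.lateral_pitch_y_um
    cx, cy = params.scan_width_um / 2, params.scan_width_um / 2
    r2 = ((x[:, None] - cx) ** 2) + ((y[None, :] - cy) ** 2)
    r2_max = cx**2 + cy**2
    bump = 1.0 - r2 / r2_max
    return params.rpe_base_depth_um + RPE_BAND_UM + params.rpe_curvature_um * bump


def _effective_layers(params: EyeParams) -> tuple[LayerSpec, LayerSpec, LayerSpec]:
    """Layer specs as rendered: eyes without a choriocapillaris carry
    middle-caliber vessels in the zone just beneath the RPE."""
    inner, middle, outer = params.layer_specs
    if not params.choriocapillaris_present:
        inner = replace(
            inner,
            vessel_diameter_um=middle.vessel_diameter_um,
            diameter_spread_um=middle.diameter_spread_um,
            max_axial_extent_um=middle.max_axial_extent_um,
        )
    return inner, middle, outer


def _layer_bands(
    params: EyeParams, layers: Sequence[LayerSpec]
) -> list[tuple[float, float]]:
    """Axial extent (um below the RPE base) of each zone's vessel band.

    The choriocapillaris band hugs the RPE (top margin 2 um); deeper bands sit
    at their zone center, except that the outer band keeps a 10 um stromal
    margin above the sclera so the choroid-sclera junction stays detectable.
    Raises if a band cannot fit (zone thinner than one vessel diameter when no
    axial cap is set, or a degenerate sliver otherwise).
    """
    T = params.choroid_thickness_um
    fractions = [s.thickness_fraction for s in layers]
    edges = np.concatenate([[0.0], np.cumsum(fractions)]) * T
    bands: list[tuple[float, float]] = []
    margin = 6.0  # stroma retained above+below a centered band, um
    for i, spec in enumerate(layers):
        zone_lo, zone_hi = edges[i], edges[i + 1]
        zone = zone_hi - zone_lo
        if spec.max_axial_extent_um is None and spec.vessel_diameter_um > zone:
            raise ValueError(
                f"layer {i} ({zone:.1f} um) is thinner than one vessel diameter "
                f"({spec.vessel_diameter_um:.1f} um); set max_axial_extent_um or "
                "thicken the layer"
            )
        cap = spec.max_axial_extent_um or spec.vessel_diameter_um
        if i == 0:
            extent = min(spec.vessel_diameter_um, cap, zone - 2 * INNER_TOP_MARGIN_UM)
            lo = zone_lo + INNER_TOP_MARGIN_UM
        else:
            extent = min(spec.vessel_diameter_um, cap, zone - margin)
            center = min((zone_lo + zone_hi) / 2, zone_hi - CSJ_MARGIN_UM - extent / 2)
            center = max(center, zone_lo + extent / 2)
            lo = center - extent / 2
        if extent < 2 * params.axial_pitch_um:
            raise ValueError(
                f"layer {i}: vessel band of {extent:.1f} um cannot be rendered at "
                f"an axial pitch of {params.axial_pitch_um:.2f} um"
            )
        bands.append((lo, lo + extent))
    return bands


def _place_vessels(
    spec: LayerSpec,
    theta_rad: float,
    params: EyeParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float]]:
    """Rasterize one zone's parallel vessel strips onto the en face grid.

    Returns the boolean coverage mask (a_scan x b_scan) and the drawn calibers.
    Strips are laid along the direction ``theta`` from the y axis; successive
    strips are separated by random stromal gaps sized so that expected coverage
    matches ``target_density``.
    """
    na, nb = params.n_ascan, params.n_bscan
    mask = np.zeros((na, nb), dtype=bool)
    if spec.target_density <= 0:
        return mask, []
    x = (np.arange(na) + 0.5) * params.lateral_pitch_x_um
    y = (np.arange(nb) + 0.5) * params.lateral_pitch_y_um
    # signed distance along the strip normal
    P = x[:, None] * math.cos(theta_rad) - y[None, :] * math.sin(theta_rad)
    p_lo, p_hi = float(P.min()), float(P.max())
    d_mean = spec.vessel_diameter_um
    rho = spec.target_density
    mean_gap = d_mean * (1.0 - rho) / rho if rho < 1 else 0.0
    calibers: list[float] = []
    edge = p_lo + float(rng.uniform(0.0, d_mean + mean_gap))
    while True:
        d = float(rng.normal(d_mean, spec.diameter_spread_um))
        d = float(np.clip(d, d_mean - 2 * spec.diameter_spread_um,
                          d_mean + 2 * spec.diameter_spread_um))
        center = edge + d / 2
        if center - d / 2 > p_hi:
            break
        mask |= np.abs(P - center) <= d / 2
        calibers.append(d)
        gap = float(rng.uniform(0.7, 1.3)) * mean_gap
        edge = center + d / 2 + gap
    return mask, calibers


def generate_volume(params: EyeParams) -> tuple[OctVolume, GroundTruth]:
    """Render one synthetic eye and its ground truth.

    Deterministic in ``params.seed``: the same parameters always yield
    bit-identical volumes.  Raises ``ValueError`` if a vessel band cannot fit
    inside its zone (see :func:`_layer_bands`).
    """
    rng = np.random.default_rng(params.seed)
    pz = params.axial_pitch_um
    na, nb, nz = params.n_ascan, params.n_bscan, params.n_axial
    layers = _effective_layers(params)
    bands = _layer_bands(params, layers)

    T_vox = int(round(params.choroid_thickness_um / pz))
    surface_um = _rpe_surface_um(params)
    base = np.rint(surface_um / pz).astype(np.int64)  # first choroidal voxel
    band_vox = int(round(RPE_BAND_UM / pz))
    if (base - band_vox).min() < 1 or (base + T_vox).max() >= nz:
        raise ValueError(
            "choroid does not fit axially: RPE base spans "
            f"[{base.min()}, {base.max()}] voxels, choroid {T_vox} voxels, "
            f"volume depth {nz}"
        )

    # choroid block in RPE-flattened coordinates: (a, b, depth-below-base)
    block = np.full((na, nb, T_vox), STROMA_INTENSITY, dtype=np.uint8)
    labels_block = np.zeros((na, nb, T_vox), dtype=bool)
    densities: list[float] = []
    diameters: list[float] = []
    offsets: list[float] = []
    thetas: list[float] = []
    for spec, (b_lo, b_hi) in zip(layers, bands):
        theta = math.radians(float(rng.uniform(-MAX_TILT_DEG, MAX_TILT_DEG)))
        plane, calibers = _place_vessels(spec, theta, params, rng)
        z0 = int(np.ceil(b_lo / pz))
        z1 = max(int(np.floor(b_hi / pz)), z0 + 1)
        z1 = min(z1, T_vox)
        stroma_col = np.full((na, nb), spec.stroma_intensity, dtype=np.uint8)
        vessel_col = np.full((na, nb), spec.vessel_intensity, dtype=np.uint8)
        block[:, :, z0:z1] = np.where(plane, vessel_col, stroma_col)[:, :, None]
        labels_block[:, :, z0:z1] = plane[:, :, None]
        densities.append(float(plane.mean()))
        diameters.append(float(np.mean(calibers)) if calibers else 0.0)
        offsets.append((b_lo + b_hi) / 2)
        thetas.append(math.degrees(theta))

    volume = np.full((na, nb, nz), PRE_RPE_INTENSITY, dtype=np.uint8)
    labels = np.zeros((na, nb, nz), dtype=bool)
    ii, jj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    for dz in range(band_vox):
        volume[ii, jj, base - band_vox + dz] = RPE_INTENSITY
    for dz in range(T_vox):
        volume[ii, jj, base + dz] = block[:, :, dz]
        labels[ii, jj, base + dz] = labels_block[:, :, dz]
    zgrid = np.arange(nz)[None, None, :]
    volume[zgrid >= (base + T_vox)[:, :, None]] = SCLERA_INTENSITY

    if params.speckle_sigma > 0:
        sigma = params.speckle_sigma
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=volume.shape)
        volume = np.clip(
            volume.astype(np.float32) * noise.astype(np.float32), 0, 255
        ).astype(np.uint8)

    oct_volume = OctVolume(
        intensities=volume,
        lateral_pitch_x_um=params.lateral_pitch_x_um,
        lateral_pitch_y_um=params.lateral_pitch_y_um,
        axial_pitch_um=pz,
        metadata={
            "eye_id": params.eye_id,
            "group": params.group,
            "age": params.age,
            "gender": params.gender,
            "seed": params.seed,
            "choroid_thickness_um": params.choroid_thickness_um,
        },
    )
    truth = GroundTruth(
        vessel_labels=labels,
        rpe_depth_map=base.astype(np.float64),
        per_layer_density=tuple(densities),
        per_layer_mean_diameter_um=tuple(diameters),
        layer_offsets_um=tuple(offsets),
        layer_bands_um=tuple((lo, hi) for lo, hi in bands),
        choroid_thickness_um=params.choroid_thickness_um,
        vessel_orientation_deg=tuple(thetas),
    )
    return oct_volume, truth


def cohort_table(eyes: Sequence[EyeParams]) -> pd.DataFrame:
    """Per-eye metadata rows (one eye per patient) for a cohort."""
    return pd.DataFrame(
        {
            "eye_id": [p.eye_id for p in eyes],
            "group": [p.group for p in eyes],
            "age": [p.age for p in eyes],
            "gender": [p.gender for p in eyes],
            "true_thickness_um": [p.choroid_thickness_um for p in eyes],
            "cc_present": [p.choriocapillaris_present for p in eyes],
            "seed": [p.seed for p in eyes],
        }
    )


def generate_cohort(
    n_per_group: Sequence[int],
    seed: int,
    render: bool = True,
    **overrides,
) -> tuple[list[tuple[OctVolume, GroundTruth] | None], pd.DataFrame]:
    """Generate a full cohort: per-eye volumes + ground truth and the metadata
    table.  With ``render=False`` only the metadata table is materialized
    (each volume slot is ``None``) — useful for statistics-only studies.

    Deterministic in ``seed``.
    """
    eyes = sample_eye_params(n_per_group, seed, **overrides)
    table = cohort_table(eyes)
    volumes: list[tuple[OctVolume, GroundTruth] | None] = []
    for params in eyes:
        volumes.append(generate_volume(params) if render else None)
    return volumes, table


def iter_cohort(
    eyes: Sequence[EyeParams],
) -> Iterator[tuple[EyeParams, OctVolume, GroundTruth]]:
    """Stream a cohort one rendered eye at a time (memory-friendly)."""
    for params in eyes:
        volume, truth = generate_volume(params)
        yield params, volume, truth
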