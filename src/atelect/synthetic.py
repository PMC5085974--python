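"""Synthetic thorax cohort generator with analytic ground truth.

Every downstream stage of the pipeline is exercised on phantom image pairs
whose truth is known in closed form.  A phantom is a 240 mm world cube
holding an elliptic-cylinder body, five ellipsoidal lung lobes, a nested
tumor, an atelectasis (consolidated) region inside one lobe, mediastinal
organs at risk (heart, esophagus, spinal cord), bone (spine + sternum)
with alignment landmarks, a carina ball for volumetric setup, and the two
calibration reference regions (air outside the body, blood in the
descending aorta).  All shapes are axis-aligned ellipsoids, cylinders or
boxes so that volumes and masses are available analytically: truth records
are computed from the geometry, never from voxel sums.

Between baseline and followup the consolidated region re-aerates: a
fraction ``r`` of the atelectatic tissue converts to aerated parenchyma at
lower density and correspondingly larger volume (the lobe boundary moves
outward), while an optional edema excess-mass fraction disappears on
resolution, producing a net mass decrease.  The tumor regresses, healthy
lobes jitter slightly in density and volume, and the whole followup
anatomy is displaced by a known rigid misalignment (translation), so both
alignment schemes can be validated against truth.

Not modelled: respiratory motion, 4-D sorting artifacts, beam hardening,
realistic airway anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .classify import classify as classify_resolution
from .measures import (ATELECTATIC, CONTRALATERAL, HEALTHY_IPSILATERAL,
                       ChangeRecord, RoiMeasures, change)
from .transfer import Beam, PlanGeometry, RigidTransform, square_aperture
from .volume_io import (LOBE_NAMES, LabelMaskSet, StructureOverlapError,
                        VolumeGrid, save_json, write_labels, write_landmarks,
                        write_volume)

# --------------------------------------------------------------------------
# Tissue densities (mg/cc) and world geometry (mm, 240 mm cube)
# --------------------------------------------------------------------------

AIR_DENSITY = 0.0
BODY_DENSITY = 1000.0
BONE_DENSITY = 1500.0
CORD_DENSITY = 1040.0
ESOPHAGUS_DENSITY = 1020.0
HEART_DENSITY = 1050.0
BLOOD_DENSITY = 1050.0
CARINA_DENSITY = 1100.0
TUMOR_DENSITY = 1060.0

WORLD_MM = 240.0

#: Axial (z) lobe-expansion factor cap; re-aeration expands a collapsed
#: lobe mostly in-plane here so the growing lobe stays inside the thorax
#: and clear of its superior neighbour (top face is anchored).
Z_EXPANSION_CAP = 1.25

#: Lowest density the re-aerated compartment may take (mg/cc).
MIN_AERATED_DENSITY = 60.0

_BODY = {"center": (118.0, 120.0), "semi": (112.0, 100.0)}
_SPINE = {"center": (118.0, 185.0), "radius": 16.0, "z": (0.0, WORLD_MM)}
_CORD = {"center": (118.0, 185.0), "radius": 5.0, "z": (0.0, WORLD_MM)}
_STERNUM = {"x": (103.0, 133.0), "y": (36.0, 48.0), "z": (60.0, 200.0)}
_AORTA = {"center": (103.0, 160.0), "radius": 9.0, "z": (40.0, 210.0)}
_BLOOD_REF = {"center": (103.0, 160.0), "radius": 6.0, "z": (90.0, 150.0)}
_ESOPHAGUS = {"center": (122.0, 162.0), "radius": 5.0, "z": (40.0, 210.0)}
_HEART = {"center": (105.0, 80.0, 95.0), "semi": (30.0, 28.0, 33.0)}
_CARINA = {"center": (118.0, 135.0, 150.0), "semi": (7.0, 7.0, 7.0)}
_AIR_REF = {"x": (30.0, 90.0), "y": (2.0, 12.0), "z": (60.0, 180.0)}

#: Bone landmarks (world mm) on the anterior spine surface and sternum.
BONE_LANDMARKS: tuple[tuple[str, float, float, float], ...] = (
    ("spine_1", 118.0, 169.0, 60.0),
    ("spine_2", 118.0, 169.0, 100.0),
    ("spine_3", 118.0, 169.0, 140.0),
    ("spine_4", 118.0, 169.0, 180.0),
    ("sternum_1", 105.0, 42.0, 90.0),
    ("sternum_2", 131.0, 42.0, 130.0),
    ("sternum_3", 118.0, 42.0, 170.0),
)

#: Sternum/spine box used for bone alignment.
BONE_ALIGNMENT_BOX = ((95.0, 30.0, 50.0), (141.0, 205.0, 210.0))


@dataclass(frozen=True)
class LobeGeometry:
    """Axis-aligned ellipsoid lobe: center and semi-axes in world mm."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    @property
    def volume_ml(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def default_lobe_geometry() -> dict[str, LobeGeometry]:
    return {
        "LUL": LobeGeometry((55.0, 115.0, 160.0), (30.0, 34.0, 34.0)),
        "LLL": LobeGeometry((55.0, 115.0, 85.0), (30.0, 34.0, 36.0)),
        "RUL": LobeGeometry((172.0, 115.0, 172.0), (30.0, 33.0, 30.0)),
        "RML": LobeGeometry((172.0, 112.0, 118.0), (28.0, 32.0, 18.0)),
        "RLL": LobeGeometry((170.0, 118.0, 62.0), (30.0, 32.0, 34.0)),
    }


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtelectasisSpec:
    """Consolidation in one lobe and how it resolves by followup.

    ``baseline_fraction_of_lobe`` is the collapsed fraction of the lobe
    volume (tumor included in the consolidated core).
    ``followup_resolution_fraction`` (r) is the fraction of atelectatic
    volume that re-aerates.  ``edema_excess_mass_fraction`` (e) is excess
    mass per unit of retained tissue mass in the consolidated region that
    disappears on resolution, so resolved tissue of mass m keeps m/(1+e).
    ``reaerated_density`` sets the density the re-aerated tissue takes
    (mg/cc), unless ``target_density_change`` (fractional, e.g. -0.66) is
    given, in which case the aerated density is solved so the whole-lobe
    (tumor-free) density change hits the target.
    """

    lobe: str = "RLL"
    baseline_fraction_of_lobe: float = 0.85
    followup_resolution_fraction: float = 0.5
    consolidated_density: float = 1050.0
    edema_excess_mass_fraction: float = 0.0
    reaerated_density: float = 300.0
    target_density_change: float | None = None


@dataclass(frozen=True)
class TumorSpec:
    lobe: str = "RLL"
    baseline_radius_mm: float = 10.0      # equivalent-sphere radius
    regression_fraction: float = 0.4

    @property
    def baseline_volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * self.baseline_radius_mm**3 / 1000.0


@dataclass(frozen=True)
class RawIntensityMap:
    """Affine map from density (mg/cc) to raw scanner units."""

    slope: float = 1.0
    intercept: float = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lobe_geometry: dict[str, LobeGeometry] = field(default_factory=default_lobe_geometry)
    atelectasis: AtelectasisSpec = field(default_factory=AtelectasisSpec)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    healthy_density: float = 260.0
    noise_sd: float = 20.0                 # mg/cc equivalent, additive in raw units
    raw_intensity_map: RawIntensityMap = field(default_factory=RawIntensityMap)
    misalignment_mm: tuple[float, float, float] = (3.0, -2.0, 2.5)
    healthy_density_jitter_sd: float = 0.02   # fractional
    healthy_volume_jitter_sd: float = 0.03    # fractional
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        at = self.atelectasis
        if not 0.0 <= at.followup_resolution_fraction <= 1.0:
            raise ValueError("resolution fraction must be in [0, 1]")
        if not 0.0 < at.baseline_fraction_of_lobe <= 1.0:
            raise ValueError("baseline atelectasis fraction must be in (0, 1]")
        if at.lobe not in self.lobe_geometry:
            raise ValueError(f"atelectasis lobe {at.lobe!r} has no geometry")
        if self.tumor.lobe != at.lobe:
            raise ValueError("tumor must sit in the atelectatic lobe (central obstruction)")
        lobe_v = self.lobe_geometry[at.lobe].volume_ml
        if at.baseline_fraction_of_lobe * lobe_v <= self.tumor.baseline_volume_ml:
            raise ValueError("consolidated core must be larger than the tumor")
        if at.consolidated_density <= self.healthy_density:
            raise ValueError("consolidated tissue must be denser than healthy parenchyma")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# --------------------------------------------------------------------------
# Analytic truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LobeTruth:
    lobe_id: str
    lobe_class: str
    baseline: RoiMeasures
    followup: RoiMeasures
    change: ChangeRecord


@dataclass(frozen=True)
class PhantomTruth:
    lobes: dict[str, LobeTruth]
    atelectasis_volume_baseline_ml: float
    atelectasis_volume_followup_ml: float
    resolution_label: str
    resolution_fraction: float
    aerated_density: float
    misalignment: RigidTransform      # maps followup world -> baseline world
    followup_geometry: dict           # internal: region volumes for painting


@dataclass(frozen=True)
class TimePoint:
    raw: VolumeGrid
    masks: LabelMaskSet
    landmarks: pd.DataFrame


@dataclass(frozen=True)
class PhantomPair:
    spec: PhantomSpec
    baseline: TimePoint
    followup: TimePoint
    truth: PhantomTruth


@dataclass(frozen=True)
class _PairDraws:
    """Per-pair random effects, drawn once so truth and voxels agree."""

    healthy_volume_factor: dict[str, float]
    healthy_density_factor: dict[str, float]
    misalignment_mm: np.ndarray


def _draw_pair_effects(spec: PhantomSpec, rng: np.random.Generator) -> _PairDraws:
    kv, kd = {}, {}
    for name in LOBE_NAMES:
        if name == spec.atelectasis.lobe:
            continue
        kv[name] = float(1.0 + rng.normal(0.0, spec.healthy_volume_jitter_sd))
        kd[name] = float(1.0 + rng.normal(0.0, spec.healthy_density_jitter_sd))
    return _PairDraws(kv, kd, np.asarray(spec.misalignment_mm, dtype=float))


def _lobe_class(name: str, spec: PhantomSpec) -> str:
    if name == spec.atelectasis.lobe:
        return ATELECTATIC
    if name[0] == spec.tumor.lobe[0]:
        return HEALTHY_IPSILATERAL
    return CONTRALATERAL


def _atelectatic_truth(spec: PhantomSpec) -> tuple[RoiMeasures, RoiMeasures, dict]:
    """Closed-form measures of the atelectatic lobe minus tumor, plus the
    followup region volumes needed for painting."""
    at = spec.atelectasis
    rho_h = spec.healthy_density
    rho_c = at.consolidated_density
    r = at.followup_resolution_fraction
    e = at.edema_excess_mass_fraction

    v_lobe = spec.lobe_geometry[at.lobe].volume_ml
    v_tum_b = spec.tumor.baseline_volume_ml
    v_tum_f = v_tum_b * (1.0 - spec.tumor.regression_fraction)
    v_core_b = at.baseline_fraction_of_lobe * v_lobe     # consolidated core incl. tumor
    at_b = v_core_b - v_tum_b                            # atelectasis volume, baseline
    at_f = (1.0 - r) * at_b
    v_core_f = v_tum_f + at_f
    v_healthy = v_lobe - v_core_b                        # untouched healthy compartment

    mass_b = rho_h * v_healthy + rho_c * at_b            # lobe minus tumor
    vol_b = v_lobe - v_tum_b
    dens_b = mass_b / vol_b

    m_resolved = r * at_b * rho_c / (1.0 + e)            # kept mass of resolved tissue
    mass_f = rho_h * v_healthy + rho_c * at_f + m_resolved

    if at.target_density_change is not None and m_resolved > 0:
        dens_target = dens_b * (1.0 + at.target_density_change)
        vol_target = mass_f / dens_target
        v_aer = vol_target - v_healthy - at_f
        rho_a = m_resolved / v_aer if v_aer > 0 else rho_c
    else:
        rho_a = at.reaerated_density
    rho_a = float(np.clip(rho_a, MIN_AERATED_DENSITY, rho_c))
    v_aer = m_resolved / rho_a if m_resolved > 0 else 0.0

    vol_f = v_healthy + at_f + v_aer
    mass_f = rho_h * v_healthy + rho_c * at_f + rho_a * v_aer  # == mass_f by construction
    dens_f = mass_f / vol_f

    geometry = {
        "v_tumor_f": v_tum_f,
        "v_core_f": v_core_f,
        "v_mid_f": v_core_f + v_aer,                     # aerated shell outer ellipsoid
        "v_lobe_f": v_lobe - v_core_b + v_core_f + v_aer,
        "aerated_density": rho_a,
        "atelectasis_f": at_f,
    }
    baseline = RoiMeasures(mass_b, dens_b, vol_b)
    followup = RoiMeasures(mass_f, dens_f, vol_f)
    return baseline, followup, geometry


def analytic_truth(spec: PhantomSpec, draws: _PairDraws | None = None) -> PhantomTruth:
    """Ground-truth measures/changes for every lobe, from geometry alone."""
    spec.validate()
    if draws is None:
        draws = _draw_pair_effects(spec, np.random.default_rng(spec.seed))
    rho_h = spec.healthy_density
    lobes: dict[str, LobeTruth] = {}
    at_name = spec.atelectasis.lobe

    base_at, foll_at, geometry = _atelectatic_truth(spec)
    lobes[at_name] = LobeTruth(
        at_name, ATELECTATIC, base_at, foll_at,
        change(base_at, foll_at, at_name, ATELECTATIC),
    )
    for name, geom in spec.lobe_geometry.items():
        if name == at_name:
            continue
        kv = draws.healthy_volume_factor[name]
        kd = draws.healthy_density_factor[name]
        v = geom.volume_ml
        base = RoiMeasures(rho_h * v, rho_h, v)
        foll = RoiMeasures(rho_h * kd * v * kv, rho_h * kd, v * kv)
        cls = _lobe_class(name, spec)
        lobes[name] = LobeTruth(name, cls, base, foll, change(base, foll, name, cls))

    at_b = spec.atelectasis.baseline_fraction_of_lobe * spec.lobe_geometry[at_name].volume_ml \
        - spec.tumor.baseline_volume_ml
    at_f = geometry["atelectasis_f"]
    label = classify_resolution(at_b, at_f)
    misalign = RigidTransform.from_translation(-draws.misalignment_mm)
    return PhantomTruth(
        lobes=lobes,
        atelectasis_volume_baseline_ml=at_b,
        atelectasis_volume_followup_ml=at_f,
        resolution_label=label,
        resolution_fraction=spec.atelectasis.followup_resolution_fraction,
        aerated_density=geometry["aerated_density"],
        misalignment=misalign,
        followup_geometry=geometry,
    )


# --------------------------------------------------------------------------
# Voxel painting
# --------------------------------------------------------------------------

def _world_axes(spec: PhantomSpec):
    axes_1d = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    return np.meshgrid(*axes_1d, indexing="ij")


def _ellipsoid(axes, center, semi) -> np.ndarray:
    X, Y, Z = axes
    return (((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2) <= 1.0


def _cylinder(axes, center_xy, radius, zrange) -> np.ndarray:
    X, Y, Z = axes
    return ((((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2) <= radius**2)
            & (Z >= zrange[0]) & (Z <= zrange[1]))


def _box(axes, x, y, z) -> np.ndarray:
    X, Y, Z = axes
    return ((X >= x[0]) & (X <= x[1]) & (Y >= y[0]) & (Y <= y[1])
            & (Z >= z[0]) & (Z <= z[1]))


def _semis_for_volume(shape_semis: np.ndarray, volume_ml: float) -> np.ndarray:
    """Semi-axes similar to ``shape_semis`` enclosing ``volume_ml``."""
    base = 4.0 / 3.0 * math.pi * float(np.prod(shape_semis)) / 1000.0
    return shape_semis * (volume_ml / base) ** (1.0 / 3.0)


def _shift(d: dict, t: np.ndarray, keys=("center",)) -> dict:
    out = dict(d)
    for k in keys:
        if k in out:
            c = np.asarray(out[k], dtype=float)
            out[k] = tuple(c + t[: c.size])
    return out


def _paint_organs(axes, density, masks, t: np.ndarray) -> None:
    """Body, mediastinum, bone, carina and reference ROIs, shifted by t."""
    X, Y, Z = axes
    cx, cy = np.asarray(_BODY["center"]) + t[:2]
    sa, sb = _BODY["semi"]
    body = ((X - cx) / sa) ** 2 + ((Y - cy) / sb) ** 2 <= 1.0
    density[body] = BODY_DENSITY

    heart = _ellipsoid(axes, np.asarray(_HEART["center"]) + t, _HEART["semi"])
    density[heart] = HEART_DENSITY
    aorta = _cylinder(axes, np.asarray(_AORTA["center"]) + t[:2], _AORTA["radius"],
                      (np.asarray(_AORTA["z"]) + t[2]))
    density[aorta] = BLOOD_DENSITY
    esoph = _cylinder(axes, np.asarray(_ESOPHAGUS["center"]) + t[:2], _ESOPHAGUS["radius"],
                      (np.asarray(_ESOPHAGUS["z"]) + t[2]))
    density[esoph] = ESOPHAGUS_DENSITY
    spine = _cylinder(axes, np.asarray(_SPINE["center"]) + t[:2], _SPINE["radius"],
                      (0.0, WORLD_MM))
    density[spine] = BONE_DENSITY
    cord = _cylinder(axes, np.asarray(_CORD["center"]) + t[:2], _CORD["radius"],
                     (0.0, WORLD_MM))
    density[cord] = CORD_DENSITY
    sternum = _box(axes, np.asarray(_STERNUM["x"]) + t[0], np.asarray(_STERNUM["y"]) + t[1],
                   np.asarray(_STERNUM["z"]) + t[2])
    density[sternum] = BONE_DENSITY
    carina = _ellipsoid(axes, np.asarray(_CARINA["center"]) + t, _CARINA["semi"])
    density[carina] = CARINA_DENSITY
    blood = _cylinder(axes, np.asarray(_BLOOD_REF["center"]) + t[:2], _BLOOD_REF["radius"],
                      (np.asarray(_BLOOD_REF["z"]) + t[2]))
    air = _box(axes, np.asarray(_AIR_REF["x"]) + t[0], np.asarray(_AIR_REF["y"]) + t[1],
               np.asarray(_AIR_REF["z"]) + t[2])

    masks.add("heart", heart)
    masks.add("esophagus", esoph)
    masks.add("spinal_cord", cord)
    masks.add("bone", spine | sternum)
    masks.add("carina", carina)
    masks.add("blood_ref", blood)
    masks.add("air_ref", air)


def _validate_structures(masks: LabelMaskSet) -> None:
    masks.validate_lobes_disjoint()
    organs = ("heart", "esophagus", "spinal_cord", "bone", "carina", "blood_ref")
    for lobe, lmask in masks.lobes().items():
        for organ in organs:
            if np.any(lmask & masks[organ]):
                raise StructureOverlapError(f"lobe {lobe} overlaps {organ}")
    if "tumor_gtv" in masks:
        tumor_outside = masks["tumor_gtv"] & ~masks.lung_union()
        if np.any(tumor_outside):
            raise StructureOverlapError("tumor extends outside the lobes")


def _paint_timepoint(spec: PhantomSpec, truth: PhantomTruth, draws: _PairDraws,
                     followup: bool) -> tuple[np.ndarray, LabelMaskSet]:
    axes = _world_axes(spec)
    t = draws.misalignment_mm if followup else np.zeros(3)
    density = np.zeros(spec.grid_shape, dtype=float)
    masks = LabelMaskSet(spec.spacing_mm, (0.0, 0.0, 0.0))
    _paint_organs(axes, density, masks, t)

    at = spec.atelectasis
    rho_h = spec.healthy_density
    geom = truth.followup_geometry

    # healthy lobes
    for name, lobe in spec.lobe_geometry.items():
        if name == at.lobe:
            continue
        center = np.asarray(lobe.center_mm) + t
        semis = np.asarray(lobe.semi_axes_mm)
        rho = rho_h
        if followup:
            semis = semis * draws.healthy_volume_factor[name] ** (1.0 / 3.0)
            rho = rho_h * draws.healthy_density_factor[name]
        mask = _ellipsoid(axes, center, semis)
        density[mask] = rho
        masks.add(name, mask)

    # atelectatic lobe: nested similar ellipsoids (tumor ⊂ core ⊂ mid ⊂ lobe)
    lobe = spec.lobe_geometry[at.lobe]
    base_semis = np.asarray(lobe.semi_axes_mm)
    v_lobe_b = lobe.volume_ml
    if not followup:
        center = np.asarray(lobe.center_mm)
        shape = base_semis
        v_tumor = spec.tumor.baseline_volume_ml
        v_core = at.baseline_fraction_of_lobe * v_lobe_b
        v_mid = v_core
        v_lobe = v_lobe_b
        rho_aer = geom["aerated_density"]
    else:
        v_lobe = geom["v_lobe_f"]
        s = (v_lobe / v_lobe_b) ** (1.0 / 3.0)
        s_z = min(s, Z_EXPANSION_CAP)
        s_xy = math.sqrt(s**3 / s_z)
        shape = base_semis * np.array([s_xy, s_xy, s_z])
        top_z = lobe.center_mm[2] + base_semis[2]
        center = np.array([lobe.center_mm[0], lobe.center_mm[1], top_z - shape[2]]) + t
        v_tumor = geom["v_tumor_f"]
        v_core = geom["v_core_f"]
        v_mid = geom["v_mid_f"]
        rho_aer = geom["aerated_density"]

    lobe_mask = _ellipsoid(axes, center, _semis_for_volume(shape, v_lobe))
    mid_mask = _ellipsoid(axes, center, _semis_for_volume(shape, v_mid))
    core_mask = _ellipsoid(axes, center, _semis_for_volume(shape, v_core))
    tumor_mask = _ellipsoid(axes, center, _semis_for_volume(shape, v_tumor))
    density[lobe_mask] = rho_h
    density[mid_mask] = rho_aer
    density[core_mask] = at.consolidated_density
    density[tumor_mask] = TUMOR_DENSITY
    masks.add(at.lobe, lobe_mask)
    masks.add("tumor_gtv", tumor_mask)
    masks.add("atelectasis", core_mask & ~tumor_mask)

    # CTV: baseline tumor + margin, rigidly carried with the anatomy
    ctv_semis = _semis_for_volume(base_semis, spec.tumor.baseline_volume_ml) + 8.0
    ctv_center = np.asarray(lobe.center_mm) + t
    masks.add("ctv", _ellipsoid(axes, ctv_center, ctv_semis))

    _validate_structures(masks)
    return density, masks


def _landmarks(t: np.ndarray) -> pd.DataFrame:
    rows = [
        {"name": name, "x_mm": x + t[0], "y_mm": y + t[1], "z_mm": z + t[2]}
        for name, x, y, z in BONE_LANDMARKS
    ]
    return pd.DataFrame(rows)


def generate_pair(spec: PhantomSpec) -> PhantomPair:
    """Build one baseline/followup phantom pair with analytic truth.

    Deterministic for a fixed spec (including its seed): regeneration is
    bit-identical.  Raises ``StructureOverlapError`` if a requested
    geometry makes structures that must be disjoint collide.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    draws = _draw_pair_effects(spec, rng)
    truth = analytic_truth(spec, draws)

    m = spec.raw_intensity_map
    timepoints = []
    for followup in (False, True):
        density, masks = _paint_timepoint(spec, truth, draws, followup)
        raw = m.slope * density + m.intercept
        if spec.noise_sd > 0:
            raw = raw + rng.normal(0.0, spec.noise_sd * abs(m.slope), size=raw.shape)
        t = draws.misalignment_mm if followup else np.zeros(3)
        timepoints.append(TimePoint(
            raw=VolumeGrid(raw, spec.spacing_mm),
            masks=masks,
            landmarks=_landmarks(t),
        ))
    return PhantomPair(spec=spec, baseline=timepoints[0], followup=timepoints[1],
                       truth=truth)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEffect:
    """Programmed effect distribution for one resolution class."""

    proportion: float
    density_change_mean_pct: float
    density_change_sd_pct: float
    resolution_range: tuple[float, float]
    edema_excess_mass_fraction: float


#: Class proportions and density-change targets for the default cohort.
DEFAULT_EFFECT_PROFILE: dict[str, ClassEffect] = {
    "full": ClassEffect(0.22, -66.0, 5.0, (0.85, 0.98), 0.10),
    "partial": ClassEffect(0.50, -25.6, 5.0, (0.30, 0.70), 0.35),
    "none": ClassEffect(0.28, -17.0, 5.0, (0.02, 0.12), 0.15),
}

#: Grid preset used for cohort runs: same 240 mm world as the default
#: phantom but 3.75 mm voxels, the coarsest grid at which lobe-boundary
#: discretization keeps class-mean density-change error well inside the
#: generator's own +/-2 percentage-point contract.
COHORT_GRID = {"grid_shape": (64, 64, 64), "spacing_mm": (3.75, 3.75, 3.75)}


def class_counts(n: int, profile: dict[str, ClassEffect]) -> dict[str, int]:
    """Largest-remainder apportionment of n patients to resolution classes."""
    names = list(profile)
    raw = np.array([profile[c].proportion for c in names], dtype=float)
    raw = raw / raw.sum() * n
    floors = np.floor(raw).astype(int)
    rem = n - floors.sum()
    order = np.argsort(-(raw - floors))
    for i in range(rem):
        floors[order[i]] += 1
    return dict(zip(names, floors.tolist()))


def _stratified_normal(rng: np.random.Generator, mean: float, sd: float,
                       size: int) -> np.ndarray:
    """Normal draws stratified on the CDF: exact N(mean, sd) marginals with
    sample means far tighter than sd/sqrt(n), so small class means track
    their programmed targets (the generator's contract)."""
    from scipy.stats import norm
    u = (np.arange(size) + rng.uniform(size=size)) / size
    draws = mean + sd * norm.ppf(u)
    rng.shuffle(draws)
    return draws


def cohort_specs(n_patients: int,
                 effect_profile: dict[str, ClassEffect] | None = None,
                 seed: int = 0,
                 grid_shape: tuple[int, int, int] = COHORT_GRID["grid_shape"],
                 spacing_mm: tuple[float, float, float] = COHORT_GRID["spacing_mm"],
                 ) -> list[tuple[str, PhantomSpec]]:
    """Per-patient (class label, PhantomSpec) list for a synthetic cohort."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    profile = effect_profile if effect_profile is not None else DEFAULT_EFFECT_PROFILE
    rng = np.random.default_rng(seed)
    counts = class_counts(n_patients, profile)
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(labels)

    targets: dict[str, list[float]] = {}
    for cls, k in counts.items():
        eff = profile[cls]
        if k > 0:
            d = _stratified_normal(rng, eff.density_change_mean_pct,
                                   eff.density_change_sd_pct, k)
            # density must decrease; extreme tails are unphysical
            targets[cls] = list(np.clip(d, -78.0, -1.0))

    out = []
    for label in labels:
        eff = profile[label]
        r = float(rng.uniform(*eff.resolution_range))
        d_target = targets[label].pop()
        mis = rng.uniform(-4.0, 4.0, size=3)
        pat_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing_mm=spacing_mm,
            atelectasis=AtelectasisSpec(
                followup_resolution_fraction=r,
                edema_excess_mass_fraction=eff.edema_excess_mass_fraction,
                target_density_change=d_target / 100.0,
            ),
            misalignment_mm=tuple(mis),
            seed=pat_seed,
        )
        out.append((label, spec))
    return out


def generate_cohort(n_patients: int,
                    effect_profile: dict[str, ClassEffect] | None = None,
                    seed: int = 0,
                    **grid_kwargs) -> Iterator[tuple[str, PhantomPair]]:
    """Lazily generate (programmed class label, PhantomPair) for a cohort.

    Pairs are yielded one at a time (a full cohort of voxel data would be
    needlessly large in memory); ``list(...)`` materializes it.
    """
    for label, spec in cohort_specs(n_patients, effect_profile, seed, **grid_kwargs):
        yield label, generate_pair(spec)


# --------------------------------------------------------------------------
# Plan construction for phantom dosimetry and disk output
# --------------------------------------------------------------------------

def build_plan(spec: PhantomSpec, prescription_dose_gy: float = 60.0,
               n_beams: int = 3, margin_mm: float = 25.0) -> PlanGeometry:
    """Equi-spaced coplanar beams targeting the tumor with a square aperture."""
    iso = spec.lobe_geometry[spec.atelectasis.lobe].center_mm
    half = spec.tumor.baseline_radius_mm + margin_mm
    beams = tuple(
        Beam(gantry_angle_deg=360.0 * i / n_beams, aperture=square_aperture(half))
        for i in range(n_beams)
    )
    return PlanGeometry(tuple(iso), beams, prescription_dose_gy)


def _truth_dict(truth: PhantomTruth) -> dict:
    return {
        "atelectasis_volume_baseline_ml": truth.atelectasis_volume_baseline_ml,
        "atelectasis_volume_followup_ml": truth.atelectasis_volume_followup_ml,
        "resolution_label": truth.resolution_label,
        "resolution_fraction": truth.resolution_fraction,
        "aerated_density": truth.aerated_density,
        "misalignment": truth.misalignment.to_dict(),
        "lobes": {
            name: {
                "lobe_class": lt.lobe_class,
                "baseline": vars(lt.baseline),
                "followup": vars(lt.followup),
                "pct_mass_change": lt.change.pct_mass_change,
                "pct_density_change": lt.change.pct_density_change,
                "pct_volume_change": lt.change.pct_volume_change,
            }
            for name, lt in truth.lobes.items()
        },
    }


def write_pair(pair: PhantomPair, outdir: str | Path) -> None:
    """Write a phantom pair as NIfTI volumes + labels, landmark CSVs and
    a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tag, tp in (("baseline", pair.baseline), ("followup", pair.followup)):
        write_volume(tp.raw, outdir / f"{tag}_image.nii.gz")
        write_labels(tp.masks, outdir / f"{tag}_labels.nii.gz")
        write_landmarks(tp.landmarks, outdir / f"{tag}_landmarks.csv")
    save_json(_truth_dict(pair.truth), outdir / "truth.json")
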