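"""Rigid plan transfer: landmark/centroid alignment, resampling, toy dose.

The followup scan is rigidly aligned to baseline in one of two ways that
mimic daily patient setup: a least-squares rigid fit on bony landmarks
restricted to a sternum/spine box (Kabsch / orthogonal Procrustes), or a
translation-only match of the carina centroid (volumetric image-guided
setup on the tracheal bifurcation).  The clinical plan geometry (beam
angles, apertures, weights, monitor units) is transferred unchanged and
dose is recomputed with a toy radiological-depth engine.

The dose engine is NOT clinically valid.  It exists so that relative dose
changes between time points can be exercised deterministically: each beam
deposits ``weight * mu * exp(-mu_eff * radiological_depth)`` inside the
diverging projection of its aperture, where radiological depth is the
density-weighted path length (density/1000 per mm) along the beam axis.
No scatter, no inverse-square law, no heterogeneity corrections beyond the
path integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as PolyPath
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume_io import LabelMaskSet, VolumeGrid


class AlignmentError(ValueError):
    """Not enough (or degenerate) correspondence information."""


class DoseEngineError(ValueError):
    """Invalid plan/grid combination for the toy dose engine."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """World-coordinate rigid map ``x -> R x + t`` (rotation in SO(3), mm)."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-6
        ):
            raise AlignmentError("rotation must be a proper orthonormal matrix (det=+1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t_mm) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t_mm, dtype=float))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.rotation.T + self.translation_mm

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation_mm)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation_mm": self.translation_mm.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation_mm"]))


def align_bone(baseline_points_mm: np.ndarray, followup_points_mm: np.ndarray,
               box_region: tuple | None = None) -> tuple[RigidTransform, float]:
    """Closed-form rigid fit mapping followup landmarks onto baseline.

    Parameters
    ----------
    baseline_points_mm, followup_points_mm:
        Corresponding (n, 3) bone landmark coordinates (world mm).
    box_region:
        Optional ``(lo_mm, hi_mm)`` axis-aligned box; only landmark pairs
        whose *baseline* point lies inside the box participate (the
        sternum/spine alignment box).

    Returns
    -------
    (transform, residual_rms_mm)
    """
    base = np.atleast_2d(np.asarray(baseline_points_mm, dtype=float))
    foll = np.atleast_2d(np.asarray(followup_points_mm, dtype=float))
    if base.shape != foll.shape or base.shape[1] != 3:
        raise AlignmentError(f"landmark sets must match as (n, 3); got {base.shape}, {foll.shape}")
    if box_region is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in box_region)
        keep = np.all((base >= lo) & (base <= hi), axis=1)
        base, foll = base[keep], foll[keep]
    if base.shape[0] < 3:
        raise AlignmentError(f"need >= 3 landmarks inside the box, got {base.shape[0]}")
    cb, cf = base.mean(axis=0), foll.mean(axis=0)
    b0, f0 = base - cb, foll - cf
    if np.linalg.matrix_rank(b0, tol=1e-9 * max(1.0, np.abs(b0).max())) < 2:
        raise AlignmentError("landmarks are collinear; rotation is undetermined")
    rot, _ = Rotation.align_vectors(b0, f0)  # Kabsch with proper-rotation constraint
    R = rot.as_matrix()
    t = cb - R @ cf
    xform = RigidTransform(R, t)
    residual = xform.apply(foll) - base
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return xform, rms


def align_carina(baseline_masks: LabelMaskSet, followup_masks: LabelMaskSet,
                 name: str = "carina") -> RigidTransform:
    """Translation-only alignment matching carina mask centroids.

    Rotation is identity by construction; the translation moves the
    followup carina centroid onto the baseline one (world mm).
    """
    for ms, label in ((baseline_masks, "baseline"), (followup_masks, "followup")):
        if name not in ms or not np.any(ms[name]):
            raise AlignmentError(f"{label} {name!r} mask is missing or empty")
    t = baseline_masks.centroid_world(name) - followup_masks.centroid_world(name)
    return RigidTransform.from_translation(t)


def resample_to_reference(moving: VolumeGrid, transform: RigidTransform,
                          reference: VolumeGrid, mode: str = "linear",
                          fill_value: float = 0.0) -> VolumeGrid:
    """Resample ``moving`` onto the reference grid under a rigid transform.

    ``transform`` maps moving-image world coordinates into reference world
    coordinates (the alignment output).  Scalars use trilinear
    interpolation; labels use nearest neighbour.  Voxels that map outside
    the moving field of view take ``fill_value`` (calibrated air density
    for density images, 0/background for labels and dose).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    inv = transform.inverse()
    ax = reference.world_axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    pts_moving = inv.apply(pts)
    idx = moving.world_to_index(pts_moving).T.reshape(3, *reference.shape)
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        idx,
        order=1 if mode == "linear" else 0,
        mode="constant",
        cval=fill_value,
    )
    return VolumeGrid(out, reference.spacing_mm, reference.origin_mm)


def resample_masks(moving: LabelMaskSet, transform: RigidTransform,
                   reference: VolumeGrid) -> LabelMaskSet:
    """Nearest-neighbour resampling of every mask onto the reference grid."""
    out = LabelMaskSet(reference.spacing_mm, reference.origin_mm)
    src_grid = VolumeGrid(
        np.zeros(moving.shape, dtype=np.uint8), moving.spacing_mm, moving.origin_mm
    )
    for name, mask in moving.items():
        res = resample_to_reference(
            src_grid.with_data(mask.astype(np.uint8)), transform, reference,
            mode="nearest", fill_value=0.0,
        )
        out.add(name, res.data > 0.5)
    return out


# ---------------------------------------------------------------------------
# Plan geometry and toy dose engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Beam:
    """One treatment beam.

    gantry_angle_deg:
        Rotation about the z (superior-inferior) axis; 0 deg enters from
        anterior travelling +y, angles increase clockwise viewed from
        superior.
    aperture:
        2-D polygon vertices (mm) in beam's-eye-view coordinates at the
        isocenter plane; u spans the in-plane axis, v the z axis.
    """

    gantry_angle_deg: float
    aperture: tuple[tuple[float, float], ...]
    weight: float = 1.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DoseEngineError("beam weight must be > 0")
        if len(self.aperture) < 3:
            raise DoseEngineError("aperture polygon needs >= 3 vertices")

    def direction(self) -> np.ndarray:
        g = np.deg2rad(self.gantry_angle_deg)
        return np.array([np.sin(g), np.cos(g), 0.0])


@dataclass(frozen=True)
class PlanGeometry:
    isocenter_mm: tuple[float, float, float]
    beams: tuple[Beam, ...]
    prescription_dose_gy: float

    def __post_init__(self) -> None:
        if not self.beams:
            raise DoseEngineError("plan has no beams")
        if self.prescription_dose_gy <= 0:
            raise DoseEngineError("prescription dose must be > 0")

    def scaled(self, factor: float) -> "PlanGeometry":
        beams = tuple(
            Beam(b.gantry_angle_deg, b.aperture, b.weight, b.mu * factor)
            for b in self.beams
        )
        return PlanGeometry(self.isocenter_mm, beams, self.prescription_dose_gy)


def square_aperture(half_width_mm: float) -> tuple[tuple[float, float], ...]:
    h = float(half_width_mm)
    return ((-h, -h), (h, -h), (h, h), (-h, h))


@dataclass(frozen=True)
class DoseEngineConfig:
    """Toy engine parameters: effective attenuation per mm of water-equivalent
    radiological depth and virtual source-axis distance (mm)."""

    mu_eff_per_mm: float = 0.005
    sad_mm: float = 1000.0


def _radiological_depth(dens: VolumeGrid, beam: Beam, iso: np.ndarray) -> np.ndarray:
    """Density-weighted depth (water-equivalent mm) along the beam axis.

    Computed in a beam-aligned frame obtained by rotating the density grid
    about the isocenter (parallel-ray approximation for depth; the aperture
    itself diverges from the virtual source).  Requires equal in-plane
    spacing so the in-plane rotation is a similarity of the index lattice.
    """
    sx, sy, sz = dens.spacing_mm
    if not np.isclose(sx, sy):
        raise DoseEngineError("toy dose engine requires equal in-plane (x, y) spacing")
    g = np.deg2rad(beam.gantry_angle_deg)
    c, s = np.cos(g), np.sin(g)
    # Rz(-g): inverse of the rotation that carries the beam direction onto +y.
    Rg = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    A = np.diag(dens.spacing_mm)
    Ainv = np.diag(1.0 / np.asarray(dens.spacing_mm))
    b = np.asarray(dens.origin_mm)

    def index_affine(Rw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # index-space matrix/offset realizing world map w -> iso + Rw (w - iso)
        M = Ainv @ Rw @ A
        off = Ainv @ (Rw @ (b - iso) + iso - b)
        return M, off

    # Density sampled in the beam frame: voxel (i,j,k) of the rotated array
    # corresponds to world point iso + Rg^{-1}(w_ijk - iso), where the beam
    # travels along +y of the beam frame.
    M, off = index_affine(Rg)
    dens_rot = ndimage.affine_transform(
        np.asarray(dens.data, dtype=float), M, offset=off, order=1,
        mode="constant", cval=0.0,
    )
    # Path integral: cumulative density along +y, in water-equivalent mm.
    step = dens.spacing_mm[1]
    depth_rot = (np.cumsum(dens_rot, axis=1) - 0.5 * dens_rot) * (step / 1000.0)
    # Map back to the original frame.
    M2, off2 = index_affine(Rg.T)
    return ndimage.affine_transform(depth_rot, M2, offset=off2, order=1,
                                    mode="constant", cval=0.0)


def compute_toy_dose(dens: VolumeGrid, plan: PlanGeometry,
                     config: DoseEngineConfig = DoseEngineConfig()) -> VolumeGrid:
    """Deterministic toy dose on the density grid (NOT clinically valid).

    For each beam, voxels inside the diverging aperture projection receive
    ``weight * mu * exp(-mu_eff * radiological_depth)``; beams sum.
    """
    iso = np.asarray(plan.isocenter_mm, dtype=float)
    frac_idx = dens.world_to_index(iso)
    if np.any(frac_idx < 0) or np.any(frac_idx > np.asarray(dens.shape) - 1):
        raise DoseEngineError(f"isocenter {tuple(iso)} lies outside the dose grid")

    ax = dens.world_axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    dose = np.zeros(pts.shape[0])
    z_axis = np.array([0.0, 0.0, 1.0])

    for beam in plan.beams:
        d = beam.direction()
        e_u = np.cross(d, z_axis)
        e_u /= np.linalg.norm(e_u)
        e_v = z_axis
        source = iso - config.sad_mm * d
        q = pts - source
        t_axis = q @ d
        downstream = t_axis > 1e-6
        # Beam's-eye-view coordinates projected back to the isocenter plane.
        scale = np.where(downstream, config.sad_mm / np.where(downstream, t_axis, 1.0), 0.0)
        u = (q @ e_u) * scale
        v = (q @ e_v) * scale
        inside = PolyPath(beam.aperture).contains_points(np.column_stack([u, v]))
        inside &= downstream
        if not np.any(inside):
            continue
        depth = _radiological_depth(dens, beam, iso).reshape(-1)
        dose[inside] += beam.weight * beam.mu * np.exp(
            -config.mu_eff_per_mm * depth[inside]
        )

    return dens.with_data(dose.reshape(dens.shape))


def normalize_plan_to_prescription(plan: PlanGeometry, dens: VolumeGrid,
                                   config: DoseEngineConfig = DoseEngineConfig()
                                   ) -> PlanGeometry:
    """Scale all beam monitor units so the isocenter dose equals prescription.

    A plan-construction step (run once on the planning image); the dose
    engine itself stays linear in the beam weights.
    """
    dose = compute_toy_dose(dens, plan, config)
    idx = np.rint(dens.world_to_index(np.asarray(plan.isocenter_mm))).astype(int)
    d_iso = float(dose.data[tuple(idx)])
    if d_iso <= 0:
        raise DoseEngineError("isocenter receives no dose; cannot normalize plan")
    return plan.scaled(plan.prescription_dose_gy / d_iso)
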