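"""Volumes, label masks, landmark tables and config I/O on axis-aligned voxel grids.

Conventions
-----------
* Array axis order is ``(x, y, z)``; voxel indices are 0-based.
* World coordinates are in millimetres: ``world = origin + index * spacing``.
  The direction matrix is assumed identity (oblique acquisitions are
  unsupported and rejected on read).
* Volumes are stored as NIfTI.  Label masks are stored as a single
  bit-packed ``uint32`` NIfTI image plus a JSON name->bit sidecar, because
  structures legitimately overlap (atelectasis and tumor lie inside a lobe).
* Landmarks are CSV tables with columns ``name,x_mm,y_mm,z_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: Canonical lung lobe names (left upper/lower, right upper/middle/lower).
LOBE_NAMES: tuple[str, ...] = ("LUL", "LLL", "RUL", "RML", "RLL")

#: Controlled vocabulary of structure names a LabelMaskSet may carry.
STRUCTURE_VOCAB: tuple[str, ...] = LOBE_NAMES + (
    "tumor_gtv",
    "ctv",
    "atelectasis",
    "spinal_cord",
    "esophagus",
    "heart",
    "air_ref",
    "blood_ref",
    "carina",
    "bone",
)

GRID_TOL_MM = 1e-6


class VolumeIOError(ValueError):
    """Malformed volume data or header (wrong dimensionality, bad spacing...)."""


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


class StructureOverlapError(ValueError):
    """Structures that must be disjoint overlap on the voxel grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar field on a regular, axis-aligned anisotropic grid.

    Parameters
    ----------
    data:
        3-D array of voxel values (any scalar meaning: raw scanner units,
        calibrated density in mg/cc, or dose in Gy).
    spacing_mm:
        Per-axis voxel spacing in millimetres, all strictly positive.
    origin_mm:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeIOError(f"data must be 3-D, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeIOError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        if len(origin) != 3:
            raise VolumeIOError(f"origin_mm must have 3 components, got {self.origin_mm}")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise VolumeIOError("data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 ml = 1 cc = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, new voxel values."""
        return VolumeGrid(data=data, spacing_mm=self.spacing_mm, origin_mm=self.origin_mm)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a] for a in range(3)
        )  # type: ignore[return-value]

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm to (fractional) voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


def check_congruent(a: VolumeGrid | "LabelMaskSet", b: VolumeGrid | "LabelMaskSet",
                    tol_mm: float = GRID_TOL_MM) -> bool:
    """True iff shapes, spacings and origins agree within ``tol_mm``."""
    if a.shape != b.shape:
        return False
    sa, sb = np.asarray(a.spacing_mm), np.asarray(b.spacing_mm)
    oa, ob = np.asarray(a.origin_mm), np.asarray(b.origin_mm)
    return bool(np.all(np.abs(sa - sb) <= tol_mm) and np.all(np.abs(oa - ob) <= tol_mm))


def require_congruent(a, b, what: str = "volumes") -> None:
    if not check_congruent(a, b):
        raise GridMismatchError(
            f"{what} are not on the same grid: "
            f"{a.shape}/{a.spacing_mm}/{a.origin_mm} vs {b.shape}/{b.spacing_mm}/{b.origin_mm}"
        )


class LabelMaskSet:
    """Named binary masks sharing one voxel grid.

    Lobe masks must be pairwise disjoint after preprocessing;
    :meth:`validate_lobes_disjoint` enforces this.  Other structures may
    overlap (atelectasis and tumor lie inside their lobe).
    """

    def __init__(self, spacing_mm, origin_mm=(0.0, 0.0, 0.0),
                 masks: dict[str, np.ndarray] | None = None) -> None:
        self.spacing_mm = tuple(float(s) for s in spacing_mm)
        self.origin_mm = tuple(float(o) for o in origin_mm)
        self._masks: dict[str, np.ndarray] = {}
        if masks:
            for name, mask in masks.items():
                self.add(name, mask)

    # -- container protocol -------------------------------------------------
    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise VolumeIOError(f"mask {name!r} must be 3-D, got ndim={mask.ndim}")
        mask = mask.astype(bool)
        if self._masks:
            ref = next(iter(self._masks.values()))
            if mask.shape != ref.shape:
                raise GridMismatchError(
                    f"mask {name!r} shape {mask.shape} != {ref.shape}")
        self._masks[name] = mask

    def __getitem__(self, name: str) -> np.ndarray:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def names(self) -> list[str]:
        return list(self._masks)

    def items(self):
        return self._masks.items()

    @property
    def shape(self) -> tuple[int, int, int]:
        if not self._masks:
            raise VolumeIOError("empty LabelMaskSet has no shape")
        return next(iter(self._masks.values())).shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    # -- derived structures -------------------------------------------------
    def lobes(self) -> dict[str, np.ndarray]:
        return {n: self._masks[n] for n in LOBE_NAMES if n in self._masks}

    def lung_union(self) -> np.ndarray:
        """Union of all present lobe masks (includes atelectasis by construction)."""
        lobes = self.lobes()
        if not lobes:
            raise VolumeIOError("no lobe masks present")
        out = np.zeros(self.shape, dtype=bool)
        for m in lobes.values():
            out |= m
        return out

    def volume_ml(self, name: str) -> float:
        return float(np.count_nonzero(self._masks[name])) * self.voxel_volume_ml

    def centroid_world(self, name: str) -> np.ndarray:
        """World-mm centroid of a mask (mean of member voxel centres)."""
        idx = np.argwhere(self._masks[name])
        if idx.size == 0:
            raise VolumeIOError(f"mask {name!r} is empty")
        return np.asarray(self.origin_mm) + idx.mean(axis=0) * np.asarray(self.spacing_mm)

    def validate_lobes_disjoint(self) -> None:
        lobes = self.lobes()
        names = list(lobes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(lobes[a] & lobes[b]):
                    raise StructureOverlapError(f"lobes {a} and {b} overlap")

    def copy(self) -> "LabelMaskSet":
        return LabelMaskSet(self.spacing_mm, self.origin_mm,
                            {n: m.copy() for n, m in self._masks.items()})


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag([*spacing_mm, 1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), _affine(vol.spacing_mm, vol.origin_mm))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume; reject non-3-D data and oblique direction matrices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path.name}: expected 3-D data, got ndim={data.ndim}")
    aff = img.affine
    rot = aff[:3, :3]
    offdiag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(offdiag)) > 1e-6:
        raise VolumeIOError(f"{path.name}: oblique direction matrix unsupported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise VolumeIOError(f"{path.name}: non-positive voxel spacing {spacing}")
    return VolumeGrid(data=data, spacing_mm=tuple(spacing), origin_mm=tuple(aff[:3, 3]))


# ---------------------------------------------------------------------------
# Label masks (bit-packed integer image + JSON sidecar)
# ---------------------------------------------------------------------------

def write_labels(masks: LabelMaskSet, path: str | Path,
                 sidecar: str | Path | None = None) -> None:
    names = masks.names()
    if len(names) > 32:
        raise VolumeIOError("more than 32 structures cannot be bit-packed into uint32")
    packed = np.zeros(masks.shape, dtype=np.uint32)
    bits = {}
    for bit, name in enumerate(names):
        packed |= masks[name].astype(np.uint32) << np.uint32(bit)
        bits[name] = bit
    img = nib.Nifti1Image(packed, _affine(masks.spacing_mm, masks.origin_mm))
    nib.save(img, str(path))
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"encoding": "bitmask", "bits": bits}, indent=1))


def read_labels(path: str | Path, sidecar: str | Path | None = None) -> LabelMaskSet:
    vol = read_volume(path)
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text())
    if meta.get("encoding") != "bitmask":
        raise VolumeIOError(f"{sidecar.name}: unknown label encoding {meta.get('encoding')!r}")
    packed = np.asarray(vol.data).astype(np.uint32)
    out = LabelMaskSet(vol.spacing_mm, vol.origin_mm)
    for name, bit in meta["bits"].items():
        out.add(name, (packed >> np.uint32(bit)) & np.uint32(1))
    return out


# ---------------------------------------------------------------------------
# Landmarks, config, results
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["name", "x_mm", "y_mm", "z_mm"]


def write_landmarks(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise VolumeIOError(f"landmark table missing columns {missing}")
    df[LANDMARK_COLUMNS].to_csv(path, index=False)


def read_landmarks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise VolumeIOError(f"{Path(path).name}: landmark table missing columns {missing}")
    return df[LANDMARK_COLUMNS]


def landmark_array(df: pd.DataFrame) -> np.ndarray:
    """(n, 3) world-mm coordinates in table order."""
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def load_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyJSONEncoder))
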