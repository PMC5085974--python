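"""Relative mass, density and volume per ROI and their percent changes.

On a density-calibrated image (mg/cc), for a binary ROI:

* relative mass  (mg) = sum over ROI voxels of density * voxel volume (cc),
* relative density (mg/cc) = mean density over the ROI,
* volume (ml) = voxel count * voxel volume (ml).

``mass = density * volume`` holds as an identity up to rounding.  Percent
change from baseline to followup is ``100 * (followup - baseline) / baseline``
and requires a positive baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import GridMismatchError, LOBE_NAMES, LabelMaskSet, VolumeGrid

ATELECTATIC = "atelectatic"
HEALTHY_IPSILATERAL = "healthy_ipsilateral"
CONTRALATERAL = "contralateral"


class EmptyROIError(ValueError):
    """Measures over an empty ROI are undefined (not zero)."""


@dataclass(frozen=True)
class RoiMeasures:
    mass_mg: float
    density_mg_cc: float
    volume_ml: float


@dataclass(frozen=True)
class ChangeRecord:
    """Baseline -> followup percent changes for one lobe."""

    lobe_id: str
    lobe_class: str
    pct_mass_change: float
    pct_density_change: float
    pct_volume_change: float


def measure_roi(dens: VolumeGrid, mask: np.ndarray) -> RoiMeasures:
    """Exact sums/means of calibrated density over a binary ROI."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dens.shape:
        raise GridMismatchError(f"mask shape {mask.shape} != volume shape {dens.shape}")
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise EmptyROIError("cannot measure an empty ROI")
    values = np.asarray(dens.data, dtype=float)[mask]
    vv_cc = dens.voxel_volume_ml  # 1 cc == 1 ml
    total = float(values.sum())
    return RoiMeasures(
        mass_mg=total * vv_cc,
        density_mg_cc=total / n,
        volume_ml=n * vv_cc,
    )


def pct_change(baseline: float, followup: float) -> float:
    if not baseline > 0:
        raise ValueError(f"percent change undefined for baseline {baseline}")
    return 100.0 * (followup - baseline) / baseline


def change(baseline: RoiMeasures, followup: RoiMeasures,
           lobe_id: str = "", lobe_class: str = "") -> ChangeRecord:
    return ChangeRecord(
        lobe_id=lobe_id,
        lobe_class=lobe_class,
        pct_mass_change=pct_change(baseline.mass_mg, followup.mass_mg),
        pct_density_change=pct_change(baseline.density_mg_cc, followup.density_mg_cc),
        pct_volume_change=pct_change(baseline.volume_ml, followup.volume_ml),
    )


def lobe_classes(masks: LabelMaskSet,
                 atelectasis_name: str = "atelectasis",
                 tumor_name: str = "tumor_gtv") -> dict[str, str]:
    """Assign each lobe to atelectatic / healthy ipsilateral / contralateral.

    A lobe overlapping the atelectasis mask is atelectatic; other lobes on
    the tumor-bearing side are healthy ipsilateral; the rest contralateral.
    Lobe laterality comes from the canonical names (L*/R*).
    """
    lobes = masks.lobes()
    atelectatic = set()
    if atelectasis_name in masks:
        at = masks[atelectasis_name]
        atelectatic = {n for n, m in lobes.items() if np.any(m & at)}
    tumor_sides = set()
    if tumor_name in masks:
        tm = masks[tumor_name]
        tumor_sides = {n[0] for n, m in lobes.items() if np.any(m & tm)}
    out = {}
    for name in lobes:
        if name in atelectatic:
            out[name] = ATELECTATIC
        elif name[0] in tumor_sides:
            out[name] = HEALTHY_IPSILATERAL
        else:
            out[name] = CONTRALATERAL
    return out


def measure_lobes(dens: VolumeGrid, analysis_masks: LabelMaskSet) -> dict[str, RoiMeasures]:
    """Per-lobe measures on prepared (tumor-free, possibly eroded) masks.

    Empty lobes (e.g. fully covered by tumor) are skipped rather than
    reported as zero.
    """
    out = {}
    for name in LOBE_NAMES:
        if name in analysis_masks and np.any(analysis_masks[name]):
            out[name] = measure_roi(dens, analysis_masks[name])
    return out


def enumerate_pairings(n_baseline: int, n_followup: int) -> list[tuple[int, int]]:
    """Scan pairings for sessions with repeat scans: matched index first.

    With k scans at each time point this yields the k matched-index pairs
    (three pairs for the three-scans-per-session case); with unequal counts
    the shorter list cycles.
    """
    if n_baseline < 1 or n_followup < 1:
        raise ValueError("need at least one scan per time point")
    k = max(n_baseline, n_followup)
    return [(i % n_baseline, i % n_followup) for i in range(k)]
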