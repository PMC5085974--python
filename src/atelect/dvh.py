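"""DVH metrics, dose-constraint evaluation and baseline->followup changes.

Metrics: D_max / D_mean / D_min (Gy, extrema and volume-weighted mean over
the structure) and V_x (% of structure volume receiving at least x Gy;
V_Rx uses the prescription dose on the GTV).  A constraint is met when the
metric value is <= its limit (limits are stated as maxima; exact equality
counts as met).  A constraint has *improved* when it was unmet at baseline
and became met at followup; *worsened* is the converse.

Lungs are defined three ways to manage the effect of tumor regression on
dose-change assessment: all lung tissue (the union of the five lobes,
which includes atelectasis), lungs minus GTV, and lungs minus CTV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measures import EmptyROIError
from .volume_io import LabelMaskSet, VolumeGrid

IMPROVED = "improved"
WORSENED = "worsened"
UNCHANGED = "unchanged"

LUNG_VARIANTS = ("lungs", "lungs_minus_gtv", "lungs_minus_ctv")


@dataclass(frozen=True)
class DVHMetricSpec:
    """One structure/metric pair, e.g. spinal cord D_max or lungs V_20."""

    structure: str
    metric: str          # "D_max" | "D_mean" | "D_min" | "V_x" | "V_Rx"
    x_gy: float | None = None   # threshold for V_x

    def __post_init__(self) -> None:
        if self.metric not in ("D_max", "D_mean", "D_min", "V_x", "V_Rx"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "V_x":
            if self.x_gy is None or self.x_gy <= 0:
                raise ValueError("V_x requires x_gy > 0")

    @property
    def units(self) -> str:
        return "%" if self.metric in ("V_x", "V_Rx") else "Gy"

    @property
    def label(self) -> str:
        if self.metric == "V_x":
            return f"{self.structure} V_{self.x_gy:g}"
        return f"{self.structure} {self.metric}"


@dataclass(frozen=True)
class ConstraintSpec:
    spec: DVHMetricSpec
    limit: float


@dataclass(frozen=True)
class ConstraintResult:
    spec: DVHMetricSpec
    value: float
    limit: float
    met: bool
    delta_from_baseline: float | None = None
    transition: str | None = None


def dvh_metric(dose: VolumeGrid, mask: np.ndarray, spec: DVHMetricSpec,
               rx_gy: float | None = None) -> float:
    """Evaluate one DVH metric over a structure mask on the dose grid."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError(f"mask shape {mask.shape} != dose shape {dose.shape}")
    values = np.asarray(dose.data, dtype=float)[mask]
    if values.size == 0:
        raise EmptyROIError(f"structure {spec.structure!r} is empty")
    if spec.metric == "D_max":
        return float(values.max())
    if spec.metric == "D_min":
        return float(values.min())
    if spec.metric == "D_mean":
        return float(values.mean())
    x = rx_gy if spec.metric == "V_Rx" else spec.x_gy
    if x is None:
        raise ValueError("V_Rx requires the prescription dose")
    # closed lower bound: dose >= x counts, in % of structure volume
    return float(100.0 * np.count_nonzero(values >= x) / values.size)


def lung_definitions(masks: LabelMaskSet, gtv_name: str = "tumor_gtv",
                     ctv_name: str = "ctv") -> dict[str, np.ndarray]:
    """The three lung definitions (lungs include atelectasis by construction)."""
    lungs = masks.lung_union()
    out = {"lungs": lungs}
    if gtv_name in masks:
        out["lungs_minus_gtv"] = lungs & ~masks[gtv_name]
    if ctv_name in masks:
        out["lungs_minus_ctv"] = lungs & ~masks[ctv_name]
    return out


def default_constraints() -> list[ConstraintSpec]:
    """RTOG-0617-style normal tissue limits used throughout."""
    out = [
        ConstraintSpec(DVHMetricSpec("spinal_cord", "D_max"), 50.5),
        ConstraintSpec(DVHMetricSpec("esophagus", "D_mean"), 34.0),
        ConstraintSpec(DVHMetricSpec("heart", "V_x", 40.0), 50.0),
        ConstraintSpec(DVHMetricSpec("heart", "V_x", 60.0), 30.0),
    ]
    for lung in LUNG_VARIANTS:
        out.append(ConstraintSpec(DVHMetricSpec(lung, "D_mean"), 20.0))
        out.append(ConstraintSpec(DVHMetricSpec(lung, "V_x", 20.0), 30.0))
        out.append(ConstraintSpec(DVHMetricSpec(lung, "V_x", 30.0), 20.0))
    return out


def constraints_from_config(entries: list[dict]) -> list[ConstraintSpec]:
    """Build constraint specs from YAML-style dicts
    (``{structure, metric, limit[, x_gy]}``)."""
    out = []
    for e in entries:
        out.append(ConstraintSpec(
            DVHMetricSpec(e["structure"], e["metric"], e.get("x_gy")), float(e["limit"])
        ))
    return out


def structure_masks(masks: LabelMaskSet) -> dict[str, np.ndarray]:
    """All constraint-relevant structures, including the lung variants."""
    out = dict(masks.items())
    if masks.lobes():
        out.update(lung_definitions(masks))
    return out


def evaluate_constraints(dose: VolumeGrid, masks: LabelMaskSet,
                         constraints: list[ConstraintSpec] | None = None,
                         rx_gy: float | None = None) -> list[ConstraintResult]:
    constraints = constraints if constraints is not None else default_constraints()
    structs = structure_masks(masks)
    out = []
    for c in constraints:
        if c.spec.structure not in structs:
            raise KeyError(f"structure {c.spec.structure!r} not available for constraint")
        value = dvh_metric(dose, structs[c.spec.structure], c.spec, rx_gy)
        out.append(ConstraintResult(c.spec, value, c.limit, met=value <= c.limit))
    return out


def transition(baseline_met: bool, followup_met: bool) -> str:
    if not baseline_met and followup_met:
        return IMPROVED
    if baseline_met and not followup_met:
        return WORSENED
    return UNCHANGED


def compare_constraints(baseline: list[ConstraintResult],
                        followup: list[ConstraintResult]) -> list[ConstraintResult]:
    """Annotate followup results with deltas and met/unmet transitions."""
    if len(baseline) != len(followup):
        raise ValueError("constraint lists do not match")
    out = []
    for b, f in zip(baseline, followup):
        if b.spec != f.spec:
            raise ValueError(f"mismatched constraint order: {b.spec} vs {f.spec}")
        out.append(ConstraintResult(
            f.spec, f.value, f.limit, f.met,
            delta_from_baseline=f.value - b.value,
            transition=transition(b.met, f.met),
        ))
    return out


# ---------------------------------------------------------------------------
# Cohort-level metric-change table
# ---------------------------------------------------------------------------

EXCEEDANCE_THRESHOLDS = (1.0, 2.0, 5.0, 10.0)


def metric_changes(per_patient: pd.DataFrame) -> dict:
    """Cohort summary of baseline->followup metric changes.

    Parameters
    ----------
    per_patient:
        Tidy frame with columns ``patient``, ``alignment`` (bone/carina),
        ``metric`` (label), ``delta`` (Gy or % depending on metric).

    Returns
    -------
    dict with a per-(alignment, metric) summary table (mean, stdev, min,
    max; stdev reported as 0 with ``stdev_defined=False`` for singleton
    groups), the fraction of changes exceeding 1/2/5/10 Gy-or-%, and the
    number of patients with at least one |change| >= 5 per alignment.
    """
    required = {"patient", "alignment", "metric", "delta"}
    missing = required - set(per_patient.columns)
    if missing:
        raise ValueError(f"change table missing columns {sorted(missing)}")
    rows = []
    for (alignment, metric), grp in per_patient.groupby(["alignment", "metric"], sort=False):
        d = grp["delta"].to_numpy(dtype=float)
        rows.append({
            "alignment": alignment,
            "metric": metric,
            "n": d.size,
            "mean": d.mean(),
            "stdev": d.std(ddof=1) if d.size > 1 else 0.0,
            "stdev_defined": d.size > 1,
            "min": d.min(),
            "max": d.max(),
        })
    summary = pd.DataFrame(rows)

    exceed = {}
    patients_large = {}
    for alignment, grp in per_patient.groupby("alignment", sort=False):
        d = grp["delta"].abs().to_numpy(dtype=float)
        exceed[alignment] = {
            f">={thr:g}": float(np.count_nonzero(d >= thr)) / d.size
            for thr in EXCEEDANCE_THRESHOLDS
        }
        large = grp.loc[grp["delta"].abs() >= 5.0, "patient"].nunique()
        patients_large[alignment] = int(large)
    return {
        "summary": summary,
        "exceedance_fraction": exceed,
        "patients_with_change_ge_5": patients_large,
    }
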