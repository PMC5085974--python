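"""End-to-end measurement workflow on image pairs and cohorts.

Each time point is calibrated with its own air/blood anchors, analysis
masks are built (tumor removed; erosion optional), per-lobe mass, density
and volume are measured, and baseline -> followup percent changes are
assembled into a tidy table together with the atelectasis-volume
resolution label.

Phantom truth records are defined on whole (tumor-free) lobe regions, so
phantom/cohort analyses default to un-eroded lobes; the clinically
motivated exterior erosion is available via ``eroded=True``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, classify as classify_resolution
from .calibration import calibrate_image
from .masking import ErosionConfig, build_analysis_masks, remove_tumor
from .measures import change, lobe_classes, measure_lobes
from .synthetic import PhantomPair
from .volume_io import LabelMaskSet, VolumeGrid


def analysis_masks(masks: LabelMaskSet, eroded: bool = True,
                   erosion: ErosionConfig = ErosionConfig()) -> LabelMaskSet:
    """Tumor-free lobe masks, exterior-eroded when ``eroded``."""
    if eroded:
        return build_analysis_masks(masks, erosion)
    return remove_tumor(masks)


def measure_timepoint(raw: VolumeGrid, masks: LabelMaskSet, eroded: bool = True,
                      erosion: ErosionConfig = ErosionConfig()):
    """Calibrate one scan and measure its lobes; returns (measures, anchors)."""
    dens, anchors = calibrate_image(raw, masks)
    prepared = analysis_masks(masks, eroded, erosion)
    return measure_lobes(dens, prepared), anchors


def measure_pair(pair: PhantomPair, eroded: bool = False,
                 erosion: ErosionConfig = ErosionConfig(),
                 classifier: ClassifierConfig = ClassifierConfig()) -> pd.DataFrame:
    """Measure a phantom pair; one row per lobe with measured and true changes."""
    meas_b, _ = measure_timepoint(pair.baseline.raw, pair.baseline.masks, eroded, erosion)
    meas_f, _ = measure_timepoint(pair.followup.raw, pair.followup.masks, eroded, erosion)
    classes = lobe_classes(pair.baseline.masks)
    at_b = pair.baseline.masks.volume_ml("atelectasis")
    at_f = pair.followup.masks.volume_ml("atelectasis")
    label = classify_resolution(at_b, at_f, classifier)

    rows = []
    for lobe in meas_b:
        if lobe not in meas_f:
            continue
        rec = change(meas_b[lobe], meas_f[lobe], lobe, classes.get(lobe, ""))
        truth = pair.truth.lobes.get(lobe)
        rows.append({
            "lobe": lobe,
            "lobe_class": rec.lobe_class,
            "pct_mass_change": rec.pct_mass_change,
            "pct_density_change": rec.pct_density_change,
            "pct_volume_change": rec.pct_volume_change,
            "atelectasis_baseline_ml": at_b,
            "atelectasis_followup_ml": at_f,
            "resolution_label": label,
            "true_pct_mass_change": truth.change.pct_mass_change if truth else np.nan,
            "true_pct_density_change": truth.change.pct_density_change if truth else np.nan,
            "true_pct_volume_change": truth.change.pct_volume_change if truth else np.nan,
            "true_resolution_label": pair.truth.resolution_label,
        })
    return pd.DataFrame(rows)


def measure_cohort(pairs: Iterable[tuple[str, PhantomPair]],
                   eroded: bool = False) -> pd.DataFrame:
    """Tidy per-(patient, lobe) change table for a generated cohort."""
    frames = []
    for patient, (label, pair) in enumerate(pairs):
        df = measure_pair(pair, eroded=eroded)
        df.insert(0, "patient", patient)
        df.insert(1, "programmed_class", label)
        frames.append(df)
    if not frames:
        raise ValueError("empty cohort")
    return pd.concat(frames, ignore_index=True)
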