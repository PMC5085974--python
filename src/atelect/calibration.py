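"""Two-point linear density calibration of raw CT intensities.

Raw scanner units are mapped to relative physical density (mg/cc) using two
reference regions drawn on each image: air outside the body (target
0 mg/cc) and blood in the descending aorta (target 1050 mg/cc).  Because the
map is affine and refit per image, any affine drift in scanner output
cancels exactly, which is the point of the procedure.  Calibrated values
below air (negative densities from noise) are retained, not clamped:
clamping would bias ROI means and mass sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LabelMaskSet, VolumeGrid, require_congruent

TARGET_AIR_MG_CC = 0.0
TARGET_BLOOD_MG_CC = 1050.0


class CalibrationError(ValueError):
    """Degenerate calibration anchors (blood not denser than air in raw units)."""


class EmptyROIError(ValueError):
    """A reference ROI contains no voxels."""


@dataclass(frozen=True)
class CalibrationAnchors:
    """Mean raw intensities of the two reference ROIs and their density targets."""

    mu_air_raw: float
    mu_blood_raw: float
    target_air: float = TARGET_AIR_MG_CC
    target_blood: float = TARGET_BLOOD_MG_CC

    def __post_init__(self) -> None:
        if not self.mu_blood_raw > self.mu_air_raw:
            raise CalibrationError(
                f"blood anchor ({self.mu_blood_raw}) must exceed air anchor ({self.mu_air_raw})"
            )

    @property
    def slope(self) -> float:
        return (self.target_blood - self.target_air) / (self.mu_blood_raw - self.mu_air_raw)


def fit_anchors(raw: VolumeGrid, masks: LabelMaskSet,
                air_name: str = "air_ref", blood_name: str = "blood_ref") -> CalibrationAnchors:
    """ROI means of raw intensity in the air and blood reference regions."""
    require_congruent(raw, masks, "raw volume and label masks")
    for name in (air_name, blood_name):
        if name not in masks:
            raise EmptyROIError(f"reference ROI {name!r} missing from mask set")
        if not np.any(masks[name]):
            raise EmptyROIError(f"reference ROI {name!r} is empty")
    mu_air = float(np.mean(raw.data[masks[air_name]]))
    mu_blood = float(np.mean(raw.data[masks[blood_name]]))
    return CalibrationAnchors(mu_air_raw=mu_air, mu_blood_raw=mu_blood)


def calibrate(raw: VolumeGrid, anchors: CalibrationAnchors) -> VolumeGrid:
    """Voxelwise linear map to relative physical density (mg/cc), no clamping.

    ``d(v) = target_blood * (v - mu_air) / (mu_blood - mu_air)`` for the
    default targets (air -> 0, blood -> 1050 mg/cc).
    """
    v = np.asarray(raw.data, dtype=float)
    dens = anchors.target_air + anchors.slope * (v - anchors.mu_air_raw)
    return raw.with_data(dens)


def calibrate_image(raw: VolumeGrid, masks: LabelMaskSet) -> tuple[VolumeGrid, CalibrationAnchors]:
    """Fit anchors on this image's own reference ROIs, then calibrate it."""
    anchors = fit_anchors(raw, masks)
    return calibrate(raw, anchors), anchors
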