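"""Analysis-mask construction: tumor removal and exterior-only lung erosion.

Lobe delineations inadvertently include extra-pleural tissue at the lung
surface.  To strip it without eating into interlobar fissures, the five
lobes are combined into one lung mask, the combined mask is eroded (1 voxel
in all dimensions, twice), and each lobe is intersected with the eroded
combined lung.  Voxels on a fissure between two lobes, deep inside the
lung, survive; the outer pleural shell does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LOBE_NAMES, LabelMaskSet


def structuring_element(kind: str) -> np.ndarray:
    """3x3x3 erosion element: ``box`` (26-neighbourhood, "1 voxel in all
    dimensions" including diagonals) or ``cross`` (6-neighbourhood)."""
    if kind == "box":
        return np.ones((3, 3, 3), dtype=bool)
    if kind == "cross":
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unknown structuring element {kind!r} (expected 'box' or 'cross')")


@dataclass(frozen=True)
class ErosionConfig:
    iterations: int = 2
    element: str = "box"

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        structuring_element(self.element)  # validate name


def remove_tumor(masks: LabelMaskSet, tumor_name: str = "tumor_gtv") -> LabelMaskSet:
    """Return a copy of ``masks`` with the tumor subtracted from every lobe."""
    out = masks.copy()
    if tumor_name not in masks:
        return out
    tumor = masks[tumor_name]
    for name in LOBE_NAMES:
        if name in out:
            out.add(name, out[name] & ~tumor)
    return out


def erode_combined_lung(masks: LabelMaskSet, config: ErosionConfig = ErosionConfig()) -> np.ndarray:
    """Erode the union of lobe masks; outside-image counts as background."""
    combined = masks.lung_union()
    if config.iterations == 0:
        return combined
    return ndimage.binary_erosion(
        combined,
        structure=structuring_element(config.element),
        iterations=config.iterations,
        border_value=0,
    )


def erode_exterior(masks: LabelMaskSet, config: ErosionConfig = ErosionConfig()) -> LabelMaskSet:
    """Erode each lobe from the exterior of the lung only.

    Each lobe is intersected with the eroded combined lung, so interlobar
    fissure voxels are preserved while the outer pleural shell is removed.
    The union of eroded lobes equals the eroded combined lung.
    """
    eroded_lung = erode_combined_lung(masks, config)
    out = masks.copy()
    for name in LOBE_NAMES:
        if name in out:
            out.add(name, out[name] & eroded_lung)
    return out


def build_analysis_masks(masks: LabelMaskSet,
                         config: ErosionConfig = ErosionConfig(),
                         remove_tumor_first: bool = True,
                         tumor_name: str = "tumor_gtv") -> LabelMaskSet:
    """Tumor-free, exterior-eroded lobe masks — the measurement masks.

    Tumor removal defaults to happening before erosion; the order matters
    when the tumor touches the lung surface (removal first exposes the
    cavity wall to the erosion; removal afterwards does not).
    """
    if remove_tumor_first:
        return erode_exterior(remove_tumor(masks, tumor_name), config)
    return remove_tumor(erode_exterior(masks, config), tumor_name)
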