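"""Resolution classification of atelectatic lobes from atelectasis volumes.

A lobe's baseline -> followup change is labelled ``full``, ``partial`` or
``none`` from the fractional and absolute decrease of atelectasis volume:
more than 80% volume reduction is full resolution, between 20% and 80% is
partial, and a decrease smaller than either 20% or 15 ml is no resolution.
The 15 ml absolute floor guards against delineation noise, which dominates
small volumes; it therefore takes precedence over the fractional rule (a
tiny lobe with 90% reduction but only 9 ml of change is still ``none``).
Volume increases are labelled ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass

FULL = "full"
PARTIAL = "partial"
NONE = "none"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for resolution labelling.

    full_threshold:
        Fractional volume reduction above which (strictly) a lobe is
        labelled full resolution.  Exactly at the threshold -> partial.
    partial_lower:
        Fractional reduction below which (strictly) the label is none.
        Exactly at the threshold -> partial.
    absolute_floor_ml:
        Absolute decrease below which (strictly) the label is none
        regardless of fraction.  Exactly at the floor -> not floored.
    """

    full_threshold: float = 0.80
    partial_lower: float = 0.20
    absolute_floor_ml: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.partial_lower < self.full_threshold < 1.0):
            raise ValueError(
                f"need 0 < partial_lower < full_threshold < 1, got "
                f"{self.partial_lower}, {self.full_threshold}"
            )
        if self.absolute_floor_ml < 0:
            raise ValueError("absolute_floor_ml must be >= 0")


def classify(v_baseline_ml: float, v_followup_ml: float,
             config: ClassifierConfig = ClassifierConfig()) -> str:
    """Label atelectasis change as ``full`` / ``partial`` / ``none``.

    Parameters are atelectasis volumes (ml) at the two time points;
    ``v_baseline_ml`` must be positive.
    """
    if not v_baseline_ml > 0:
        raise ValueError(f"baseline atelectasis volume must be > 0, got {v_baseline_ml}")
    if v_followup_ml < 0:
        raise ValueError(f"followup atelectasis volume must be >= 0, got {v_followup_ml}")
    decrease_ml = v_baseline_ml - v_followup_ml
    fraction = decrease_ml / v_baseline_ml
    if fraction < config.partial_lower or decrease_ml < config.absolute_floor_ml:
        return NONE
    if fraction > config.full_threshold:
        return FULL
    return PARTIAL
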