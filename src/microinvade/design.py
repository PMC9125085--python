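"""Experimental-design arithmetic for the microcosm columns.

Snowmelt rates are reported in the glaciological unit mm we/day
(millimetres of water equivalent per day): the depth of liquid water
released per day over the column's cross-section.  A microcosm built in a
50 ml conical centrifugal tube (inner diameter ~30 mm) therefore converts a
melt rate into a daily input volume via the tube cross-sectional area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import ValidationError

#: Inner diameter of a 50 ml conical centrifugal tube, in mm.  This is the
#: unique round value for which the Arctic average melt rate (9 mm we/day)
#: and the fast scenario (35 mm we/day) convert to 6.4 and 24.7 ml/day.
DEFAULT_INNER_DIAMETER_MM = 30.0


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention the printed volumes use)."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def melt_rate_to_volume(
    rate_mm_we_per_day: float,
    inner_diameter_mm: float = DEFAULT_INNER_DIAMETER_MM,
    *,
    rounded: bool = True,
) -> float:
    """Convert a snowmelt rate (mm we/day) to a daily input volume (ml/day).

    volume = rate × π × (d/2)² / 1000, i.e. water depth times the column
    cross-section, with mm³ → ml conversion.  The result is rounded half-up
    to one decimal unless ``rounded=False``.

    >>> melt_rate_to_volume(9)
    6.4
    >>> melt_rate_to_volume(35)
    24.7
    """
    if rate_mm_we_per_day < 0:
        raise ValidationError("melt rate must be non-negative")
    if inner_diameter_mm <= 0:
        raise ValidationError("inner diameter must be positive")
    volume = rate_mm_we_per_day * math.pi * (inner_diameter_mm / 2.0) ** 2 / 1000.0
    return _round_half_up(volume, 1) if rounded else volume


@dataclass
class ExperimentDesign:
    """Bookkeeping for one microcosm experiment's layout.

    Four arms (2 conditions × treatment/control) in triplicate give the
    standard 12 microcosms per experiment.
    """

    experiments: tuple[str, ...] = ("melt_rate", "soil_ph")
    arms_per_experiment: int = 4
    replicates: int = 3
    #: daily input volume (ml/day) per arm label
    input_schedule_ml_per_day: dict = field(
        default_factory=lambda: {
            "average": melt_rate_to_volume(9),
            "fast": melt_rate_to_volume(35),
        }
    )
    soil_mass_g: float = 30.0
    inner_diameter_mm: float = DEFAULT_INNER_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.arms_per_experiment < 1:
            raise ValidationError("arms_per_experiment must be >= 1")

    @property
    def microcosms_per_experiment(self) -> int:
        return self.arms_per_experiment * self.replicates
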