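"""Small assay formulas: LDH-release cytotoxicity and caliper tumor volume."""

from __future__ import annotations

from dataclasses import dataclass

MM_PER_UNIT = {"mm": 1.0, "cm": 10.0}


@dataclass(frozen=True)
class LdhMeasurement:
    """OD490 readings from an LDH release assay."""

    od_treated: float
    od_spontaneous: float
    od_maximum: float

    def __post_init__(self) -> None:
        if min(self.od_treated, self.od_spontaneous, self.od_maximum) < 0:
            raise ValueError("optical densities must be non-negative")
        if self.od_maximum <= self.od_spontaneous:
            raise ValueError(
                "maximum LDH activity must exceed spontaneous activity "
                "(cytotoxicity undefined otherwise)"
            )


def ldh_cytotoxicity(m: LdhMeasurement) -> float:
    """Percent cytotoxicity: 100 x (treated - spontaneous) / (maximum - spontaneous).

    Values outside [0, 100] are reported as-is (they indicate readings outside
    the spontaneous/maximum bracket).
    """
    return 100.0 * (m.od_treated - m.od_spontaneous) / (m.od_maximum - m.od_spontaneous)


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper length/width; length is the longer axis by convention."""

    length: float
    width: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.unit not in MM_PER_UNIT:
            raise ValueError(f"unit must be one of {sorted(MM_PER_UNIT)}")
        if self.width <= 0 or self.length <= 0:
            raise ValueError("measurements must be positive")
        if self.length < self.width:
            raise ValueError("length must be the longer axis (length >= width)")


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-approximation tumor volume in mm^3: L x W^2 x 0.5."""
    scale = MM_PER_UNIT[m.unit]
    length_mm = m.length * scale
    width_mm = m.width * scale
    return length_mm * width_mm**2 * 0.5
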