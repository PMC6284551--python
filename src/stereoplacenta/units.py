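"""Minimal length/area/volume unit tags.

Stereological estimators work internally in micrometres; diffusion-capacity
arithmetic is done in centimetres, as is conventional for the Krogh
coefficient. This module exists so that the reporting boundary is explicit
and a µm value cannot silently be fed where a cm value is expected.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnitError(ValueError):
    """Raised when a quantity carries the wrong unit/dimension."""


# scale factors to the base unit of each dimension (um, um^2, um^3)
_UNITS: dict[str, tuple[str, float]] = {
    "um": ("length", 1.0),
    "mm": ("length", 1e3),
    "cm": ("length", 1e4),
    "um^2": ("area", 1.0),
    "mm^2": ("area", 1e6),
    "cm^2": ("area", 1e8),
    "um^3": ("volume", 1.0),
    "mm^3": ("volume", 1e9),
    "cm^3": ("volume", 1e12),
}


@dataclass(frozen=True)
class Quantity:
    """A number with a length-like unit tag."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; known: {sorted(_UNITS)}")

    @property
    def dimension(self) -> str:
        return _UNITS[self.unit][0]

    def to(self, unit: str) -> "Quantity":
        if unit not in _UNITS:
            raise UnitError(f"unknown unit {unit!r}")
        dim_to, scale_to = _UNITS[unit]
        dim_from, scale_from = _UNITS[self.unit]
        if dim_to != dim_from:
            raise UnitError(
                f"cannot convert {self.unit} ({dim_from}) to {unit} ({dim_to})"
            )
        return Quantity(self.value * scale_from / scale_to, unit)

    def value_in(self, unit: str) -> float:
        return self.to(unit).value


def as_quantity(x: "Quantity | float", unit: str) -> Quantity:
    """Coerce *x* to a Quantity in *unit*.

    Floats are taken to already be in *unit*; Quantities are converted
    (raising :class:`UnitError` on a dimension mismatch).
    """
    if isinstance(x, Quantity):
        return x.to(unit)
    return Quantity(float(x), unit)
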