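"""Energy units, exact conversion, and the shared physical constants.

All internal arithmetic elsewhere in the package is done in kJ/mol;
conversion happens only at input/output boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UNITS",
    "HARTREE_IN_KJ_PER_MOL",
    "KCAL_IN_KJ",
    "EV_IN_KJ_PER_MOL",
    "TEMPERATURE_K",
    "H_ATOM_THERMAL_CORRECTION_HARTREE",
    "ConstantSet",
    "DEFAULT_CONSTANTS",
    "EnergyValue",
    "UnknownUnitError",
    "convert",
    "as_kj_per_mol",
    "from_kj_per_mol",
    "h_atom_enthalpy",
    "round_printed",
]

#: Defining conversion constants (thermochemical calorie).
HARTREE_IN_KJ_PER_MOL = 2625.49964
KCAL_IN_KJ = 4.184
EV_IN_KJ_PER_MOL = 96.48533

#: All enthalpies handled by this package refer to this temperature.
TEMPERATURE_K = 298.15

#: Thermal enthalpy correction of a free H atom at 298.15 K, in hartree
#: (5/2 RT plus the electronic-energy offset convention of compound models).
H_ATOM_THERMAL_CORRECTION_HARTREE = 0.002361

UNITS = ("hartree", "kJ/mol", "kcal/mol", "eV")

_TO_KJ = {
    "hartree": HARTREE_IN_KJ_PER_MOL,
    "kJ/mol": 1.0,
    "kcal/mol": KCAL_IN_KJ,
    "eV": EV_IN_KJ_PER_MOL,
}

# Case/spacing-tolerant aliases accepted at the boundary.
_UNIT_ALIASES = {
    "hartree": "hartree",
    "ha": "hartree",
    "au": "hartree",
    "a.u.": "hartree",
    "kj/mol": "kJ/mol",
    "kjmol": "kJ/mol",
    "kj mol-1": "kJ/mol",
    "kcal/mol": "kcal/mol",
    "kcalmol": "kcal/mol",
    "kcal mol-1": "kcal/mol",
    "ev": "eV",
}


class UnknownUnitError(ValueError):
    """Raised when a unit string is not in the closed unit enumeration."""

    def __init__(self, unit: object):
        super().__init__(
            f"unknown energy unit {unit!r}; expected one of {', '.join(UNITS)}"
        )
        self.unit = unit


def canonical_unit(unit: str) -> str:
    """Return the canonical spelling of *unit*, or raise :class:`UnknownUnitError`."""
    if unit in _TO_KJ:
        return unit
    key = str(unit).strip().lower()
    if key in _UNIT_ALIASES:
        return _UNIT_ALIASES[key]
    raise UnknownUnitError(unit)


@dataclass(frozen=True)
class ConstantSet:
    """The numerical constants every other module relies on."""

    hartree_in_kJ_per_mol: float = HARTREE_IN_KJ_PER_MOL
    kcal_in_kJ: float = KCAL_IN_KJ
    eV_in_kJ_per_mol: float = EV_IN_KJ_PER_MOL
    temperature_K: float = TEMPERATURE_K
    h_atom_thermal_correction_hartree: float = H_ATOM_THERMAL_CORRECTION_HARTREE


DEFAULT_CONSTANTS = ConstantSet()


@dataclass(frozen=True)
class EnergyValue:
    """A magnitude with an explicit energy unit."""

    magnitude: float
    unit: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude):
            raise ValueError(f"energy magnitude must be finite, got {self.magnitude!r}")
        object.__setattr__(self, "unit", canonical_unit(self.unit))

    def to(self, target_unit: str) -> "EnergyValue":
        """Express the same physical quantity in *target_unit*."""
        return convert(self, target_unit)

    @property
    def kj(self) -> float:
        """Magnitude in kJ/mol."""
        return self.magnitude * _TO_KJ[self.unit]


def convert(value: EnergyValue, target_unit: str) -> EnergyValue:
    """Convert *value* to *target_unit*.

    Conversion to the same unit is the exact identity (no arithmetic).
    """
    target = canonical_unit(target_unit)
    if target == value.unit:
        return value
    return EnergyValue(value.kj / _TO_KJ[target], target)


def as_kj_per_mol(magnitude: float, unit: str) -> float:
    """Scalar convenience: *magnitude* expressed in *unit* -> kJ/mol."""
    return magnitude * _TO_KJ[canonical_unit(unit)]


def from_kj_per_mol(magnitude_kj: float, unit: str) -> float:
    """Scalar convenience: a kJ/mol magnitude -> *unit*."""
    return magnitude_kj / _TO_KJ[canonical_unit(unit)]


def h_atom_enthalpy(electronic_energy_hartree: float) -> EnergyValue:
    """Enthalpy of a free H atom at 298.15 K from its electronic energy.

    Adds the fixed thermal correction of 0.002361 hartree.
    """
    if not math.isfinite(electronic_energy_hartree):
        raise ValueError(
            f"electronic energy must be finite, got {electronic_energy_hartree!r}"
        )
    return EnergyValue(
        electronic_energy_hartree + H_ATOM_THERMAL_CORRECTION_HARTREE, "hartree"
    )


def round_printed(value: float, decimals: int) -> float:
    """Round half away from zero, as printed thermochemistry tables do.

    A relative epsilon of 1e-9 is applied before rounding to guard against
    binary-representation edge cases (e.g. a value stored as x.x4999...9).
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    if value == 0:
        return 0.0
    scale = 10.0**decimals
    scaled = value * scale
    scaled += math.copysign(abs(scaled) * 1e-9, scaled)
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / scale
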