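"""Reference-particle catalog: H+, e- and H. enthalpies per medium and method.

The built-in catalog ships the gas-phase proton and electron enthalpies, the
H-atom enthalpy for four DFT functionals over the common Pople basis-set
families, and the solvation enthalpies of the three reference particles in
five solvents.  The central derived quantity is the ionization enthalpy of
the H atom in a medium::

    IP_H = [H(H+) + dHsolv(H+)] + [H(e-) + dHsolv(e-)] - [H(H.) + dHsolv(H.)]

which is the exact, antioxidant-independent difference between the combined
two-step scavenging enthalpy and BDE.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .units import EnergyValue, as_kj_per_mol, from_kj_per_mol

__all__ = [
    "MethodKey",
    "Medium",
    "Catalog",
    "normalize_basis",
    "normalize_functional",
    "default_catalog",
    "UnknownMethodError",
    "UnknownMediumError",
]

_KNOWN_FUNCTIONALS = ("B3LYP", "PBE0", "M062x", "M052x")

# Polarization variants that are numerically degenerate with G(d,p) for the
# one-electron H atom; "(3df,pd)" covers a typographical variant seen in print.
_POLARIZATION_DEGENERATE = re.compile(r"\((2d,2p|3df,3pd|3df,pd)\)")


def normalize_basis(name: str) -> str:
    """Collapse a Pople basis-set name onto its canonical catalog key.

    Rules: whitespace is stripped; ``**`` is shorthand for ``(d,p)``; a
    transposed diffuse marker (``6-31G+``) is fixed; extra polarization sets
    degenerate for a one-electron atom map to ``(d,p)``; and within each
    family the variants that yield identical H-atom enthalpies collapse
    (``6-311G`` onto ``6-311+G``, ``6-31G`` onto ``6-31+G``).
    """
    s = re.sub(r"\s+", "", str(name))
    if not s:
        raise ValueError("basis name must be non-empty")
    s = s.replace("**", "(d,p)")
    s = s.replace("G+(", "+G(")
    s = _POLARIZATION_DEGENERATE.sub("(d,p)", s)
    if s.startswith("6-311G"):
        s = "6-311+G" + s[len("6-311G"):]
    elif s.startswith("6-31G"):
        s = "6-31+G" + s[len("6-31G"):]
    return s


def normalize_functional(name: str) -> str:
    """Canonical functional name; UB3LYP/ROB3LYP resolve to B3LYP, etc."""
    s = str(name).strip()
    if not s:
        raise ValueError("functional name must be non-empty")
    low = s.lower()
    for known in _KNOWN_FUNCTIONALS:
        if low == known.lower():
            return known
        # unrestricted / restricted-open-shell prefixes use the same H atom
        if low in ("u" + known.lower(), "ro" + known.lower(), "r" + known.lower()):
            return known
    return s


@dataclass(frozen=True)
class MethodKey:
    """A (functional, basis set) pair identifying a level of theory."""

    functional: str
    basis: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "functional", normalize_functional(self.functional))
        object.__setattr__(self, "basis", normalize_basis(self.basis))

    @classmethod
    def parse(cls, spec: str) -> "MethodKey":
        """Parse ``"FUNCTIONAL/BASIS"``, e.g. ``"B3LYP/6-311++G(d,p)"``."""
        functional, sep, basis = str(spec).partition("/")
        if not sep or not basis:
            raise ValueError(f"expected FUNCTIONAL/BASIS, got {spec!r}")
        return cls(functional, basis)

    def __str__(self) -> str:
        return f"{self.functional}/{self.basis}"


@dataclass(frozen=True)
class Medium:
    """A named environment with solvation enthalpies for H+, e- and H. (kJ/mol)."""

    name: str
    dH_solv_proton: float
    dH_solv_electron: float
    dH_solv_hatom: float
    provenance: str = ""

    def __post_init__(self) -> None:
        for field in ("dH_solv_proton", "dH_solv_electron", "dH_solv_hatom"):
            v = getattr(self, field)
            if not math.isfinite(v):
                raise ValueError(f"{field} of medium {self.name!r} must be finite")

    @property
    def solvation_shift_kj(self) -> float:
        """Medium-induced shift of IP_H relative to gas (method-independent)."""
        return self.dH_solv_proton + self.dH_solv_electron - self.dH_solv_hatom


class UnknownMethodError(KeyError):
    def __init__(self, method: MethodKey, available: Iterable[MethodKey]):
        keys = ", ".join(sorted(str(m) for m in available))
        super().__init__(f"no H-atom enthalpy for {method}; available: {keys}")
        self.method = method


class UnknownMediumError(KeyError):
    def __init__(self, name: str, available: Iterable[str]):
        super().__init__(
            f"unknown medium {name!r}; available: {', '.join(sorted(available))}"
        )
        self.name = name


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


class Catalog:
    """Reference catalog of particle enthalpies, media and methods.

    Loaded from a structured YAML document; the packaged default mirrors the
    published reference tables and can be overridden or extended with a user
    file of the same schema (merged on top of the default).
    """

    def __init__(self, spec: Mapping):
        self._spec = dict(spec)
        gas = self._spec["gas_particles"]
        #: gas-phase translational enthalpies, kJ/mol
        self.proton_gas_kj = float(gas["proton_kj_per_mol"])
        self.electron_gas_kj = float(gas["electron_kj_per_mol"])
        self._h_atom = {
            normalize_functional(func): {
                normalize_basis(basis): float(value) for basis, value in table.items()
            }
            for func, table in self._spec["h_atom_enthalpy_hartree"].items()
        }
        self._media: dict[str, Medium] = {}
        for name, entry in self._spec["media"].items():
            self._media[name] = Medium(
                name=name,
                dH_solv_proton=float(entry["proton"]),
                dH_solv_electron=float(entry["electron"]),
                dH_solv_hatom=float(entry["h_atom"]),
                provenance=str(entry.get("provenance", "")),
            )
        self._variants: dict[str, Medium] = {}
        for name, entry in self._spec.get("variants", {}).items():
            base = self._media[entry["base"]]
            self._variants[name] = Medium(
                name=name,
                dH_solv_proton=float(entry.get("proton", base.dH_solv_proton)),
                dH_solv_electron=float(entry.get("electron", base.dH_solv_electron)),
                dH_solv_hatom=float(entry.get("h_atom", base.dH_solv_hatom)),
                provenance=str(entry.get("provenance", "")),
            )

    # -- construction --------------------------------------------------

    @classmethod
    def default(cls) -> "Catalog":
        text = resources.files("radaudit.data").joinpath("reference_media.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "Catalog":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def with_override(self, override: Mapping | str | Path) -> "Catalog":
        """New catalog with *override* (mapping or YAML path) merged on top."""
        if not isinstance(override, Mapping):
            with open(override) as fh:
                override = yaml.safe_load(fh)
        return Catalog(_deep_merge(self._spec, override))

    # -- lookups -------------------------------------------------------

    def media(self) -> list[Medium]:
        return list(self._media.values())

    def medium(self, name: str, *, variant: str | None = None) -> Medium:
        if variant is not None:
            if variant not in self._variants:
                raise UnknownMediumError(variant, self._variants)
            return self._variants[variant]
        if name not in self._media:
            raise UnknownMediumError(name, self._media)
        return self._media[name]

    def methods(self) -> list[MethodKey]:
        return [
            MethodKey(func, basis)
            for func, table in self._h_atom.items()
            for basis in table
        ]

    def lookup_h_atom(self, method: MethodKey | str) -> EnergyValue:
        """Tabulated H-atom enthalpy (hartree) for a level of theory.

        Degenerate basis variants resolve to the same stored value via
        :func:`normalize_basis`.
        """
        if isinstance(method, str):
            method = MethodKey.parse(method)
        table = self._h_atom.get(method.functional)
        if table is None or method.basis not in table:
            raise UnknownMethodError(method, self.methods())
        return EnergyValue(table[method.basis], "hartree")

    def iph(
        self,
        method: MethodKey | str,
        medium: Medium | str,
        unit: str = "kJ/mol",
    ) -> EnergyValue:
        """Ionization enthalpy of the H atom in *medium* at *method* level.

        Assembled as gas-phase particle enthalpies plus the medium's solvation
        terms; with an all-zero medium this reduces to the gas-phase value.
        """
        if isinstance(medium, str):
            medium = self.medium(medium)
        h_h_kj = as_kj_per_mol(self.lookup_h_atom(method).magnitude, "hartree")
        value_kj = (
            (self.proton_gas_kj + medium.dH_solv_proton)
            + (self.electron_gas_kj + medium.dH_solv_electron)
            - (h_h_kj + medium.dH_solv_hatom)
        )
        return EnergyValue(from_kj_per_mol(value_kj, unit), unit)

    # -- annexes -------------------------------------------------------

    @staticmethod
    def koopmans_annex() -> pd.DataFrame:
        """Read-only annex of HOMO-based (Koopmans) IP_H estimates.

        Shipped for comparison display only; these estimates are known to be
        unreliable and nothing in the package computes with them.
        """
        with resources.files("radaudit.data").joinpath("koopmans_annex.csv").open() as fh:
            return pd.read_csv(fh)

    @staticmethod
    def printed_iph_table() -> pd.DataFrame:
        """Published IP_H reference cells in three units, with erratum flags."""
        with resources.files("radaudit.data").joinpath("printed_iph.csv").open() as fh:
            df = pd.read_csv(fh)
        df["erratum"] = df["erratum"].fillna("")
        return df


def default_catalog() -> Catalog:
    """The packaged built-in catalog."""
    return Catalog.default()
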