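"""The five mechanism descriptors computed from species enthalpies.

Descriptors (all balanced reaction enthalpies, kJ/mol internally):

* ``BDE = H(AX.) + H(H.) - H(AXH)``          - single-step H-atom transfer
* ``IP  = H(AXH+.) + H(e-) - H(AXH)``        - first step, electron loss
* ``PDE = H(AX.) + H(H+) - H(AXH+.)``        - second step, proton loss
* ``PA  = H(AX-) + H(H+) - H(AXH)``          - first step, proton loss
* ``ETE = H(AX.) + H(e-) - H(AX-)``          - second step, electron loss

Reference-particle enthalpies in a solvent are assembled as the gas-phase
value plus the medium's solvation term.  Two exact identities follow from
the shared endpoints of the two-step routes and from Hess's law:
``IP + PDE = PA + ETE`` and ``IP + PDE - BDE = IP_H(medium)``.

Gibbs-energy inputs satisfy the same algebra; the quantity kind is a
dataset-level tag, not a separate code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .media import Catalog, Medium, MethodKey
from .units import EnergyValue

__all__ = [
    "SpeciesEnthalpies",
    "DescriptorSet",
    "compute_descriptors",
    "combined",
    "corollary_orderings",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = ("BDE", "IP", "PDE", "PA", "ETE")


@dataclass(frozen=True)
class SpeciesEnthalpies:
    """Per-site enthalpies of the four antioxidant-derived species.

    The parent ``AXH`` and radical ``AX.`` are required for any descriptor;
    the anion ``AX-`` and radical cation ``AXH+.`` are each needed only for
    the descriptors that involve them.
    """

    molecule_id: str
    site_id: str = ""
    H_AXH: Optional[EnergyValue] = None
    H_AXrad: Optional[EnergyValue] = None
    H_AXanion: Optional[EnergyValue] = None
    H_AXHcation: Optional[EnergyValue] = None
    medium: str = "gas"
    method: Optional[MethodKey] = None
    provenance: str = ""


@dataclass
class DescriptorSet:
    """Descriptor values for one molecule/site, with reported vs computed slots.

    ``setpt``/``splet``/``iph_base`` hold values *as reported* in a source
    table; ``setpt_computed``/``splet_computed`` are filled from the step
    components by :func:`combined` and never overwrite reported cells.
    ``iph_base`` is the reported value of the two-step sum minus BDE.
    """

    molecule_id: str
    site_id: str = ""
    medium: str = "gas"
    unit: str = "kJ/mol"
    bde: Optional[float] = None
    ip: Optional[float] = None
    pde: Optional[float] = None
    pa: Optional[float] = None
    ete: Optional[float] = None
    setpt: Optional[float] = None
    splet: Optional[float] = None
    iph_base: Optional[float] = None
    setpt_computed: Optional[float] = None
    splet_computed: Optional[float] = None
    method: Optional[MethodKey] = None
    #: half-ranges of "a±b" cells, keyed by upper-case descriptor name
    uncertainty: dict = field(default_factory=dict)
    #: reasons individual descriptors are absent (missing species, bad cells)
    missing: dict = field(default_factory=dict)
    #: row-level provenance, e.g. "table.csv:3" or "computed"
    provenance: str = ""

    def get(self, name: str) -> Optional[float]:
        """Descriptor value by conventional name (case-insensitive)."""
        key = name.strip().upper()
        if key in ("BDE", "IP", "PDE", "PA", "ETE"):
            return getattr(self, key.lower())
        if key in ("SETPT", "SET-PT", "IP+PDE"):
            return self.setpt
        if key in ("SPLET", "PA+ETE"):
            return self.splet
        if key in ("IPH", "IPH_BASE"):
            return self.iph_base
        raise KeyError(name)

    @property
    def label(self) -> str:
        return f"{self.molecule_id}/{self.site_id}" if self.site_id else self.molecule_id


def _kj(value: Optional[EnergyValue]) -> Optional[float]:
    return None if value is None else value.kj


def compute_descriptors(
    species: SpeciesEnthalpies,
    catalog: Catalog,
    medium: Medium | str | None = None,
) -> DescriptorSet:
    """All computable descriptors for one site, in kJ/mol.

    Descriptors whose species are missing are absent (with a reason recorded
    in ``missing``), never silently zero.  The reference-particle enthalpies
    are resolved for the given medium as gas value + solvation term.
    """
    if medium is None:
        medium = species.medium
    if isinstance(medium, str):
        medium = catalog.medium(medium)
    if species.method is None:
        raise ValueError(
            f"species set {species.molecule_id!r} has no level-of-theory key; "
            "one is required to resolve the H-atom enthalpy"
        )

    h_proton = catalog.proton_gas_kj + medium.dH_solv_proton
    h_electron = catalog.electron_gas_kj + medium.dH_solv_electron
    h_hatom = catalog.lookup_h_atom(species.method).kj + medium.dH_solv_hatom

    axh = _kj(species.H_AXH)
    rad = _kj(species.H_AXrad)
    anion = _kj(species.H_AXanion)
    cation = _kj(species.H_AXHcation)

    out = DescriptorSet(
        molecule_id=species.molecule_id,
        site_id=species.site_id,
        medium=medium.name,
        unit="kJ/mol",
        method=species.method,
        provenance=f"computed:{species.molecule_id}"
        + (f"/{species.site_id}" if species.site_id else ""),
    )
    if axh is None:
        out.missing = {d: "H(AXH) missing" for d in ("BDE", "IP", "PA")}
    if rad is None:
        for d in ("BDE", "PDE", "ETE"):
            out.missing.setdefault(d, "H(AX.) missing")

    # math.fsum keeps each balanced-reaction sum correctly rounded, so the
    # exact identities survive at the 1e-9 kJ/mol level even for
    # total-energy magnitudes of ~1e6 kJ/mol.
    if axh is not None and rad is not None:
        out.bde = math.fsum((rad, h_hatom, -axh))
    if axh is not None and cation is not None:
        out.ip = math.fsum((cation, h_electron, -axh))
    elif cation is None:
        out.missing.setdefault("IP", "H(AXH+.) missing")
    if rad is not None and cation is not None:
        out.pde = math.fsum((rad, h_proton, -cation))
    elif cation is None:
        out.missing.setdefault("PDE", "H(AXH+.) missing")
    if axh is not None and anion is not None:
        out.pa = math.fsum((anion, h_proton, -axh))
    elif anion is None:
        out.missing.setdefault("PA", "H(AX-) missing")
    if rad is not None and anion is not None:
        out.ete = math.fsum((rad, h_electron, -anion))
    elif anion is None:
        out.missing.setdefault("ETE", "H(AX-) missing")

    return combined(out)


def combined(d: DescriptorSet) -> DescriptorSet:
    """Fill the combined two-step sums from components.

    Reported ``setpt``/``splet`` cells are left untouched; computed sums are
    stored alongside in the ``*_computed`` slots.  Absent addends yield an
    absent sum.
    """
    out = replace(d) if isinstance(d, DescriptorSet) else d
    out.uncertainty = dict(d.uncertainty)
    out.missing = dict(d.missing)
    if d.ip is not None and d.pde is not None:
        out.setpt_computed = d.ip + d.pde
    if d.pa is not None and d.ete is not None:
        out.splet_computed = d.pa + d.ete
    if out.setpt is None:
        out.setpt = out.setpt_computed
    if out.splet is None:
        out.splet = out.splet_computed
    return out


def corollary_orderings(d: DescriptorSet, tie_tol: float = 1e-9) -> dict:
    """Verdicts for the four ordering biconditionals linking the step enthalpies.

    With the two-step sums exactly equal, ``IP < PA`` forces ``PDE > ETE``
    and so on; each check returns ``consistent``, ``violated`` or ``tied``
    (either comparison within *tie_tol*).  Requires all four step descriptors.
    """
    pairs = {
        "C1a": (("IP", "PA", "<"), ("PDE", "ETE", ">")),
        "C1b": (("IP", "PA", ">"), ("PDE", "ETE", "<")),
        "C1c": (("IP", "ETE", "<"), ("PDE", "PA", ">")),
        "C1d": (("IP", "ETE", ">"), ("PDE", "PA", "<")),
    }
    values = {"IP": d.ip, "PA": d.pa, "PDE": d.pde, "ETE": d.ete}
    if any(v is None for v in values.values()):
        absent = [k for k, v in values.items() if v is None]
        raise ValueError(f"ordering checks need IP, PDE, PA, ETE; missing {absent}")

    def side(a: str, b: str, op: str) -> Optional[bool]:
        diff = values[a] - values[b]
        if abs(diff) <= tie_tol:
            return None
        return diff < 0 if op == "<" else diff > 0

    report = {}
    for check, (lhs, rhs) in pairs.items():
        left, right = side(*lhs), side(*rhs)
        if left is None or right is None:
            report[check] = "tied"
        else:
            report[check] = "consistent" if left == right else "violated"
    return report
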