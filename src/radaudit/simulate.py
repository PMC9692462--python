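"""Seeded synthetic species/descriptor tables with labeled fault injection.

Tables are consistent by construction: species enthalpies are drawn so the
derived descriptors land in realistic windows (BDE in [300, 500] kJ/mol,
adiabatic IP in [500, 900] kJ/mol — spans taken from published tables, not
from physical modeling), and the two exact identities hold to float
precision.  Controlled violations can then be injected with ground-truth
labels, to measure audit sensitivity and specificity.

Randomness comes exclusively from an explicitly seeded generator passed
through every public entry point; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .descriptors import DescriptorSet, SpeciesEnthalpies, combined, compute_descriptors
from .media import Catalog, MethodKey
from .units import KCAL_IN_KJ, EnergyValue, from_kj_per_mol

__all__ = [
    "ViolationSpec",
    "TruthLabel",
    "VIOLATION_KINDS",
    "generate_consistent",
    "inject",
    "write_simulation",
    "BDE_WINDOW_KJ",
    "IP_WINDOW_KJ",
    "PA_WINDOW_KJ",
]

VIOLATION_KINDS = (
    "none",
    "t1_offset",
    "t2_offset",
    "unit_mixup",
    "medium_mislabel",
    "transcription_error",
)

BDE_WINDOW_KJ = (300.0, 500.0)
IP_WINDOW_KJ = (500.0, 900.0)
PA_WINDOW_KJ = (50.0, 600.0)

#: scale of the absolute species enthalpies; irrelevant to the descriptors
_AXH_WINDOW_KJ = (-2.1e6, -1.9e6)


@dataclass(frozen=True)
class ViolationSpec:
    """What to break, by how much, and where."""

    kind: str = "none"
    magnitude_kj: float = 0.0
    #: row indices to perturb; None means every row
    target_rows: Optional[tuple[int, ...]] = None
    #: for medium_mislabel: the wrong medium to declare
    mislabel_as: str = "gas"

    def __post_init__(self) -> None:
        if self.kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind {self.kind!r}")
        if self.magnitude_kj < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one injected violation."""

    row_index: int
    kind: str
    expected_checks: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"row_index": self.row_index, "kind": self.kind,
                "expected_checks": list(self.expected_checks)}


def generate_consistent(
    n_molecules: int,
    sites_per_molecule: int,
    medium: str,
    method: MethodKey | str,
    seed: int,
    catalog: Catalog | None = None,
) -> tuple[list[SpeciesEnthalpies], list[DescriptorSet]]:
    """Random species enthalpies plus the descriptor table they imply.

    The ionization value is drawn once per molecule (it belongs to the parent
    species); BDE and the deprotonation enthalpy vary per site.  The returned
    descriptor rows are recomputed from the species through the standard
    descriptor path, so both exact identities hold by construction.
    """
    if n_molecules < 1 or sites_per_molecule < 1:
        raise ValueError("molecule and site counts must be >= 1")
    if isinstance(method, str):
        method = MethodKey.parse(method)
    catalog = catalog or Catalog.default()
    med = catalog.medium(medium)
    rng = np.random.default_rng(seed)

    h_proton = catalog.proton_gas_kj + med.dH_solv_proton
    h_electron = catalog.electron_gas_kj + med.dH_solv_electron
    h_hatom = catalog.lookup_h_atom(method).kj + med.dH_solv_hatom

    species: list[SpeciesEnthalpies] = []
    for m in range(n_molecules):
        molecule = f"mol{m + 1:03d}"
        axh = rng.uniform(*_AXH_WINDOW_KJ)
        ip = rng.uniform(*IP_WINDOW_KJ)
        cation = axh + ip - h_electron
        for s in range(sites_per_molecule):
            bde = rng.uniform(*BDE_WINDOW_KJ)
            pa = rng.uniform(*PA_WINDOW_KJ)
            species.append(SpeciesEnthalpies(
                molecule_id=molecule,
                site_id=f"{s + 1}-OH",
                H_AXH=EnergyValue(axh, "kJ/mol"),
                H_AXrad=EnergyValue(axh + bde - h_hatom, "kJ/mol"),
                H_AXanion=EnergyValue(axh + pa - h_proton, "kJ/mol"),
                H_AXHcation=EnergyValue(cation, "kJ/mol"),
                medium=med.name,
                method=method,
                provenance=f"simulated(seed={seed})",
            ))

    descriptors = [compute_descriptors(sp, catalog, med) for sp in species]
    return species, descriptors


def _shift(value: Optional[float], delta: float) -> Optional[float]:
    return None if value is None else value + delta


def inject(
    rows: Sequence[DescriptorSet],
    spec: ViolationSpec,
    catalog: Catalog | None = None,
) -> tuple[list[DescriptorSet], list[TruthLabel]]:
    """Apply a labeled violation to selected rows of a descriptor table.

    Returns the perturbed rows plus ground-truth labels naming the checks an
    audit should fire.  ``unit_mixup`` multiplies the proton-first-route
    cells by 4.184 (one side of the identity, as a kcal/kJ transcription slip
    would); ``medium_mislabel`` changes only the declared medium string.
    """
    if spec.kind != "none" and spec.target_rows is not None:
        bad = [i for i in spec.target_rows if not 0 <= i < len(rows)]
        if bad:
            raise ValueError(f"target rows {bad} outside table of {len(rows)} rows")
        targets = set(spec.target_rows)
        if not targets:
            raise ValueError("violation targets no rows")
    else:
        targets = set(range(len(rows)))

    out: list[DescriptorSet] = []
    labels: list[TruthLabel] = []
    for i, d in enumerate(rows):
        if spec.kind == "none" or i not in targets:
            out.append(d)
            continue
        delta = from_kj_per_mol(spec.magnitude_kj, d.unit)
        if spec.kind == "t1_offset":
            row = replace(d, ete=_shift(d.ete, delta), splet=None, splet_computed=None)
            checks = ("T1",)
        elif spec.kind == "t2_offset":
            # shift both second steps equally: T1 survives, the base moves
            row = replace(d, pde=_shift(d.pde, delta), ete=_shift(d.ete, delta),
                          setpt=None, splet=None,
                          setpt_computed=None, splet_computed=None)
            checks = ("T2_reference", "T2_site_invariance")
        elif spec.kind == "unit_mixup":
            row = replace(d,
                          pa=None if d.pa is None else d.pa * KCAL_IN_KJ,
                          ete=None if d.ete is None else d.ete * KCAL_IN_KJ,
                          splet=None, splet_computed=None)
            checks = ("T1",)
        elif spec.kind == "medium_mislabel":
            if spec.mislabel_as == d.medium:
                raise ValueError("mislabel_as must differ from the true medium")
            row = replace(d, medium=spec.mislabel_as)
            checks = ("T2_reference",)
        elif spec.kind == "transcription_error":
            if d.setpt is None:
                raise ValueError("transcription_error needs a reported combined sum")
            row = replace(d, setpt=d.setpt + delta)
            checks = ("transcription",)
        else:  # pragma: no cover - guarded by ViolationSpec
            raise AssertionError(spec.kind)
        row = combined(replace(row))
        row.uncertainty = dict(d.uncertainty)
        out.append(row)
        labels.append(TruthLabel(i, spec.kind, checks))
    return out, labels


def write_simulation(
    out_dir: str | Path,
    species: Sequence[SpeciesEnthalpies],
    rows: Sequence[DescriptorSet],
    labels: Sequence[TruthLabel],
    manifest: dict,
) -> None:
    """Write species table, descriptor table, truth labels and a manifest."""
    from .tableio import write_descriptor_table, write_species_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_species_table(species, out / "species.csv")
    write_descriptor_table(rows, out / "descriptors.csv")
    (out / "truth.json").write_text(
        json.dumps([label.to_dict() for label in labels], indent=2)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
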