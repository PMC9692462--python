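"""Readers and writers for descriptor tables, species tables and reports.

CSV/TSV in, text or JSON out.  Parsing never fabricates values: blank or
malformed cells become absent values (with a warning on standard error) and
stay absent through the whole pipeline.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, TextIO

import pandas as pd

from .audit import AuditReport
from .descriptors import DescriptorSet, SpeciesEnthalpies, combined
from .media import MethodKey
from .units import EnergyValue, canonical_unit

__all__ = [
    "TableDialect",
    "read_descriptor_table",
    "read_species_table",
    "write_descriptor_table",
    "write_species_table",
    "write_report",
    "read_report_json",
    "fixture_path",
    "load_fixture",
    "FIXTURES",
]

logger = logging.getLogger("radaudit")

#: Packaged descriptor-table fixtures (printed source tables).
FIXTURES = (
    "vitamins_aqueous",
    "peonidin",
    "atorvastatin_methanol",
    "vitamin_b3",
)

_UNCERTAIN = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*(?:±|\+/-)\s*(\d+(?:\.\d+)?)\s*$")

_DESCRIPTOR_COLUMNS = {
    "bde": "bde", "ip": "ip", "pde": "pde", "pa": "pa", "ete": "ete",
    "setpt": "setpt", "set-pt": "setpt", "ip+pde": "setpt",
    "splet": "splet", "pa+ete": "splet",
    "iph": "iph_base", "iph_base": "iph_base",
}
_ID_COLUMNS = {
    "molecule_id": "molecule_id", "molecule": "molecule_id",
    "site_id": "site_id", "site": "site_id", "position": "site_id",
    "medium": "medium", "unit": "unit",
    "functional": "functional", "basis": "basis", "basis_set": "basis",
}

_SPECIES_ROLES = ("AXH", "AX_radical", "AX_anion", "AXH_cation")


@dataclass(frozen=True)
class TableDialect:
    """How a delimited table is spelled."""

    delimiter: Optional[str] = None  # None: "\t" for .tsv/.tab, else ","
    decimal: str = "."
    missing_tokens: tuple[str, ...] = ("", "na", "nan", "-", "--")
    uncertainty_pattern: re.Pattern = _UNCERTAIN

    def __post_init__(self) -> None:
        if self.delimiter is not None and self.delimiter == self.decimal:
            raise ValueError("delimiter and decimal mark must differ")

    def resolve_delimiter(self, path: str | Path) -> str:
        if self.delimiter is not None:
            return self.delimiter
        return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _parse_cell(
    raw: Optional[str], dialect: TableDialect, where: str
) -> tuple[Optional[float], Optional[float]]:
    """One numeric cell -> (value, half_range); malformed -> (None, None)."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, None
    text = str(raw).strip()
    if text.lower() in dialect.missing_tokens:
        return None, None
    if dialect.decimal != ".":
        text = text.replace(dialect.decimal, ".")
    m = dialect.uncertainty_pattern.match(text)
    if m:
        return float(m.group(1)), float(m.group(2))
    try:
        return float(text), None
    except ValueError:
        logger.warning("malformed numeric cell %r at %s; treated as absent", raw, where)
        return None, None


def _read_raw(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=dialect.resolve_delimiter(path), dtype=str,
                        skipinitialspace=True)
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def read_descriptor_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    unit: Optional[str] = None,
    default_medium: Optional[str] = None,
    fill_ip: bool = True,
) -> list[DescriptorSet]:
    """Parse a descriptor table into provenance-tagged rows.

    The unit may be declared per row (``unit`` column) or once for the whole
    table via the *unit* argument — exactly one of the two must apply per
    energy row.  With *fill_ip* (the default) a molecule's single reported
    adiabatic ionization value is fanned out to all of its site rows, since
    it is a property of the parent molecule, not of the donation site.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    try:
        frame = _read_raw(path, dialect)
    except pd.errors.EmptyDataError:
        logger.warning("empty descriptor table %s", path)
        return []
    lower = {c.lower(): c for c in frame.columns}
    if "molecule_id" not in {_ID_COLUMNS.get(c) for c in lower}:
        raise ValueError(f"{path}: missing mandatory column molecule_id")
    if not any(c in _DESCRIPTOR_COLUMNS for c in lower):
        raise ValueError(
            f"{path}: no descriptor column found; expected one of "
            + ", ".join(sorted(set(_DESCRIPTOR_COLUMNS)))
        )

    rows: list[DescriptorSet] = []
    for idx, record in frame.iterrows():
        where = f"{path.name}:{idx + 2}"  # 1-based with header line

        def cell(name: str) -> Optional[str]:
            col = lower.get(name)
            if col is None:
                return None
            value = record[col]
            return None if pd.isna(value) else str(value).strip()

        row_unit = cell("unit") or unit
        if row_unit is None:
            logger.warning("%s: no unit declared for row; row skipped", where)
            continue
        molecule = cell("molecule_id") or cell("molecule")
        if not molecule:
            logger.warning("%s: blank molecule_id; row skipped", where)
            continue

        d = DescriptorSet(
            molecule_id=molecule,
            site_id=cell("site_id") or cell("site") or cell("position") or "",
            medium=cell("medium") or default_medium or "gas",
            unit=canonical_unit(row_unit),
            provenance=where,
        )
        functional, basis = cell("functional"), cell("basis") or cell("basis_set")
        if functional and basis:
            d.method = MethodKey(functional, basis)
        for name, attr in _DESCRIPTOR_COLUMNS.items():
            if name not in lower:
                continue
            value, half = _parse_cell(record[lower[name]], dialect, where)
            if value is not None and getattr(d, attr) is None:
                setattr(d, attr, value)
                if half is not None:
                    d.uncertainty[attr.upper()] = half
        rows.append(combined(d))

    if fill_ip:
        _fan_out_ip(rows)
    return rows


def _fan_out_ip(rows: list[DescriptorSet]) -> None:
    """Propagate a molecule's single IP value to its other site rows in place."""
    by_molecule: dict[tuple[str, str], list[DescriptorSet]] = {}
    for d in rows:
        by_molecule.setdefault((d.molecule_id, d.medium), []).append(d)
    for group in by_molecule.values():
        ips = {d.ip for d in group if d.ip is not None}
        if len(ips) != 1:
            continue
        (ip,) = ips
        for d in group:
            if d.ip is None:
                d.ip = ip
                updated = combined(d)
                d.setpt, d.splet = updated.setpt, updated.splet
                d.setpt_computed = updated.setpt_computed
                d.splet_computed = updated.splet_computed


def read_species_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    medium: str = "gas",
    method: MethodKey | None = None,
) -> list[SpeciesEnthalpies]:
    """Parse a long-format species-enthalpy table.

    Expected columns: molecule_id, site_id, species_role (one of
    AXH / AX_radical / AX_anion / AXH_cation), energy, unit.  The parent
    and cation rows may leave site_id blank; they then apply to every site
    of the molecule.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    frame = _read_raw(path, dialect)
    lower = {c.lower(): c for c in frame.columns}
    required = ("molecule_id", "species_role", "energy", "unit")
    missing = [c for c in required if c not in lower]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {', '.join(missing)}")

    # site-level species keyed per site; molecule-level species fanned out
    per_site: dict[tuple[str, str], dict[str, EnergyValue]] = {}
    per_molecule: dict[str, dict[str, EnergyValue]] = {}
    for idx, record in frame.iterrows():
        where = f"{path.name}:{idx + 2}"
        role = str(record[lower["species_role"]]).strip()
        if role not in _SPECIES_ROLES:
            logger.warning("%s: unknown species_role %r; row skipped", where, role)
            continue
        value, _ = _parse_cell(record[lower["energy"]], dialect, where)
        if value is None:
            continue
        energy = EnergyValue(value, str(record[lower["unit"]]).strip())
        molecule = str(record[lower["molecule_id"]]).strip()
        site_raw = record[lower["site_id"]] if "site_id" in lower else ""
        site = "" if pd.isna(site_raw) else str(site_raw).strip()
        if site:
            per_site.setdefault((molecule, site), {})[role] = energy
        else:
            per_molecule.setdefault(molecule, {})[role] = energy

    out = []
    keys = list(per_site) or [(m, "") for m in per_molecule]
    for molecule, site in keys:
        merged = dict(per_molecule.get(molecule, {}))
        merged.update(per_site.get((molecule, site), {}))
        out.append(SpeciesEnthalpies(
            molecule_id=molecule,
            site_id=site,
            H_AXH=merged.get("AXH"),
            H_AXrad=merged.get("AX_radical"),
            H_AXanion=merged.get("AX_anion"),
            H_AXHcation=merged.get("AXH_cation"),
            medium=medium,
            method=method,
            provenance=str(path),
        ))
    return out


def write_descriptor_table(rows: Sequence[DescriptorSet], path: str | Path) -> None:
    """Write rows back to CSV; absent cells stay blank."""
    records = []
    for d in rows:
        records.append({
            "molecule_id": d.molecule_id,
            "site_id": d.site_id,
            "medium": d.medium,
            "unit": d.unit,
            "functional": d.method.functional if d.method else "",
            "basis": d.method.basis if d.method else "",
            "BDE": d.bde, "IP": d.ip, "PDE": d.pde, "PA": d.pa, "ETE": d.ete,
            "SETPT": d.setpt, "SPLET": d.splet, "IPH": d.iph_base,
        })
    frame = pd.DataFrame.from_records(records)
    frame.to_csv(path, index=False, float_format="%.6f")


def write_species_table(species: Sequence[SpeciesEnthalpies], path: str | Path) -> None:
    records = []
    for s in species:
        for role, value in (
            ("AXH", s.H_AXH), ("AX_radical", s.H_AXrad),
            ("AX_anion", s.H_AXanion), ("AXH_cation", s.H_AXHcation),
        ):
            if value is None:
                continue
            records.append({
                "molecule_id": s.molecule_id, "site_id": s.site_id,
                "species_role": role, "energy": repr(value.magnitude),
                "unit": value.unit,
            })
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_report(report: AuditReport, fmt: str = "text", stream: TextIO | None = None) -> str:
    """Render an audit report as human-readable text or schema-stable JSON."""
    if fmt == "json":
        text = json.dumps(report.to_dict(), indent=2)
    elif fmt == "text":
        buf = io.StringIO()
        row_level = [f for f in report.findings if not f.row.startswith("dataset(")]
        dataset_level = [f for f in report.findings if f.row.startswith("dataset(")]
        for f in row_level:
            _format_finding(buf, f)
        if dataset_level:
            buf.write("-- dataset-level --\n")
            for f in dataset_level:
                _format_finding(buf, f)
        n_fail = len(report.failures())
        buf.write(f"{len(report.findings)} checks, {n_fail} failed\n")
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if stream is not None:
        stream.write(text)
    return text


def _format_finding(buf: TextIO, f) -> None:
    residual = "" if f.residual is None else f" residual={f.residual:+.4g} {f.unit}"
    tol = "" if f.tolerance is None else f" tol={f.tolerance:.4g}"
    diag = "" if f.diagnosis == "none" else f" [{f.diagnosis}]"
    detail = f" ({f.detail})" if f.detail else ""
    buf.write(f"{f.row:<28} {f.check:<18} {f.verdict:<13}{residual}{tol}{diag}{detail}\n")


def read_report_json(source: str | Path | TextIO) -> AuditReport:
    """Inverse of ``write_report(..., fmt="json")``."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(text) as fh:
                payload = json.load(fh)
    return AuditReport.from_dict(payload)


def fixture_path(name: str):
    """Path-like resource for a packaged fixture table."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    return resources.files("radaudit.data").joinpath(f"fixtures/{name}.csv")


def load_fixture(name: str, **kwargs) -> list[DescriptorSet]:
    """Parse a packaged fixture table into descriptor rows."""
    with resources.as_file(fixture_path(name)) as path:
        return read_descriptor_table(path, **kwargs)
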