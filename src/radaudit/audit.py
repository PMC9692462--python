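"""Theorem checks, rounding-aware tolerances and diagnostics for reported tables.

Checks applied to a reported descriptor table:

* ``T1``                  - the two two-step sums must be equal per row.
* ``T2_site_invariance``  - the two-step sum minus BDE must be one constant
                            across all rows sharing a medium (reference-free).
* ``T2_reference``        - that constant must sit near the catalog (or
                            overridden) H-atom ionization enthalpy for the
                            declared medium (loose proximity tolerance, since
                            ~2 kJ/mol protocol offsets are legitimate).
* ``C1a``-``C1d``         - the four ordering biconditionals.
* ``positivity``          - the two-step sum must exceed BDE.
* ``transcription``       - reported combined sums vs their own components.

Printed-precision tolerances scale with the number of independently rounded
terms entering a residual: k terms at d printed decimals give k * 0.5e-d.
Failures carry a diagnosis tag: a residual that collapses under a 4.184
rescale of one side suggests a kcal/kJ mix-up; a two-step-minus-BDE value
closer to a different medium's reference suggests a mislabeled medium;
anything else is flagged as gross inconsistency.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .descriptors import DescriptorSet, corollary_orderings
from .media import Catalog, MethodKey
from .units import KCAL_IN_KJ, as_kj_per_mol, from_kj_per_mol

__all__ = [
    "AuditConfig",
    "AuditFinding",
    "AuditReport",
    "MediumInference",
    "theorem1_check",
    "theorem2_site_invariance",
    "theorem2_reference_check",
    "infer_medium",
    "audit_table",
    "convert_row_units",
]


@dataclass
class AuditConfig:
    """Tolerances and reference data steering an audit run."""

    printed_decimals: int = 1
    tolerance_mode: str = "printed_precision"  # or "absolute"
    absolute_tol_kj: float = 0.1
    iph_proximity_tol_kj: float = 5.0
    #: per-dataset reference override, in the table's unit
    iph_override: Optional[float] = None
    #: explicit candidate references as (medium name, IP_H in kJ/mol);
    #: when None they are derived from the catalog for the row's method
    candidate_media: Optional[tuple[tuple[str, float], ...]] = None
    catalog: Optional[Catalog] = None
    #: fallback level of theory when rows carry none
    method: Optional[MethodKey] = None

    def __post_init__(self) -> None:
        if self.tolerance_mode not in ("printed_precision", "absolute"):
            raise ValueError(f"unknown tolerance mode {self.tolerance_mode!r}")
        if self.absolute_tol_kj < 0 or self.iph_proximity_tol_kj < 0:
            raise ValueError("tolerances must be >= 0")
        if self.printed_decimals < 0:
            raise ValueError("printed_decimals must be >= 0")

    def tolerance(self, n_rounded_terms: int, unit: str) -> float:
        """Tolerance (in *unit*) for a residual built from k rounded terms."""
        if self.tolerance_mode == "absolute":
            return from_kj_per_mol(self.absolute_tol_kj, unit)
        return n_rounded_terms * 0.5 * 10.0 ** (-self.printed_decimals)

    def proximity_tolerance(self, unit: str) -> float:
        return from_kj_per_mol(self.iph_proximity_tol_kj, unit)


@dataclass(frozen=True)
class AuditFinding:
    """One check verdict: residual, tolerance, and (on failure) a diagnosis."""

    row: str
    check: str
    residual: Optional[float]
    unit: str
    tolerance: Optional[float]
    verdict: str  # pass | fail | indeterminate
    diagnosis: str = "none"
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "check": self.check,
            "residual": self.residual,
            "unit": self.unit,
            "tolerance": self.tolerance,
            "verdict": self.verdict,
            "diagnosis": self.diagnosis,
            "detail": self.detail,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AuditFinding":
        return cls(**payload)


@dataclass
class AuditReport:
    """Structured outcome of an audit: one finding per executed check."""

    findings: list[AuditFinding] = field(default_factory=list)
    unit: str = "kJ/mol"

    def by_check(self, check: str) -> list[AuditFinding]:
        return [f for f in self.findings if f.check == check]

    def failures(self) -> list[AuditFinding]:
        return [f for f in self.findings if f.verdict == "fail"]

    def to_dict(self) -> dict:
        return {"unit": self.unit, "findings": [f.to_dict() for f in self.findings]}

    @classmethod
    def from_dict(cls, payload: dict) -> "AuditReport":
        return cls(
            findings=[AuditFinding.from_dict(f) for f in payload["findings"]],
            unit=payload["unit"],
        )


@dataclass(frozen=True)
class MediumInference:
    """Ranked medium candidates for an observed two-step-minus-BDE value."""

    ranked: tuple[tuple[str, float], ...]  # (medium, |deviation| in kJ/mol)
    asserted: bool

    @property
    def best(self) -> str:
        return self.ranked[0][0]


# -- helpers -----------------------------------------------------------


def convert_row_units(d: DescriptorSet, unit: str) -> DescriptorSet:
    """Express every energy cell of a descriptor row in *unit*."""
    def conv(v: Optional[float]) -> Optional[float]:
        return None if v is None else from_kj_per_mol(as_kj_per_mol(v, d.unit), unit)

    out = replace(
        d,
        unit=unit,
        bde=conv(d.bde), ip=conv(d.ip), pde=conv(d.pde), pa=conv(d.pa), ete=conv(d.ete),
        setpt=conv(d.setpt), splet=conv(d.splet), iph_base=conv(d.iph_base),
        setpt_computed=conv(d.setpt_computed), splet_computed=conv(d.splet_computed),
    )
    out.uncertainty = {k: conv(v) for k, v in d.uncertainty.items()}
    out.missing = dict(d.missing)
    return out


def _row_ref(d: DescriptorSet) -> str:
    return d.provenance or d.label


def _setpt_side(d: DescriptorSet) -> tuple[Optional[float], int]:
    """Two-step sum via the electron-first route, preferring components."""
    if d.ip is not None and d.pde is not None:
        return d.ip + d.pde, 2
    if d.setpt is not None:
        return d.setpt, 1
    return None, 0


def _splet_side(d: DescriptorSet) -> tuple[Optional[float], int]:
    if d.pa is not None and d.ete is not None:
        return d.pa + d.ete, 2
    if d.splet is not None:
        return d.splet, 1
    return None, 0


def _base(d: DescriptorSet) -> tuple[Optional[float], int]:
    """Two-step sum minus BDE, preferring the reported base column."""
    if d.iph_base is not None:
        return d.iph_base, 1
    total, k = _setpt_side(d)
    if total is None:
        total, k = _splet_side(d)
    if total is None or d.bde is None:
        return None, 0
    return total - d.bde, k + 1


def _rescale_collapses(lhs: float, rhs: float, tol: float) -> bool:
    """True if a thermochemical-calorie rescale of one side explains the gap."""
    alternates = (lhs / KCAL_IN_KJ - rhs, lhs * KCAL_IN_KJ - rhs,
                  lhs - rhs / KCAL_IN_KJ, lhs - rhs * KCAL_IN_KJ)
    return min(abs(a) for a in alternates) <= tol


# -- row-level checks --------------------------------------------------


def theorem1_check(d: DescriptorSet, cfg: AuditConfig) -> AuditFinding:
    """Equality of the two two-step sums for one row (inclusive tolerance).

    The residual is evaluated from step components when all four are present
    (the primary data), falling back to the reported combined sums.  When the
    component route fails but the reported sums agree within their own
    tolerance, the row passes on the sums route: the internal component/sum
    disagreement is a transcription issue and is flagged separately by
    :func:`transcription_checks`.
    """
    routes: list[tuple[float, float, str]] = []  # (residual, tol, route label)
    if all(v is not None for v in (d.ip, d.pde, d.pa, d.ete)):
        routes.append(((d.ip + d.pde) - (d.pa + d.ete),
                       cfg.tolerance(4, d.unit), "components"))
    if d.setpt is not None and d.splet is not None and (
        d.setpt != d.setpt_computed or d.splet != d.splet_computed or not routes
    ):
        routes.append((d.setpt - d.splet, cfg.tolerance(2, d.unit), "reported sums"))
    if not routes:
        lhs, _ = _setpt_side(d)
        absent = "electron-first sum" if lhs is None else "proton-first sum"
        return AuditFinding(_row_ref(d), "T1", None, d.unit, None,
                            "indeterminate", detail=f"{absent} unavailable")
    residual, tol, route = routes[0]
    if abs(residual) > tol:
        for alt_residual, alt_tol, alt_route in routes[1:]:
            if abs(alt_residual) <= alt_tol:
                return AuditFinding(
                    _row_ref(d), "T1", alt_residual, d.unit, alt_tol, "pass",
                    detail=f"via {alt_route}; {route} route disagrees "
                           f"(residual {residual:+.4g}, see transcription check)",
                )
    if abs(residual) <= tol:
        detail = f"via {route}" if route != "components" else ""
        return AuditFinding(_row_ref(d), "T1", residual, d.unit, tol, "pass",
                            detail=detail)
    lhs, _ = _setpt_side(d)
    rhs, _ = _splet_side(d)
    diagnosis = (
        "unit_mixup_suspected"
        if _rescale_collapses(lhs, rhs, tol * KCAL_IN_KJ)
        else "gross_inconsistency"
    )
    return AuditFinding(_row_ref(d), "T1", residual, d.unit, tol, "fail", diagnosis)


def transcription_checks(d: DescriptorSet, cfg: AuditConfig) -> list[AuditFinding]:
    """Cross-check reported combined sums against their own components."""
    findings = []
    for name, reported, computed in (
        ("SETPT", d.setpt, d.setpt_computed),
        ("SPLET", d.splet, d.splet_computed),
    ):
        if reported is None or computed is None or reported == computed:
            continue
        tol = cfg.tolerance(3, d.unit)
        residual = reported - computed
        verdict = "pass" if abs(residual) <= tol else "fail"
        findings.append(AuditFinding(
            _row_ref(d), "transcription", residual, d.unit, tol, verdict,
            "gross_inconsistency" if verdict == "fail" else "none",
            detail=f"reported {name} vs recomputed components",
        ))
    return findings


def positivity_check(d: DescriptorSet, cfg: AuditConfig) -> AuditFinding:
    """The two-step sum must exceed BDE (their difference is IP_H > 0)."""
    base, k = _base(d)
    if base is None:
        return AuditFinding(_row_ref(d), "positivity", None, d.unit, None,
                            "indeterminate", detail="two-step sum or BDE unavailable")
    tol = cfg.tolerance(k, d.unit)
    verdict = "pass" if base > -tol else "fail"
    return AuditFinding(_row_ref(d), "positivity", base, d.unit, tol, verdict,
                        "gross_inconsistency" if verdict == "fail" else "none")


def corollary_checks(d: DescriptorSet, cfg: AuditConfig) -> list[AuditFinding]:
    """The four ordering biconditionals, with printed-precision tie handling."""
    try:
        verdicts = corollary_orderings(d, tie_tol=cfg.tolerance(2, d.unit))
    except ValueError as exc:
        return [AuditFinding(_row_ref(d), c, None, d.unit, None, "indeterminate",
                             detail=str(exc)) for c in ("C1a", "C1b", "C1c", "C1d")]
    out = []
    for check, verdict in verdicts.items():
        out.append(AuditFinding(
            _row_ref(d), check, None, d.unit, cfg.tolerance(2, d.unit),
            "fail" if verdict == "violated" else "pass",
            "gross_inconsistency" if verdict == "violated" else "none",
            detail=verdict,
        ))
    return out


# -- reference resolution ----------------------------------------------


def _candidates_kj(cfg: AuditConfig, method: Optional[MethodKey]) -> list[tuple[str, float]]:
    if cfg.candidate_media is not None:
        return [(name, float(v)) for name, v in cfg.candidate_media]
    if cfg.catalog is None:
        return []
    method = method or cfg.method
    if method is None:
        return []
    return [
        (medium.name, cfg.catalog.iph(method, medium).kj)
        for medium in cfg.catalog.media()
    ]


def infer_medium(
    base_kj: float,
    cfg: AuditConfig,
    method: Optional[MethodKey] = None,
) -> MediumInference:
    """Rank candidate media by how close their IP_H sits to *base_kj*.

    The top match is asserted only when its deviation is below half the
    smallest gap separating any two candidate references; otherwise the
    ranking is advisory.
    """
    candidates = _candidates_kj(cfg, method)
    if not candidates:
        raise ValueError("no candidate media: provide candidate_media or catalog+method")
    ranked = sorted(((name, abs(base_kj - v)) for name, v in candidates), key=lambda t: t[1])
    values = sorted(v for _, v in candidates)
    gaps = [b - a for a, b in zip(values, values[1:])]
    asserted = bool(gaps) and ranked[0][1] < min(gaps) / 2.0
    return MediumInference(tuple(ranked), asserted)


def theorem2_reference_check(d: DescriptorSet, cfg: AuditConfig) -> AuditFinding:
    """Two-step sum minus BDE against the reference IP_H for the declared medium."""
    base, _k = _base(d)
    if base is None:
        return AuditFinding(_row_ref(d), "T2_reference", None, d.unit, None,
                            "indeterminate", detail="two-step sum or BDE unavailable")
    if cfg.iph_override is not None:
        ref = cfg.iph_override
        ref_label = "override"
    else:
        candidates = {name: v for name, v in _candidates_kj(cfg, d.method)}
        if d.medium not in candidates:
            return AuditFinding(
                _row_ref(d), "T2_reference", None, d.unit, None, "indeterminate",
                detail=f"no IP_H reference resolvable for medium {d.medium!r}",
            )
        ref = from_kj_per_mol(candidates[d.medium], d.unit)
        ref_label = f"catalog[{d.medium}]"
    tol = cfg.proximity_tolerance(d.unit)
    residual = base - ref
    if abs(residual) <= tol:
        return AuditFinding(_row_ref(d), "T2_reference", residual, d.unit, tol,
                            "pass", detail=f"reference {ref_label}")
    diagnosis = "gross_inconsistency"
    if _rescale_collapses(base, ref, tol * KCAL_IN_KJ):
        diagnosis = "unit_mixup_suspected"
    else:
        try:
            inference = infer_medium(as_kj_per_mol(base, d.unit), cfg, d.method)
        except ValueError:
            inference = None
        if inference is not None and inference.best != d.medium:
            diagnosis = "medium_mismatch_suspected"
    return AuditFinding(_row_ref(d), "T2_reference", residual, d.unit, tol,
                        "fail", diagnosis, detail=f"reference {ref_label}")


# -- dataset-level checks ----------------------------------------------


def theorem2_site_invariance(
    rows: Sequence[DescriptorSet],
    cfg: AuditConfig,
) -> AuditFinding:
    """Spread of the two-step-minus-BDE values across rows of one medium.

    This is the strict, reference-free half of the Hess's-law constraint:
    whatever the reference value, all rows must agree on it.
    """
    if not rows:
        raise ValueError("site-invariance check needs at least one row")
    unit = rows[0].unit
    label = f"dataset(medium={rows[0].medium})"
    bases, ks = [], []
    for d in rows:
        base, k = _base(d)
        if base is not None:
            bases.append(base)
            ks.append(k)
    if not bases:
        return AuditFinding(label, "T2_site_invariance", None, unit, None,
                            "indeterminate", detail="no row has two-step sum and BDE")
    center = statistics.median(bases)
    spread = max(abs(b - center) for b in bases)
    tol = cfg.tolerance(2 * max(ks), unit)
    verdict = "pass" if spread <= tol else "fail"
    return AuditFinding(
        label, "T2_site_invariance", spread, unit, tol, verdict,
        "gross_inconsistency" if verdict == "fail" else "none",
        detail=f"median base {center:.4g} over {len(bases)} rows",
    )


def audit_table(rows: Sequence[DescriptorSet], cfg: AuditConfig) -> AuditReport:
    """Run every applicable check over a parsed descriptor table.

    Rows are audited individually (T1, orderings, positivity, reference
    proximity, transcription); rows sharing a declared medium are then pooled
    for site invariance and, when the reference checks fail, for medium
    inference.  Unreadable rows surface as indeterminate findings, never as
    fatal errors.
    """
    rows = [r if r.unit == rows[0].unit else convert_row_units(r, rows[0].unit)
            for r in rows] if rows else []
    report = AuditReport(unit=rows[0].unit if rows else "kJ/mol")

    for d in rows:
        report.findings.append(theorem1_check(d, cfg))
        report.findings.extend(transcription_checks(d, cfg))
        report.findings.append(positivity_check(d, cfg))
        if all(v is not None for v in (d.ip, d.pde, d.pa, d.ete)):
            report.findings.extend(corollary_checks(d, cfg))
        report.findings.append(theorem2_reference_check(d, cfg))

    # site invariance holds per environment *and* protocol: rows computed
    # with different basis sets legitimately carry slightly different bases
    media_groups: dict[tuple, list[DescriptorSet]] = {}
    for d in rows:
        media_groups.setdefault((d.medium, d.method), []).append(d)
    for (medium, _method), group in media_groups.items():
        report.findings.append(theorem2_site_invariance(group, cfg))
        # dataset-level medium diagnosis when the declared reference misfits
        group_refs = [
            f for f in report.findings
            if f.check == "T2_reference" and f.verdict == "fail"
            and any(_row_ref(d) == f.row for d in group)
        ]
        if not group_refs:
            continue
        bases = [b for b, _ in (_base(d) for d in group) if b is not None]
        if not bases:
            continue
        base_kj = as_kj_per_mol(statistics.median(bases), group[0].unit)
        try:
            inference = infer_medium(base_kj, cfg, group[0].method)
        except ValueError:
            continue
        if inference.best != medium:
            report.findings.append(AuditFinding(
                f"dataset(medium={medium})", "T2_reference",
                None, group[0].unit, None, "fail", "medium_mismatch_suspected",
                detail=(
                    f"median two-step-minus-BDE is nearest the {inference.best} "
                    f"reference (deviation {inference.ranked[0][1]:.1f} kJ/mol), "
                    f"not the declared {medium}"
                ),
            ))
    return report
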