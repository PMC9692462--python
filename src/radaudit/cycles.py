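"""Generalized Hess's-law identity discovery over a reaction system.

Each thermochemical quantity is a balanced reaction encoded as an integer
stoichiometric row vector over an ordered species list (products positive,
reactants negative).  Every linear identity that correctly computed values
must satisfy is a left-null vector of that matrix; the basis of that space
is found in exact rational arithmetic, so identities are identities, not
approximations.  For the canonical descriptor system the basis has
dimension two: the equality of the two two-step sums, and the two-step sum
minus BDE minus IP_H.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Mapping, Optional, Sequence

import sympy
import yaml

__all__ = [
    "ReactionSystem",
    "IdentityBasis",
    "IdentityCheck",
    "identity_basis",
    "verify_against_identities",
    "canonical_system",
    "system_from_config",
    "CANONICAL_SPECIES",
    "CANONICAL_QUANTITIES",
]

CANONICAL_SPECIES = ("AXH", "AX_radical", "AX_anion", "AXH_cation", "H_atom", "H_plus", "e_minus")
CANONICAL_QUANTITIES = ("BDE", "IP", "PDE", "PA", "ETE", "IPH")

_CANONICAL_REACTIONS: dict[str, dict[str, int]] = {
    "BDE": {"AXH": -1, "AX_radical": 1, "H_atom": 1},
    "IP": {"AXH": -1, "AXH_cation": 1, "e_minus": 1},
    "PDE": {"AXH_cation": -1, "AX_radical": 1, "H_plus": 1},
    "PA": {"AXH": -1, "AX_anion": 1, "H_plus": 1},
    "ETE": {"AX_anion": -1, "AX_radical": 1, "e_minus": 1},
    "IPH": {"H_atom": -1, "H_plus": 1, "e_minus": 1},
}


@dataclass(frozen=True)
class ReactionSystem:
    """Quantities as balanced integer reactions over an ordered species list."""

    species: tuple[str, ...]
    quantities: tuple[str, ...]
    matrix: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.quantities or not self.species:
            raise ValueError("reaction system must have at least one quantity and one species")
        if len(self.matrix) != len(self.quantities):
            raise ValueError("one matrix row is required per quantity")
        for name, row in zip(self.quantities, self.matrix):
            if len(row) != len(self.species):
                raise ValueError(f"row for {name!r} has wrong length")
            if all(c == 0 for c in row):
                raise ValueError(f"quantity {name!r} is not a reaction (all-zero row)")

    @classmethod
    def from_reactions(
        cls,
        species: Sequence[str],
        reactions: Mapping[str, Mapping[str, int]],
    ) -> "ReactionSystem":
        """Build from ``{quantity: {species: signed coefficient}}`` maps."""
        species = tuple(species)
        index = {s: i for i, s in enumerate(species)}
        rows = []
        for name, rxn in reactions.items():
            row = [0] * len(species)
            for sp, coeff in rxn.items():
                if sp not in index:
                    raise ValueError(f"reaction {name!r} uses unknown species {sp!r}")
                row[index[sp]] = int(coeff)
            rows.append(tuple(row))
        return cls(species, tuple(reactions), tuple(rows))


@dataclass(frozen=True)
class IdentityBasis:
    """Basis of the linear identities a reaction system enforces.

    Each vector is a primitive integer coefficient vector over the system's
    quantities with positive leading coefficient; ``sum(c_i * value_i) = 0``
    for any consistently computed value set.
    """

    quantities: tuple[str, ...]
    vectors: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.vectors)

    def describe(self) -> list[str]:
        """Human-readable identity equations, e.g. ``+IP +PDE -PA -ETE = 0``."""
        lines = []
        for vec in self.vectors:
            terms = []
            for coeff, name in zip(vec, self.quantities):
                if coeff == 0:
                    continue
                mag = "" if abs(coeff) == 1 else f"{abs(coeff)}*"
                terms.append(f"{'+' if coeff > 0 else '-'}{mag}{name}")
            lines.append(" ".join(terms) + " = 0")
        return lines


@dataclass(frozen=True)
class IdentityCheck:
    """Residual of one identity against a concrete value set."""

    identity: str
    residual: Optional[float]
    tolerance: float
    verdict: str  # pass | fail | indeterminate
    missing: tuple[str, ...] = ()


def _normalize_vector(vec: Sequence[sympy.Rational]) -> tuple[int, ...]:
    denom_lcm = 1
    for c in vec:
        denom_lcm = sympy.ilcm(denom_lcm, sympy.Rational(c).q)
    ints = [int(sympy.Rational(c) * denom_lcm) for c in vec]
    g = 0
    for c in ints:
        g = gcd(g, abs(c))
    if g > 1:
        ints = [c // g for c in ints]
    leading = next((c for c in ints if c != 0), 0)
    if leading < 0:
        ints = [-c for c in ints]
    return tuple(ints)


def identity_basis(system: ReactionSystem) -> IdentityBasis:
    """Exact basis of the left-dependency space of the stoichiometric matrix.

    Computed with rational arithmetic; dimension equals the number of
    quantities minus the rank of the matrix.  Vectors are normalized to
    primitive integer form, ordered by (lexicographic) support.
    """
    matrix = sympy.Matrix(system.matrix)
    raw = matrix.T.nullspace()
    vectors = [_normalize_vector(v) for v in raw]
    vectors.sort(key=lambda v: (tuple(i for i, c in enumerate(v) if c != 0), v))
    return IdentityBasis(system.quantities, tuple(vectors))


def verify_against_identities(
    values: Mapping[str, float],
    basis: IdentityBasis,
    tol: float,
) -> list[IdentityCheck]:
    """Evaluate each identity residual ``sum(c_i * value_i)`` against *tol*.

    Pass iff ``|residual| <= tol`` (inclusive).  Identities touching a
    quantity with no supplied value are reported indeterminate.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    checks = []
    for vec, label in zip(basis.vectors, basis.describe()):
        needed = [q for c, q in zip(vec, basis.quantities) if c != 0]
        missing = tuple(q for q in needed if values.get(q) is None)
        if missing:
            checks.append(IdentityCheck(label, None, tol, "indeterminate", missing))
            continue
        residual = sum(c * float(values[q]) for c, q in zip(vec, basis.quantities) if c != 0)
        verdict = "pass" if abs(residual) <= tol else "fail"
        checks.append(IdentityCheck(label, residual, tol, verdict))
    return checks


def canonical_system() -> ReactionSystem:
    """The shipped preset: five descriptors plus IP_H over seven species."""
    return ReactionSystem.from_reactions(CANONICAL_SPECIES, _CANONICAL_REACTIONS)


def system_from_config(source) -> ReactionSystem:
    """Load a reaction system from a YAML/JSON mapping or file path.

    Schema::

        species: [AXH, AX_radical, ...]
        reactions:
          BDE: {AXH: -1, AX_radical: 1, H_atom: 1}
          ...
    """
    if not isinstance(source, Mapping):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    return ReactionSystem.from_reactions(source["species"], source["reactions"])
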