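# radaudit

Consistency auditing for free-radical-scavenging thermochemistry tables.

The five reaction enthalpies used to characterize antioxidant mechanisms —
BDE (direct H-atom transfer), IP and PDE (electron transfer then proton
transfer), PA and ETE (proton loss then electron transfer) — are not
independent molecular properties. Because the two two-step routes share
reactants and products, and because of Hess's law, any correctly computed
descriptor set satisfies two exact identities:

1. `IP + PDE = PA + ETE` (route equality), and
2. `IP + PDE − BDE = PA + ETE − BDE = IP_H(medium) > 0`, where `IP_H` is the
   ionization enthalpy of the hydrogen atom in the same environment — a
   single positive constant for *all* molecules and H-donation sites in one
   medium and protocol.

`radaudit` computes the descriptors from species enthalpies, derives the
identities by exact linear algebra over the underlying reaction
stoichiometry, and audits published descriptor tables against them with
rounding-aware tolerances, diagnosing likely causes of violations
(kcal/kJ unit mix-ups, gas/solvent medium mislabels, gross inconsistency).
It deliberately never ranks mechanisms: route equality makes "which two-step
pathway is thermodynamically preferred" unanswerable from the antioxidant's
descriptors alone.

## What is in the box

| Module | Purpose |
| --- | --- |
| `radaudit.units` | Exact energy-unit conversion (hartree, kJ/mol, kcal/mol, eV), print-style rounding, shared constants |
| `radaudit.media` | Built-in catalog of H+/e−/H• reference enthalpies per medium and DFT method; `IP_H` in any medium |
| `radaudit.descriptors` | BDE/IP/PDE/PA/ETE (+ combined sums) from species enthalpies; ordering corollaries |
| `radaudit.cycles` | Generic Hess's-law identity discovery: exact left-nullspace of a stoichiometric matrix |
| `radaudit.audit` | Theorem checks, tolerances, diagnostics, structured findings |
| `radaudit.tableio` | CSV/TSV descriptor & species tables, `a±b` cells, text/JSON reports, packaged fixtures |
| `radaudit.simulate` | Seeded consistent-by-construction synthetic tables with labeled fault injection |
| `radaudit.cli` | `radaudit convert / iph / descriptors / identities / audit / simulate` |

Reference data (catalog and the packaged descriptor-table fixtures) ship
inside the package under `radaudit/data/`; every catalog entry carries a
provenance string and can be overridden from a user YAML file.

## CLI examples

```sh
# H-atom ionization enthalpy in water at a given level of theory
radaudit iph -f B3LYP -b "6-311++G(d,p)" -m water --decimals 1
# -> 164.9 kJ/mol

# exact unit conversion
radaudit convert 1321.8 kJ/mol kcal/mol --decimals 1

# the two identities of the canonical descriptor system
radaudit identities --preset canonical

# audit a reported table (exit code 1 when any check fails)
radaudit audit --table mytable.csv -f M062x -b "6-311++G(d,p)" --json report.json

# descriptors from a species-enthalpy table
radaudit descriptors --species species.csv -m water -f B3LYP -b "6-311++G(d,p)"

# synthetic fixture with an injected route-equality violation
radaudit simulate --n 5 --sites 3 --violation t1_offset --magnitude 5 --seed 42 --out sim/
```

Descriptor tables are CSV/TSV with columns
`molecule_id, site_id, medium, unit, functional, basis, BDE, IP, PDE, PA,
ETE, SETPT, SPLET, IPH` (blank = absent; `a±b` cells are parsed as
mean ± half-range; `IP` may be given once per molecule and is fanned out to
its site rows). Species tables are long-format:
`molecule_id, site_id, species_role ∈ {AXH, AX_radical, AX_anion,
AXH_cation}, energy, unit`.

## Notes on the shipped reference data

The packaged printed-value table (`printed_iph.csv`) carries an `erratum`
column: six PBE0 rows duplicate another functional's values in the original
print, and five isolated cells are internally chain-rounded (their three
unit columns are mutually inconsistent by one unit of the last printed
digit). Tests assert both facts rather than hiding them.
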