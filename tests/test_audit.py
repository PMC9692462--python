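from dataclasses import replace

import numpy as np
import pytest

from radaudit.audit import (
    AuditConfig,
    audit_table,
    convert_row_units,
    infer_medium,
    theorem1_check,
    theorem2_reference_check,
    theorem2_site_invariance,
)
from radaudit.descriptors import DescriptorSet, combined
from radaudit.simulate import ViolationSpec, generate_consistent, inject
from radaudit.tableio import load_fixture
from radaudit.units import round_printed


def rounded_copy(d: DescriptorSet, decimals: int = 1) -> DescriptorSet:
    """A descriptor row as it would appear printed at *decimals*."""
    fields = {
        name: (None if getattr(d, name) is None
               else round_printed(getattr(d, name), decimals))
        for name in ("bde", "ip", "pde", "pa", "ete")
    }
    row = replace(d, **fields, setpt=None, splet=None,
                  setpt_computed=None, splet_computed=None)
    return combined(row)


@pytest.fixture()
def clean_rows(catalog, b3lyp_tz):
    _, rows = generate_consistent(4, 3, "water", b3lyp_tz, seed=3, catalog=catalog)
    return rows


class TestTheorem1:
    def test_vitamin_row_fails_with_printed_residual(self):
        row = load_fixture("vitamins_aqueous")[0]
        finding = theorem1_check(row, AuditConfig(printed_decimals=1))
        assert finding.verdict == "fail"
        assert finding.residual == pytest.approx(1210.0)

    def test_component_route_tolerance(self):
        d = combined(DescriptorSet("ATV", "1-OH", unit="kcal/mol", bde=91.4,
                                   ip=107.0, pde=22.4, pa=23.8, ete=105.7))
        finding = theorem1_check(d, AuditConfig(printed_decimals=1))
        assert finding.verdict == "pass"
        assert finding.residual == pytest.approx(-0.1)
        assert finding.tolerance == pytest.approx(0.2)

    def test_exact_synthetic_residual_zero(self, clean_rows):
        finding = theorem1_check(clean_rows[0], AuditConfig(printed_decimals=1))
        assert finding.verdict == "pass"
        assert finding.residual == pytest.approx(0.0, abs=1e-9)

    def test_indeterminate_when_side_missing(self):
        d = DescriptorSet("m", ip=1.0, pde=2.0)
        finding = theorem1_check(combined(d), AuditConfig())
        assert finding.verdict == "indeterminate"

    def test_inclusive_at_boundary(self):
        d = DescriptorSet("m", setpt=100.1, splet=100.0, unit="kJ/mol")
        finding = theorem1_check(d, AuditConfig(printed_decimals=1))
        assert finding.tolerance == pytest.approx(0.1)
        assert finding.verdict == "pass"

    def test_unit_mixup_diagnosis(self, clean_rows):
        bad, _ = inject(clean_rows, ViolationSpec("unit_mixup", target_rows=(0,)))
        finding = theorem1_check(bad[0], AuditConfig(printed_decimals=1))
        assert finding.verdict == "fail"
        assert finding.diagnosis == "unit_mixup_suspected"

    def test_sums_route_rescues_transcription_slip(self):
        # printed sums agree; one component cell is a transcription error
        d = DescriptorSet("m", unit="kcal/mol", bde=85.5, ip=106.2, pde=17.4,
                          pa=43.8, ete=79.0, setpt=123.6, splet=123.6)
        finding = theorem1_check(combined(d), AuditConfig(printed_decimals=1))
        assert finding.verdict == "pass"
        assert "transcription" in finding.detail


class TestSiteInvariance:
    def test_atv_table_zero_spread(self, catalog):
        rows = load_fixture("atorvastatin_methanol")
        finding = theorem2_site_invariance(rows, AuditConfig(printed_decimals=1))
        assert finding.verdict == "pass"
        assert finding.residual == pytest.approx(0.0, abs=1e-12)

    def test_vitamin_table_fails_with_large_spread(self):
        rows = load_fixture("vitamins_aqueous")
        finding = theorem2_site_invariance(rows, AuditConfig(printed_decimals=1))
        assert finding.verdict == "fail"
        bases = [r.iph_base for r in rows]
        assert max(bases) - min(bases) == pytest.approx(93.0)

    def test_single_row_trivially_passes(self, clean_rows):
        finding = theorem2_site_invariance(clean_rows[:1], AuditConfig())
        assert finding.verdict == "pass"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            theorem2_site_invariance([], AuditConfig())


class TestReferenceCheck:
    def test_gas_column_passes_at_proximity_tolerance(self, catalog):
        gas = load_fixture("peonidin")[0]
        cfg = AuditConfig(printed_decimals=2, catalog=catalog)
        finding = theorem2_reference_check(gas, cfg)
        assert finding.verdict == "pass"
        # default proximity 5 kJ/mol is about 1.2 kcal/mol
        assert finding.tolerance == pytest.approx(1.195, abs=0.001)

    def test_water_column_fails_far_from_reference(self, catalog):
        water = load_fixture("peonidin")[1]
        cfg = AuditConfig(printed_decimals=2, catalog=catalog)
        finding = theorem2_reference_check(water, cfg)
        assert finding.verdict == "fail"
        assert finding.residual > 270.0  # base ~314 vs reference ~38 kcal/mol

    def test_override_reference(self, catalog):
        rows = [r for r in load_fixture("vitamin_b3")
                if r.medium == "water" and "reported" not in r.molecule_id]
        cfg = AuditConfig(printed_decimals=1, iph_override=166.65)
        for row in rows:
            assert theorem2_reference_check(row, cfg).verdict == "pass"

    def test_synthetic_from_catalog_residual_small(self, clean_rows, catalog):
        cfg = AuditConfig(catalog=catalog)
        finding = theorem2_reference_check(clean_rows[0], cfg)
        assert finding.verdict == "pass"
        assert finding.residual == pytest.approx(0.0, abs=1e-9)

    def test_indeterminate_without_reference(self, clean_rows):
        finding = theorem2_reference_check(clean_rows[0], AuditConfig())
        assert finding.verdict == "indeterminate"


class TestInferMedium:
    TWO_CANDIDATES = (("water", 155.6), ("gas", 1312.6))

    def test_vitamin_base_points_to_gas(self):
        cfg = AuditConfig(candidate_media=self.TWO_CANDIDATES)
        inference = infer_medium(1309.0, cfg)
        assert inference.best == "gas"
        assert inference.asserted

    def test_exact_value_zero_deviation(self):
        cfg = AuditConfig(candidate_media=self.TWO_CANDIDATES)
        inference = infer_medium(155.6, cfg)
        assert inference.best == "water"
        assert inference.ranked[0][1] == 0.0

    def test_seeded_recovery_within_half_gap(self, catalog, b3lyp_tz):
        cfg = AuditConfig(candidate_media=self.TWO_CANDIDATES)
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            truth, value = ("water", 155.6) if rng.random() < 0.5 else ("gas", 1312.6)
            inference = infer_medium(value + rng.uniform(-1, 1), cfg)
            hits += inference.best == truth and inference.asserted
        assert hits == 100

    def test_full_catalog_recovery_below_minimum_gap(self, catalog, b3lyp_tz):
        cfg = AuditConfig(catalog=catalog)
        references = {m.name: catalog.iph(b3lyp_tz, m).kj for m in catalog.media()}
        values = sorted(references.values())
        half_gap = min(b - a for a, b in zip(values, values[1:])) / 2
        rng = np.random.default_rng(6)
        for _ in range(100):
            name = rng.choice(list(references))
            noise = rng.uniform(-0.99, 0.99) * half_gap
            inference = infer_medium(references[name] + noise, cfg, b3lyp_tz)
            assert inference.best == name

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            infer_medium(100.0, AuditConfig())


class TestAuditTable:
    def test_vitamin_table_full_audit(self, catalog):
        rows = load_fixture("vitamins_aqueous")
        m05, m06 = "M052x/6-311++G(d,p)", "M062x/6-311++G(d,p)"
        candidates = tuple(
            (name, (catalog.iph(m05, name).kj + catalog.iph(m06, name).kj) / 2)
            for name in ("gas", "water")
        )
        report = audit_table(rows, AuditConfig(printed_decimals=1,
                                               candidate_media=candidates))
        t1 = report.by_check("T1")
        assert [f.verdict for f in t1] == ["fail"] * 5
        invariance = report.by_check("T2_site_invariance")
        assert len(invariance) == 1 and invariance[0].verdict == "fail"
        dataset = [f for f in report.findings if f.row.startswith("dataset(")
                   and f.diagnosis == "medium_mismatch_suspected"]
        assert dataset and "gas" in dataset[0].detail

    def test_b3_rows_pass_with_override(self, catalog):
        rows = [r for r in load_fixture("vitamin_b3")
                if r.medium == "water" and "reported" not in r.molecule_id]
        cfg = AuditConfig(printed_decimals=1, iph_override=166.65, catalog=catalog)
        report = audit_table(rows, cfg)
        assert report.failures() == []

    def test_clean_fixture_zero_failures(self, catalog, b3lyp_tz):
        _, rows = generate_consistent(5, 3, "water", b3lyp_tz, seed=42,
                                      catalog=catalog)
        report = audit_table(rows, AuditConfig(catalog=catalog))
        assert report.failures() == []

    @pytest.mark.parametrize("seed", range(5))
    def test_no_false_positives_after_rounding(self, catalog, b3lyp_tz, seed):
        _, rows = generate_consistent(4, 3, "methanol", b3lyp_tz, seed=seed,
                                      catalog=catalog)
        printed = [rounded_copy(d, 1) for d in rows]
        report = audit_table(printed, AuditConfig(printed_decimals=1,
                                                  catalog=catalog))
        assert report.failures() == []

    def test_detection_power_bounds(self, catalog, b3lyp_tz):
        _, rows = generate_consistent(3, 2, "water", b3lyp_tz, seed=9,
                                      catalog=catalog)
        cfg = AuditConfig(printed_decimals=1, catalog=catalog)
        tol_kj = cfg.tolerance(4, "kJ/mol")  # component-route T1 tolerance
        big, _ = inject(rows, ViolationSpec("t1_offset", 2.0 * tol_kj, (1,)))
        fails = audit_table(big, cfg).failures()
        assert any(f.check == "T1" for f in fails)
        small, _ = inject(rows, ViolationSpec("t1_offset", 0.49 * tol_kj, (1,)))
        assert audit_table(small, cfg).failures() == []

    def test_verdicts_invariant_under_unit_conversion(self, catalog, b3lyp_tz):
        _, rows = generate_consistent(3, 2, "water", b3lyp_tz, seed=13,
                                      catalog=catalog)
        bad, _ = inject(rows, ViolationSpec("t1_offset", 5.0, (2,)))
        cfg = AuditConfig(tolerance_mode="absolute", absolute_tol_kj=0.5,
                          catalog=catalog)
        verdicts_kj = [(f.check, f.verdict) for f in audit_table(bad, cfg).findings]
        kcal = [convert_row_units(d, "kcal/mol") for d in bad]
        verdicts_kcal = [(f.check, f.verdict) for f in audit_table(kcal, cfg).findings]
        assert verdicts_kj == verdicts_kcal

    def test_positivity_flags_impossible_table(self):
        # combined two-step sum below BDE cannot be right in any medium
        d = combined(DescriptorSet("m", unit="kcal/mol", bde=400.0,
                                   ip=80.0, pde=60.0, pa=20.0, ete=120.0))
        report = audit_table([d], AuditConfig(printed_decimals=1))
        positivity = report.by_check("positivity")
        assert positivity[0].verdict == "fail"


class TestAuditConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            AuditConfig(tolerance_mode="vibes")
        with pytest.raises(ValueError):
            AuditConfig(absolute_tol_kj=-1.0)
        with pytest.raises(ValueError):
            AuditConfig(printed_decimals=-2)

    def test_printed_precision_tolerance_scaling(self):
        cfg = AuditConfig(printed_decimals=1)
        assert cfg.tolerance(4, "kJ/mol") == pytest.approx(0.2)
        assert AuditConfig(printed_decimals=2).tolerance(2, "kcal/mol") == pytest.approx(0.01)
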