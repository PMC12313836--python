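"""Costing operations: item/phase/drug/staff/facility costs, follow-up
mixtures, productivity loss, retreatment uplift, totals, comparison."""

from decimal import Decimal

import pytest
from hypothesis import given
from hypothesis import strategies as st

from abcost import (
    ComparisonError,
    ConfigurationError,
    CostItem,
    DatasetValidationError,
    DrugCategoryPolicy,
    DrugLine,
    FacilityParams,
    FollowUpCourse,
    IndirectCostParams,
    InterventionDataset,
    compare,
    drug_category_costs,
    drug_cost,
    facility_cost,
    followup_expected_cost,
    intervention_total,
    item_cost,
    phase_cost,
    productivity_loss,
    reconcile,
    retreatment_uplift,
    staff_cost,
    to_cents,
)

D = Decimal


class TestItemAndPhase:
    def test_flat_item_costs_its_unit_cost(self):
        assert item_cost(CostItem(label="levothyroxine", unit_cost="47.63")) == D("47.63")

    def test_zero_quantity_costs_nothing(self):
        assert item_cost(CostItem(label="x", quantity="0", unit_cost="100")) == 0

    def test_quantity_times_unit_cost(self):
        item = CostItem(label="stay", quantity="2.40", unit_cost="674.00")
        assert item_cost(item) == D("1617.60")

    def test_weighted_override_wins(self):
        item = CostItem(label="x", quantity="3", unit_cost="10",
                        weighted_cost_override="12.34")
        assert item_cost(item) == D("12.34")

    def test_prehospitalization_phase_sums_exactly(self, thyroidectomy):
        assert phase_cost(thyroidectomy.prehosp_items) == D("281.80")

    def test_materials_phase_sums_exactly(self, thyroidectomy):
        assert phase_cost(thyroidectomy.material_items) == D("199.54")

    def test_empty_phase_is_zero_and_override_wins(self):
        assert phase_cost([]) == 0
        assert phase_cost([], override=D("5")) == D("5")


class TestDrugAggregation:
    def test_mean_of_alternatives_categories(self, thyroidectomy):
        cats = drug_category_costs(thyroidectomy.drug_lines,
                                   thyroidectomy.drug_policies)
        assert to_cents(cats["opioids"]) == D("6.30")
        assert to_cents(cats["antibiotics"]) == D("2.70")
        assert cats["anesthetics"] == D("1.54")  # pinned category override

    def test_total_sums_unrounded_category_costs(self, thyroidectomy):
        # rounding the displayed category values first would give 11.50
        assert to_cents(drug_cost(thyroidectomy.drug_lines,
                                  thyroidectomy.drug_policies)) == D("11.49")

    def test_single_line_mean_is_that_line(self):
        lines = [DrugLine(category="antibiotics", drug="cefazolin", cost="3.24")]
        policies = [DrugCategoryPolicy(category="antibiotics",
                                       aggregation="mean_of_alternatives")]
        assert drug_cost(lines, policies) == D("3.24")

    def test_missing_policy_is_configuration_error(self):
        lines = [DrugLine(category="opioids", drug="fentanyl", cost="1")]
        with pytest.raises(ConfigurationError, match="no policy"):
            drug_cost(lines, [])


class TestStaffAndFacility:
    def test_staff_totals(self, thyroidectomy, ablation):
        assert staff_cost(ablation.staff_lines) == D("35.34")
        # the published staff-table total is a cent above the column sum
        assert abs(staff_cost(thyroidectomy.staff_lines) - D("232.47")) <= D("0.02")
        assert staff_cost([]) == 0

    def test_stay_cost_from_days_and_rate(self):
        params = FacilityParams(stay_days="2.00", stay_rate_per_day="674.00")
        assert facility_cost(params)[1] == D("1348.00")

    def test_or_cost_from_minutes_and_rate(self):
        params = FacilityParams(or_minutes="66.43", or_rate_per_minute="20.4272")
        or_cost, _ = facility_cost(params, mode="raw")
        assert to_cents(or_cost) == D("1356.98")

    def test_zero_stay_costs_nothing(self):
        assert facility_cost(FacilityParams(stay_days="0",
                                            stay_rate_per_day="674"))[1] == 0

    def test_rate_without_duration_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="rate given without"):
            facility_cost(FacilityParams(stay_days="1", or_rate_per_minute="20"))


class TestFollowUpMixture:
    def test_thyroidectomy_mixture(self, thyroidectomy):
        value = followup_expected_cost(thyroidectomy.followup_courses)
        assert D("152.49") <= to_cents(value) <= D("152.50")

    def test_single_course_at_full_frequency(self):
        course = FollowUpCourse(name="standard", frequency="1",
                                printed_total="97.97")
        assert followup_expected_cost([course]) == D("97.97")

    def test_ablation_weighted_standard_course(self, ablation):
        value = followup_expected_cost(ablation.followup_courses)
        assert to_cents(value) == D("91.11")
        with_residual = followup_expected_cost(ablation.followup_courses,
                                               ablation.followup_residual)
        assert to_cents(with_residual) == D("108.70")

    def test_frequency_sum_above_one_rejected(self):
        courses = [
            FollowUpCourse(name="standard", frequency="0.8", printed_total="1"),
            FollowUpCourse(name="acute_complications", frequency="0.7",
                           printed_total="1"),
        ]
        with pytest.raises(DatasetValidationError, match="sum"):
            followup_expected_cost(courses)

    @given(
        freqs=st.lists(st.decimals(min_value=0, max_value=Decimal("0.33"), places=3),
                       min_size=1, max_size=3),
        costs=st.lists(st.decimals(min_value=0, max_value=500, places=2),
                       min_size=3, max_size=3),
    )
    def test_mixture_bounded_by_costliest_course(self, freqs, costs):
        names = ("standard", "acute_complications", "chronic_complications")
        courses = [
            FollowUpCourse(name=names[i], frequency=f, printed_total=costs[i])
            for i, f in enumerate(freqs)
        ]
        value = followup_expected_cost(courses)
        assert 0 <= value <= max(costs[: len(freqs)])


class TestProductivityLoss:
    def test_fidelity_reproduces_published_totals(self, thyroidectomy,
                                                  hemithyroidectomy):
        tt = productivity_loss(thyroidectomy.indirect)
        assert (tt.patient_loss, tt.caregiver_loss, tt.total_loss) == (
            D("956.84"), D("47.84"), D("1004.68"))
        assert productivity_loss(hemithyroidectomy.indirect).total_loss == D("755.97")

    def test_raw_mode_recomputes_from_the_formula(self, thyroidectomy):
        raw = productivity_loss(thyroidectomy.indirect, mode="raw")
        assert raw.total_days == D("13.62")
        assert to_cents(raw.total_loss) == D("1004.65")

    def test_no_caregiver_means_patient_only(self):
        params = IndirectCostParams(hosp_days="1", convalescence_days="4",
                                    caregiver_share="0")
        loss = productivity_loss(params)
        assert loss.caregiver_loss == 0
        assert loss.total_loss == loss.patient_loss


class TestRetreatmentUplift:
    @pytest.mark.parametrize("base,expected", [
        ("321.09", "369.25"),
        ("35.34", "40.64"),
        ("168.50", "193.78"),
    ])
    def test_published_uplifted_values(self, base, expected):
        assert retreatment_uplift(D(base), D("0.15")) == D(expected)

    def test_zero_rate_is_identity(self):
        assert retreatment_uplift(D("123.45"), 0) == D("123.45")

    def test_negative_rate_rejected(self):
        with pytest.raises(DatasetValidationError):
            retreatment_uplift(D("1"), D("-0.1"))


class TestInterventionTotals:
    def test_societal_grand_totals_match_published_summary(
        self, thyroidectomy, hemithyroidectomy, ablation
    ):
        expected = {
            thyroidectomy.name: D("5185.36"),
            hemithyroidectomy.name: D("4211.92"),
            ablation.name: D("1560.06"),
        }
        for dataset in (thyroidectomy, hemithyroidectomy, ablation):
            total = intervention_total(dataset, "societal").grand_total
            assert abs(total - expected[dataset.name]) <= D("0.02")

    def test_opportunity_cost_totals_exact(self, hemithyroidectomy, ablation):
        assert intervention_total(
            hemithyroidectomy, "opportunity_cost_societal"
        ).grand_total == D("4027.17")
        assert intervention_total(
            ablation, "opportunity_cost_societal"
        ).grand_total == D("1519.42")

    def test_perspective_algebra(self, thyroidectomy, hemithyroidectomy, ablation):
        """societal - personnel = opportunity-cost total, to the cent."""
        for dataset in (thyroidectomy, hemithyroidectomy, ablation):
            societal = intervention_total(dataset, "societal")
            opportunity = intervention_total(dataset, "opportunity_cost_societal")
            assert (societal.grand_total - societal.phase_costs["personnel"]
                    == opportunity.grand_total)

    def test_nhs_direct_excludes_productivity(self, thyroidectomy):
        societal = intervention_total(thyroidectomy, "societal")
        direct = intervention_total(thyroidectomy, "nhs_direct")
        assert (societal.grand_total - societal.phase_costs["productivity"]
                == direct.grand_total)

    def test_grand_total_is_sum_of_audit_components(self, ablation):
        b = intervention_total(ablation, "societal")
        included = sum(e.post_uplift for e in b.audit)
        assert b.grand_total == included

    def test_ablation_uplift_audit_trail(self, ablation):
        b = intervention_total(ablation, "societal")
        audit = {e.component: e for e in b.audit}
        assert audit["prehospitalization"].pre_uplift == D("321.09")
        assert audit["prehospitalization"].post_uplift == D("369.25")
        assert audit["followup"].pre_uplift == audit["followup"].post_uplift

    def test_uplift_zero_rate_reproduces_base(self, ablation):
        no_retreat = ablation.model_copy(deep=True)
        no_retreat.retreatment_rate = D(0)
        b = intervention_total(no_retreat, "societal")
        assert b.phase_costs["prehospitalization"] == D("321.09")
        assert b.phase_costs["personnel"] == D("35.34")


class TestComparison:
    def test_ablation_vs_surgery_savings(self, thyroidectomy, hemithyroidectomy,
                                         ablation):
        breakdowns = [intervention_total(d, "societal")
                      for d in (thyroidectomy, hemithyroidectomy, ablation)]
        results = {r.comparator: r for r in compare(breakdowns,
                                                    "total_thyroidectomy")}
        assert abs(results["thermal_ablation"].relative_saving - D("0.70")) < D("0.01")
        hemi_vs = compare(breakdowns, "hemithyroidectomy")
        ablation_vs_hemi = {r.comparator: r for r in hemi_vs}["thermal_ablation"]
        assert ablation_vs_hemi.relative_saving > D("0.60")

    def test_identical_breakdowns_save_nothing(self, ablation):
        a = intervention_total(ablation, "societal")
        twin = a.model_copy(update={"intervention": "twin"})
        results = compare([a, twin], ablation.name)
        assert results[0].absolute_saving == 0
        assert results[0].relative_saving == 0

    def test_mixed_perspectives_rejected(self, thyroidectomy, ablation):
        with pytest.raises(ComparisonError, match="mixed"):
            compare([intervention_total(thyroidectomy, "societal"),
                     intervention_total(ablation, "nhs_direct")], "thermal_ablation")


class TestDocumentedErrata:
    """The source tables carry four internal inconsistencies; the validator
    must flag each with its specific printed value, never hide it."""

    def _mismatches(self, dataset):
        return {n.location: n for n in reconcile(dataset) if n.level == "mismatch"}

    def test_materials_table_total_off_by_13(self, thyroidectomy):
        note = self._mismatches(thyroidectomy)[
            "total_thyroidectomy: materials table total"]
        assert note.printed == D("3489.42")
        assert note.computed == D("3502.42")

    def test_ablation_materials_table_irreconcilable(self, ablation):
        note = self._mismatches(ablation)["thermal_ablation: materials table total"]
        assert note.printed == D("755.15")
        assert note.computed == D("1219.15")

    def test_hemi_followup_subtotal_erratum(self, hemithyroidectomy):
        note = self._mismatches(hemithyroidectomy)[
            "hemithyroidectomy: summary followup subtotal"]
        assert note.printed == D("49.79")
        assert note.computed == D("122.38")

    def test_ablation_followup_residual_is_pinned(self, ablation):
        # the published follow-up subtotal exceeds the weighted course by 17.59
        assert ablation.followup_residual == D("17.59")
        b = intervention_total(ablation, "societal")
        assert b.followup_subtotal == D("108.70")
        assert b.followup_weighted["standard"] == D("91.11")

    def test_bundled_fixtures_otherwise_reconcile(self, thyroidectomy,
                                                  hemithyroidectomy, ablation):
        known = {
            "total_thyroidectomy": 3,  # two course sums + materials table
            "hemithyroidectomy": 3,    # course sum + summary personnel + followup
            "thermal_ablation": 1,     # materials table
        }
        for dataset in (thyroidectomy, hemithyroidectomy, ablation):
            assert len(self._mismatches(dataset)) == known[dataset.name]
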