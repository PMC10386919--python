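"""Replication scenario models: staffing, pricing, dominance and config."""

from __future__ import annotations

from fractions import Fraction

import pytest

from microcost import (
    Arm,
    Category,
    ScenarioError,
    apply_scenario,
    canonical_scenarios,
    derive_capacity,
    identity_spec,
    load_observed_fixture,
    scenario_from_config,
    scenario_grid,
    staffing_requirement,
    summarize_arm,
)
from microcost.scenario import CANONICAL_SCENARIO_NAMES


class TestStaffingRequirement:
    def test_exact_fill_needs_one_counselor(self):
        assert staffing_requirement(100, 100, "stand_alone") == 1

    def test_one_over_capacity_triggers_hire(self):
        assert staffing_requirement(101, 100, "stand_alone") == 2

    def test_integrated_is_proportional(self):
        assert staffing_requirement(101, 100, "integrated") == Fraction(101, 100)

    def test_zero_participants_zero_staff(self):
        assert staffing_requirement(0, 100, "stand_alone") == 0
        assert staffing_requirement(0, 100, "integrated") == 0

    def test_capacity_below_one_rejected(self):
        with pytest.raises(ScenarioError):
            staffing_requirement(10, 0, "stand_alone")


class TestApplyScenario:
    def test_identity_reproduces_observed_total_exactly(self, templates):
        """Re-pricing at observed salaries/capacity/n returns the observed cost."""
        for arm, template in templates.items():
            observed = summarize_arm(load_observed_fixture(arm), arm)
            cost = apply_scenario(template, identity_spec(template))
            assert cost.total == observed.total
            assert cost.counselors_required == 1

    def test_empty_programme_has_fixed_costs_only(self, templates):
        t = templates[Arm.LIVE]
        spec = identity_spec(t).with_n(0)
        spec = type(spec)(**{**spec.__dict__, "include_startup": False, "integration": "integrated"})
        cost = apply_scenario(t, spec)
        expected = sum(t.intervention_recurring.values(), Fraction(0))
        # oversight re-priced at the observed value -> intervention recurring only
        assert cost.total == expected
        with pytest.raises(ScenarioError):
            cost.per_participant

    def test_moh_with_lower_salaries_is_strictly_cheaper(self, templates):
        t = templates[Arm.LIVE]
        specs = canonical_scenarios(t, 500)
        ngo = apply_scenario(t, specs["ngo_standalone"])
        moh = apply_scenario(t, specs["moh_standalone"])
        assert moh.total < ngo.total

    def test_breakdown_sums_to_total(self, templates):
        for t in templates.values():
            for spec in canonical_scenarios(t, 777, include_startup=True).values():
                cost = apply_scenario(t, spec)
                leaves = sum(cost.breakdown["start_up"].values(), Fraction(0))
                for block in cost.breakdown["implementation"].values():
                    leaves += sum(block.values(), Fraction(0))
                assert leaves == cost.total

    def test_missing_salary_role_rejected(self, templates):
        t = templates[Arm.LIVE]
        spec = identity_spec(t)
        bad = type(spec)(**{**spec.__dict__, "salary_table": {"counselor": 1000}})
        with pytest.raises(ScenarioError, match="oversight"):
            apply_scenario(t, bad)

    def test_startup_included_only_when_requested(self, templates):
        t = templates[Arm.SMS]
        spec = canonical_scenarios(t, 100)["ngo_integrated"]
        without = apply_scenario(t, spec)
        with_startup = apply_scenario(t, type(spec)(**{**spec.__dict__, "include_startup": True}))
        assert with_startup.total - without.total == t.startup_total

    def test_connectivity_flag_moves_cost_to_participant_level(self, templates):
        t = templates[Arm.IVR]
        spec = canonical_scenarios(t, t.n_obs)["ngo_integrated"]
        fixed = apply_scenario(t, spec)
        scaled = apply_scenario(
            t, type(spec)(**{**spec.__dict__, "connectivity_per_participant": True})
        )
        # at the observed n the per-head rate reproduces the fixed cost
        assert scaled.total == fixed.total
        assert "connectivity" in scaled.breakdown["implementation"]["participant"]
        assert "connectivity" not in scaled.breakdown["implementation"]["intervention"]


class TestScenarioGrid:
    def test_integrated_never_exceeds_stand_alone(self, templates):
        for t in templates.values():
            for n in (40, 101, 1000):
                costs = scenario_grid(t, n)
                assert costs["ngo_integrated"].total <= costs["ngo_standalone"].total
                assert costs["moh_integrated"].total <= costs["moh_standalone"].total

    def test_all_four_scenarios_returned(self, templates):
        costs = scenario_grid(templates[Arm.SMS], 250)
        assert set(costs) == set(CANONICAL_SCENARIO_NAMES)

    def test_exact_capacity_multiple_equalizes_staffing_modes(self, templates):
        t = templates[Arm.LIVE]
        specs = canonical_scenarios(t, 40)
        cap = specs["ngo_standalone"].counselor_capacity
        sa = apply_scenario(t, specs["ngo_standalone"].with_n(3 * cap))
        integ = apply_scenario(t, specs["ngo_integrated"].with_n(3 * cap))
        assert sa.total == integ.total

    def test_step_jump_is_one_counselor_annual_cost(self, templates):
        """Stand-alone totals step up by exactly one loaded counselor-year."""
        t = templates[Arm.LIVE]
        spec = canonical_scenarios(t, 40)["ngo_standalone"]
        cap = spec.counselor_capacity
        annual = spec.salary_table["counselor"] + spec.counselor_overhead_per_fte
        unit = t.participant_unit_total
        for k in (1, 2, 5):
            at = apply_scenario(t, spec.with_n(k * cap)).total
            after = apply_scenario(t, spec.with_n(k * cap + 1)).total
            assert after - at == annual + unit
        # away from thresholds, only the participant-level unit cost accrues
        mid = apply_scenario(t, spec.with_n(cap + 2)).total
        assert mid - apply_scenario(t, spec.with_n(cap + 1)).total == unit


class TestDeriveCapacity:
    def test_capacity_from_observed_effort(self, templates):
        t = templates[Arm.LIVE]
        # 9179.40 / 3.75 / 160 h per participant; 1760 productive hours
        expected = int(1760 / (float(t.counselor_time_total) / 3.75 / 160))
        assert derive_capacity(t) == expected

    def test_rate_must_be_positive(self, templates):
        with pytest.raises(ScenarioError):
            derive_capacity(templates[Arm.LIVE], 0)


class TestScenarioConfig:
    CONFIG = {
        "operator": "moh",
        "integration": "integrated",
        "counselor_capacity": 120,
        "salary_table": {"counselor": 2640, "oversight": 3705},
        "n_participants": 500,
        "excluded_categories": ["office_consumables"],
        "include_startup": False,
    }

    def test_mapping_config_accepted(self, templates):
        spec = scenario_from_config(self.CONFIG)
        assert spec.excluded_categories == frozenset({Category.OFFICE_CONSUMABLES})
        cost = apply_scenario(templates[Arm.LIVE], spec)
        assert "office_consumables" not in cost.breakdown["implementation"]["intervention"]

    def test_yaml_file_config(self, tmp_path, templates):
        import yaml

        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(self.CONFIG))
        spec = scenario_from_config(path)
        assert spec.operator == "moh"
        assert spec.counselor_capacity == 120

    def test_missing_keys_rejected(self):
        with pytest.raises(ScenarioError, match="missing"):
            scenario_from_config({"operator": "ngo"})

    def test_unknown_keys_rejected(self):
        bad = dict(self.CONFIG, typo_key=1)
        with pytest.raises(ScenarioError, match="unknown"):
            scenario_from_config(bad)
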