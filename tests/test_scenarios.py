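import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eabsim import (
    ScenarioSpec,
    SequencingError,
    ValidationError,
    builtin_scenarios,
    get_scenario,
    run_scenario,
)
from eabsim.scenarios import initial_state, step_year

# Reference count grids (scenario -> {year: (ash, nonash)}) for the
# trajectories the ceiling-recurrence engine reproduces exactly.
REFERENCE_COUNTS = {
    "Remove Dead Ash Only (Control)": {
        1: (1192, 0), 5: (490, 0), 10: (162, 0), 15: (55, 0), 20: (20, 0)},
    "Remove Dead Ash then Replant": {
        1: (1192, 0), 5: (490, 697), 10: (162, 953), 15: (55, 1033), 20: (20, 1056)},
    "Preemptive Removal then Replant": {
        1: (1090, 366), 5: (0, 1130), 10: (0, 1059), 15: (0, 1024), 20: (0, 989)},
    "Inject, Preemptive Removal, and Replant": {
        1: (1449, 38), 5: (1295, 158), 10: (0, 1122), 15: (0, 1069), 20: (0, 1039)},
    "Injection in Perpetuity": {
        1: (1449, 0), 5: (1295, 0), 10: (1125, 0), 15: (979, 0), 20: (852, 0)},
    "Injection in Perpetuity with Replanting": {
        1: (1449, 38), 5: (1295, 158), 10: (1125, 292), 15: (979, 403), 20: (852, 504)},
}


def records_by_year(result):
    return {r.year: r for r in result.records}


class TestBuiltinScenarios:
    def test_exactly_seven_named_specs(self, builtins):
        assert len(builtins) == 7
        assert len({s.name for s in builtins}) == 7

    def test_lookup_by_name_case_insensitive(self):
        spec = get_scenario("injection in perpetuity")
        assert spec.name == "Injection in Perpetuity"

    def test_unknown_name_raises(self):
        with pytest.raises(ValidationError):
            get_scenario("mystery option")

    @pytest.mark.parametrize("name,years", [
        (name, years) for name, years in REFERENCE_COUNTS.items()
    ])
    def test_reference_count_grid(self, name, years, params, by_name):
        result = run_scenario(by_name[name], params)
        recs = records_by_year(result)
        for year, (ash, nonash) in years.items():
            assert (recs[year].ash_count, recs[year].nonash_count) == (ash, nonash), \
                f"{name} year {year}"

    def test_control_intermediate_years(self, params, by_name):
        result = run_scenario(by_name["Remove Dead Ash Only (Control)"], params)
        series = [r.ash_count for r in result.records[1:6]]
        assert series == [1192, 954, 764, 612, 490]

    def test_perpetuity_retains_852_at_year_20(self, params, by_name):
        result = run_scenario(by_name["Injection in Perpetuity"], params)
        assert result.records[-1].ash_count == 852

    def test_inject_preemptive_replant_no_ash_by_year_10(self, params, by_name):
        result = run_scenario(by_name["Inject, Preemptive Removal, and Replant"], params)
        assert records_by_year(result)[10].ash_count == 0

    def test_proactive_scenario_caps_total_plantings(self, params, by_name):
        result = run_scenario(by_name["Replant, Inject, then Preemptive Removal"], params)
        assert result.final_state.total_planted == 1490


class TestStepYear:
    def test_cannot_step_past_horizon(self, params):
        spec = ScenarioSpec(name="one-year", horizon=1)
        state = initial_state(params)
        state, _ = step_year(state, spec, params)
        with pytest.raises(SequencingError):
            step_year(state, spec, params)

    def test_preemptive_year_suppresses_mortality(self, params, by_name):
        spec = by_name["Preemptive Removal then Replant"]
        state = initial_state(params)
        state, record = step_year(state, spec, params)
        assert record.ash_count == 1490 - 400 == 1090
        assert record.ash_deaths == 0
        assert record.removals == 400

    def test_records_are_end_of_year_states(self, params, by_name):
        spec = by_name["Remove Dead Ash Only (Control)"]
        state = initial_state(params)
        state, record = step_year(state, spec, params)
        assert record.year == 1
        assert record.ash_count == state.ash_count == 1192

    def test_zero_rate_scenario_is_constant(self):
        from eabsim import DemographyParams
        p = DemographyParams(
            natural_mortality=0.0, injected_ash_mortality=0.0,
            noninjected_ash_mortality=0.0, ash_growth=0.0, nonash_growth=0.0)
        spec = ScenarioSpec(name="static", horizon=10)
        result = run_scenario(spec, p)
        assert all(r.ash_count == p.initial_ash_count for r in result.records)


class TestScenarioValidation:
    def test_perpetuity_excludes_preemptive(self):
        spec = ScenarioSpec(name="bad", inject_mode="perpetuity",
                            preemptive_start=1, preemptive_rate=100)
        with pytest.raises(ValidationError, match="preemptive"):
            spec.validate()

    def test_window_requires_inject_end(self):
        with pytest.raises(ValidationError, match="inject_end"):
            ScenarioSpec(name="bad", inject_mode="window").validate()

    def test_error_lists_all_offending_fields(self):
        spec = ScenarioSpec(name="bad", replant_lag=2, preemptive_rate=-1,
                            preemptive_start=0)
        with pytest.raises(ValidationError) as exc:
            spec.validate()
        message = str(exc.value)
        assert "replant_lag" in message and "preemptive_rate" in message \
            and "preemptive_start" in message

    def test_run_scenario_rejects_invalid_spec(self, params):
        spec = ScenarioSpec(name="bad", replant_lag=5)
        with pytest.raises(ValidationError):
            run_scenario(spec, params)


class TestInvariants:
    def test_ash_monotone_non_increasing_everywhere(self, params, econ, builtins):
        for spec in builtins:
            counts = [r.ash_count for r in run_scenario(spec, params, econ).records]
            assert all(b <= a for a, b in zip(counts, counts[1:])), spec.name

    def test_conservation_every_year(self, params, econ, builtins):
        for spec in builtins:
            result = run_scenario(spec, params, econ)
            recs = result.records
            for prev, cur in zip(recs, recs[1:]):
                # remove_dead: dead ash appear in both deaths and removals,
                # but never in the same year as preemptive removals.
                ash_losses = (max(cur.ash_deaths, cur.removals) if spec.remove_dead
                              else cur.ash_deaths + cur.removals)
                assert prev.ash_count == cur.ash_count + ash_losses, spec.name
                assert (prev.nonash_count + cur.plantings - cur.nonash_deaths
                        == cur.nonash_count), spec.name

    def test_perpetual_injection_matches_closed_form_loop(self, params, by_name):
        result = run_scenario(by_name["Injection in Perpetuity"], params)
        n = params.initial_ash_count
        for record in result.records[1:]:
            n = math.ceil(n * (1 - params.injected_ash_mortality))
            assert record.ash_count == n

    def test_preemptive_extinction_bound(self, params):
        for rate in (100, 250, 400, 700):
            spec = ScenarioSpec(name="p", preemptive_start=1, preemptive_rate=rate)
            result = run_scenario(spec, params)
            deadline = math.ceil(params.initial_ash_count / rate)  # start year 1
            recs = records_by_year(result)
            if deadline <= spec.horizon:
                assert recs[deadline].ash_count == 0

    def test_match_plantings_never_exceed_lagged_losses(self, params, by_name):
        spec = by_name["Remove Dead Ash then Replant"]
        result = run_scenario(spec, params)
        recs = result.records
        for prev, cur in zip(recs, recs[1:]):
            assert cur.plantings <= prev.ash_deaths + prev.removals

    @given(cap=st.integers(0, 2000))
    @settings(max_examples=20, deadline=None)
    def test_total_plantings_respect_cap(self, cap, params):
        spec = ScenarioSpec(
            name="capped", replant_mode="proactive_alternative_site",
            replant_rate=300, replant_cap=cap)
        result = run_scenario(spec, params)
        assert result.final_state.total_planted <= cap

    def test_determinism_bit_for_bit(self, params, econ, builtins):
        for spec in builtins:
            r1 = run_scenario(spec, params, econ)
            r2 = run_scenario(spec, params, econ)
            assert r1.records == r2.records

    def test_year0_record_present(self, params, builtins):
        for spec in builtins:
            result = run_scenario(spec, params)
            assert result.records[0].year == 0
            assert result.records[0].ash_count == params.initial_ash_count
            assert len(result.records) == spec.horizon + 1
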