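"""The misspecification sensitivity grid and its probability-validity
handling."""

import math

import numpy as np
import pytest

import colliderbias as cb
from colliderbias import Stratum
from colliderbias.misspecification import (
    LEVELS,
    MisspecificationScenario,
    expected_direction,
    load_default_grid,
    resolve_invalid,
    scenario_grid,
    write_grid_yaml,
)

# The default grid, frozen: additive log-scale deltas at 50/100/200%.
EQ1_DELTAS = {
    "lg0": (-0.05, -0.1, -0.2),
    "lg1": (-0.075, -0.15, -0.3),
    "la[Black]": (0.125, 0.25, 0.5),
    "la[Asian]": (0.125, 0.25, 0.5),
    "la[Mixed/Other]": (0.1, 0.2, 0.4),
    "lb[Black]": (-0.1, -0.2, -0.4),
    "lb[Asian]": (-0.1, -0.2, -0.4),
    "lb[Mixed/Other]": (-0.1, -0.2, -0.4),
}
EQ2_EXTRA_DELTAS = {
    "lg2": (0.25, 0.5, 1.0),
    "lg3": (-0.35, -0.7, -1.4),
    "lc[Black]": (0.125, 0.25, 0.5),
    "lc[Asian]": (-0.1, -0.2, -0.4),
    "lc[Mixed/Other]": (0.125, 0.25, 0.5),
    "ld[Black]": (0.1, 0.2, 0.4),
    "ld[Asian]": (0.1, 0.2, 0.4),
    "ld[Mixed/Other]": (0.1, 0.2, 0.4),
}
COMPANIONED = {
    "la[Black]", "la[Asian]", "la[Mixed/Other]",
    "lg2", "lc[Black]", "lc[Asian]", "lc[Mixed/Other]",
    "ld[Black]", "ld[Asian]", "ld[Mixed/Other]",
}


def fitted_eq1_params():
    return cb.fit_inclusion_model(cb.strata_table_from_risks(waves=(1,)), "eq1")


class TestGrid:
    def test_eq1_grid_has_24_scenarios_with_expected_deltas(self):
        scenarios = scenario_grid("eq1")
        assert len(scenarios) == 24
        by_target = {}
        for s in scenarios:
            by_target.setdefault(s.target_coefficient, {})[s.level] = s.delta
        assert set(by_target) == set(EQ1_DELTAS)
        for target, deltas in EQ1_DELTAS.items():
            assert tuple(by_target[target][l] for l in LEVELS) == deltas

    def test_eq2_grid_extends_to_48_scenarios(self):
        scenarios = scenario_grid("eq2")
        assert len(scenarios) == 48
        by_target = {}
        for s in scenarios:
            by_target.setdefault(s.target_coefficient, {})[s.level] = s.delta
        assert set(by_target) == set(EQ1_DELTAS) | set(EQ2_EXTRA_DELTAS)
        for target, deltas in EQ2_EXTRA_DELTAS.items():
            assert tuple(by_target[target][l] for l in LEVELS) == deltas

    def test_companion_shift_applied_exactly_where_footnoted(self):
        for s in scenario_grid("eq2"):
            if s.target_coefficient in COMPANIONED:
                assert s.companion_deltas == {"lg1": -0.15}
            else:
                assert s.companion_deltas == {}

    def test_unknown_ethnicity_never_shifted(self):
        for s in scenario_grid("eq2"):
            assert "Unknown" not in s.target_coefficient
            assert all("Unknown" not in c for c in s.companion_deltas)

    def test_malformed_grid_rejected(self):
        grid = load_default_grid()
        grid["eq1"]["lg0"]["deltas"] = {50: -0.2, 100: -0.1, 200: -0.05}
        with pytest.raises(cb.ConfigurationError, match="grow in"):
            scenario_grid("eq1", grid)

    def test_grid_yaml_round_trip(self, tmp_path):
        grid = load_default_grid()
        path = tmp_path / "grid.yaml"
        write_grid_yaml(grid, path)
        from colliderbias.misspecification import load_grid
        assert scenario_grid("eq2", load_grid(path)) == scenario_grid("eq2")


class TestApply:
    def test_shift_is_additive_on_log_scale(self):
        params = fitted_eq1_params()
        scenario = MisspecificationScenario("lg0@100%", "lg0", 100, -0.1)
        shifted = cb.apply_scenario(params, scenario)
        assert shifted.coef["lg0"] == pytest.approx(params.coef["lg0"] - 0.1, abs=1e-15)
        assert math.exp(shifted.coef["lg0"]) == pytest.approx(
            math.exp(params.coef["lg0"]) * math.exp(-0.1), rel=1e-12
        )
        # the original is untouched
        assert params.coef["lg0"] == cb.fit_inclusion_model(
            cb.strata_table_from_risks(waves=(1,)), "eq1"
        ).coef["lg0"]

    def test_zero_delta_is_identity(self):
        params = fitted_eq1_params()
        shifted = cb.apply_scenario(
            params, MisspecificationScenario("noop", "lg0", 100, 0.0)
        )
        assert shifted.coef == params.coef

    def test_companion_applied_simultaneously(self):
        params = fitted_eq1_params()
        scenarios = {
            s.scenario_id: s for s in scenario_grid("eq1")
        }
        shifted = cb.apply_scenario(params, scenarios["la[Black]@50%"])
        assert shifted.coef["la[Black]"] == pytest.approx(
            params.coef["la[Black]"] + 0.125, abs=1e-15
        )
        assert shifted.coef["lg1"] == pytest.approx(
            params.coef["lg1"] - 0.15, abs=1e-15
        )

    def test_unknown_target_coefficient_rejected(self):
        params = fitted_eq1_params()
        with pytest.raises(cb.ConfigurationError):
            cb.apply_scenario(
                params, MisspecificationScenario("bad", "lg9", 100, -0.1)
            )

    def test_apply_then_negate_restores_parameters(self):
        params = cb.fit_inclusion_model(
            cb.strata_table_from_risks(waves=(1, 2)), "eq2"
        )
        for scenario in scenario_grid("eq2"):
            shifted = cb.apply_scenario(params, scenario)
            undone = shifted.shifted(
                {k: -v for k, v in scenario.all_deltas().items()}
            )
            for name in params.coef:
                assert undone.coef[name] == pytest.approx(
                    params.coef[name], abs=1e-12
                )

    def test_companion_only_touches_unshifted_ethnicities_through_lg1(self):
        """For footnoted scenarios, died-stratum probabilities of ethnicities
        whose own coefficients are untouched change exactly by e^-0.15."""
        params = fitted_eq1_params()
        scenarios = {s.scenario_id: s for s in scenario_grid("eq1")}
        shifted = cb.apply_scenario(params, scenarios["la[Black]@100%"])
        for eth in ("White", "Unknown"):
            s = Stratum(eth, True)
            before = cb.predict_probability(params, s, check=False)
            after = cb.predict_probability(shifted, s, check=False)
            assert after == pytest.approx(before * math.exp(-0.15), rel=1e-12)


class TestValidity:
    def test_fitted_parameters_are_valid_on_their_own_strata(self):
        params = fitted_eq1_params()
        strata = [Stratum(e, bool(d)) for e in cb.ETHNICITIES for d in (0, 1)]
        report = cb.validate_probabilities(params, strata)
        assert report["valid"].all()

    def test_probability_pushed_above_one_is_flagged(self):
        params = fitted_eq1_params()  # died strata sit at 0.90
        shifted = params.shifted({"lg1": 0.2})  # 0.9 * e^0.2 ~ 1.099
        strata = [Stratum("White", True), Stratum("White", False)]
        report = cb.validate_probabilities(shifted, strata, baseline=params)
        died = report[report["died"] == 1].iloc[0]
        surv = report[report["died"] == 0].iloc[0]
        assert not died["valid"]
        assert died["probability_after"] == pytest.approx(0.9 * math.exp(0.2), rel=1e-9)
        assert surv["valid"]

    def test_baseline_shift_decreases_every_stratum(self):
        params = fitted_eq1_params()
        shifted = params.shifted({"lg0": -0.1})
        strata = [Stratum(e, bool(d)) for e in cb.ETHNICITIES for d in (0, 1)]
        report = cb.validate_probabilities(shifted, strata, baseline=params)
        assert (report["direction"] == "decrease").all()

    def test_levels_move_probabilities_monotonically(self):
        params = cb.fit_inclusion_model(
            cb.strata_table_from_risks(waves=(1, 2)), "eq2"
        )
        all_strata = [
            Stratum(e, bool(d), w)
            for e in cb.ETHNICITIES for d in (0, 1) for w in (1, 2)
        ]
        by_target = {}
        for s in scenario_grid("eq2"):
            by_target.setdefault(s.target_coefficient, []).append(s)
        for target, scenarios in by_target.items():
            scenarios.sort(key=lambda s: s.level)
            for stratum in all_strata:
                probs = [
                    cb.predict_probability(
                        cb.apply_scenario(params, s), stratum, check=False
                    )
                    for s in scenarios
                ]
                # strata the target coefficient enters respond strictly
                # monotonically in the target's direction; strata touched
                # only by the (level-constant) companion stay put
                probe = MisspecificationScenario("probe", target, 100,
                                                 scenarios[0].delta)
                direction = expected_direction(probe, stratum, "eq2")
                if direction == "increase":
                    assert probs[0] < probs[1] < probs[2]
                elif direction == "decrease":
                    assert probs[0] > probs[1] > probs[2]
                else:
                    assert probs[0] == probs[1] == probs[2]


class TestInvalidPolicy:
    def _invalid_case(self):
        params = fitted_eq1_params()
        scenario = MisspecificationScenario("lg1@+", "lg1", 100, 0.2)
        strata = [Stratum(e, bool(d)) for e in cb.ETHNICITIES for d in (0, 1)]
        return params, scenario, strata

    def test_skip_policy_drops_scenario_with_record(self):
        params, scenario, strata = self._invalid_case()
        shifted, meta = resolve_invalid(params, scenario, strata, policy="skip")
        assert shifted is None
        assert meta["action"] == "skipped" and meta["n_invalid"] > 0

    def test_clip_policy_keeps_parameters_and_records_cap(self):
        params, scenario, strata = self._invalid_case()
        shifted, meta = resolve_invalid(params, scenario, strata, policy="clip")
        assert shifted is not None
        assert meta["action"] == "clip_probabilities"

    def test_shrink_policy_finds_largest_valid_delta(self):
        params, scenario, strata = self._invalid_case()
        shifted, meta = resolve_invalid(params, scenario, strata, policy="shrink")
        assert shifted is not None
        assert meta["action"] == "shrunk_delta"
        assert 0 <= meta["delta_used"] < scenario.delta
        report = cb.validate_probabilities(shifted, strata)
        assert report["valid"].all()
        # the shrunk delta is maximal: the worst stratum sits at the boundary
        assert report["probability_after"].max() == pytest.approx(1.0, abs=1e-6)

    def test_valid_scenario_passes_through_unchanged(self):
        params = fitted_eq1_params()
        scenario = MisspecificationScenario("lg0@100%", "lg0", 100, -0.1)
        strata = [Stratum(e, bool(d)) for e in cb.ETHNICITIES for d in (0, 1)]
        shifted, meta = resolve_invalid(params, scenario, strata, policy="skip")
        assert shifted is not None and meta["action"] == "none"
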