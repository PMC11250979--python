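"""The saturated log-risk inclusion model: closed-form fit, prediction,
standard errors and weight derivation."""

import math

import numpy as np
import pandas as pd
import pytest

import colliderbias as cb
from colliderbias import Stratum
from colliderbias.inclusion import linear_predictor

from conftest import small_population

ETHS = cb.ETHNICITIES
NONREF = cb.NON_REFERENCE_ETHNICITIES


def random_strata(rng, model_form: str, n_at_risk: float | None = 10_000) -> pd.DataFrame:
    waves = (1, 2) if model_form == "eq2" else (1,)
    rows = []
    for w in waves:
        for e in ETHS:
            for d in (0, 1):
                risk = rng.uniform(0.01, 0.99)
                rows.append(
                    {"ethnicity": e, "wave": w, "died": d,
                     "n_at_risk": np.nan if n_at_risk is None else n_at_risk,
                     "risk": risk}
                )
    return pd.DataFrame(rows)


def cell_risk(strata: pd.DataFrame, e: str, d: int, w: int = 1) -> float:
    m = (strata["ethnicity"] == e) & (strata["died"] == d) & (strata["wave"] == w)
    return float(strata.loc[m, "risk"].iloc[0])


class TestSaturatedFit:
    def test_reference_only_table_fits_baseline_and_death_effect(self):
        strata = pd.DataFrame(
            [
                {"ethnicity": "White", "died": 0, "risk": 0.2},
                {"ethnicity": "White", "died": 1, "risk": 0.8},
            ]
        )
        params = cb.fit_inclusion_model(strata, "eq1")
        e = params.exp_coef()
        assert e["lg0"] == pytest.approx(0.2, abs=1e-12)
        assert e["lg1"] == pytest.approx(4.0, abs=1e-12)
        for eth in NONREF:
            assert e[f"la[{eth}]"] == 1.0 and e[f"lb[{eth}]"] == 1.0

    @pytest.mark.parametrize("model_form", ["eq1", "eq2"])
    def test_coefficients_are_cell_risk_ratios(self, model_form):
        rng = np.random.default_rng(3)
        strata = random_strata(rng, model_form)
        params = cb.fit_inclusion_model(strata, model_form)
        e = params.exp_coef()
        r = lambda eth, d, w=1: cell_risk(strata, eth, d, w)
        assert e["lg0"] == pytest.approx(r("White", 0), rel=1e-12)
        assert e["lg1"] == pytest.approx(r("White", 1) / r("White", 0), rel=1e-12)
        for eth in NONREF:
            assert e[f"la[{eth}]"] == pytest.approx(
                r(eth, 0) / r("White", 0), rel=1e-12
            )
            assert e[f"lb[{eth}]"] == pytest.approx(
                (r(eth, 1) / r(eth, 0)) / (r("White", 1) / r("White", 0)), rel=1e-12
            )
        if model_form == "eq2":
            assert e["lg2"] == pytest.approx(r("White", 0, 2) / r("White", 0), rel=1e-12)
            for eth in NONREF:
                assert e[f"lc[{eth}]"] == pytest.approx(
                    (r(eth, 0, 2) / r(eth, 0)) / (r("White", 0, 2) / r("White", 0)),
                    rel=1e-12,
                )

    @pytest.mark.parametrize("model_form", ["eq1", "eq2"])
    def test_fitted_probabilities_reproduce_cell_risks(self, model_form):
        rng = np.random.default_rng(4)
        strata = random_strata(rng, model_form)
        params = cb.fit_inclusion_model(strata, model_form)
        for _, row in strata.iterrows():
            s = Stratum(row["ethnicity"], bool(row["died"]), int(row["wave"]))
            assert cb.predict_probability(params, s) == pytest.approx(
                row["risk"], rel=1e-12
            )

    @pytest.mark.parametrize("model_form", ["eq1", "eq2"])
    def test_iterative_log_binomial_agrees_with_closed_form(self, model_form):
        rng = np.random.default_rng(5)
        strata = random_strata(rng, model_form)
        closed = cb.fit_inclusion_model(strata, model_form)
        mle = cb.fit_inclusion_model_mle(strata, model_form)
        for name in closed.coef:
            assert mle.coef[name] == pytest.approx(closed.coef[name], abs=1e-8)

    def test_wave_effect_from_published_survivor_risks(self):
        """Fitting the bundled two-wave risks reproduces the published
        exponentiated wave effect within the rounding of its 3-significant-
        figure inputs."""
        strata = cb.strata_table_from_risks(waves=(1, 2))
        e = cb.fit_inclusion_model(strata, "eq2").exp_coef()
        assert e["lg2"] == pytest.approx(0.00068 / 0.00126, rel=1e-12)
        assert abs(e["lg2"] - 0.5405) < 0.005

    def test_zero_risk_is_non_identifiable(self):
        strata = cb.strata_table_from_risks(waves=(1,)).copy()
        strata.loc[0, "risk"] = 0.0
        with pytest.raises(cb.ModelError, match="non-identifiable"):
            cb.fit_inclusion_model(strata, "eq1")

    def test_risk_above_one_is_evidence_inconsistency(self):
        strata = cb.strata_table_from_risks(waves=(1,)).copy()
        strata.loc[1, "risk"] = 1.2
        with pytest.raises(cb.EvidenceInconsistencyError):
            cb.fit_inclusion_model(strata, "eq1")

    def test_standard_errors_follow_observed_information(self):
        strata = cb.strata_table_from_risks(waves=(1,), n_at_risk=50_000)
        params = cb.fit_inclusion_model(strata, "eq1")
        p0 = cell_risk(strata, "White", 0)
        expected = p0 * math.sqrt((1 - p0) / (50_000 * p0))
        assert params.se_exp["lg0"] == pytest.approx(expected, rel=1e-12)
        # a ratio coefficient accumulates the variances of all its cells
        p1 = cell_risk(strata, "White", 1)
        var = (1 - p0) / (50_000 * p0) + (1 - p1) / (50_000 * p1)
        assert params.se_exp["lg1"] == pytest.approx(
            (p1 / p0) * math.sqrt(var), rel=1e-12
        )


class TestPrediction:
    def test_null_parameters_predict_certainty(self):
        params = cb.InclusionModelParams(
            "eq1", dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        )
        for e in ETHS:
            for d in (False, True):
                assert cb.predict_probability(params, Stratum(e, d)) == 1.0

    def test_published_parameter_product_for_black_death_stratum(self):
        """Under the published exponentiated first-wave parameters, the
        Black died-stratum probability is the plain product of the printed
        factors (~0.988 — above the 0.90 design value because printed
        parameters are rounded)."""
        printed = {"lg0": 0.0012, "lg1": 823.70, "la[Black]": 1.9190,
                   "lb[Black]": 0.5211}
        coef = dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        coef.update({k: math.log(v) for k, v in printed.items()})
        params = cb.InclusionModelParams("eq1", coef)
        p = cb.predict_probability(params, Stratum("Black", True))
        assert p == pytest.approx(0.0012 * 823.70 * 1.9190 * 0.5211, rel=1e-12)
        assert cb.predict_probability(params, Stratum("White", False)) == (
            pytest.approx(0.0012, rel=1e-12)
        )

    def test_probability_above_one_raises(self):
        coef = dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        coef["lg1"] = 0.5
        params = cb.InclusionModelParams("eq1", coef)
        with pytest.raises(cb.InvalidProbabilityError):
            cb.predict_probability(params, Stratum("White", True))

    def test_increasing_any_coefficient_increases_covered_strata(self):
        rng = np.random.default_rng(6)
        strata = random_strata(rng, "eq2", n_at_risk=None)
        params = cb.fit_inclusion_model(strata, "eq2")
        all_strata = [
            Stratum(e, bool(d), w) for e in ETHS for d in (0, 1) for w in (1, 2)
        ]
        for name in params.coef:
            bumped = params.shifted({name: 0.3})
            for s in all_strata:
                before = linear_predictor(params, s)
                after = linear_predictor(bumped, s)
                zero = cb.InclusionModelParams(
                    "eq2", dict.fromkeys(params.coef, 0.0)
                ).shifted({name: 1.0})
                touches = linear_predictor(zero, s) != 0.0
                if touches:
                    assert after > before
                else:
                    assert after == before


class TestWeights:
    def test_weight_is_reciprocal_probability(self):
        coef = dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        coef["lg0"] = math.log(0.0012)
        params = cb.InclusionModelParams("eq1", coef)
        cohort = pd.DataFrame(
            {"ethnicity": ["White", "White"], "died": [0, 0], "wave": [1, 1]}
        )
        weighted = cb.derive_weights(params, cohort)
        assert weighted["weight"].iloc[0] == pytest.approx(1 / 0.0012)
        # identical strata receive identical weights
        assert weighted["weight"].nunique() == 1

    def test_certain_inclusion_gives_unit_weight(self):
        params = cb.InclusionModelParams(
            "eq1", dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        )
        cohort = pd.DataFrame({"ethnicity": ["Black"], "died": [1], "wave": [1]})
        assert cb.derive_weights(params, cohort)["weight"].iloc[0] == 1.0

    def test_unknown_category_is_a_mapping_error(self):
        params = cb.InclusionModelParams(
            "eq1", dict.fromkeys(cb.coefficient_names("eq1"), 0.0)
        )
        cohort = pd.DataFrame({"ethnicity": ["Martian"], "died": [0], "wave": [1]})
        with pytest.raises(cb.ConfigurationError):
            cb.derive_weights(params, cohort)

    def test_weight_sum_estimates_full_population_stratum_sizes(self):
        """IPW pseudo-population: summed weights of hospitalised persons in
        a stratum estimate that stratum's size in the source population."""
        config = small_population(seed=17, n=150_000,
                                 baseline_hosp_risk_survivor=0.01,
                                 baseline_death_risk=0.02)
        pop = cb.simulate_population(config)
        summary = cb.derive_external_summary(pop)
        strata = cb.build_strata_from_marginals(
            summary[summary["wave"] == 1], 0.9
        )
        params = cb.fit_inclusion_model(strata, "eq1")
        cohort = cb.restrict_to_hospitalised(pop)
        weighted = cb.derive_weights(params, cohort)
        for eth in ("White", "Black"):
            for died in (0, 1):
                true_n = ((pop["ethnicity"] == eth) & (pop["died"] == died)).sum()
                w_sum = weighted.loc[
                    (weighted["ethnicity"] == eth) & (weighted["died"] == died),
                    "weight",
                ].sum()
                assert w_sum == pytest.approx(true_n, rel=0.1)


def test_params_json_round_trip(tmp_path):
    strata = cb.strata_table_from_risks(waves=(1, 2), n_at_risk=1e6)
    params = cb.fit_inclusion_model(strata, "eq2")
    path = tmp_path / "params.json"
    params.to_json(path)
    restored = cb.InclusionModelParams.from_json(path)
    assert restored.model_form == "eq2"
    for name, value in params.coef.items():
        assert restored.coef[name] == pytest.approx(value, abs=1e-15)
        assert restored.se_exp[name] == pytest.approx(params.se_exp[name])
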