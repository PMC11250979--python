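"""Saturated log-risk model of hospitalisation and the selection weights.

The probability that a person appears in the hospitalised cohort is modelled
on the log scale from the external stratum risks:

    ln P(hosp) = lg0 + lg1*death + la[e]                    (single wave)
    ln P(hosp) = lg0 + lg1*death + lg2*wave2 + lg3*death*wave2
                 + la[e] + lb[e]*death + lc[e]*wave2
                 + ld[e]*death*wave2                        (two waves)

with White as the reference ethnicity (contributing no ethnicity terms) and
wave 1 as the reference wave. Exponentiated coefficients are risk ratios:
``exp(lg0)`` is the baseline (White survivor, wave 1) hospitalisation risk,
``exp(lg1)`` the death-vs-survival risk ratio, ``exp(la[e])`` the ethnicity
risk ratio among survivors, and so on. (The single-wave linear predictor
also carries ``lb[e]*death``; it is written out in full in the two-wave
form above.)

Because the model is *saturated* in its strata — one coefficient per cell —
the maximum-likelihood fit is available in closed form: fitted probabilities
equal observed stratum risks exactly, and each coefficient is a signed sum
of log cell risks. An iterative log-binomial GLM route is provided for
non-saturated extensions and must agree with the closed form on saturated
inputs.

The inverse of each predicted stratum probability is that stratum's
inverse-probability-of-selection weight; attaching these to the hospitalised
cohort reconstructs a pseudo-population representative of the community, so
that a weighted survival analysis is freed of the collider conditioning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .common import (
    ConfigurationError,
    EvidenceInconsistencyError,
    InvalidProbabilityError,
    ModelError,
    NON_REFERENCE_ETHNICITIES,
    REFERENCE_ETHNICITY,
    Stratum,
)

logger = logging.getLogger(__name__)

MODEL_FORMS = ("eq1", "eq2")


def coefficient_names(model_form: str) -> list[str]:
    """Coefficient names for a model form, in design order."""
    if model_form not in MODEL_FORMS:
        raise ConfigurationError(f"model_form must be one of {MODEL_FORMS}")
    names = ["lg0", "lg1"]
    if model_form == "eq2":
        names += ["lg2", "lg3"]
    names += [f"la[{e}]" for e in NON_REFERENCE_ETHNICITIES]
    names += [f"lb[{e}]" for e in NON_REFERENCE_ETHNICITIES]
    if model_form == "eq2":
        names += [f"lc[{e}]" for e in NON_REFERENCE_ETHNICITIES]
        names += [f"ld[{e}]" for e in NON_REFERENCE_ETHNICITIES]
    return names


@dataclass
class InclusionModelParams:
    """Log-scale coefficients of the inclusion model.

    ``coef`` maps coefficient name -> log-scale value; ``se_exp`` (optional)
    maps name -> standard error on the exponentiated scale, as derived from
    the observed information of the log-binomial likelihood.
    """

    model_form: str
    coef: dict[str, float]
    se_exp: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        expected = set(coefficient_names(self.model_form))
        got = set(self.coef)
        if got != expected:
            raise ConfigurationError(
                f"{self.model_form} parameter set must have coefficients "
                f"{sorted(expected)}; missing {sorted(expected - got)}, "
                f"unexpected {sorted(got - expected)}"
            )
        for name, value in self.coef.items():
            if not math.isfinite(value):
                raise ModelError(f"coefficient {name} is not finite: {value}")

    def exp_coef(self) -> dict[str, float]:
        """Coefficients on the exponentiated (risk-ratio) scale, as printed
        in parameter tables."""
        return {k: math.exp(v) for k, v in self.coef.items()}

    def shifted(self, deltas: dict[str, float]) -> "InclusionModelParams":
        """A new parameter set with additive log-scale shifts applied; the
        original is untouched. Standard errors are dropped (a shifted set is
        no longer a fit)."""
        unknown = set(deltas) - set(self.coef)
        if unknown:
            raise ConfigurationError(
                f"unknown coefficient name(s) {sorted(unknown)} for "
                f"{self.model_form}"
            )
        new = dict(self.coef)
        for name, d in deltas.items():
            new[name] = new[name] + d
        return replace(self, coef=new, se_exp=None)

    # -- serialisation ---------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "model_form": self.model_form,
            "coefficients": [
                {
                    "name": name,
                    "log_value": self.coef[name],
                    "exp_value": math.exp(self.coef[name]),
                    "se_exp": None if self.se_exp is None else self.se_exp.get(name),
                }
                for name in coefficient_names(self.model_form)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "InclusionModelParams":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        coef = {c["name"]: c["log_value"] for c in payload["coefficients"]}
        ses = {
            c["name"]: c["se_exp"]
            for c in payload["coefficients"]
            if c.get("se_exp") is not None
        }
        return cls(payload["model_form"], coef, ses or None)


# ---------------------------------------------------------------------------
# Closed-form saturated fit
# ---------------------------------------------------------------------------


def _cell_contrasts(model_form: str) -> dict[str, list[tuple[tuple, int]]]:
    """Each coefficient as a signed sum of log cell risks.

    Cells are keyed (ethnicity, died) for eq1 and (ethnicity, died, wave)
    for eq2. E.g. la[e] = ln risk(e, survived) - ln risk(White, survived).
    """
    W = REFERENCE_ETHNICITY

    def cell(e, d, w=None):
        return (e, d) if w is None else (e, d, w)

    if model_form == "eq1":
        contrasts = {
            "lg0": [(cell(W, 0), +1)],
            "lg1": [(cell(W, 1), +1), (cell(W, 0), -1)],
        }
        for e in NON_REFERENCE_ETHNICITIES:
            contrasts[f"la[{e}]"] = [(cell(e, 0), +1), (cell(W, 0), -1)]
            contrasts[f"lb[{e}]"] = [
                (cell(e, 1), +1), (cell(e, 0), -1),
                (cell(W, 1), -1), (cell(W, 0), +1),
            ]
        return contrasts

    contrasts = {
        "lg0": [(cell(W, 0, 1), +1)],
        "lg1": [(cell(W, 1, 1), +1), (cell(W, 0, 1), -1)],
        "lg2": [(cell(W, 0, 2), +1), (cell(W, 0, 1), -1)],
        "lg3": [
            (cell(W, 1, 2), +1), (cell(W, 0, 2), -1),
            (cell(W, 1, 1), -1), (cell(W, 0, 1), +1),
        ],
    }
    for e in NON_REFERENCE_ETHNICITIES:
        contrasts[f"la[{e}]"] = [(cell(e, 0, 1), +1), (cell(W, 0, 1), -1)]
        contrasts[f"lb[{e}]"] = [
            (cell(e, 1, 1), +1), (cell(e, 0, 1), -1),
            (cell(W, 1, 1), -1), (cell(W, 0, 1), +1),
        ]
        contrasts[f"lc[{e}]"] = [
            (cell(e, 0, 2), +1), (cell(e, 0, 1), -1),
            (cell(W, 0, 2), -1), (cell(W, 0, 1), +1),
        ]
        contrasts[f"ld[{e}]"] = [
            (cell(e, 1, 2), +1), (cell(e, 0, 2), -1),
            (cell(e, 1, 1), -1), (cell(e, 0, 1), +1),
            (cell(W, 1, 2), -1), (cell(W, 0, 2), +1),
            (cell(W, 1, 1), +1), (cell(W, 0, 1), -1),
        ]
    return contrasts


def _extract_cells(strata: pd.DataFrame, model_form: str):
    """Index risks (and n) by cell key, validating completeness."""
    table = strata.copy()
    if "risk" not in table.columns:
        table["risk"] = table["n_hospitalised"] / table["n_at_risk"]
    has_wave = "wave" in table.columns
    if model_form == "eq2":
        if not has_wave or set(table["wave"]) != {1, 2}:
            raise ConfigurationError(
                "eq2 requires strata for both waves (wave column with values 1 and 2)"
            )
        keyed = True
    else:
        if has_wave and table["wave"].nunique() > 1:
            raise ConfigurationError(
                "eq1 fits a single wave; filter the strata table to one wave first"
            )
        keyed = False

    risks, ns = {}, {}
    for _, row in table.iterrows():
        key = (row["ethnicity"], int(row["died"]))
        if keyed:
            key = key + (int(row["wave"]),)
        if key in risks:
            raise ConfigurationError(f"duplicate stratum {key} in strata table")
        risk = float(row["risk"])
        name = f"(ethnicity={key[0]}, died={key[1]}" + (
            f", wave={key[2]})" if keyed else ")"
        )
        if risk > 1.0:
            raise EvidenceInconsistencyError(
                f"stratum {name} has risk {risk:.6g} > 1 "
                "(inconsistent pseudo-counts)"
            )
        if risk <= 0.0 or not math.isfinite(risk):
            raise ModelError(
                f"stratum {name} has risk {risk!r}; the corresponding "
                "coefficient is non-identifiable"
            )
        n = row.get("n_at_risk", np.nan)
        if not np.isnan(n) and n <= 0:
            raise ConfigurationError(f"stratum {name} has n_at_risk {n} <= 0")
        risks[key] = risk
        ns[key] = float(n)

    # the reference-ethnicity cells are always required; a non-reference
    # ethnicity may be absent entirely (its ratio coefficients default to 1,
    # i.e. log 0) but must never be partially observed
    cells_per_eth = {}
    for key in _expected_cells(model_form):
        cells_per_eth.setdefault(key[0], set()).add(key)
    missing_ref = cells_per_eth[REFERENCE_ETHNICITY] - set(risks)
    if missing_ref:
        raise ConfigurationError(
            f"strata table is missing reference-ethnicity cells "
            f"{sorted(missing_ref)} for {model_form}"
        )
    absent = []
    for eth in NON_REFERENCE_ETHNICITIES:
        have = cells_per_eth[eth] & set(risks)
        if not have:
            absent.append(eth)
        elif have != cells_per_eth[eth]:
            raise ConfigurationError(
                f"strata table has only some cells for ethnicity {eth!r}: "
                f"missing {sorted(cells_per_eth[eth] - have)}"
            )
    return risks, ns, tuple(absent)


def _expected_cells(model_form: str) -> set:
    eths = (REFERENCE_ETHNICITY,) + NON_REFERENCE_ETHNICITIES
    if model_form == "eq1":
        return {(e, d) for e in eths for d in (0, 1)}
    return {(e, d, w) for e in eths for d in (0, 1) for w in (1, 2)}


def fit_inclusion_model(strata: pd.DataFrame, model_form: str = "eq1") -> InclusionModelParams:
    """Fit the saturated log-risk inclusion model in closed form.

    Fitted probabilities equal observed stratum risks exactly; each
    coefficient is the corresponding log risk ratio. Standard errors (on the
    exponentiated scale) come from the observed information of the
    log-binomial likelihood, var(ln p) = (1 - p) / (n p) per cell, summed
    over the cells entering each contrast; they are reported only when the
    strata table carries ``n_at_risk``.
    """
    if model_form not in MODEL_FORMS:
        raise ConfigurationError(f"model_form must be one of {MODEL_FORMS}")
    risks, ns, absent = _extract_cells(strata, model_form)
    if absent:
        logger.warning(
            "ethnicities %s absent from strata table; their risk-ratio "
            "coefficients default to 1", list(absent),
        )
    contrasts = {
        name: terms
        for name, terms in _cell_contrasts(model_form).items()
        if not any(name.endswith(f"[{e}]") for e in absent)
    }
    coef = dict.fromkeys(coefficient_names(model_form), 0.0)
    for name, terms in contrasts.items():
        coef[name] = sum(sign * math.log(risks[cell]) for cell, sign in terms)
    se_exp = None
    if all(np.isfinite(list(ns.values()))):
        se_exp = {}
        for name, terms in contrasts.items():
            var = sum(
                (1.0 - risks[cell]) / (ns[cell] * risks[cell]) for cell, _ in terms
            )
            se_exp[name] = math.exp(coef[name]) * math.sqrt(var)
    return InclusionModelParams(model_form, coef, se_exp)


def fit_inclusion_model_mle(
    strata: pd.DataFrame, model_form: str = "eq1"
) -> InclusionModelParams:
    """Iterative maximum-likelihood log-binomial fit.

    The general-purpose route for (future) non-saturated designs; on
    saturated inputs it must agree with :func:`fit_inclusion_model` to high
    precision. Fits a binomial GLM with log link on the per-stratum risks,
    weighting each stratum by its denominator, started at the closed-form
    solution to keep the log-link fit inside its constrained domain.
    """
    closed = fit_inclusion_model(strata, model_form)
    risks, ns, absent = _extract_cells(strata, model_form)
    if absent:
        raise ConfigurationError(
            f"iterative fit requires a complete strata table; ethnicities "
            f"{list(absent)} are absent"
        )
    names = coefficient_names(model_form)
    cells = sorted(risks)
    X = np.zeros((len(cells), len(names)))
    for i, cell in enumerate(cells):
        eth, died = cell[0], cell[1]
        wave2 = int(cell[2] == 2) if model_form == "eq2" else 0
        row = dict.fromkeys(names, 0.0)
        row["lg0"] = 1.0
        row["lg1"] = died
        if model_form == "eq2":
            row["lg2"] = wave2
            row["lg3"] = died * wave2
        if eth != REFERENCE_ETHNICITY:
            row[f"la[{eth}]"] = 1.0
            row[f"lb[{eth}]"] = died
            if model_form == "eq2":
                row[f"lc[{eth}]"] = wave2
                row[f"ld[{eth}]"] = died * wave2
        X[i] = [row[n] for n in names]
    y = np.array([risks[c] for c in cells])
    w = np.array([ns[c] for c in cells])
    if not np.all(np.isfinite(w)):
        w = np.ones_like(y)  # risks-only table: denominators only scale the likelihood
    import warnings as _warnings

    with _warnings.catch_warnings():
        # The log link on a binomial family and an exactly-fitting saturated
        # design both trigger advisory warnings; they are the intended model.
        _warnings.simplefilter("ignore")
        model = sm.GLM(
            y, X, family=sm.families.Binomial(sm.families.links.Log()), var_weights=w
        )
        start = np.array([closed.coef[n] for n in names])
        try:
            result = model.fit(start_params=start, maxiter=200, tol=1e-12)
        except Exception as exc:  # pragma: no cover - defensive
            raise ModelError(f"log-binomial GLM failed to converge: {exc}") from exc
    coef = dict(zip(names, result.params))
    return InclusionModelParams(model_form, coef)


# ---------------------------------------------------------------------------
# Prediction and weights
# ---------------------------------------------------------------------------


def linear_predictor(params: InclusionModelParams, stratum: Stratum) -> float:
    """The log-probability of hospitalisation for a stratum."""
    c = params.coef
    died = int(stratum.died)
    eta = c["lg0"] + died * c["lg1"]
    e = stratum.ethnicity
    if e != REFERENCE_ETHNICITY:
        eta += c[f"la[{e}]"] + died * c[f"lb[{e}]"]
    if params.model_form == "eq2":
        wave2 = int(stratum.wave == 2)
        eta += wave2 * c["lg2"] + died * wave2 * c["lg3"]
        if e != REFERENCE_ETHNICITY:
            eta += wave2 * c[f"lc[{e}]"] + died * wave2 * c[f"ld[{e}]"]
    return eta


def predict_probability(
    params: InclusionModelParams, stratum: Stratum, check: bool = True
) -> float:
    """Predicted probability of hospitalisation, exp(linear predictor).

    With ``check=True`` (default) a value above 1 raises
    :class:`InvalidProbabilityError` — the signature of a misspecified
    parameter set under the log link.
    """
    p = math.exp(linear_predictor(params, stratum))
    if check and p > 1.0:
        raise InvalidProbabilityError(
            f"predicted probability {p:.6g} > 1 for stratum {stratum}"
        )
    return p


def stratum_of_record(record, model_form: str) -> Stratum:
    """Map a cohort row to its weighting stratum. Survival status comes from
    the ``died`` column if present, else from ``event_type == 'death'``."""
    keys = record.index if hasattr(record, "index") else record
    died = bool(record["died"]) if "died" in keys else record["event_type"] == "death"
    wave = int(record["wave"]) if model_form == "eq2" else 1
    return Stratum(record["ethnicity"], died, wave)


def derive_weights(params: InclusionModelParams, cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach inverse-probability-of-selection weights to a cohort.

    Each record's weight is the reciprocal of its stratum's predicted
    hospitalisation probability — weights are looked up per stratum, never
    refitted per record — so the weighted cohort stands in for the full
    community population. Returns a copy with a ``weight`` column.
    """
    if cohort.empty:
        out = cohort.copy()
        out["weight"] = pd.Series(dtype=float)
        return out
    required = {"ethnicity"} | ({"wave"} if params.model_form == "eq2" else set())
    missing = required - set(cohort.columns)
    if missing:
        raise ConfigurationError(f"cohort lacks columns {sorted(missing)}")
    if "died" in cohort.columns:
        died = cohort["died"].astype(bool)
    elif "event_type" in cohort.columns:
        died = cohort["event_type"] == "death"
    else:
        raise ConfigurationError("cohort needs a 'died' or 'event_type' column")

    waves = cohort["wave"].astype(int) if params.model_form == "eq2" else pd.Series(1, index=cohort.index)
    strata = pd.DataFrame({"ethnicity": cohort["ethnicity"], "died": died, "wave": waves})
    weights = np.empty(len(cohort))
    for (eth, d, w), idx in strata.groupby(
        ["ethnicity", "died", "wave"], observed=True
    ).groups.items():
        p = predict_probability(params, Stratum(eth, bool(d), int(w)))
        weights[cohort.index.get_indexer(idx)] = 1.0 / p
    out = cohort.copy()
    out["weight"] = weights
    return out
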