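"""Weighted cause-specific Cox models for death during hospitalisation.

Time to death is analysed with a Cox proportional hazards model in which
discharge is a competing event: discharge (like administrative censoring)
removes a patient from the risk set at their event time without a death,
i.e. the cause-specific hazard of death is modelled. Three iterations are
fitted: (1) unadjusted, ethnicity only; (2) adjusted for the nine baseline
covariates; (3) adjusted and weighted by the inverse probability of
selection. Variances are robust (sandwich) estimates throughout, which
remain valid under weighting.

The partial likelihood maximisation itself is delegated to lifelines
(Efron tie handling); this module owns the cause-specific event coding,
design construction (ethnicity and IMD quintile as categorical contrasts
with White / quintile 1 as references), weight plumbing, degeneracy checks
and result summarisation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .common import (
    COVARIATE_COLUMNS,
    ConfigurationError,
    ModelError,
    NON_REFERENCE_ETHNICITIES,
    REFERENCE_ETHNICITY,
)

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for confidence intervals.
Z95 = float(stats.norm.ppf(0.975))

ITERATION_NAMES = ("unadjusted", "adjusted", "adjusted_ipw")


@dataclass
class CoxResult:
    """Per-term hazard ratios with robust standard errors.

    ``table`` has one row per model term: ``log_hr``, ``hazard_ratio``,
    ``robust_se`` (of the log hazard ratio), ``ci_lower``/``ci_upper``
    (95%, normal approximation on the log scale) and ``p_value``.
    """

    table: pd.DataFrame
    n: int
    n_events: int
    weighted: bool
    converged: bool = True
    ties: str = "efron"
    metadata: dict = field(default_factory=dict)

    def hr(self, term: str) -> float:
        return float(self.table.loc[term, "hazard_ratio"])

    def log_hr(self, term: str) -> float:
        return float(self.table.loc[term, "log_hr"])

    def robust_se(self, term: str) -> float:
        return float(self.table.loc[term, "robust_se"])

    @property
    def empty(self) -> bool:
        return self.table.empty


def _empty_result(n: int, n_events: int, weighted: bool) -> CoxResult:
    cols = ["log_hr", "hazard_ratio", "robust_se", "ci_lower", "ci_upper", "p_value"]
    return CoxResult(
        table=pd.DataFrame(columns=cols), n=n, n_events=n_events,
        weighted=weighted, metadata={"note": "no estimable terms"},
    )


def build_design(
    cohort: pd.DataFrame,
    terms: list[str],
    imd_categorical: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Expand model terms into a numeric design.

    ``ethnicity`` becomes indicator columns ``ethnicity[<group>]`` against
    the White reference (only for groups present in the data);
    ``imd_quintile`` becomes ``imd[2..5]`` against quintile 1 unless
    ``imd_categorical`` is False (then entered as a single ordinal column).
    Other terms are taken as numeric columns. Returns (design, column names).
    """
    pieces, names = [], []
    for term in terms:
        if term == "ethnicity":
            present = [
                e for e in NON_REFERENCE_ETHNICITIES
                if (cohort["ethnicity"] == e).any()
            ]
            if not (cohort["ethnicity"] == REFERENCE_ETHNICITY).any() and present:
                logger.warning(
                    "reference ethnicity %r absent from cohort; contrasts are "
                    "against the remaining groups' baseline", REFERENCE_ETHNICITY,
                )
            for e in present:
                col = f"ethnicity[{e}]"
                pieces.append((cohort["ethnicity"] == e).astype(float).rename(col))
                names.append(col)
        elif term == "imd_quintile" and imd_categorical:
            for q in (2, 3, 4, 5):
                col = f"imd[{q}]"
                pieces.append((cohort["imd_quintile"] == q).astype(float).rename(col))
                names.append(col)
        else:
            if term not in cohort.columns:
                raise ConfigurationError(f"term {term!r} is not a cohort column")
            pieces.append(cohort[term].astype(float).rename(term))
            names.append(term)
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=cohort.index)
    return design, names


def _check_degeneracy(design: pd.DataFrame) -> None:
    """Fail loudly on constant or collinear columns rather than letting the
    optimiser silently struggle."""
    if design.shape[1] == 0:
        return
    X = design.to_numpy()
    constant = [c for c, v in zip(design.columns, X.std(axis=0)) if v == 0.0]
    if constant:
        raise ModelError(f"degenerate (constant) model terms: {constant}")
    centred = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centred)
    if rank < design.shape[1]:
        raise ModelError(
            f"collinear model terms: design rank {rank} < {design.shape[1]} "
            f"columns {list(design.columns)}"
        )


def _breslow_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-12,
    maxiter: int = 100,
):
    """Weighted Cox partial likelihood with Breslow tie handling.

    Newton-Raphson on the weighted Breslow log partial likelihood. Under
    Breslow ties, integer case weights are exactly equivalent to replicating
    records — the property Efron's correction does not share. Returns
    (beta, naive covariance, robust Lin-Wei sandwich covariance).
    """
    order = np.argsort(time, kind="stable")
    X, time, event, weights = X[order], time[order], event[order], weights[order]
    n, p = X.shape

    # risk set of i = {j : t_j >= t_i}; with ascending times these are the
    # suffix sums, extended across tie groups so equal times share risk sets
    _, first_idx, inverse = np.unique(time, return_index=True, return_inverse=True)

    def suffix_by_group(values):
        # suffix cumulative sum taken at the first index of each tie group
        suffix = np.cumsum(values[::-1], axis=0)[::-1]
        return suffix[first_idx][inverse]

    def loglik(beta):
        eta = X @ beta
        r = weights * np.exp(eta)
        S0 = suffix_by_group(r)
        return float(np.sum(weights[event] * (eta[event] - np.log(S0[event]))))

    event = event.astype(bool)
    beta = np.zeros(p)
    ll = loglik(beta)
    for _ in range(maxiter):
        eta = X @ beta
        r = weights * np.exp(eta)
        S0 = suffix_by_group(r)
        S1 = suffix_by_group(r[:, None] * X)
        xbar = S1 / S0[:, None]
        S2 = suffix_by_group(r[:, None, None] * X[:, :, None] * X[:, None, :])
        grad = np.einsum("i,ij->j", weights[event], X[event] - xbar[event])
        info = np.einsum(
            "i,ijk->jk",
            weights[event],
            S2[event] / S0[event, None, None]
            - xbar[event, :, None] * xbar[event, None, :],
        )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular information matrix in Breslow fit: {exc}") from exc
        new_beta, new_ll, halves = beta + step, None, 0
        while halves < 30:
            new_ll = loglik(new_beta)
            if new_ll >= ll - 1e-14:
                break
            new_beta = beta + (new_beta - beta) / 2.0
            halves += 1
        converged = np.max(np.abs(new_beta - beta)) < tol or abs(new_ll - ll) < tol
        beta, ll = new_beta, new_ll
        if converged:
            break
    else:
        raise ModelError(
            f"Breslow Cox fit did not converge; gradient norm "
            f"{np.linalg.norm(grad):.3g}"
        )

    # final quantities at the optimum
    eta = X @ beta
    r = weights * np.exp(eta)
    S0 = suffix_by_group(r)
    S1 = suffix_by_group(r[:, None] * X)
    xbar = S1 / S0[:, None]
    S2 = suffix_by_group(r[:, None, None] * X[:, :, None] * X[:, None, :])
    info = np.einsum(
        "i,ijk->jk",
        weights[event],
        S2[event] / S0[event, None, None]
        - xbar[event, :, None] * xbar[event, None, :],
    )
    naive_cov = np.linalg.inv(info)

    # Lin-Wei robust variance from per-record score residuals:
    # U_i = d_i (x_i - xbar(t_i)) - e^{eta_i} [x_i * cumA(t_i) - cumB(t_i)]
    # with hazard increments dL0(t_d) = (sum of death weights at t_d) / S0(t_d).
    death_w = np.where(event, weights, 0.0)
    dw_at = np.bincount(inverse, weights=death_w)
    S0_at = S0[first_idx]  # S0 per unique time
    dL0 = dw_at / S0_at
    xbar_at = xbar[first_idx]
    cumA = np.cumsum(dL0)[inverse]
    cumB = np.cumsum(xbar_at * dL0[:, None], axis=0)[inverse]
    U = np.where(event[:, None], X - xbar, 0.0) - np.exp(eta)[:, None] * (
        X * cumA[:, None] - cumB
    )
    WU = weights[:, None] * U
    robust_cov = naive_cov @ (WU.T @ WU) @ naive_cov
    return beta, naive_cov, robust_cov


def fit_weighted_cox(
    cohort: pd.DataFrame,
    terms: list[str],
    use_weights: bool = False,
    imd_categorical: bool = True,
    ties: str = "efron",
) -> CoxResult:
    """Fit the cause-specific Cox model for death.

    ``event = 1`` iff ``event_type == 'death'``; discharge and censoring end
    follow-up without an event. With ``use_weights``, per-record sampling
    weights (column ``weight``) enter the partial likelihood and the robust
    sandwich variance. With all weights equal to 1 the weighted fit equals
    the unweighted one.

    ``ties='efron'`` (default) delegates to lifelines; ``ties='breslow'``
    uses the internal Newton solver, under which integer case weights are
    exactly equivalent to record replication.
    """
    if ties not in ("efron", "breslow"):
        raise ConfigurationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if cohort.empty:
        raise ModelError("cannot fit a Cox model on an empty cohort")
    if (cohort["time_to_event"] <= 0).any():
        raise ConfigurationError("time_to_event must be positive for every record")
    event = (cohort["event_type"] == "death").astype(int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ModelError("no death events; the death hazard is unestimable")

    design, names = build_design(cohort, terms, imd_categorical=imd_categorical)
    if not names:
        warnings.warn("no estimable terms; returning an empty result", stacklevel=2)
        return _empty_result(len(cohort), n_events, use_weights)
    _check_degeneracy(design)

    if use_weights:
        if "weight" not in cohort.columns or cohort["weight"].isna().any():
            raise ConfigurationError(
                "use_weights requires a complete 'weight' column (run the "
                "weight-derivation step first)"
            )
        if (cohort["weight"] <= 0).any():
            raise ConfigurationError("weights must be positive")
        weights = cohort["weight"].to_numpy(dtype=float)
    else:
        weights = np.ones(len(cohort))

    if ties == "breslow":
        beta, _, robust_cov = _breslow_newton(
            design.to_numpy(dtype=float),
            cohort["time_to_event"].to_numpy(dtype=float),
            event.to_numpy(dtype=bool),
            weights,
        )
        log_hr = pd.Series(beta, index=names)
        robust_se = pd.Series(np.sqrt(np.diag(robust_cov)), index=names)
    else:
        frame = design.copy()
        frame["_time"] = cohort["time_to_event"].to_numpy(dtype=float)
        frame["_event"] = event.to_numpy()
        fit_kwargs = {"robust": True}
        if use_weights:
            frame["_weight"] = weights
            fit_kwargs["weights_col"] = "_weight"
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                # Non-integer sampling weights are exactly the intended use
                # here; lifelines' reminder about robust=True is satisfied.
                warnings.filterwarnings("ignore", message=".*weights.*", category=UserWarning)
                warnings.filterwarnings("ignore", category=RuntimeWarning)
                cph.fit(frame, duration_col="_time", event_col="_event", **fit_kwargs)
        except ConvergenceError as exc:
            raise ModelError(f"Cox partial likelihood did not converge: {exc}") from exc
        summary = cph.summary
        log_hr = summary["coef"]
        robust_se = summary["se(coef)"]  # sandwich SEs because robust=True
    table = pd.DataFrame(
        {
            "log_hr": log_hr,
            "hazard_ratio": np.exp(log_hr),
            "robust_se": robust_se,
            "ci_lower": np.exp(log_hr - Z95 * robust_se),
            "ci_upper": np.exp(log_hr + Z95 * robust_se),
            "p_value": 2.0 * stats.norm.sf(np.abs(log_hr / robust_se)),
        }
    )
    table.index.name = "term"
    return CoxResult(
        table=table,
        n=len(cohort),
        n_events=n_events,
        weighted=use_weights,
        ties=ties,
        metadata={"terms": names},
    )


def run_model_iterations(
    cohort: pd.DataFrame, imd_categorical: bool = True
) -> dict[str, CoxResult]:
    """The three model iterations of the ethnicity-mortality analysis.

    1. ``unadjusted``   — ethnicity only;
    2. ``adjusted``     — ethnicity + the nine baseline covariates;
    3. ``adjusted_ipw`` — as (2), weighted by inverse selection probability.
    """
    if cohort["ethnicity"].nunique() < 2:
        warnings.warn(
            "cohort contains a single ethnicity; ethnicity effects are "
            "unestimable", stacklevel=2,
        )
    if "weight" not in cohort.columns:
        raise ConfigurationError(
            "iteration 3 needs IPW weights; derive them before running the "
            "model iterations"
        )
    adjusted_terms = ["ethnicity", *COVARIATE_COLUMNS]
    return {
        "unadjusted": fit_weighted_cox(cohort, ["ethnicity"], use_weights=False,
                                       imd_categorical=imd_categorical),
        "adjusted": fit_weighted_cox(cohort, adjusted_terms, use_weights=False,
                                     imd_categorical=imd_categorical),
        "adjusted_ipw": fit_weighted_cox(cohort, adjusted_terms, use_weights=True,
                                         imd_categorical=imd_categorical),
    }


def summarise_hr(results: dict[str, CoxResult]) -> pd.DataFrame:
    """Forest-style long table: one row per (iteration, ethnicity term)."""
    rows = []
    for iteration, result in results.items():
        for term, r in result.table.iterrows():
            if not str(term).startswith("ethnicity["):
                continue
            rows.append(
                {
                    "iteration": iteration,
                    "ethnicity": str(term)[len("ethnicity["):-1],
                    "hazard_ratio": r["hazard_ratio"],
                    "ci_lower": r["ci_lower"],
                    "ci_upper": r["ci_upper"],
                    "p_value": r["p_value"],
                    "log_hr": r["log_hr"],
                    "robust_se": r["robust_se"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "iteration", "ethnicity", "hazard_ratio", "ci_lower", "ci_upper",
            "p_value", "log_hr", "robust_se",
        ],
    )


def format_hr(hr: float, lower: float, upper: float, p: float) -> str:
    """Results-text convention: ``HR = 1.06 (0.56, 2.00), p = 0.851``."""
    return f"HR = {hr:.2f} ({lower:.2f}, {upper:.2f}), p = {p:.3f}"


def forest_plot(summary: pd.DataFrame, path=None):
    """Forest plot of HRs by ethnicity and iteration (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    iterations = list(dict.fromkeys(summary["iteration"]))
    ethnicities = list(dict.fromkeys(summary["ethnicity"]))
    offsets = np.linspace(-0.25, 0.25, max(len(iterations), 1))
    markers = {"unadjusted": "o", "adjusted": "s", "adjusted_ipw": "^"}
    for off, iteration in zip(offsets, iterations):
        sub = summary[summary["iteration"] == iteration]
        y = [ethnicities.index(e) + off for e in sub["ethnicity"]]
        ax.errorbar(
            sub["hazard_ratio"], y,
            xerr=[sub["hazard_ratio"] - sub["ci_lower"],
                  sub["ci_upper"] - sub["hazard_ratio"]],
            fmt=markers.get(iteration, "o"), capsize=3, label=iteration,
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(range(len(ethnicities)))
    ax.set_yticklabels(ethnicities)
    ax.set_xlabel(f"Hazard ratio vs {REFERENCE_ETHNICITY} (log scale)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
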