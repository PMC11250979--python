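"""Structured misspecification of the inclusion model.

The inclusion model is fitted to *national* evidence but applied to a
*local* cohort, so its coefficients may be systematically off. This module
implements the quantitative bias analysis that stress-tests the weights:
each coefficient is shifted additively on the log scale by three graded
deltas — 50% (mild), 100% (the discrepancy suggested by local comparison
data) and 200% (extreme) — one target coefficient at a time, and the
resulting stratum probabilities are re-derived, validity-checked against
(0, 1], and passed back through the weighting and weighted survival fit.

Shifts that raise a survivor-stratum coefficient carry a mandatory
companion: a 100% downward shift of the death main effect (lg1 - 0.15).
Without it, died-stratum probabilities — already near the assumed 0.90 —
would exceed 1, so the companion makes room for the survivor-side increase.
The default grid ships as package data (YAML) and can be overridden.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .common import ConfigurationError, Stratum
from .inclusion import (
    InclusionModelParams,
    coefficient_names,
    linear_predictor,
    predict_probability,
)

logger = logging.getLogger(__name__)

LEVELS = (50, 100, 200)
INVALID_POLICIES = ("skip", "clip", "shrink")
_CLIP_EPS = 1e-9


@dataclass(frozen=True)
class MisspecificationScenario:
    """One cell of the sensitivity grid: an additive log-scale shift of a
    single coefficient, plus any mandated companion shifts."""

    scenario_id: str
    target_coefficient: str
    level: int  # percent label: 50, 100 or 200
    delta: float
    companion_deltas: dict[str, float] = field(default_factory=dict)

    def all_deltas(self) -> dict[str, float]:
        deltas = dict(self.companion_deltas)
        deltas[self.target_coefficient] = deltas.get(self.target_coefficient, 0.0) + self.delta
        return deltas


def load_default_grid() -> dict:
    """The bundled default grid specification (parsed YAML)."""
    text = (
        importlib.resources.files("colliderbias.data")
        .joinpath("misspecification_grid.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_grid(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def scenario_grid(
    model_form: str = "eq1", grid: dict | None = None
) -> list[MisspecificationScenario]:
    """Expand a grid specification into scenarios.

    For the single-wave model this is 8 coefficients x 3 levels = 24
    scenarios; the two-wave model adds the 8 wave-related coefficients for
    48. Within one coefficient the three deltas share sign and grow in
    magnitude. Unknown-ethnicity coefficients are never part of the grid.
    """
    if grid is None:
        grid = load_default_grid()
    companion = dict(grid.get("companion_deltas", {}))
    blocks = [grid["eq1"]]
    if model_form == "eq2":
        blocks.append(grid["eq2_extra"])
    elif model_form != "eq1":
        raise ConfigurationError(f"model_form must be 'eq1' or 'eq2', got {model_form!r}")

    valid_names = set(coefficient_names(model_form))
    scenarios = []
    for block in blocks:
        for coef_name, spec in block.items():
            if coef_name not in valid_names:
                raise ConfigurationError(
                    f"grid coefficient {coef_name!r} is not a {model_form} coefficient"
                )
            deltas = {int(k): float(v) for k, v in spec["deltas"].items()}
            if set(deltas) != set(LEVELS):
                raise ConfigurationError(
                    f"grid for {coef_name!r} must give deltas for levels {LEVELS}"
                )
            magnitudes = [abs(deltas[l]) for l in LEVELS]
            signs = {math.copysign(1, deltas[l]) for l in LEVELS}
            if len(signs) != 1 or not magnitudes[0] < magnitudes[1] < magnitudes[2]:
                raise ConfigurationError(
                    f"deltas for {coef_name!r} must share sign and grow in "
                    f"magnitude across levels {LEVELS}"
                )
            comp = dict(companion) if spec.get("companion", False) else {}
            for level in LEVELS:
                scenarios.append(
                    MisspecificationScenario(
                        scenario_id=f"{coef_name}@{level}%",
                        target_coefficient=coef_name,
                        level=level,
                        delta=deltas[level],
                        companion_deltas=comp,
                    )
                )
    return scenarios


def apply_scenario(
    params: InclusionModelParams, scenario: MisspecificationScenario
) -> InclusionModelParams:
    """Shift the target (and companion) log-coefficients; returns a new
    parameter set, leaving the original untouched."""
    return params.shifted(scenario.all_deltas())


def validate_probabilities(
    params: InclusionModelParams,
    strata: list[Stratum],
    baseline: InclusionModelParams | None = None,
) -> pd.DataFrame:
    """Predict every stratum probability and report validity.

    Returns one row per stratum with the probability under ``params``, a
    ``valid`` flag (probability in (0, 1]) and — when a ``baseline``
    parameter set is supplied — the probability before the shift and the
    direction of change. Report-only: downstream policy decides what to do
    with invalid scenarios.
    """
    rows = []
    for s in strata:
        p_after = predict_probability(params, s, check=False)
        row = {
            "ethnicity": s.ethnicity,
            "died": int(s.died),
            "wave": s.wave,
            "probability_after": p_after,
            "valid": 0.0 < p_after <= 1.0,
        }
        if baseline is not None:
            p_before = predict_probability(baseline, s, check=False)
            row["probability_before"] = p_before
            row["direction"] = (
                "unchanged" if math.isclose(p_after, p_before, rel_tol=1e-15)
                else ("increase" if p_after > p_before else "decrease")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def expected_direction(
    scenario: MisspecificationScenario, stratum: Stratum, model_form: str
) -> str:
    """The direction a scenario should move a stratum's probability, from
    the net shift it applies to that stratum's linear predictor."""
    zero = InclusionModelParams(
        model_form, dict.fromkeys(coefficient_names(model_form), 0.0)
    )
    shift = linear_predictor(zero.shifted(scenario.all_deltas()), stratum)
    if shift > 0:
        return "increase"
    if shift < 0:
        return "decrease"
    return "unchanged"


def resolve_invalid(
    params: InclusionModelParams,
    scenario: MisspecificationScenario,
    strata: list[Stratum],
    policy: str = "skip",
) -> tuple[InclusionModelParams | None, dict]:
    """Apply a scenario and handle out-of-range probabilities per policy.

    Policies:
      * ``skip``   — drop the scenario (returns ``None``) with a warning;
      * ``clip``   — keep the shifted parameters but cap each predicted
                     probability at 1 - eps when deriving weights (the cap
                     is recorded; prediction itself is left intact);
      * ``shrink`` — reduce the magnitude of the *target* delta (companions
                     fixed) to the largest value keeping all probabilities
                     in (0, 1].

    Returns (parameter set or None, metadata dict describing what was done).
    """
    if policy not in INVALID_POLICIES:
        raise ConfigurationError(f"invalid-probability policy must be one of {INVALID_POLICIES}")
    shifted = apply_scenario(params, scenario)
    report = validate_probabilities(shifted, strata, baseline=params)
    meta = {
        "scenario_id": scenario.scenario_id,
        "policy": policy,
        "n_invalid": int((~report["valid"]).sum()),
        "action": "none",
    }
    if report["valid"].all():
        return shifted, meta

    if policy == "skip":
        logger.warning(
            "scenario %s produces %d invalid stratum probabilities; skipped",
            scenario.scenario_id, meta["n_invalid"],
        )
        meta["action"] = "skipped"
        return None, meta

    if policy == "clip":
        meta["action"] = "clip_probabilities"
        meta["clip_at"] = 1.0 - _CLIP_EPS
        return shifted, meta

    # shrink: probabilities affected by the target delta scale as
    # A_s * exp(t) in the target delta t, so the largest valid |t| has a
    # closed form from the most extreme affected stratum.
    base_with_companions = params.shifted(scenario.companion_deltas)
    max_log_a = None
    for s in strata:
        direction = expected_direction(
            MisspecificationScenario("probe", scenario.target_coefficient, 100, 1.0),
            s, params.model_form,
        )
        if direction == "unchanged":
            continue  # target coefficient does not enter this stratum
        log_a = linear_predictor(base_with_companions, s)
        max_log_a = log_a if max_log_a is None else max(max_log_a, log_a)
    if max_log_a is None:
        raise ConfigurationError(
            f"target coefficient {scenario.target_coefficient!r} enters no stratum"
        )
    limit = math.log(1.0 - _CLIP_EPS) - max_log_a  # largest admissible positive delta
    if scenario.delta > 0:
        new_delta = min(scenario.delta, max(limit, 0.0))
    else:
        new_delta = scenario.delta  # negative deltas cannot push above 1
    shrunk = base_with_companions.shifted({scenario.target_coefficient: new_delta})
    still = validate_probabilities(shrunk, strata)
    if not still["valid"].all():
        # companions alone already break validity; nothing left to shrink
        logger.warning(
            "scenario %s invalid even at zero target delta; skipped",
            scenario.scenario_id,
        )
        meta["action"] = "skipped"
        return None, meta
    meta["action"] = "shrunk_delta"
    meta["delta_used"] = new_delta
    return shrunk, meta


def write_grid_yaml(grid: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(grid, fh, sort_keys=False)
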