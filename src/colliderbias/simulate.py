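"""Synthetic source population with a collider structure.

Generates a community population in which ethnicity raises the probability
of hospitalisation among survivors, death strongly raises the probability of
hospitalisation, and ethnicity modestly raises the probability of death —
the directed-acyclic-graph structure (ethnicity -> hospitalisation,
death -> hospitalisation, ethnicity -> death) under which restricting a
study to hospitalised patients induces collider bias.

The generator emits both views a real analysis would have:

* the "external" marginal summary per (ethnicity, wave) — population size,
  number hospitalised, number died — with the hospitalisation x survival
  cross-tabulation deliberately withheld, mirroring published national
  summary tables; and
* the patient-level hospitalised cohort, i.e. the collider-selected sample.

Survival status is simulated as a latent binary first, and the event time is
then drawn conditional on it (a mixture formulation). This makes the
per-stratum probabilities — the quantities the inclusion model must
recover — exactly controllable, at the cost of the cause-specific hazard
ratio only approximating the configured death-risk ratio (the approximation
is excellent while death risks are small; see the methods note).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .common import (
    COHORT_COLUMNS,
    ConfigurationError,
    ETHNICITIES,
    EVENT_TYPES,
    WAVES,
)

logger = logging.getLogger(__name__)

# Default survivor hospitalisation risks follow the magnitudes of published
# national (English primary-care) summary data: roughly 0.001-0.003 in wave 1
# with minority ethnicities at an elevated risk relative to White, and lower
# risks in wave 2. Expressed as White baseline x per-ethnicity multiplier.
_DEFAULT_ETHNICITY_PROPORTIONS = {
    # London-catchment-like diversity rather than national proportions.
    "White": 0.55,
    "Black": 0.15,
    "Asian": 0.15,
    "Mixed/Other": 0.08,
    "Unknown": 0.07,
}

_DEFAULT_HOSP_MULTIPLIERS_SURVIVOR = {
    "White": 1.0,
    "Black": 1.889,       # 0.00238 / 0.00126
    "Asian": 1.563,       # 0.00197 / 0.00126
    "Mixed/Other": 1.230, # 0.00155 / 0.00126
    "Unknown": 0.802,     # 0.00101 / 0.00126
}

_DEFAULT_DEATH_MULTIPLIERS = {
    "White": 1.0,
    "Black": 1.1,  # the "true" exposure -> outcome effect to be recovered
    "Asian": 1.0,
    "Mixed/Other": 1.0,
    "Unknown": 1.0,
}

_DEFAULT_COVARIATE_MODEL = {
    # Marginals loosely typical of an admitted adult COVID-19 cohort.
    # Binary covariates: prevalence, either a scalar or a per-ethnicity map.
    "age": {"mean": 65.0, "sd": 16.0, "min": 18.0, "max": 100.0},
    "sex": 0.55,
    "imd_quintile": [0.25, 0.25, 0.20, 0.15, 0.15],  # quintile 1 = most deprived
    "dnr": 0.15,
    "cardiovascular": 0.30,
    "copd": 0.10,
    "diabetes": 0.25,
    "liver": 0.03,
    "kidney": 0.15,
}

_DEFAULT_SURVIVAL_TIME_MODEL = {
    # Exponential event-time rates per day and an administrative horizon.
    "death_rate": 0.10,
    "discharge_rate": 0.125,
    "censor_horizon": 60.0,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic source population.

    Probabilities are composed multiplicatively: e.g. the death risk of a
    wave-2 person of ethnicity *e* is ``baseline_death_risk *
    death_risk_multipliers[e] * wave2_death_multiplier``. Generation fails
    with :class:`ConfigurationError` if any composed probability leaves
    [0, 1].
    """

    population_size: int = 200_000
    ethnicity_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ETHNICITY_PROPORTIONS)
    )
    wave_proportions: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.4}
    )
    baseline_death_risk: float = 0.005
    death_risk_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEATH_MULTIPLIERS)
    )
    baseline_hosp_risk_survivor: float = 0.00126
    hosp_risk_multipliers_survivor: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HOSP_MULTIPLIERS_SURVIVOR)
    )
    #: P(hospitalised | died), per ethnicity; uniform 0.90 by default,
    #: matching the base-analysis assumption that 90% of deaths occur after
    #: hospitalisation.
    hosp_prob_death: dict[str, float] = field(
        default_factory=lambda: {e: 0.90 for e in ETHNICITIES}
    )
    wave2_hosp_multiplier: float = 0.54   # 0.00068 / 0.00126
    wave2_death_multiplier: float = 1.0
    covariate_model: dict = field(
        default_factory=lambda: json.loads(json.dumps(_DEFAULT_COVARIATE_MODEL))
    )
    survival_time_model: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SURVIVAL_TIME_MODEL)
    )
    seed: int = 0

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.population_size <= 0:
            raise ConfigurationError("population_size must be positive")
        for name, props, keys in (
            ("ethnicity_proportions", self.ethnicity_proportions, ETHNICITIES),
            ("wave_proportions", self.wave_proportions, WAVES),
        ):
            if set(props) - set(keys):
                raise ConfigurationError(
                    f"{name} has unknown categories {set(props) - set(keys)}"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"{name} contains negative probabilities")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
        if not 0 <= self.baseline_death_risk < 1:
            raise ConfigurationError("baseline_death_risk must lie in [0, 1)")
        for eth in ETHNICITIES:
            for label, p in self._stratum_probabilities(eth).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"probability {label} for stratum ethnicity={eth!r} "
                        f"is {p:.6g}, outside [0, 1]"
                    )
        stm = self.survival_time_model
        if stm["death_rate"] <= 0 or stm["discharge_rate"] <= 0:
            raise ConfigurationError("event-time rates must be positive")
        if stm["censor_horizon"] <= 0:
            raise ConfigurationError("censor_horizon must be positive")

    def _stratum_probabilities(self, eth: str) -> dict[str, float]:
        """All composed probabilities touching ethnicity ``eth``."""
        out = {}
        for wave in WAVES:
            wd = self.wave2_death_multiplier if wave == 2 else 1.0
            wh = self.wave2_hosp_multiplier if wave == 2 else 1.0
            out[f"P(death | wave {wave})"] = (
                self.baseline_death_risk * self.death_risk_multipliers[eth] * wd
            )
            out[f"P(hosp | survived, wave {wave})"] = (
                self.baseline_hosp_risk_survivor
                * self.hosp_risk_multipliers_survivor[eth]
                * wh
            )
        out["P(hosp | died)"] = self.hosp_prob_death[eth]
        return out

    def death_risk(self, eth: str, wave: int) -> float:
        wd = self.wave2_death_multiplier if wave == 2 else 1.0
        return self.baseline_death_risk * self.death_risk_multipliers[eth] * wd

    def hosp_risk_survivor(self, eth: str, wave: int) -> float:
        wh = self.wave2_hosp_multiplier if wave == 2 else 1.0
        return (
            self.baseline_hosp_risk_survivor
            * self.hosp_risk_multipliers_survivor[eth]
            * wh
        )

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "wave_proportions" in d:
            d["wave_proportions"] = {int(k): v for k, v in d["wave_proportions"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -- generation ----------------------------------------------------------


def _draw_binary(rng, n, spec, ethnicity: np.ndarray) -> np.ndarray:
    """Bernoulli draw with prevalence either scalar or per-ethnicity."""
    if isinstance(spec, Mapping):
        p = np.array([spec[e] for e in ethnicity])
    else:
        p = float(spec)
    return (rng.random(n) < p).astype(np.int64)


def _draw_covariates(rng, ethnicity: np.ndarray, model: Mapping) -> dict[str, np.ndarray]:
    n = len(ethnicity)
    age_spec = model["age"]
    age = rng.normal(age_spec["mean"], age_spec["sd"], size=n)
    age = np.clip(age, age_spec["min"], age_spec["max"]).round(1)
    imd = rng.choice(np.arange(1, 6), size=n, p=np.asarray(model["imd_quintile"]))
    out = {"age": age, "imd_quintile": imd}
    for cov in ("sex", "dnr", "cardiovascular", "copd", "diabetes", "liver", "kidney"):
        out[cov] = _draw_binary(rng, n, model[cov], ethnicity)
    return out


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full (community) population, one row per person.

    Causal ordering: ethnicity and wave are drawn marginally; death is drawn
    conditional on (ethnicity, wave); hospitalisation conditional on
    (ethnicity, wave, died); the event time conditional on survival status.
    Identical config (including ``seed``) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.population_size

    eth_labels = list(config.ethnicity_proportions)
    ethnicity = rng.choice(
        eth_labels, size=n, p=[config.ethnicity_proportions[e] for e in eth_labels]
    )
    wave_labels = sorted(config.wave_proportions)
    wave = rng.choice(
        wave_labels, size=n, p=[config.wave_proportions[w] for w in wave_labels]
    ).astype(np.int64)

    p_death = np.array([config.death_risk(e, w) for e, w in zip(ethnicity, wave)])
    died = (rng.random(n) < p_death).astype(np.int64)

    p_hosp = np.where(
        died == 1,
        np.array([config.hosp_prob_death[e] for e in ethnicity]),
        np.array([config.hosp_risk_survivor(e, w) for e, w in zip(ethnicity, wave)]),
    )
    hospitalised = (rng.random(n) < p_hosp).astype(np.int64)

    stm = config.survival_time_model
    horizon = float(stm["censor_horizon"])
    raw_time = np.where(
        died == 1,
        rng.exponential(1.0 / stm["death_rate"], size=n),
        rng.exponential(1.0 / stm["discharge_rate"], size=n),
    )
    censored = raw_time > horizon
    time_to_event = np.minimum(raw_time, horizon)
    event_type = np.where(
        censored, "censored", np.where(died == 1, "death", "discharge")
    )

    frame = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "ethnicity": ethnicity,
            "wave": wave,
            "died": died,
            "hospitalised": hospitalised,
            "time_to_event": time_to_event,
            "event_type": pd.Categorical(event_type, categories=list(EVENT_TYPES)),
        }
    )
    for name, values in _draw_covariates(rng, ethnicity, config.covariate_model).items():
        frame[name] = values
    return frame


def derive_external_summary(population: pd.DataFrame) -> pd.DataFrame:
    """Tally the marginal summary per (ethnicity, wave).

    Returns one row per (ethnicity, wave) — including empty strata as zero
    rows — with columns ``n_total``, ``n_hospitalised``, ``n_died``. The
    hospitalisation x survival cross-tabulation is deliberately *not*
    reported: the downstream evidence module must reconstruct it under an
    assumed hospitalised-death fraction, exactly as with real published
    marginal tables.
    """
    if population.empty:
        raise ConfigurationError("population is empty; nothing to summarise")
    idx = pd.MultiIndex.from_product(
        [list(ETHNICITIES), list(WAVES)], names=["ethnicity", "wave"]
    )
    grouped = (
        population.groupby(["ethnicity", "wave"], observed=True)
        .agg(
            n_total=("id", "size"),
            n_hospitalised=("hospitalised", "sum"),
            n_died=("died", "sum"),
        )
        .reindex(idx, fill_value=0)
        .reset_index()
    )
    return grouped.astype({"n_total": int, "n_hospitalised": int, "n_died": int})


def restrict_to_hospitalised(population: pd.DataFrame) -> pd.DataFrame:
    """Condition on hospitalisation: the collider-selection step.

    Returns the patient-level cohort (persons with ``hospitalised == 1``),
    dropping the now-constant ``hospitalised`` column. An empty cohort is
    permitted but warned about.
    """
    cohort = population.loc[population["hospitalised"] == 1].drop(
        columns=["hospitalised"]
    )
    if cohort.empty:
        warnings.warn("restriction produced an empty cohort", stacklevel=2)
        logger.warning("restriction produced an empty cohort")
    return cohort.reset_index(drop=True)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, index=False)


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
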