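"""Shared vocabulary for the collider-bias correction pipeline.

The analysis concerns a hospitalised COVID-19 cohort in which both the
exposure (ethnic group) and the outcome (death during admission) influence
the probability of hospitalisation — the conditioning variable that induces
collider bias. Every module indexes external evidence, inclusion-model
coefficients and patient weights by the same stratum: (ethnicity, survival
status, epidemic wave).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Ethnic group categories, ONS-style broad groupings. "White" is the
#: reference category throughout; "Unknown" absorbs unreported ethnicity.
ETHNICITIES: tuple[str, ...] = ("White", "Black", "Asian", "Mixed/Other", "Unknown")
REFERENCE_ETHNICITY: str = "White"
NON_REFERENCE_ETHNICITIES: tuple[str, ...] = ("Black", "Asian", "Mixed/Other", "Unknown")

#: Epidemic waves: wave 1 up to 31 Aug 2020, wave 2 from 1 Sep 2020.
#: Wave 1 is the reference; the wave indicator equals 1 for wave 2.
WAVES: tuple[int, ...] = (1, 2)

EVENT_TYPES: tuple[str, ...] = ("death", "discharge", "censored")

#: The nine baseline covariates of the survival models, in model order.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age",
    "sex",
    "imd_quintile",
    "dnr",
    "cardiovascular",
    "copd",
    "diabetes",
    "liver",
    "kidney",
)

#: Columns of a patient-level cohort table (weight added by the IPW step).
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "ethnicity",
    "wave",
    "died",
    "time_to_event",
    "event_type",
) + COVARIATE_COLUMNS


class ColliderBiasError(Exception):
    """Base class for pipeline errors; ``exit_code`` drives the CLI."""

    exit_code = 1


class ConfigurationError(ColliderBiasError):
    """Invalid configuration, paths or coefficient names."""

    exit_code = 2


class EvidenceInconsistencyError(ColliderBiasError):
    """External summary counts that contradict each other (e.g. a negative
    survivor hospitalisation count after splitting deaths out of the
    marginal, or a stratum risk above 1)."""

    exit_code = 3


class ModelError(ColliderBiasError):
    """Model fitting or prediction failure."""

    exit_code = 4


class InvalidProbabilityError(ModelError):
    """A predicted inclusion probability left the (0, 1] interval,
    signalling a misspecified parameter set."""


@dataclass(frozen=True)
class Stratum:
    """The (ethnicity, survival status, wave) cell indexing the external
    evidence and each patient's inverse probability weight."""

    ethnicity: str
    died: bool
    wave: int = 1

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ConfigurationError(
                f"unknown ethnicity category {self.ethnicity!r}; "
                f"expected one of {ETHNICITIES}"
            )
        if self.wave not in WAVES:
            raise ConfigurationError(f"wave must be one of {WAVES}, got {self.wave!r}")
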