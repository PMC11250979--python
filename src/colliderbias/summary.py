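"""External summary evidence: strata construction and the risk calculus.

Published national summary tables report, per ethnic group and wave, the
population denominator, the number hospitalised with COVID-19 and the number
who died — but not the hospitalisation x survival cross-tabulation. The
inclusion model, however, needs the risk of hospitalisation *within* each
(ethnicity, survival status, wave) stratum. :func:`build_strata_from_marginals`
closes that gap under the assumption that a fixed fraction of deaths (0.90 in
the base analysis) occurred after hospitalisation, regardless of ethnicity.

The same module implements the comparison calculus used to calibrate the
misspecification sensitivity grid: risks (cases / population), risk ratios
against a stated reference group, and differences of log-metrics between a
local catchment area and the national evidence. A transcription of the
published first-wave national-vs-catchment comparison is bundled so the
calculus can be exercised (and its printed values recomputed) without any
external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .common import ConfigurationError, EvidenceInconsistencyError, ETHNICITIES

#: Default assumed share of COVID-19 deaths occurring after hospitalisation.
DEFAULT_HOSPITALISED_DEATH_FRACTION = 0.90

# ---------------------------------------------------------------------------
# Bundled published evidence (transcribed printed values)
# ---------------------------------------------------------------------------

#: Survivor hospitalisation risks per (ethnicity, wave) from the published
#: national primary-care analysis. These are the "hypothesised risk of
#: hospitalisation" inputs of the base analysis; the death-stratum risk is
#: the assumed hospitalised-death fraction (0.90) in every group.
NATIONAL_SURVIVOR_RISKS: dict[tuple[str, int], float] = {
    ("White", 1): 0.00126,
    ("Black", 1): 0.00238,
    ("Asian", 1): 0.00197,
    ("Mixed/Other", 1): 0.00155,
    ("Unknown", 1): 0.00101,
    ("White", 2): 0.00068,
    ("Black", 2): 0.00083,
    ("Asian", 2): 0.00140,
    ("Mixed/Other", 2): 0.00070,
    ("Unknown", 2): 0.00052,
}

#: First-wave comparison between the national evidence and the local
#: hospital catchment area (NHS-reported cases or analysed cohort over ONS
#: population estimates; ONS place-of-death data for the death row). Each
#: entry carries the printed risks and, where the source printed them, the
#: risk ratios it derived from unrounded counts. ``informs`` names the
#: inclusion-model coefficient whose misspecification the row calibrates.
WAVE1_CATCHMENT_COMPARISON: tuple[dict, ...] = (
    {
        "label": "overall",
        "metric": "risk",
        "risk_national": 0.00187,
        "risk_local": 0.00177,
        "informs": "lg0",
    },
    {
        "label": "death_vs_no_death",
        "metric": "rr",
        "risk_national": 0.90,        # assumed hospitalised-death fraction
        "risk_local": 0.76359734,     # share of local COVID deaths in hospital
        "reference_risk_national": 0.00121,  # no-death hospitalisation risk
        "reference_risk_local": 0.00104,
        "informs": "lg1",
    },
    {
        "label": "Black",
        "metric": "rr",
        "risk_national": 0.00307,
        "risk_local": 0.00118,
        "reference_risk_national": 0.00185,  # White
        "reference_risk_local": 0.00047,
        "rr_local_printed": 2.48,  # source computed RRs before rounding risks
        "informs": "la[Black]",
    },
    {
        "label": "Asian",
        "metric": "rr",
        "risk_national": 0.00257,
        "risk_local": 0.00089,
        "reference_risk_national": 0.00185,
        "reference_risk_local": 0.00047,
        "rr_local_printed": 1.87,
        "informs": "la[Asian]",
    },
    {
        "label": "Mixed/Other",
        "metric": "rr",
        "risk_national": 0.00188,
        "risk_local": 0.00054,
        "reference_risk_national": 0.00185,
        "reference_risk_local": 0.00047,
        "rr_local_printed": 1.14,
        "informs": "la[Mixed/Other]",
    },
)


# ---------------------------------------------------------------------------
# Strata construction
# ---------------------------------------------------------------------------


def build_strata_from_marginals(
    marginals: pd.DataFrame,
    hospitalised_death_fraction: float = DEFAULT_HOSPITALISED_DEATH_FRACTION,
    rounding: str = "fractional",
) -> pd.DataFrame:
    """Split marginal (ethnicity, wave) counts into survival-status strata.

    For each marginal row with counts ``n_total``, ``n_hospitalised``,
    ``n_died``, emit two strata:

    * died:      ``n_at_risk = n_died``,
      ``n_hospitalised = f * n_died``;
    * survived:  ``n_at_risk = n_total - n_died``,
      ``n_hospitalised = n_hospitalised_marginal - f * n_died``;

    where ``f`` is the hospitalised-death fraction. Counts stay fractional
    by default (the saturated fit consumes risks, and rounding biases small
    strata); ``rounding="integer"`` rounds the died-stratum count to the
    nearest integer before differencing, for count-based fitters.

    Raises
    ------
    EvidenceInconsistencyError
        If the implied survivor hospitalisation count is negative — the
        assumed fraction is inconsistent with the marginal counts.
    ConfigurationError
        If the fraction leaves [0, 1] or required columns are missing.
    """
    if not 0.0 <= hospitalised_death_fraction <= 1.0:
        raise ConfigurationError(
            f"hospitalised_death_fraction must lie in [0, 1], "
            f"got {hospitalised_death_fraction}"
        )
    if rounding not in ("fractional", "integer"):
        raise ConfigurationError(f"unknown rounding mode {rounding!r}")
    required = {"ethnicity", "n_total", "n_hospitalised", "n_died"}
    missing = required - set(marginals.columns)
    if missing:
        raise ConfigurationError(f"marginal table lacks columns {sorted(missing)}")

    has_wave = "wave" in marginals.columns
    rows = []
    for _, row in marginals.iterrows():
        n_total, n_hosp, n_died = row["n_total"], row["n_hospitalised"], row["n_died"]
        stratum_name = row["ethnicity"] if not has_wave else (
            f"{row['ethnicity']}/wave {row['wave']}"
        )
        if n_died > n_total or n_hosp > n_total:
            raise EvidenceInconsistencyError(
                f"stratum {stratum_name}: counts exceed the denominator"
            )
        hosp_died = hospitalised_death_fraction * n_died
        if rounding == "integer":
            hosp_died = round(hosp_died)
        hosp_survived = n_hosp - hosp_died
        if hosp_survived < 0:
            raise EvidenceInconsistencyError(
                f"stratum {stratum_name}: implied survivor hospitalisation "
                f"count {hosp_survived:.6g} is negative "
                f"(n_hospitalised={n_hosp}, fraction x n_died={hosp_died:.6g})"
            )
        base = {"ethnicity": row["ethnicity"]}
        if has_wave:
            base["wave"] = int(row["wave"])
        rows.append({**base, "died": 1, "n_at_risk": float(n_died),
                     "n_hospitalised": float(hosp_died)})
        rows.append({**base, "died": 0, "n_at_risk": float(n_total - n_died),
                     "n_hospitalised": float(hosp_survived)})

    strata = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        strata["risk"] = np.where(
            strata["n_at_risk"] > 0,
            strata["n_hospitalised"] / strata["n_at_risk"],
            np.nan,
        )
    return strata


def strata_table_from_risks(
    survivor_risks: dict[tuple[str, int], float] | dict[str, float] | None = None,
    death_risk: float = DEFAULT_HOSPITALISED_DEATH_FRACTION,
    waves: tuple[int, ...] = (1,),
    n_at_risk: float | None = None,
) -> pd.DataFrame:
    """Assemble a strata table directly from per-stratum risks.

    Convenience for working from published risk tables (rather than raw
    counts): survivor risks are given per (ethnicity, wave) — or per
    ethnicity for a single-wave table — and every died stratum is assigned
    ``death_risk``. ``n_at_risk`` (if given) is attached uniformly so that
    standard errors can be computed; risks are what the saturated fit uses.
    Defaults to the bundled national wave-1 risks.
    """
    rows = []
    for wave in waves:
        for eth in ETHNICITIES:
            if survivor_risks is None:
                risk = NATIONAL_SURVIVOR_RISKS[(eth, wave)]
            else:
                key = (eth, wave) if (eth, wave) in survivor_risks else eth
                risk = survivor_risks[key]
            for died, r in ((0, risk), (1, death_risk)):
                rows.append({
                    "ethnicity": eth, "wave": wave, "died": died,
                    "n_at_risk": np.nan if n_at_risk is None else float(n_at_risk),
                    "n_hospitalised": np.nan if n_at_risk is None else float(n_at_risk) * r,
                    "risk": r,
                })
    return pd.DataFrame(rows)


def collapse_ethnicities(table: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Collapse fine-grained ethnicity categories (e.g. a 16-category source)
    into the analysis categories by summing counts. ``mapping`` sends each
    source category to one of the analysis categories."""
    unknown_targets = set(mapping.values()) - set(ETHNICITIES)
    if unknown_targets:
        raise ConfigurationError(
            f"mapping targets {sorted(unknown_targets)} are not analysis categories"
        )
    out = table.copy()
    try:
        out["ethnicity"] = out["ethnicity"].map(lambda e: mapping[e])
    except KeyError as exc:
        raise ConfigurationError(f"no mapping for source category {exc}") from exc
    keys = [c for c in ("ethnicity", "wave") if c in out.columns]
    return out.groupby(keys, as_index=False).sum(numeric_only=True)


# ---------------------------------------------------------------------------
# Comparison calculus
# ---------------------------------------------------------------------------


def compute_risk(cases: float, population: float) -> float:
    """Risk = cases / population. Zero cases in a nonzero population is risk
    zero; a zero population is undefined regardless of cases."""
    if population <= 0:
        raise EvidenceInconsistencyError(
            f"risk undefined for population={population} (cases={cases})"
        )
    if cases < 0:
        raise EvidenceInconsistencyError(f"negative case count {cases}")
    return cases / population


def compute_risk_ratio(risk: float, reference_risk: float) -> float:
    """Risk ratio against a stated reference group."""
    if reference_risk <= 0:
        raise EvidenceInconsistencyError(
            f"risk ratio undefined for reference_risk={reference_risk}"
        )
    if risk < 0:
        raise EvidenceInconsistencyError(f"negative risk {risk}")
    return risk / reference_risk


def compare_ln(metric_local: float, metric_reference: float) -> float:
    """ln(local) - ln(reference): the log-scale discrepancy between a local
    metric (risk or RR) and the external reference value. Its sign gives the
    direction, its magnitude the size, of the suggested misspecification."""
    if metric_local <= 0 or metric_reference <= 0:
        raise EvidenceInconsistencyError(
            f"log comparison requires positive metrics, got "
            f"({metric_local}, {metric_reference})"
        )
    return math.log(metric_local) - math.log(metric_reference)


@dataclass(frozen=True)
class RiskComparison:
    """One row of the local-vs-national comparison: the metric (risk or RR)
    on both sides and the log-scale difference that calibrates the
    misspecification of the coefficient named in ``informs``."""

    label: str
    metric: str                 # "risk" or "rr"
    risk_local: float
    risk_reference: float
    rr_local: float | None
    rr_reference: float | None
    ln_diff: float
    informs: str


def risk_comparison_row(entry: dict) -> RiskComparison:
    """Evaluate one bundled comparison entry into a :class:`RiskComparison`.

    For RR rows, each side's RR is computed from its printed risks unless the
    source printed an RR it derived from unrounded counts
    (``rr_local_printed``), in which case that value is honoured.
    """
    metric = entry["metric"]
    r_nat, r_loc = entry["risk_national"], entry["risk_local"]
    if metric == "risk":
        rr_nat = rr_loc = None
        ln_diff = compare_ln(r_loc, r_nat)
    else:
        rr_nat = compute_risk_ratio(r_nat, entry["reference_risk_national"])
        rr_loc = entry.get("rr_local_printed")
        if rr_loc is None:
            rr_loc = compute_risk_ratio(r_loc, entry["reference_risk_local"])
        ln_diff = compare_ln(rr_loc, rr_nat)
    return RiskComparison(
        label=entry["label"], metric=metric,
        risk_local=r_loc, risk_reference=r_nat,
        rr_local=rr_loc, rr_reference=rr_nat,
        ln_diff=ln_diff, informs=entry["informs"],
    )


def wave1_catchment_comparison() -> pd.DataFrame:
    """The bundled first-wave national-vs-catchment comparison, evaluated.

    Returns one row per comparison with the computed risk ratios and
    ln-differences at full precision (round for display only).
    """
    rows = [risk_comparison_row(e) for e in WAVE1_CATCHMENT_COMPARISON]
    return pd.DataFrame([r.__dict__ for r in rows])


def comparison_report_markdown(comparison: pd.DataFrame) -> str:
    """Render a comparison table as Markdown (2 d.p. for log differences,
    matching conventional display precision)."""
    lines = [
        "| Comparison | National risk | Local risk | National RR | Local RR | ln diff | Informs |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in comparison.iterrows():
        fmt = lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.4g}"
        lines.append(
            f"| {r['label']} | {fmt(r['risk_reference'])} | {fmt(r['risk_local'])} "
            f"| {fmt(r['rr_reference'])} | {fmt(r['rr_local'])} "
            f"| {r['ln_diff']:.2f} | {r['informs']} |"
        )
    return "\n".join(lines)


def read_marginals_csv(path) -> pd.DataFrame:
    """Read a marginal summary CSV (ethnicity, [wave], n_total,
    n_hospitalised, n_died)."""
    table = pd.read_csv(path)
    required = {"ethnicity", "n_total", "n_hospitalised", "n_died"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(
            f"summary CSV {path} lacks columns {sorted(missing)}"
        )
    return table
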