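"""End-to-end orchestration of the collider-bias-corrected analysis.

Stage chain: simulate (or ingest) -> external summary -> strata table ->
inclusion-model fit -> inverse probability weights -> three survival model
iterations -> optional misspecification sensitivity grid. Every stage
persists its artifact (CSV/JSON) under the output directory together with a
run manifest (seed, config hash, package version), so that a rerun with the
same configuration and seed reproduces every numeric output exactly and a
resumed run can reload completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from importlib.metadata import PackageNotFoundError, version as _pkg_version

from .common import ConfigurationError, ETHNICITIES, Stratum, WAVES
from .inclusion import (
    InclusionModelParams,
    derive_weights,
    fit_inclusion_model,
)
from .misspecification import (
    load_default_grid,
    load_grid,
    resolve_invalid,
    scenario_grid,
)
from .simulate import (
    SimulationConfig,
    derive_external_summary,
    restrict_to_hospitalised,
    simulate_population,
    write_cohort_csv,
    write_summary_csv,
)
from .summary import (
    DEFAULT_HOSPITALISED_DEATH_FRACTION,
    build_strata_from_marginals,
    read_marginals_csv,
)
from .survival import fit_weighted_cox, run_model_iterations, summarise_hr
from .common import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)

try:
    _version = _pkg_version("colliderbias")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _version = "0+unknown"

_CLIP_EPS = 1e-9


def _read_csv(path) -> pd.DataFrame:
    # round_trip parsing: reloaded artifacts carry bit-identical floats, so
    # resumed stages reproduce the original results exactly
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class AnalysisConfig:
    """Configuration of a full run.

    ``mode='synthetic'`` simulates the source population from
    ``simulation``; ``mode='user-data'`` reads the marginal summary and
    patient cohort from ``summary_path`` / ``cohort_path`` CSVs.
    """

    mode: str = "synthetic"
    summary_path: str | None = None
    cohort_path: str | None = None
    model_form: str = "eq1"
    hospitalised_death_fraction: float = DEFAULT_HOSPITALISED_DEATH_FRACTION
    sensitivity: bool = False
    scenario_grid_path: str | None = None
    invalid_policy: str = "skip"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    output_dir: str = "colliderbias-output"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'user-data', got {self.mode!r}")
        if self.mode == "user-data":
            for label, path in (("summary_path", self.summary_path),
                                ("cohort_path", self.cohort_path)):
                if path is None:
                    raise ConfigurationError(f"user-data mode requires {label}")
                if not Path(path).exists():
                    raise ConfigurationError(f"{label} {path!r} does not exist")
        if self.scenario_grid_path is not None and not Path(self.scenario_grid_path).exists():
            raise ConfigurationError(
                f"scenario_grid_path {self.scenario_grid_path!r} does not exist"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d) -> "AnalysisConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        # output_dir is where results land, not what they are: excluded so
        # that relocated outputs still match their manifest
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _analysis_strata(model_form: str) -> list[Stratum]:
    waves = WAVES if model_form == "eq2" else (1,)
    return [
        Stratum(e, bool(d), w) for e in ETHNICITIES for d in (0, 1) for w in waves
    ]


def _seeded_config(config: AnalysisConfig) -> SimulationConfig:
    """Derive the simulation seed from the top-level seed (single source of
    randomness, split by stream index)."""
    child = np.random.SeedSequence(config.seed, spawn_key=(0,))
    sim = SimulationConfig.from_dict(config.simulation.to_dict())
    sim.seed = int(child.generate_state(1)[0] % (2**31))
    return sim


def run_analysis(config: AnalysisConfig, resume: bool = False) -> dict:
    """Execute the stage chain; returns the in-memory artifact bundle.

    Persisted under ``config.output_dir``: external summary and cohort CSVs
    (synthetic mode), the strata table, the fitted parameters (JSON), the
    weighted cohort, the three Cox result tables, the HR summary and a run
    manifest. With ``resume=True`` and a manifest whose config hash matches,
    completed artifacts are reloaded instead of recomputed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    eq2 = config.model_form == "eq2"

    resumable = False
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        resumable = manifest.get("config_hash") == config.config_hash()
        if not resumable:
            logger.warning("existing manifest does not match config; recomputing")

    def _stage(path: Path, compute, read, write):
        if resumable and path.exists():
            logger.info("resume: reusing %s", path.name)
            return read(path)
        artifact = compute()
        write(artifact, path)
        return artifact

    # -- inputs ----------------------------------------------------------
    if config.mode == "synthetic":
        sim = _seeded_config(config)
        population = simulate_population(sim)
        marginals = _stage(
            out / "external_summary.csv",
            lambda: derive_external_summary(population),
            _read_csv, write_summary_csv,
        )
        cohort = _stage(
            out / "cohort.csv",
            lambda: restrict_to_hospitalised(population),
            _read_csv, write_cohort_csv,
        )
    else:
        marginals = read_marginals_csv(config.summary_path)
        cohort = pd.read_csv(config.cohort_path)
        missing = ({"ethnicity", "time_to_event", "event_type"} | set(COVARIATE_COLUMNS)) - set(cohort.columns)
        if missing:
            raise ConfigurationError(f"cohort CSV lacks columns {sorted(missing)}")

    if eq2 and "wave" not in cohort.columns:
        raise ConfigurationError("eq2 requires a wave column in the cohort")
    if eq2 and "wave" not in marginals.columns:
        raise ConfigurationError("eq2 requires a wave column in the summary")
    if not eq2:
        # single-wave analysis: restrict both views to wave 1 when waves exist
        if "wave" in marginals.columns:
            marginals = marginals[marginals["wave"] == 1]
        if "wave" in cohort.columns:
            cohort = cohort[cohort["wave"] == 1].reset_index(drop=True)

    # -- evidence and inclusion model ------------------------------------
    strata = _stage(
        out / "strata_table.csv",
        lambda: build_strata_from_marginals(
            marginals, config.hospitalised_death_fraction
        ),
        _read_csv, lambda a, p: a.to_csv(p, index=False),
    )
    params = fit_inclusion_model(strata, config.model_form)
    params.to_json(out / "inclusion_params.json")

    weighted_cohort = _stage(
        out / "weighted_cohort.csv",
        lambda: derive_weights(params, cohort),
        _read_csv, write_cohort_csv,
    )

    # -- survival iterations ---------------------------------------------
    results = run_model_iterations(weighted_cohort)
    for name, result in results.items():
        result.table.to_csv(out / f"cox_{name}.csv")
    hr_summary = summarise_hr(results)
    hr_summary.to_csv(out / "hr_summary.csv", index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": _version,
        "model_form": config.model_form,
        "hospitalised_death_fraction": config.hospitalised_death_fraction,
        "n_cohort": int(len(weighted_cohort)),
        "n_events": int((weighted_cohort["event_type"] == "death").sum()),
        "artifacts": sorted(
            p.name for p in out.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle = {
        "marginals": marginals,
        "strata": strata,
        "params": params,
        "cohort": weighted_cohort,
        "results": results,
        "hr_summary": hr_summary,
        "manifest": manifest,
    }
    logger.info(
        "analysis complete: n=%d, events=%d, model=%s",
        manifest["n_cohort"], manifest["n_events"], config.model_form,
    )
    return bundle


def run_sensitivity(config: AnalysisConfig, base: dict | None = None) -> dict:
    """Run the misspecification grid against a completed base analysis.

    For every scenario: shift the fitted coefficients, validity-check the
    predicted stratum probabilities, apply the configured invalid-probability
    policy, re-derive weights and refit the weighted (adjusted + IPW)
    iteration. Emits a long-format HR table keyed by (scenario_id,
    ethnicity), the per-stratum validity report and scenario metadata;
    invalid scenarios are handled per policy and recorded, never dropped
    silently.
    """
    if base is None:
        base = run_analysis(config, resume=True)
    out = Path(config.output_dir)
    params: InclusionModelParams = base["params"]
    cohort = base["cohort"]
    strata_list = _analysis_strata(config.model_form)
    grid_spec = (
        load_grid(config.scenario_grid_path)
        if config.scenario_grid_path
        else load_default_grid()
    )
    scenarios = scenario_grid(config.model_form, grid_spec)

    adjusted_terms = ["ethnicity", *COVARIATE_COLUMNS]
    rows, meta_rows, validity_rows = [], [], []
    for scenario in scenarios:
        shifted, meta = resolve_invalid(
            params, scenario, strata_list, policy=config.invalid_policy
        )
        meta.update(
            target_coefficient=scenario.target_coefficient, level=scenario.level,
            delta=scenario.delta,
        )
        meta_rows.append(meta)
        from .misspecification import apply_scenario, validate_probabilities

        report = validate_probabilities(
            apply_scenario(params, scenario), strata_list, baseline=params
        )
        report.insert(0, "scenario_id", scenario.scenario_id)
        validity_rows.append(report)
        if shifted is None:
            continue

        reweighted = derive_weights(shifted, cohort.drop(columns=["weight"]))
        if meta.get("action") == "clip_probabilities":
            # cap implied probabilities at 1 - eps, i.e. floor the weights
            reweighted["weight"] = np.maximum(
                reweighted["weight"], 1.0 / (1.0 - _CLIP_EPS)
            )
        result = fit_weighted_cox(reweighted, adjusted_terms, use_weights=True)
        for term, r in result.table.iterrows():
            if not str(term).startswith("ethnicity["):
                continue
            rows.append(
                {
                    "scenario_id": scenario.scenario_id,
                    "target_coefficient": scenario.target_coefficient,
                    "level": scenario.level,
                    "delta": scenario.delta,
                    "ethnicity": str(term)[len("ethnicity["):-1],
                    "hazard_ratio": r["hazard_ratio"],
                    "ci_lower": r["ci_lower"],
                    "ci_upper": r["ci_upper"],
                    "p_value": r["p_value"],
                    "log_hr": r["log_hr"],
                    "robust_se": r["robust_se"],
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "scenario_id", "target_coefficient", "level", "delta", "ethnicity",
            "hazard_ratio", "ci_lower", "ci_upper", "p_value", "log_hr",
            "robust_se",
        ],
    )
    validity = (
        pd.concat(validity_rows, ignore_index=True)
        if validity_rows else pd.DataFrame()
    )
    meta_table = pd.DataFrame(meta_rows)
    table.to_csv(out / "sensitivity_hr.csv", index=False)
    validity.to_csv(out / "sensitivity_validity.csv", index=False)
    meta_table.to_csv(out / "sensitivity_scenarios.csv", index=False)
    with open(out / "sensitivity_metadata.json", "w") as fh:
        json.dump(
            {
                "invalid_policy": config.invalid_policy,
                "n_scenarios": len(scenarios),
                "n_run": int(meta_table["action"].ne("skipped").sum()) if len(meta_table) else 0,
                "n_skipped": int(meta_table["action"].eq("skipped").sum()) if len(meta_table) else 0,
            },
            fh, indent=2, sort_keys=True,
        )
    skipped = [m["scenario_id"] for m in meta_rows if m["action"] == "skipped"]
    if skipped:
        logger.warning("skipped %d invalid scenarios: %s", len(skipped), skipped)
    return {"table": table, "validity": validity, "scenarios": meta_table,
            "base": base}


def sensitivity_panels(table: pd.DataFrame, base_summary: pd.DataFrame, path=None):
    """Panel plot of weighted HRs by target coefficient and level,
    analogous to the per-parameter sensitivity figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coefs = list(dict.fromkeys(table["target_coefficient"]))
    ncol = 2
    nrow = (len(coefs) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.8 * nrow), squeeze=False)
    base_w = base_summary[base_summary["iteration"] == "adjusted_ipw"]
    for ax, coef in zip(axes.flat, coefs):
        sub = table[table["target_coefficient"] == coef]
        for eth in dict.fromkeys(sub["ethnicity"]):
            es = sub[sub["ethnicity"] == eth].sort_values("level")
            ax.plot(es["level"], es["hazard_ratio"], marker="o", label=eth)
            base_hr = base_w.loc[base_w["ethnicity"] == eth, "hazard_ratio"]
            if len(base_hr):
                ax.axhline(float(base_hr.iloc[0]), lw=0.6, ls=":", color="grey")
        ax.set_title(coef, fontsize=9)
        ax.set_xlabel("% misspecification")
        ax.set_ylabel("weighted HR")
    for ax in axes.flat[len(coefs):]:
        ax.set_visible(False)
    handles, labels = axes.flat[0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower right", fontsize=8, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
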