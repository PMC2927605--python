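"""End-to-end reproducible workflow: simulate -> analyze -> compare.

A run is driven by one configuration mapping plus a seed; outputs land in an
output directory together with a machine-readable manifest (config hash,
seed, library versions, produced files).  Identical configuration and seed
give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from time import perf_counter

import numpy as np
import pandas as pd

from . import __version__
from .attrition_analysis import attrition_table, complete_case_filter, fit_attrition_model
from .bias_model import ScenarioParams, canonical_scenarios, run_scenario
from .cohort_simulator import (
    AttritionModelSpec,
    CohortTable,
    assign_final_status,
    assign_transition_surveys,
    assign_weights,
    calibrate_intercepts,
    enumerate_joint,
    generate_baseline,
    impose_missingness,
)
from .io import (
    baseline_specs_from_config,
    load_baseline_config,
    load_table1_marginals,
    load_table2_coefficients,
    write_cohort_csv,
)
from .population_comparison import dichotomize, weighted_prevalence

log = logging.getLogger("cohortdrift")

__all__ = ["simulate_cohort", "calibrated_model", "wave_prevalence", "run_pipeline"]


def calibrated_model(
    specs=None, config: dict | None = None, null: bool = False
) -> AttritionModelSpec:
    """The shipped coefficient fixture with intercepts calibrated so that, in
    expectation over the exact baseline joint distribution, the Survey-5
    status marginals hit the configured targets."""
    config = config or load_baseline_config()
    specs = specs or baseline_specs_from_config(config)
    if null:
        model = AttritionModelSpec.null()
    else:
        model = AttritionModelSpec.from_or_table(load_table2_coefficients())
        model.validate_against(specs)
    grid, probs = enumerate_joint(specs)
    return calibrate_intercepts(model, grid, config["survey5_marginals"], weights=probs)


def simulate_cohort(
    n: int,
    seed: int,
    config: dict | None = None,
    model: AttritionModelSpec | None = None,
    waves: bool = True,
    missingness: bool = True,
    weights: bool = True,
) -> CohortTable:
    """Full generator pipeline for one synthetic cohort.

    Baseline factors -> area strata and sampling weights -> model-drawn
    Survey-5 status (odds-ratio structure and calibrated marginals) ->
    wave back-fill from the per-survey attrition table -> MCAR missingness.
    """
    config = config or load_baseline_config()
    specs = baseline_specs_from_config(config)
    if model is None:
        model = calibrated_model(specs, config)
    cohort = generate_baseline(n, specs, seed)
    if weights:
        strata = config["strata"]
        cohort = assign_weights(
            cohort, strata["sampling_fractions"], strata["population_shares"], seed
        )
    cohort = assign_final_status(cohort, model, seed)
    if waves:
        cohort = assign_transition_surveys(cohort, load_table1_marginals(), seed)
    if missingness:
        cohort = impose_missingness(cohort, config.get("missingness", {}), seed)
    return cohort


def wave_prevalence(
    cohort: CohortTable, factor: str, rule, weight_col: str = "weight"
) -> dict[int, float]:
    """Weighted prevalence of a dichotomized baseline factor among the
    participants still responding at each survey."""
    indicator = dichotomize(cohort.data[factor], rule)
    w = (
        cohort.data[weight_col].to_numpy(dtype=float)
        if weight_col in cohort.data.columns
        else np.ones(len(cohort))
    )
    out: dict[int, float] = {}
    for col in cohort.status_columns:
        mask = (cohort.data[col] == "respondent").to_numpy()
        out[int(col[-1])] = weighted_prevalence(indicator[mask], w[mask])
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Execute the configured stages and write a run manifest.

    Recognized top-level config sections: ``scenarios`` (list of canonical
    scenario names or parameter mappings), ``simulate`` (n, waves,
    missingness), ``analyze`` (factors to model), ``compare`` (factor,
    rule).  A stage failure removes that stage's partial outputs and aborts
    with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "versions": {
            "cohortdrift": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": [],
    }
    cohort: CohortTable | None = None

    def stage(name, fn, outputs):
        t0 = perf_counter()
        try:
            result = fn()
        except Exception as err:
            for f in outputs:
                Path(f).unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log.info("stage %s finished in %.2fs", name, perf_counter() - t0)
        manifest["outputs"].extend(str(Path(f).name) for f in outputs)
        return result

    if "scenarios" in config:
        def _scenarios():
            canon = canonical_scenarios()
            for entry in config["scenarios"]:
                if isinstance(entry, str):
                    name, params = entry, canon[entry]
                else:
                    name, params = entry["name"], ScenarioParams.from_mapping(
                        {k: v for k, v in entry.items() if k != "name"}
                    )
                path = out_dir / f"scenario_{name}.csv"
                run_scenario(params).to_csv(path)
                files.append(path)

        files: list[Path] = []
        stage("scenario", _scenarios, files)

    if "simulate" in config:
        sim = config["simulate"]
        path = out_dir / "cohort.csv"

        def _simulate():
            nonlocal cohort
            cohort = simulate_cohort(
                n=int(sim.get("n", 12432)),
                seed=seed,
                waves=bool(sim.get("waves", True)),
                missingness=bool(sim.get("missingness", True)),
            )
            write_cohort_csv(cohort, path)
            attrition_table(cohort).to_percent_frame().to_csv(out_dir / "attrition_table.csv")

        stage("simulate", _simulate, [path, out_dir / "attrition_table.csv"])

    if "analyze" in config:
        if cohort is None:
            raise RuntimeError("analyze stage requires a simulate stage (or cohort input)")
        ana = config["analyze"]
        path = out_dir / "ortable.csv"

        def _analyze():
            specs = baseline_specs_from_config(load_baseline_config())
            wanted = ana.get("factors")
            if wanted:
                specs = [s for s in specs if s.name in wanted]
            cc, report = complete_case_filter(cohort, [s.name for s in specs])
            table = fit_attrition_model(cc, specs)
            table.to_wide().to_csv(path, index=False)
            (out_dir / "complete_case_report.json").write_text(json.dumps(report, indent=2))

        stage("analyze", _analyze, [path, out_dir / "complete_case_report.json"])

    if "compare" in config:
        if cohort is None:
            raise RuntimeError("compare stage requires a simulate stage (or cohort input)")
        cmp_cfg = config["compare"]
        path = out_dir / "bias.csv"

        def _compare():
            factor, rule = cmp_cfg["factor"], cmp_cfg["rule"]
            keep = cohort.data[factor].notna()
            sub = CohortTable(cohort.data.loc[keep].reset_index(drop=True), cohort.factors)
            prev = wave_prevalence(sub, factor, rule)
            indicator = dichotomize(sub.data[factor], rule)
            baseline_prev = float(indicator.mean())  # static population benchmark
            frame = pd.DataFrame(
                {
                    "survey": list(prev),
                    "cohort_prevalence": list(prev.values()),
                    "population_prevalence": baseline_prev,
                }
            )
            frame["bias"] = frame["population_prevalence"] - frame["cohort_prevalence"]
            frame.to_csv(path, index=False)

        stage("compare", _compare, [path])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
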