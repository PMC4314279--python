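"""End-to-end pipeline: synthetic data (or user CSVs) -> alkene
regressions -> attraction GLMs -> genotype landscape (with and without
the suppressor) -> simulation grid, with a hashed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import io as oio
from .alkenes import fit_alkene_models
from .attraction import fit_attraction_glm, permute_within_groups
from .landscape import enumerate_genotypes, predict_genotype_landscape
from .popsim import SimulationConfig, build_attraction_cache, run_scenario_grid
from .synthetic import (
    GroundTruthParams,
    generate_choice_trials,
    generate_expression_scent,
    paper_like_fixture,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineRun", "PipelineError", "run_full_pipeline", "reference_expression"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineRun:
    """Configuration and provenance for one end-to-end run."""

    out_dir: Path
    seed: int = 0
    params: GroundTruthParams | None = None  # default: paper_like_fixture()
    expression_csv: Path | None = None       # user data instead of simdata
    choice_csv: Path | None = None
    n_perm: int = 300
    n_perturb: int = 500
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    run_simulations: bool = True


def reference_expression(expression: pd.DataFrame) -> tuple[float, float]:
    """Homozygote reference expression estimated from the data: mean
    SAD2A expression among sphegodes and mean SAD5A among exaltata."""
    r2 = float(expression.loc[expression["species"] == "sphegodes", "sad2a_expr"].mean())
    r5 = float(expression.loc[expression["species"] == "exaltata", "sad5a_expr"].mean())
    if not (r2 > 0 and r5 > 0):
        raise ValueError("cannot estimate positive reference expression from data")
    return r2, r5


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_full_pipeline(run: PipelineRun) -> dict:
    """Execute all stages and return the output manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = oio.spawn_seeds(run.seed, 5)
    params = run.params or paper_like_fixture()

    # stage: data
    stage = _stage("simdata")
    if run.expression_csv is not None:
        expression = _stage("read-expression")(oio.read_expression_scent, run.expression_csv)
    else:
        expression = stage(generate_expression_scent, params, seed=seeds[0])
    if run.choice_csv is not None:
        choice = _stage("read-choice")(oio.read_choice_trials, run.choice_csv)
    else:
        choice = stage(generate_choice_trials, params, seed=seeds[1])
    oio.write_expression_scent(expression, out / "expression_scent.csv")
    oio.write_choice_trials(choice, out / "choice_trials.csv")

    # stage: step-1 regressions
    alkene_model = _stage("fit-alkenes")(fit_alkene_models, expression)
    oio.save_model(alkene_model, out / "alkene_model.json")

    # stage: step-2 GLMs
    def fit_both():
        expanded = permute_within_groups(choice, n_perm=run.n_perm, seed=seeds[2])
        return {
            "C_cunicularius": fit_attraction_glm(expanded, "C_cunicularius"),
            "A_nigroaenea": fit_attraction_glm(expanded, "A_nigroaenea"),
        }

    attraction_models = _stage("fit-attraction")(fit_both)
    oio.save_model(attraction_models["C_cunicularius"], out / "attraction_cc.json")
    oio.save_model(attraction_models["A_nigroaenea"], out / "attraction_an.json")

    # stage: step-3 landscape
    ref_expr = _stage("landscape")(reference_expression, expression)

    def build_landscapes():
        results = {}
        for tag, include_sus in (("nosus", False), ("sus", True)):
            lscape = predict_genotype_landscape(
                enumerate_genotypes(include_sus=include_sus),
                alkene_model,
                attraction_models,
                ref_expr,
                n_perturb=run.n_perturb,
                seed=seeds[3],
            )
            lscape.to_csv(out / f"landscape_{tag}.csv", index=False)
            results[tag] = lscape
        return results

    landscapes = _stage("landscape")(build_landscapes)

    # stage: step-4 simulations
    if run.run_simulations:
        def simulate():
            cache = build_attraction_cache(alkene_model, attraction_models, ref_expr)
            cfg = replace(run.sim_config, seed=seeds[4])
            table, _ = run_scenario_grid(cfg, cache)
            table.to_csv(out / "trajectories.csv", index=False)
            return table

        _stage("simulate")(simulate)

    manifest = {
        "seed": run.seed,
        "stage_seeds": seeds,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
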