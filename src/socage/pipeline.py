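"""End-to-end experiment orchestration.

Composes the five stages — generate observations, fit edge posteriors, draw
networks, compute centralities, simulate epidemics, summarize with mixed
models — from a single configuration with one master seed.  Every stage's
seed is derived reproducibly from the master seed, and a manifest recording
seeds, the parameter grid and run counts is written alongside the outputs,
so any experiment can be re-run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import centrality as centrality_mod
from . import edges as edges_mod
from . import epi as epi_mod
from . import inference as inference_mod
from . import synthetic as synthetic_mod
from .edges import DEFAULT_PRIOR
from .epi import SI_VALUES, EpiParams
from .inference import ProtectiveEffectReport

__all__ = [
    "ExperimentConfig",
    "run_pipeline",
    "expected_run_count",
    "validate_against_worked_examples",
]

log = logging.getLogger("socage")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: generator settings, edge-model priors, grid choice.

    ``grid`` is "full" (all 24 cells), "control" (the three
    no-immunosenescence cells) or an explicit list of :class:`EpiParams`.
    ``si_values`` restricts the transmissibilities in either named grid.
    All stage seeds derive from ``master_seed``.
    """

    n_group_years: int = 5
    n_draws: int = 50
    grid: str | Sequence[EpiParams] = "control"
    si_values: Sequence[float] = SI_VALUES
    prior_shape: float = DEFAULT_PRIOR[0]
    prior_rate: float = DEFAULT_PRIOR[1]
    n_steps: int = 500
    n_initial_infected: float = 0.1
    age_decline_rate: float | None = None  # None = generator default
    master_seed: int = 0
    out_dir: str | None = None
    contrasts: bool = True

    def generator_config(self) -> synthetic_mod.GeneratorConfig:
        seed = _stage_seed(self.master_seed, 0)
        kw = {"n_group_years": self.n_group_years, "rng_seed": seed}
        if self.age_decline_rate is not None:
            kw["age_decline_rate"] = self.age_decline_rate
        return synthetic_mod.GeneratorConfig(**kw)

    def grid_params(self) -> list[EpiParams]:
        if isinstance(self.grid, str):
            if self.grid == "full":
                return epi_mod.enumerate_parameter_grid(
                    self.si_values, n_steps=self.n_steps,
                    n_initial_infected=self.n_initial_infected,
                )
            if self.grid == "control":
                return epi_mod.control_grid(
                    self.si_values, n_steps=self.n_steps,
                    n_initial_infected=self.n_initial_infected,
                )
            raise ValueError(f"unknown grid {self.grid!r}")
        return list(self.grid)


def _stage_seed(master_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence((master_seed, stage))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def expected_run_count(n_group_years: int, n_draws: int, n_grid_cells: int) -> int:
    """Simulation runs implied by a full design (group-years x draws x cells)."""
    return n_group_years * n_draws * n_grid_cells


@dataclass(frozen=True)
class PipelineResult:
    """Everything run_pipeline produces, in memory."""

    reports: list[ProtectiveEffectReport]
    report_table: pd.DataFrame
    results: pd.DataFrame
    centralities: pd.DataFrame
    observations: list[synthetic_mod.GroupYearObservations]
    n_runs: int
    manifest: dict


def run_pipeline(config: ExperimentConfig) -> PipelineResult:
    """Run the full generate -> edges -> centrality -> simulate -> summarize
    pipeline; write artifacts when ``config.out_dir`` is set."""
    t0 = time.time()
    grid = config.grid_params()
    gen_cfg = config.generator_config()

    stage = "generate"
    try:
        observations = synthetic_mod.generate_study(gen_cfg)
        log.info("generated %d group-years", len(observations))

        stage = "fit-edges"
        posteriors = [
            edges_mod.fit_edge_posterior(o, config.prior_shape, config.prior_rate)
            for o in observations
        ]

        stage = "draw-networks"
        draw_seed = _stage_seed(config.master_seed, 1)
        draws = []
        for k, post in enumerate(posteriors):
            ss = np.random.SeedSequence((draw_seed, k))
            draws.extend(edges_mod.draw_networks(post, config.n_draws, ss))

        stage = "centrality"
        cents = centrality_mod.centrality_table(draws)

        stage = "simulate"
        sim_seed = _stage_seed(config.master_seed, 2)
        results_list = list(epi_mod.run_experiment(draws, grid, master_seed=sim_seed))
        n_runs = len(results_list)
        assert n_runs == expected_run_count(len(observations), config.n_draws, len(grid))
        results = epi_mod.results_table(results_list)

        stage = "summarize"
        reports = inference_mod.summarize_experiment(results, cents, contrasts=config.contrasts)
        table = inference_mod.report_table(reports)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "master_seed": config.master_seed,
        "stage_seeds": {"generate": gen_cfg.rng_seed,
                        "draw-networks": _stage_seed(config.master_seed, 1),
                        "simulate": _stage_seed(config.master_seed, 2)},
        "n_group_years": len(observations),
        "n_draws": config.n_draws,
        "grid": [p.param_id for p in grid],
        "n_runs": n_runs,
        "elapsed_s": round(time.time() - t0, 2),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if not isinstance(v, EpiParams)},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for o in observations:
            synthetic_mod.write_group_year(o, out / "observations" / o.label)
        synthetic_mod.write_config(gen_cfg, out / "generator_config.txt")
        cents.to_csv(out / "centralities.tsv", sep="\t", index=False)
        results.to_csv(out / "simulation_results.tsv", sep="\t", index=False)
        table.to_csv(out / "report.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineResult(
        reports=reports,
        report_table=table,
        results=results,
        centralities=cents,
        observations=observations,
        n_runs=n_runs,
        manifest=manifest,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(**raw)


def validate_against_worked_examples() -> pd.DataFrame:
    """Evaluate the pure-arithmetic fixtures of the analysis against their
    published values; returns a pass/fail table.

    These checks exercise the protective-effect subtraction, the cost-unit
    to infection conversion, the infection-cost equation at its extremes,
    the susceptibility ratio implied by the maximum age increment, and the
    parameter-grid design counts.
    """
    checks: list[tuple[str, float, float]] = []

    checks.append(("protective_effect(-1.09, -0.26)",
                   inference_mod.protective_effect(-1.09, -0.26), -0.83))
    checks.append(("protective_effect(20.9, 22.1)",
                   round(inference_mod.protective_effect(20.9, 22.1), 10), -1.2))
    checks.append(("cost_to_infections(22)", inference_mod.cost_to_infections(22.0), 4.4))
    checks.append(("cost_to_infections(21.6)",
                   round(inference_mod.cost_to_infections(21.6), 2), 4.32))
    checks.append(("cost_to_infections(39.0)", inference_mod.cost_to_infections(39.0), 7.8))
    checks.append(("infection_cost(5, 0, 1, 0)", epi_mod.infection_cost(5, 0, 1.0, 0.0), 5.0))
    checks.append(("infection_cost(5, 10, 1, 2)", epi_mod.infection_cost(5, 10, 1.0, 2.0), 45.0))
    checks.append(("oldest duration di + adi", 5 + epi_mod.duration_increment(28, 10.0), 15))
    checks.append(("oldest per-step cost ci + aci", 1 + epi_mod.severity_increment(28, 2.0), 3.0))
    checks.append(("susceptibility ratio at si=0.45",
                   round((0.45 + epi_mod.susceptibility_increment(28, 0.25)) / 0.45, 2), 1.56))
    checks.append(("grid size", len(epi_mod.enumerate_parameter_grid()), 24))
    checks.append(("controls in grid",
                   sum(p.is_control for p in epi_mod.enumerate_parameter_grid()), 3))
    checks.append(("full-design run count", expected_run_count(23, 1000, 24), 552_000))

    rows = [
        {"check": name, "value": float(value), "expected": float(expected),
         "passed": bool(np.isclose(float(value), float(expected), rtol=0, atol=1e-9))}
        for name, value, expected in checks
    ]
    return pd.DataFrame(rows)
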