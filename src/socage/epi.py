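"""Stochastic discrete-time SIS epidemics with linear immunosenescence.

A hypothetical, directly transmitted endemic pathogen spreads over a weighted
grooming network.  Individuals are susceptible (S) or infected (I); a
recovered (R) state exists in the machinery but its duration is 0 here, so
individuals return straight to S and can be reinfected.  For each step-long
contact between susceptible *i* and infected *j*, transmission occurs with
probability

    P(tr) = (si + ai_i) * A_ij ** 0.7,

where ``si`` is the baseline transmission probability, ``ai_i`` an age-based
susceptibility increment and ``A_ij`` the grooming-network edge weight.  The
0.7 exponent slightly boosts the epidemiological importance of weak ties.
The product is clamped to [0, 1] (it can exceed 1 on very strong edges).

An infection of individual *i* lasts ``di + adi_i`` steps and accrues
``ci + aci_i`` cost units per infected step, so a full infection costs
``(di + adi_i) * (ci + aci_i)``.  The three age increments rise linearly in
age between global anchors (youngest 6, oldest 28):

    f(a) = clamp((a - 6) / (28 - 6), 0, 1)
    ai_i  = ai_max  * f(a)        (max 0.25 when susceptibility ageing is on)
    adi_i = round(adi_max * f(a)) (max 10; durations are whole steps)
    aci_i = aci_max * f(a)        (max 2)

The experiment grid crosses each effect on/off with three baseline
transmissibilities (0.45, 0.60, 0.75), giving 24 parameterizations; with all
effects off the model is the no-immunosenescence control, where every
completed infection costs exactly di * ci = 5 units.

Within a step, transmissions are evaluated synchronously against the
step-start infected set, then durations are decremented; an individual whose
infection expires at step t is susceptible from step t+1 and cannot transmit
at t+1.  Per susceptible, the independent per-infected-neighbour Bernoulli
trials are drawn as a single equivalent-in-distribution combined trial with
success probability 1 - prod_j (1 - p_ij).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .edges import PosteriorNetworkDraw

__all__ = [
    "AGE_ANCHORS",
    "SI_VALUES",
    "AI_MAX_ON",
    "ADI_MAX_ON",
    "ACI_MAX_ON",
    "EpiParams",
    "SimulationResult",
    "age_fraction",
    "susceptibility_increment",
    "duration_increment",
    "severity_increment",
    "transmission_probability",
    "infection_cost",
    "run_sis",
    "estimate_R0",
    "equilibrium_prevalence",
    "enumerate_parameter_grid",
    "run_experiment",
    "results_table",
]

#: Global age-normalization anchors (youngest, oldest) in years.
AGE_ANCHORS: tuple[float, float] = (6.0, 28.0)

#: Baseline transmission probabilities: low / medium / high transmissibility.
SI_VALUES: tuple[float, float, float] = (0.45, 0.60, 0.75)

#: Maximum age increment to susceptibility when the effect is on.  Chosen so
#: that the oldest-to-youngest transmission-probability ratio (si + 0.25)/si
#: spans roughly 1.33-1.56 across the three si values.
AI_MAX_ON: float = 0.25
#: Maximum age increment to infection duration (steps) when on: durations
#: span 5 (youngest) to 15 (oldest).
ADI_MAX_ON: int = 10
#: Maximum age increment to per-step cost when on: costs span 1 to 3.
ACI_MAX_ON: float = 2.0


@dataclass(frozen=True)
class EpiParams:
    """All constants for one cell of the parameter grid."""

    si: float = 0.60
    di: int = 5
    dr: int = 0
    ci: float = 1.0
    ai_max: float = 0.0
    adi_max: float = 0.0
    aci_max: float = 0.0
    edge_exponent: float = 0.7
    n_steps: int = 500
    n_initial_infected: float = 0.1  # fraction if < 1, else absolute count
    age_anchors: tuple[float, float] = AGE_ANCHORS
    rng_seed: int = 0
    param_id: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.si <= 1):
            raise ValueError("si must be in (0, 1]")
        if self.di < 1 or self.dr < 0 or self.n_steps < 1:
            raise ValueError("di >= 1, dr >= 0 and n_steps >= 1 required")
        if not (0 < self.edge_exponent <= 1):
            raise ValueError("edge_exponent must be in (0, 1]")
        if self.ai_max < 0 or self.adi_max < 0:
            raise ValueError("age-effect maxima must be >= 0")

    @property
    def is_control(self) -> bool:
        """True when all three immunosenescence effects are off."""
        return self.ai_max == 0 and self.adi_max == 0 and self.aci_max == 0


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one (network draw x parameterization) run."""

    group_year: str
    draw_index: int
    param_id: str
    ids: tuple[str, ...]
    ages: tuple[int, ...]
    accumulated_cost: np.ndarray
    n_infections: np.ndarray
    infected_steps: np.ndarray
    prevalence: np.ndarray
    rng_seed: int
    # (step, node index, realized duration) per infection event, when logged
    events: tuple[tuple[int, int, int], ...] | None = None


def age_fraction(age, anchors: tuple[float, float] = AGE_ANCHORS):
    """Linear age scaling f(a) on the global anchors, clamped to [0, 1]."""
    lo, hi = anchors
    return np.clip((np.asarray(age, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def susceptibility_increment(age, ai_max: float, anchors=AGE_ANCHORS):
    return ai_max * age_fraction(age, anchors)


def duration_increment(age, adi_max: float, anchors=AGE_ANCHORS):
    """Age increment to infection duration, rounded to whole steps."""
    return np.rint(adi_max * age_fraction(age, anchors)).astype(int)


def severity_increment(age, aci_max: float, anchors=AGE_ANCHORS):
    return aci_max * age_fraction(age, anchors)


def transmission_probability(si: float, ai_i: float, weight: float, edge_exponent: float = 0.7) -> float:
    """Per-contact transmission probability (si + ai) * w**exponent, clamped to [0, 1]."""
    w = np.asarray(weight, dtype=float)
    if np.any(w < 0):
        raise ValueError("edge weight must be >= 0")
    p = (si + ai_i) * w**edge_exponent
    return float(np.clip(p, 0.0, 1.0)) if np.ndim(weight) == 0 else np.clip(p, 0.0, 1.0)


def infection_cost(di: int, adi_i: int, ci: float, aci_i: float) -> float:
    """Total cost of one full infection: (di + adi_i) * (ci + aci_i)."""
    return (di + adi_i) * (ci + aci_i)


def _n_seeds(params: EpiParams, n: int) -> int:
    v = params.n_initial_infected
    k = int(round(v * n)) if 0 < v < 1 else int(v)
    return max(1, min(k, n))


def run_sis(
    net: PosteriorNetworkDraw, params: EpiParams, record_events: bool = False
) -> SimulationResult:
    """Run one SIS simulation over a posterior network draw.

    Deterministic under ``params.rng_seed``.  ``record_events`` keeps a log
    of infection events for conservation checks; off by default to keep
    large experiments light.
    """
    n = net.n
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(params.rng_seed)
    ages = np.asarray(net.ages, dtype=float)
    f = age_fraction(ages, params.age_anchors)
    dur = params.di + np.rint(params.adi_max * f).astype(int)
    step_cost = params.ci + params.aci_max * f

    with np.errstate(invalid="ignore"):
        p = np.clip((params.si + params.ai_max * f)[:, None] * net.weights**params.edge_exponent, 0.0, 1.0)
    np.fill_diagonal(p, 0.0)
    with np.errstate(divide="ignore"):
        log1mp = np.log1p(-p)  # -inf where p == 1

    seeds = rng.choice(n, size=_n_seeds(params, n), replace=False)
    remaining = np.zeros(n, dtype=int)
    recovered = np.zeros(n, dtype=int)  # dormant R state (dr = 0 here)
    remaining[seeds] = dur[seeds]
    n_inf = np.zeros(n, dtype=int)
    n_inf[seeds] = 1
    infected_steps = np.zeros(n, dtype=int)
    prevalence = np.zeros(params.n_steps)
    events = [(0, int(i), int(dur[i])) for i in seeds] if record_events else None

    idx = np.arange(n)
    for t in range(params.n_steps):
        inf = remaining > 0
        prevalence[t] = inf.mean()
        infected_steps[inf] += 1
        sus = ~inf & (recovered == 0)
        new = idx[:0]
        if inf.any() and sus.any():
            sus_idx = idx[sus]
            logq = log1mp[np.ix_(sus_idx, idx[inf])].sum(axis=1)
            p_any = -np.expm1(logq)
            new = sus_idx[rng.random(sus_idx.size) < p_any]
        expiring = inf & (remaining == 1)
        remaining[inf] -= 1
        recovered[recovered > 0] -= 1
        if params.dr > 0:
            recovered[expiring] = params.dr
        if new.size:
            remaining[new] = dur[new]
            n_inf[new] += 1
            if events is not None:
                events.extend((t + 1, int(i), int(dur[i])) for i in new)

    return SimulationResult(
        group_year=net.label,
        draw_index=net.draw_index,
        param_id=params.param_id,
        ids=net.ids,
        ages=net.ages,
        accumulated_cost=infected_steps * step_cost,
        n_infections=n_inf,
        infected_steps=infected_steps,
        prevalence=prevalence,
        rng_seed=params.rng_seed,
        events=tuple(events) if events is not None else None,
    )


def estimate_R0(prevalence: float) -> float:
    """Endemic-equilibrium approximation R0 = 1 / (1 - prevalence)."""
    if not (0 <= prevalence < 1):
        raise ValueError("prevalence must be in [0, 1)")
    return 1.0 / (1.0 - prevalence)


def equilibrium_prevalence(result: SimulationResult, window: int = 100) -> float:
    """Mean proportion infected over the final ``window`` steps."""
    return float(result.prevalence[-window:].mean())


def enumerate_parameter_grid(
    si_values: Sequence[float] = SI_VALUES,
    n_steps: int = 500,
    n_initial_infected: float = 0.1,
) -> list[EpiParams]:
    """Full factorial {ai on/off} x {adi on/off} x {aci on/off} x si.

    24 cells with the default three transmissibilities; the three all-off
    cells are the controls.  ``param_id`` labels are stable.
    """
    grid = []
    for si in si_values:
        for ai_on in (0, 1):
            for adi_on in (0, 1):
                for aci_on in (0, 1):
                    grid.append(
                        EpiParams(
                            si=si,
                            ai_max=AI_MAX_ON * ai_on,
                            adi_max=ADI_MAX_ON * adi_on,
                            aci_max=ACI_MAX_ON * aci_on,
                            n_steps=n_steps,
                            n_initial_infected=n_initial_infected,
                            param_id=f"si{si:g}_ai{ai_on}_adi{adi_on}_aci{aci_on}",
                        )
                    )
    return grid


def control_grid(si_values: Sequence[float] = SI_VALUES, **kw) -> list[EpiParams]:
    """The no-immunosenescence controls, one per transmissibility."""
    return [p for p in enumerate_parameter_grid(si_values, **kw) if p.is_control]


def run_experiment(
    networks: Iterable[PosteriorNetworkDraw],
    grid: Sequence[EpiParams],
    master_seed: int = 0,
    record_events: bool = False,
) -> Iterator[SimulationResult]:
    """Run every (network draw x parameterization) pair, streaming results.

    Per-run seeds are derived reproducibly from ``master_seed`` and the run
    identity (group-year, draw, grid cell), so results do not depend on
    iteration order and reruns are identical.
    """
    networks = list(networks)
    if not networks or not grid:
        raise ValueError("need at least one network and one parameterization")
    for net in networks:
        for gk, params in enumerate(grid):
            ss = np.random.SeedSequence(
                (master_seed, _stable_hash(net.label), net.draw_index, gk)
            )
            seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            try:
                yield run_sis(net, replace(params, rng_seed=seed), record_events=record_events)
            except Exception as exc:  # surface run identity with the failure
                raise RuntimeError(
                    f"simulation failed for {net.label} draw {net.draw_index} "
                    f"cell {params.param_id!r}: {exc}"
                ) from exc


def _stable_hash(label: str) -> int:
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


def results_table(results: Iterable[SimulationResult]) -> pd.DataFrame:
    """Flatten results to a long-format per-individual table."""
    rows = []
    for r in results:
        for k, id_ in enumerate(r.ids):
            rows.append(
                (r.group_year, r.draw_index, r.param_id, id_, r.ages[k],
                 float(r.accumulated_cost[k]), int(r.n_infections[k]))
            )
    return pd.DataFrame(
        rows,
        columns=["group_year", "draw", "param_id", "id", "age", "cost", "n_infections"],
    )


def write_results(results: Iterable[SimulationResult], path: str | Path) -> int:
    """Append per-individual results to a delimited table; returns run count."""
    path = Path(path)
    new = not path.exists()
    count = 0
    with open(path, "a") as fh:
        if new:
            fh.write("group_year\tdraw\tparam_id\tid\tage\tcost\tn_infections\n")
        for r in results:
            count += 1
            for k, id_ in enumerate(r.ids):
                fh.write(
                    f"{r.group_year}\t{r.draw_index}\t{r.param_id}\t{id_}\t"
                    f"{r.ages[k]}\t{r.accumulated_cost[k]:.6g}\t{r.n_infections[k]}\n"
                )
    return count
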