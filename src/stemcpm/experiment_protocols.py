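"""Experimental designs built on the core simulator.

Three protocols beyond plain growth:

* therapy and relapse — grow to a trigger volume, kill cycling cells
  during a finite treatment window, let the survivors repopulate to the
  trigger volume again, and compare pre/post phenotype distributions;
* constant-population evolution — grow to a fixed volume, then balance
  every division by uniformly random cell death until a division budget
  is spent, giving the stationary phenotype distribution free of the
  expanding-front bias;
* replicate batches — n independent seeded runs aggregated as
  mean +- SD per statistic.

Therapy is operationalized as kill-on-division-attempt during the
window: any cell that reaches its division trigger while treatment is
active dies instead of dividing. Quiescent cells never cycle and
always survive; slow-cycling (low-fitness) cells tend not to complete
a cycle within the window and survive preferentially, which is what
lets a relapse occur at all. Apoptosis stays active throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis_stats, mutation_models
from .cpm_core import (
    LatticeState,
    SimulationConfig,
    SimulationResult,
    apoptosis_sweep,
    audit_state,
    clone_table_frame,
    kill_cell,
    monte_carlo_step,
    run_simulation,
    seed_founder,
)
from .hierarchy import CellType

__all__ = [
    "PhaseSummary",
    "ExperimentReport",
    "summarize_state",
    "apply_therapy",
    "run_therapy_experiment",
    "run_constant_population",
    "run_growth",
    "run_replicates",
]


@dataclass
class PhaseSummary:
    """Snapshot statistics of one experimental phase (e.g. pre-therapy)."""

    phase: str
    time_hours: float
    n_cells: int
    n_csc: int
    shannon_norm: float
    mean_fitness: float
    phenotype_histogram: Optional[np.ndarray] = None
    clone_table: Optional[pd.DataFrame] = None

    def as_row(self) -> dict:
        return {
            "phase": self.phase,
            "time_hours": self.time_hours,
            "n_cells": self.n_cells,
            "n_csc": self.n_csc,
            "shannon_norm": self.shannon_norm,
            "mean_fitness": self.mean_fitness,
        }


@dataclass
class ExperimentReport:
    """Per-replicate phase summaries plus aggregate statistics."""

    seeds: list
    replicates: list  # list of lists of PhaseSummary (one list per replicate)
    statuses: list = field(default_factory=list)
    results: list = field(default_factory=list)  # optional SimulationResults

    def __post_init__(self) -> None:
        if len(self.seeds) != len(self.replicates):
            raise ValueError("replicate count must match seed list length")

    @property
    def n(self) -> int:
        return len(self.replicates)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for seed, phases in zip(self.seeds, self.replicates):
            for ph in phases:
                row = {"replicate_seed": seed}
                row.update(ph.as_row())
                rows.append(row)
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        """mean +- SD of every numeric statistic, per phase."""
        table = self.summary_table()
        if table.empty:
            return table
        num = table.drop(columns=["replicate_seed"])
        grouped = num.groupby("phase", sort=False)
        agg = grouped.agg(["mean", "std"])
        agg.columns = [f"{a}_{b}" for a, b in agg.columns]
        return agg.reset_index()

    def phase_values(self, phase: str, statistic: str) -> np.ndarray:
        table = self.summary_table()
        sel = table[table["phase"] == phase]
        return sel[statistic].to_numpy()


def summarize_state(
    state: LatticeState, config: SimulationConfig, phase: str, landscape=None
) -> PhaseSummary:
    """Collect the standard per-phase statistics from a live state."""
    if landscape is None:
        landscape = mutation_models.get_landscape(
            config.landscape if config.mode != "neutral" else "neutral"
        )
    n_live = state.n_live_cells()
    label_kind = "methylation" if config.mode == "neutral" else "phenotype"
    if n_live > 0:
        table = analysis_stats.clone_abundance(state, label_kind=label_kind)
        shannon = analysis_stats.normalized_shannon(table)
        hist = analysis_stats.phenotype_histogram(state)
        mfit = (
            analysis_stats.mean_fitness(state, landscape)
            if config.mode != "neutral"
            else float("nan")
        )
        clones = clone_table_frame(state, config)
    else:
        shannon, mfit = float("nan"), float("nan")
        hist, clones = None, None
    return PhaseSummary(
        phase=phase,
        time_hours=float(state.clock_hours),
        n_cells=n_live,
        n_csc=state.count_type(CellType.CSC),
        shannon_norm=shannon,
        mean_fitness=mfit,
        phenotype_histogram=hist,
        clone_table=clones,
    )


def apply_therapy(
    state: LatticeState,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> LatticeState:
    """Kill the proliferating cells; quiescent and slow cells survive.

    Three operationalizations of "all proliferating cells are killed",
    selected by ``therapy_rule``:

    * ``"fitness"`` (default) — an instantaneous, phenotype-targeted
      kill: every non-quiescent cell — CSC or TAC alike — dies with
      probability f(x) / f_max, where f_max is the highest fitness
      among live cells. Fast-cycling (high-fitness) phenotypes are
      eliminated almost surely; slow-cycling clones survive
      preferentially, and quiescent DCs always survive.
    * ``"cycling"`` — an instantaneous kill of every cell whose growth
      clock is currently running (non-quiescent and not
      contact-inhibited); compressed cells and DCs survive.
    * ``"window"`` — for ``therapy_window_hours`` of simulated time the
      dynamics continue but every cell arriving at its division
      trigger dies instead of dividing. A window of zero length kills
      nothing.
    """
    rng = rng if rng is not None else state.rng
    if config.therapy_rule == "fitness":
        landscape = mutation_models.get_landscape(
            config.landscape if config.mode != "neutral" else "neutral"
        )
        n = state.next_sigma
        sigmas = np.flatnonzero(state.alive[:n] & (state.ctype[:n] != int(CellType.DC)))
        if sigmas.size == 0:
            return state
        f = landscape.fitness(state.phen[:n][sigmas].astype(np.int64))
        doomed = sigmas[rng.random(sigmas.size) < f / f.max()]
        for sigma in doomed:
            kill_cell(state, int(sigma))
        return state
    if config.therapy_rule == "cycling":
        n = state.next_sigma
        cycling = (
            state.alive[:n]
            & (state.ctype[:n] != int(CellType.DC))
            & (state.volume[:n] >= state.target[:n] - config.growth_gate_margin)
        )
        for sigma in np.flatnonzero(cycling):
            kill_cell(state, int(sigma))
        return state
    landscape = mutation_models.get_landscape(
        config.landscape if config.mode != "neutral" else "neutral"
    )
    window_end = state.clock_hours + config.therapy_window_hours
    next_apoptosis = (math.floor(state.clock_hours / 24.0) + 1) * 24.0
    while state.clock_hours < window_end and state.n_live_cells() > 0:
        monte_carlo_step(state, config, landscape, therapy_active=True)
        if state.clock_hours >= next_apoptosis:
            audit_state(state)
            apoptosis_sweep(state, config.apoptosis_rate, rng)
            next_apoptosis += 24.0
    return state


def run_therapy_experiment(config: SimulationConfig) -> ExperimentReport:
    """Grow, treat at the trigger volume, regrow; summarize both states.

    Grows the tumor to ``therapy_trigger_volume`` cells, snapshots the
    pre-treatment state, applies the treatment window, then resumes
    growth until the trigger volume is reached again. Extinction after
    therapy is reported through the replicate's status, not raised.
    """
    if config.mode != "therapy":
        raise ValueError("run_therapy_experiment requires mode='therapy'")
    grown = run_simulation(config, stop_volume=config.therapy_trigger_volume)
    state = grown.state
    pre = summarize_state(state, config, "pre_treatment", grown.landscape)
    if grown.status != "reached_volume":
        return ExperimentReport(
            seeds=[config.seed], replicates=[[pre]], statuses=[grown.status],
            results=[grown],
        )
    apply_therapy(state, config)
    post_therapy = summarize_state(state, config, "post_treatment", grown.landscape)
    regrown = run_simulation(
        config, state=state, stop_volume=config.therapy_trigger_volume
    )
    relapse = summarize_state(state, config, "relapse", grown.landscape)
    status = "relapsed" if regrown.status == "reached_volume" else regrown.status
    return ExperimentReport(
        seeds=[config.seed],
        replicates=[[pre, post_therapy, relapse]],
        statuses=[status],
        results=[regrown],
    )


def run_constant_population(config: SimulationConfig) -> ExperimentReport:
    """Stationary evolution at fixed volume under a division budget.

    Grows to ``constpop_start_volume`` cells, then after every MCS kills
    uniformly random cells to restore that volume, until
    ``constpop_division_budget`` total divisions have occurred. Reports
    the stationary phenotype distribution.
    """
    if config.mode != "constant_population":
        raise ValueError("run_constant_population requires mode='constant_population'")
    grown = run_simulation(config, stop_volume=config.constpop_start_volume)
    state = grown.state
    start = summarize_state(state, config, "at_volume", grown.landscape)
    if grown.status != "reached_volume":
        return ExperimentReport(
            seeds=[config.seed], replicates=[[start]], statuses=[grown.status],
            results=[grown],
        )
    target_volume = state.n_live_cells()
    budget = config.constpop_division_budget
    divisions_at_start = state.total_divisions
    next_apoptosis = (math.floor(state.clock_hours / 24.0) + 1) * 24.0
    landscape = grown.landscape
    status = "budget_spent"
    while state.total_divisions - divisions_at_start < budget:
        if state.n_proliferative() == 0 or state.n_live_cells() == 0:
            status = "extinct" if state.n_live_cells() == 0 else "quiescent"
            break
        if state.clock_hours >= config.max_hours:
            status = "timeout"
            break
        monte_carlo_step(state, config, landscape)
        excess = state.n_live_cells() - target_volume
        if excess > 0:
            live = state.live_sigmas()
            doomed = state.rng.choice(live, size=excess, replace=False)
            for sigma in doomed:
                kill_cell(state, int(sigma))
        if state.clock_hours >= next_apoptosis:
            audit_state(state)
            apoptosis_sweep(state, config.apoptosis_rate)
            next_apoptosis += 24.0
    final = summarize_state(state, config, "stationary", landscape)
    return ExperimentReport(
        seeds=[config.seed], replicates=[[start, final]], statuses=[status],
        results=[grown],
    )


def run_growth(config: SimulationConfig) -> ExperimentReport:
    """Plain growth to the stop volume, as a single-replicate report."""
    result = run_simulation(config)
    final = summarize_state(result.state, config, "final", result.landscape)
    return ExperimentReport(
        seeds=[config.seed], replicates=[[final]], statuses=[result.status],
        results=[result],
    )


_PROTOCOLS = {
    "neutral": run_growth,
    "fitness": run_growth,
    "therapy": run_therapy_experiment,
    "constant_population": run_constant_population,
}


def run_replicates(
    config: SimulationConfig,
    n: Optional[int] = None,
    seeds: Optional[Sequence[int]] = None,
    keep_results: bool = False,
) -> ExperimentReport:
    """Execute independent replicates with distinct seeds and pool them.

    ``seeds`` defaults to ``config.seed + 0 .. n-1``. The aggregate
    (mean +- SD per phase and statistic) is available through
    :meth:`ExperimentReport.aggregate` and is invariant to seed order.
    """
    if seeds is None:
        if n is None or n < 1:
            raise ValueError("need n >= 1 or an explicit seed list")
        seeds = [config.seed + k for k in range(n)]
    seeds = list(seeds)
    if n is not None and len(seeds) != n:
        raise ValueError("seed list length must equal n")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds are not allowed")
    protocol = _PROTOCOLS[config.mode]
    all_phases, statuses, results = [], [], []
    for seed in seeds:
        rep = protocol(config.replace(seed=seed))
        all_phases.append(rep.replicates[0])
        statuses.append(rep.statuses[0])
        if keep_results:
            results.append(rep.results[0])
    return ExperimentReport(
        seeds=seeds, replicates=all_phases, statuses=statuses, results=results
    )
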