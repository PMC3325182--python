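"""The stochastic birth-death loop.

Each event (one "iteration") recomputes resource exchange and fitness for
the whole filament, draws one reproducer with probability proportional to
fitness, inserts a trait-copying daughter between the parent and one of its
adjacent positions, lets the daughter differentiate and mutate, and then
removes one cell chosen uniformly at random (possibly the daughter).  In
the connected topology the dead cell's neighbours rejoin; in the broken
topology the chain stays severed at that point.  One generation is
``n_cells`` events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .fitness import population_fitness
from .model_core import (
    ConfigurationError,
    InitSpec,
    ModelParams,
    Population,
    TraitVector,
    make_population,
    spawn_streams,
    validate_params,
)
from .resource_exchange import compute_exchange, interaction_reach

__all__ = ["StepEvent", "step", "run_generation", "run_simulation", "SimulationResult"]

DEFAULT_INIT = TraitVector(0.5, 0.5, 0.5, 0.5)

TRAJECTORY_COLUMNS = [
    "generation",
    "mean_p_keep",
    "mean_p_diff",
    "mean_n_keep",
    "mean_n_diff",
    "median_p_keep",
    "median_p_diff",
    "median_n_keep",
    "median_n_diff",
    "eff_diff_p",
    "eff_diff_n",
    "n_photo",
    "n_fixer",
    "n_fragments",
    "mean_fitness_photo",
    "mean_fitness_fixer",
]


@dataclass(frozen=True)
class StepEvent:
    """Record of one birth-death event."""

    iteration: int
    reproducer: int
    side: str  # "left" or "right" daughter placement
    differentiated: bool
    mutated_traits: tuple[bool, bool, bool, bool]
    death_index: int


def _kernel_args(params: ModelParams) -> tuple:
    return (
        params.sigma,
        params.eps_base,
        params.gamma,
        params.cost_frac,
        params.cost_const,
        params.cost_mode == "constant",
        params.cost_active,
        interaction_reach(params),
        params.kernel == "gaussian",
        params.gaussian_sd,
        params.symmetric_variant,
        params.topology == "broken",
        params.mu_mut,
        params.delta_mut,
        params.w_produce,
    )


class _Buffers:
    """Capacity-(n+1) working copies of the population arrays."""

    def __init__(self, pop: Population):
        n = len(pop)
        self.n = n
        self.pheno = np.empty(n + 1, dtype=np.int8)
        self.traits = np.empty((n + 1, 4), dtype=np.float64)
        self.cost = np.empty(n + 1, dtype=np.uint8)
        self.flags = np.empty(n + 1, dtype=np.uint8)
        self.pheno[:n] = pop.phenotype
        self.traits[:n] = pop.traits
        self.cost[:n] = pop.cost_pending
        self.flags[:n] = pop.break_after

    def write_back(self, pop: Population) -> None:
        n = self.n
        pop.phenotype[:] = self.pheno[:n]
        pop.traits[:] = self.traits[:n]
        pop.cost_pending[:] = self.cost[:n]
        pop.break_after[:] = self.flags[:n]

    def run(self, params: ModelParams, u: np.ndarray) -> np.ndarray:
        events = np.empty((u.shape[0], 5), dtype=np.int64)
        _kernel._run_steps(
            self.pheno,
            self.traits,
            self.cost,
            self.flags,
            self.n,
            u,
            events,
            *_kernel_args(params),
        )
        return events


def step(
    pop: Population, params: ModelParams, rng: np.random.Generator, iteration: int = 0
) -> tuple[Population, StepEvent]:
    """Execute one birth-death event in place; returns the population and
    the event record."""
    u = rng.random((1, _kernel.N_UNIFORMS))
    buf = _Buffers(pop)
    ev = buf.run(params, u)[0]
    buf.write_back(pop)
    event = StepEvent(
        iteration=iteration,
        reproducer=int(ev[0]),
        side="right" if ev[1] else "left",
        differentiated=bool(ev[2]),
        mutated_traits=tuple(bool(ev[3] >> k & 1) for k in range(4)),
        death_index=int(ev[4]),
    )
    return pop, event


def _summarize(pop: Population, params: ModelParams, generation: int) -> dict:
    ledger = compute_exchange(pop, params)
    W = population_fitness(pop, ledger, params)
    photo = pop.phenotype == 1
    t = pop.traits
    row = {
        "generation": generation,
        "mean_p_keep": t[:, 0].mean(),
        "mean_p_diff": t[:, 1].mean(),
        "mean_n_keep": t[:, 2].mean(),
        "mean_n_diff": t[:, 3].mean(),
        "median_p_keep": float(np.median(t[:, 0])),
        "median_p_diff": float(np.median(t[:, 1])),
        "median_n_keep": float(np.median(t[:, 2])),
        "median_n_diff": float(np.median(t[:, 3])),
        # effective post-division differentiation rates (keep x diff)
        "eff_diff_p": float(np.mean(t[:, 0] * t[:, 1])),
        "eff_diff_n": float(np.mean(t[:, 2] * t[:, 3])),
        "n_photo": int(photo.sum()),
        "n_fixer": int((~photo).sum()),
        "n_fragments": pop.n_fragments,
        "mean_fitness_photo": float(W[photo].mean()) if photo.any() else np.nan,
        "mean_fitness_fixer": float(W[~photo].mean()) if (~photo).any() else np.nan,
    }
    return row


def run_generation(
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[Population, dict]:
    """Execute ``n_cells`` birth-death events and return the population and
    a per-generation summary (trait means and medians, phenotype counts,
    fragment count, mean fitness per phenotype)."""
    n = len(pop)
    u = rng.random((n, _kernel.N_UNIFORMS))
    buf = _Buffers(pop)
    buf.run(params, u)
    buf.write_back(pop)
    return pop, _summarize(pop, params, generation)


@dataclass
class SimulationResult:
    """Trajectory of per-generation summaries plus the final state."""

    trajectory: pd.DataFrame
    final_population: Population
    params: ModelParams
    n_generations: int
    window: float = 0.1
    final_window_means: TraitVector = field(init=False)

    def __post_init__(self) -> None:
        self.final_window_means = self.window_means(self.window)

    def window_means(self, window: float) -> TraitVector:
        """Trait means averaged over the final ``window`` fraction of
        generations."""
        n = len(self.trajectory)
        k = max(1, int(round(window * n)))
        tail = self.trajectory.iloc[-k:]
        return TraitVector(
            float(np.clip(tail["mean_p_keep"].mean(), 0, 1)),
            float(np.clip(tail["mean_p_diff"].mean(), 0, 1)),
            float(np.clip(tail["mean_n_keep"].mean(), 0, 1)),
            float(np.clip(tail["mean_n_diff"].mean(), 0, 1)),
        )


def run_simulation(
    params: ModelParams,
    n_generations: int,
    rng: np.random.Generator | int | None = None,
    init: InitSpec | None = None,
    pop: Population | None = None,
    record_every: int = 1,
) -> SimulationResult:
    """Run the full evolutionary simulation.

    ``rng`` may be a Generator, an integer root seed (split into
    independent initialization and evolution streams), or None to use
    ``params.seed``.  ``init`` defaults to the homogeneous trait vector
    (0.5, 0.5, 0.5, 0.5); pass ``"random"`` for one uniform trait vector
    per simulation, or provide ``pop`` to continue from an explicit state.
    """
    validate_params(params)
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    if isinstance(rng, np.random.Generator):
        init_rng = evo_rng = rng
    else:
        seed = params.seed if rng is None else int(rng)
        streams = spawn_streams(seed)
        init_rng, evo_rng = streams["init"], streams["evolution"]
    if pop is None:
        pop = make_population(
            params.n_cells, DEFAULT_INIT if init is None else init, init_rng,
            topology=params.topology,
        )
    elif len(pop) != params.n_cells:
        raise ConfigurationError("explicit population size != n_cells")
    n = len(pop)
    buf = _Buffers(pop)
    rows = []
    for gen in range(1, n_generations + 1):
        u = evo_rng.random((n, _kernel.N_UNIFORMS))
        buf.run(params, u)
        if gen % record_every == 0 or gen == n_generations:
            buf.write_back(pop)
            rows.append(_summarize(pop, params, gen))
    buf.write_back(pop)
    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return SimulationResult(traj, pop, params, n_generations)


def write_trajectory(result: SimulationResult, path) -> None:
    """Dump the trajectory as a TSV with a fixed column order."""
    result.trajectory.to_csv(path, sep="\t", index=False, float_format="%.6g")
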