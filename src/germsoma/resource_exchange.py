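"""Resource production and exchange along the filament.

For a fixed population state, computes each cell's interaction
neighbourhood and the per-step resource flows: every photosynthetic cell
produces one unit of carbohydrate, keeps the fraction ``p_keep`` and splits
the remainder over the nitrogen-fixing cells within its interaction range;
every nitrogen-fixing cell re-exports part of the carbohydrate it received
as fixed nitrogen (``gamma`` units per carbohydrate consumed), split over
its photosynthetic neighbours.  Export with no eligible recipient is lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model_core import ModelParams, Population, ResourceLedger

__all__ = ["NeighborSet", "neighbors_within_range", "compute_exchange", "check_conservation"]


@dataclass(frozen=True)
class NeighborSet:
    """Interacting neighbours of one focal cell: indices and dimensionless
    interaction weights (all 1 for the uniform kernel)."""

    focal: int
    indices: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def interaction_reach(params: ModelParams) -> int:
    """Maximum chain distance reached: K/2 per side for the uniform kernel,
    3 standard deviations for the gaussian kernel."""
    if params.kernel == "gaussian":
        return max(1, int(np.floor(3.0 * params.gaussian_sd + 1e-12)))
    return params.k_range // 2


def neighbors_within_range(pop: Population, i: int, params: ModelParams) -> NeighborSet:
    """Neighbours of cell ``i`` along its fragment, honouring chain breaks
    and ring wraparound.  An isolated single-cell fragment yields an empty
    set."""
    n = len(pop)
    if not (0 <= i < n):
        raise IndexError(f"cell index {i} out of range for population of {n}")
    idx_buf = np.empty(n + 1, dtype=np.int64)
    w_buf = np.empty(n + 1, dtype=np.float64)
    cnt = _kernel._fill_neighbors(
        pop.break_after,
        i,
        n,
        interaction_reach(params),
        params.kernel == "gaussian",
        params.gaussian_sd,
        idx_buf,
        w_buf,
    )
    return NeighborSet(i, idx_buf[:cnt].copy(), w_buf[:cnt].copy())


def compute_exchange(pop: Population, params: ModelParams) -> ResourceLedger:
    """Run one production/exchange phase and return the per-cell ledger.

    The ledger's ``fitness`` column is left unset; see
    :func:`germsoma.fitness.population_fitness`.
    """
    n = len(pop)
    g = np.zeros(n)
    h = np.zeros(n)
    idx_buf = np.empty(n + 1, dtype=np.int64)
    w_buf = np.empty(n + 1, dtype=np.float64)
    _kernel._exchange(
        pop.phenotype,
        pop.traits,
        pop.break_after,
        n,
        interaction_reach(params),
        params.kernel == "gaussian",
        params.gaussian_sd,
        params.gamma,
        params.symmetric_variant,
        params.w_produce,
        g,
        h,
        idx_buf,
        w_buf,
    )
    photo = pop.phenotype == 1
    produced = np.where(photo, params.w_produce, 0.0)
    # optimal fixation split for nitrogen fixers; photosynthetic cells keep
    # their own carbohydrate and use received nitrogen directly
    s_star = np.where(photo, 0.0, pop.traits[:, 2] / (1.0 + params.gamma))
    if params.symmetric_variant:
        avail_c = np.where(photo, pop.traits[:, 0] * params.w_produce, g)
        avail_n = np.where(photo, h, pop.traits[:, 2] * params.w_produce)
        s_star = np.zeros(n)
    else:
        avail_c = np.where(
            photo,
            pop.traits[:, 0] * params.w_produce,
            (pop.traits[:, 2] - s_star) * g,
        )
        avail_n = np.where(photo, h, params.gamma * s_star * g)
    return ResourceLedger(
        produced_c=produced,
        received_c=g,
        received_n=h,
        fix_fraction=s_star,
        avail_c=avail_c,
        avail_n=avail_n,
    )


@dataclass
class ConservationReport:
    """Mass-balance audit of one exchange phase."""

    ok: bool
    carbo_residuals: np.ndarray
    nitrogen_residual: float
    carbo_lost: float
    nitrogen_lost: float

    def __str__(self) -> str:
        state = "OK" if self.ok else "VIOLATION"
        return (
            f"conservation {state}: max carbo residual "
            f"{np.max(np.abs(self.carbo_residuals)):.3e}, nitrogen residual "
            f"{abs(self.nitrogen_residual):.3e}, lost C {self.carbo_lost:.6f}, "
            f"lost N {self.nitrogen_lost:.6f}"
        )


def check_conservation(
    ledger: ResourceLedger, pop: Population, params: ModelParams, atol: float = 1e-12
) -> ConservationReport:
    """Verify that carbohydrate and fixed nitrogen are conserved.

    Carbohydrate: per photosynthetic donor, kept + distributed + lost equals
    production.  Fixed nitrogen: total received + lost equals total export.
    Amounts exported by donors with no opposite-type neighbour are "lost".
    """
    n = len(pop)
    photo = pop.phenotype == 1
    carbo_residuals = np.zeros(n)
    carbo_lost = 0.0
    distributed = np.zeros(n)  # carbohydrate each donor actually delivered
    for j in range(n):
        if not photo[j]:
            continue
        nb = neighbors_within_range(pop, j, params)
        opp = ~photo[nb.indices] if len(nb) else np.array([], dtype=bool)
        give = (1.0 - pop.traits[j, 0]) * params.w_produce
        if len(nb) and opp.any():
            distributed[j] = give
        else:
            carbo_lost += give
        kept = pop.traits[j, 0] * params.w_produce
        carbo_residuals[j] = kept + give - params.w_produce
    # does the delivered total match what recipients booked?
    carbo_delivery_residual = distributed.sum() - ledger.received_c.sum()
    total_export = 0.0
    nitrogen_lost = 0.0
    for j in range(n):
        if photo[j]:
            continue
        if params.symmetric_variant:
            export = (1.0 - pop.traits[j, 2]) * params.w_produce
        else:
            export = params.gamma * (1.0 - pop.traits[j, 2]) * ledger.received_c[j]
        total_export += export
        nb = neighbors_within_range(pop, j, params)
        if not (len(nb) and photo[nb.indices].any()):
            nitrogen_lost += export
    nitrogen_residual = total_export - nitrogen_lost - ledger.received_n.sum()
    ok = (
        float(np.max(np.abs(carbo_residuals), initial=0.0)) <= atol
        and abs(carbo_delivery_residual) <= atol * max(1, n)
        and abs(nitrogen_residual) <= atol * max(1, n)
    )
    return ConservationReport(
        ok=ok,
        carbo_residuals=carbo_residuals,
        nitrogen_residual=float(nitrogen_residual),
        carbo_lost=float(carbo_lost),
        nitrogen_lost=float(nitrogen_lost),
    )
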