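"""Per-cell fitness: growth limited by the scarcer resource.

A cell needs carbohydrate and fixed nitrogen in equal parts, so its
division propensity is the minimum of the two amounts available for its
own growth, plus a small base fitness ``eps_base`` that keeps every
division weight positive.  Photosynthetic fitness carries the relative
division rate ``sigma``; nitrogen-fixing cells split their kept
carbohydrate optimally between growth and nitrogen fixation.
"""

from __future__ import annotations

import numpy as np

from .model_core import Cell, ModelParams, Phenotype, Population, ResourceLedger

__all__ = [
    "optimal_fixation_fraction",
    "fitness_nitrogen_fixer",
    "fitness_photosynthetic",
    "apply_differentiation_cost",
    "division_probabilities",
    "population_fitness",
]

# floor factor for the constant-cost mode: fitness never drops below
# eps_base * COST_FLOOR_FACTOR, keeping selection weights positive
COST_FLOOR_FACTOR = 0.1


def optimal_fixation_fraction(n_keep: float, g: float, gamma: float) -> float:
    """Fraction s* of received carbohydrate a nitrogen fixer consumes in
    nitrogen fixation to maximise min(C, N) with C = (n_keep - s) g and
    N = gamma s g.  Closed form: s* = n_keep / (1 + gamma), independent
    of g."""
    if g < 0:
        raise ValueError("g must be >= 0")
    return n_keep / (1.0 + gamma)


def fitness_nitrogen_fixer(cell: Cell, g: float, params: ModelParams) -> float:
    """Division propensity of a nitrogen-fixing cell given received
    carbohydrate ``g``.

    Base model: W = eps + gamma * n_keep * g / (1 + gamma), the balanced
    optimum of min((n_keep - s) g, gamma s g).  Symmetric variant: the cell
    produces one unit of fixed nitrogen without consuming carbohydrate and
    W = eps + min(n_keep, g), mirroring the photosynthetic form.
    """
    if g < 0:
        raise ValueError("received carbohydrate g must be >= 0 (ledger corruption)")
    n_keep = cell.traits.n_keep
    if params.symmetric_variant:
        w = params.eps_base + min(n_keep * params.w_produce, g)
    else:
        s = optimal_fixation_fraction(n_keep, g, params.gamma)
        w = params.eps_base + min((n_keep - s) * g, params.gamma * s * g)
    return apply_differentiation_cost(w, cell, params)


def fitness_photosynthetic(cell: Cell, h: float, params: ModelParams) -> float:
    """Division propensity of a photosynthetic cell given received fixed
    nitrogen ``h``: W = eps + sigma * min(p_keep * w_produce, h)."""
    if h < 0:
        raise ValueError("received nitrogen h must be >= 0 (ledger corruption)")
    w = params.eps_base + params.sigma * min(cell.traits.p_keep * params.w_produce, h)
    return apply_differentiation_cost(w, cell, params)


def apply_differentiation_cost(w: float, cell: Cell, params: ModelParams) -> float:
    """Reduce fitness while the cell's differentiation cost is pending.

    Fractional mode multiplies by (1 - cost_frac); constant mode subtracts
    cost_const, floored at a small positive value so selection weights stay
    positive.
    """
    if not cell.cost_pending:
        return w
    if params.cost_mode == "constant":
        return max(w - params.cost_const, params.eps_base * COST_FLOOR_FACTOR)
    return w * (1.0 - params.cost_frac)


def division_probabilities(ledger: ResourceLedger) -> np.ndarray:
    """Fitness-proportional selection probabilities W_i / sum(W)."""
    W = ledger.fitness
    if W is None:
        raise ValueError("ledger has no fitness column; run population_fitness first")
    if np.any(W <= 0):
        raise RuntimeError("nonpositive fitness violates the base-fitness contract")
    return W / W.sum()


def population_fitness(
    pop: Population, ledger: ResourceLedger, params: ModelParams
) -> np.ndarray:
    """Vectorised fitness for every cell; also written into the ledger."""
    photo = pop.phenotype == 1
    p_keep = pop.traits[:, 0]
    n_keep = pop.traits[:, 2]
    w_p = params.eps_base + params.sigma * np.minimum(
        p_keep * params.w_produce, ledger.received_n
    )
    if params.symmetric_variant:
        w_n = params.eps_base + np.minimum(n_keep * params.w_produce, ledger.received_c)
    else:
        w_n = params.eps_base + params.gamma * n_keep * ledger.received_c / (
            1.0 + params.gamma
        )
    W = np.where(photo, w_p, w_n)
    pending = pop.cost_pending.astype(bool)
    if params.cost_mode == "constant":
        W = np.where(
            pending,
            np.maximum(W - params.cost_const, params.eps_base * COST_FLOOR_FACTOR),
            W,
        )
    else:
        W = np.where(pending, W * (1.0 - params.cost_frac), W)
    ledger.fitness = W
    return W
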