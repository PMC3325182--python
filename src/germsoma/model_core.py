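"""Domain types, parameters and the seeded random-state contract.

The model describes a filament of two metabolically complementary cell
types -- photosynthetic cells that produce carbohydrate, and nitrogen-fixing
cells that convert received carbohydrate into fixed nitrogen.  Every cell
carries four evolvable traits controlling how much of its product it keeps
and how often its daughters differentiate into the other type.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "Phenotype",
    "TraitVector",
    "Cell",
    "Population",
    "ModelParams",
    "ConfigurationError",
    "validate_params",
    "make_population",
    "spawn_streams",
    "ResourceLedger",
]

TRAIT_NAMES = ("p_keep", "p_diff", "n_keep", "n_diff")


class ConfigurationError(ValueError):
    """An invalid model configuration (bad parameter or initial state)."""


class Phenotype(enum.IntEnum):
    NITROGEN_FIXING = 0
    PHOTOSYNTHETIC = 1

    @property
    def short(self) -> str:
        return "P" if self is Phenotype.PHOTOSYNTHETIC else "N"


@dataclass(frozen=True)
class TraitVector:
    """The four evolvable traits of a cell, each in [0, 1].

    p_keep : fraction of produced carbohydrate a photosynthetic cell keeps.
    p_diff : probability a photosynthetic cell's post-division daughter
             differentiates into a nitrogen-fixing cell.
    n_keep : fraction of received carbohydrate a nitrogen-fixing cell keeps
             for its own growth (the rest is re-exported as fixed nitrogen).
    n_diff : probability a nitrogen-fixing cell's post-division daughter
             differentiates into a photosynthetic cell.
    """

    p_keep: float
    p_diff: float
    n_keep: float
    n_diff: float

    def __post_init__(self) -> None:
        for name in TRAIT_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"trait {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_keep, self.p_diff, self.n_keep, self.n_diff])

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "TraitVector":
        return cls(*(float(x) for x in arr))


@dataclass
class Cell:
    """One cell of the filament: phenotype, traits and pending cost flag.

    ``cost_pending`` is true from the moment the cell differentiated until
    the first time it is chosen for division.
    """

    phenotype: Phenotype
    traits: TraitVector
    cost_pending: bool = False


@dataclass(frozen=True)
class ModelParams:
    """All tunable parameters of the model.

    sigma       : relative division rate of photosynthetic cells (>0).
    eps_base    : small base fitness keeping division weights positive.
    gamma       : fixed nitrogen produced per carbohydrate consumed in
                  nitrogen fixation.
    cost_frac   : differentiation cost as a fitness fraction (fractional mode).
    cost_mode   : "fractional" or "constant".
    cost_const  : absolute fitness reduction in constant mode.
    k_range     : total number of interacting chain neighbours (even; K/2
                  on each side), uniform kernel.
    kernel      : "uniform" or "gaussian" interaction strength.
    gaussian_sd : width of the gaussian kernel (chain-distance units).
    mu_mut      : per-trait mutation probability at birth.
    delta_mut   : half-width of the uniform mutation step.
    symmetric_variant : if true, nitrogen fixers produce one unit of fixed
                  nitrogen without consuming carbohydrate, mirroring the
                  photosynthetic fitness form.
    topology    : "connected" (chain rejoins after death) or "broken"
                  (death fragments the filament permanently).
    w_produce   : carbohydrate produced per photosynthetic cell per step.
    """

    n_cells: int = 400
    sigma: float = 3.0
    eps_base: float = 0.01
    gamma: float = 1.0
    cost_frac: float = 0.0
    cost_mode: str = "fractional"
    cost_const: float = 0.0
    k_range: int = 2
    kernel: str = "uniform"
    gaussian_sd: float = 1.0
    mu_mut: float = 0.01
    delta_mut: float = 0.1
    symmetric_variant: bool = False
    topology: str = "broken"
    w_produce: float = 1.0
    seed: int = 0

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    @property
    def cost_active(self) -> bool:
        if self.cost_mode == "fractional":
            return self.cost_frac > 0.0
        return self.cost_const > 0.0


def validate_params(params: ModelParams) -> ModelParams:
    """Check every parameter invariant; raise ConfigurationError naming the
    offending field, otherwise return ``params`` unchanged."""
    p = params
    if p.n_cells < 2:
        raise ConfigurationError("n_cells must be >= 2")
    if not p.sigma > 0:
        raise ConfigurationError("sigma must be > 0")
    if not p.eps_base > 0:
        raise ConfigurationError("eps_base must be > 0")
    if not p.gamma > 0:
        raise ConfigurationError("gamma must be > 0")
    if not (0.0 <= p.cost_frac < 1.0):
        raise ConfigurationError("cost_frac must be in [0, 1)")
    if p.cost_mode not in ("fractional", "constant"):
        raise ConfigurationError("cost_mode must be 'fractional' or 'constant'")
    if p.cost_const < 0:
        raise ConfigurationError("cost_const must be >= 0")
    if p.k_range < 1:
        raise ConfigurationError("k_range must be >= 1")
    if p.kernel == "uniform" and p.k_range % 2 != 0:
        raise ConfigurationError("k_range must be even (K/2 neighbours per side)")
    if p.kernel not in ("uniform", "gaussian"):
        raise ConfigurationError("kernel must be 'uniform' or 'gaussian'")
    if p.kernel == "gaussian" and not p.gaussian_sd > 0:
        raise ConfigurationError("gaussian_sd must be > 0")
    if not (0.0 <= p.mu_mut <= 1.0):
        raise ConfigurationError("mu_mut must be in [0, 1]")
    if p.delta_mut < 0:
        raise ConfigurationError("delta_mut must be >= 0")
    if p.topology not in ("connected", "broken"):
        raise ConfigurationError("topology must be 'connected' or 'broken'")
    if not p.w_produce > 0:
        raise ConfigurationError("w_produce must be > 0")
    return p


class Population:
    """Ordered cells on a ring or a set of chain fragments.

    State is held in flat arrays for speed:

    phenotype   : int8[n], 1 = photosynthetic, 0 = nitrogen fixing.
    traits      : float64[n, 4] columns (p_keep, p_diff, n_keep, n_diff).
    cost_pending: uint8[n].
    break_after : uint8[n]; ``break_after[i] == 1`` means there is no
                  adjacency between position i and position (i+1) % n.
                  A ring has no breaks; fragments are the maximal runs
                  between breaks.
    """

    def __init__(
        self,
        phenotype: np.ndarray,
        traits: np.ndarray,
        cost_pending: np.ndarray | None = None,
        break_after: np.ndarray | None = None,
        topology: str = "broken",
    ) -> None:
        n = len(phenotype)
        if n < 2:
            raise ConfigurationError("population needs at least 2 cells")
        self.phenotype = np.asarray(phenotype, dtype=np.int8).copy()
        self.traits = np.asarray(traits, dtype=np.float64).reshape(n, 4).copy()
        if np.any(self.traits < 0) or np.any(self.traits > 1):
            raise ConfigurationError("traits outside [0, 1]")
        self.cost_pending = (
            np.zeros(n, dtype=np.uint8)
            if cost_pending is None
            else np.asarray(cost_pending, dtype=np.uint8).copy()
        )
        self.break_after = (
            np.zeros(n, dtype=np.uint8)
            if break_after is None
            else np.asarray(break_after, dtype=np.uint8).copy()
        )
        if topology not in ("connected", "broken"):
            raise ConfigurationError("topology must be 'connected' or 'broken'")
        self.topology = topology

    def __len__(self) -> int:
        return len(self.phenotype)

    @property
    def n_fragments(self) -> int:
        """Number of maximal chains (a ring with no breaks is one fragment)."""
        return max(1, int(self.break_after.sum()))

    @property
    def fragments(self) -> list[list[int]]:
        """Index partition into maximal chains, in ring order."""
        n = len(self)
        breaks = np.flatnonzero(self.break_after)
        if breaks.size == 0:
            return [list(range(n))]
        frags = []
        order = np.concatenate([np.arange(breaks[-1] + 1, n), np.arange(breaks[-1] + 1)])
        cur: list[int] = []
        for i in order:
            cur.append(int(i))
            if self.break_after[i]:
                frags.append(cur)
                cur = []
        return frags

    @property
    def cells(self) -> list[Cell]:
        return [
            Cell(
                Phenotype(int(self.phenotype[i])),
                TraitVector.from_array(self.traits[i]),
                bool(self.cost_pending[i]),
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_cells(cls, cells: Sequence[Cell], topology: str = "broken") -> "Population":
        pheno = np.array([int(c.phenotype) for c in cells], dtype=np.int8)
        traits = np.stack([c.traits.as_array() for c in cells])
        cost = np.array([c.cost_pending for c in cells], dtype=np.uint8)
        return cls(pheno, traits, cost, topology=topology)

    def copy(self) -> "Population":
        return Population(
            self.phenotype, self.traits, self.cost_pending, self.break_after, self.topology
        )


InitSpec = Union[TraitVector, str, Sequence[Cell]]


def make_population(
    n_cells: int,
    init: InitSpec,
    rng: np.random.Generator,
    topology: str = "broken",
) -> Population:
    """Build the initial ring population.

    ``init`` is a :class:`TraitVector` applied homogeneously, the string
    ``"random"`` (one trait vector drawn uniformly on [0,1]^4 and applied
    homogeneously -- the random-initial-conditions design), or an explicit
    cell list for testing.  Phenotypes are i.i.d. Bernoulli(1/2) unless an
    explicit cell list fixes them.
    """
    if n_cells < 2:
        raise ConfigurationError("n_cells must be >= 2")
    if isinstance(init, TraitVector):
        tv = init.as_array()
    elif isinstance(init, str):
        if init != "random":
            raise ConfigurationError(f"unknown init spec {init!r}")
        tv = rng.uniform(0.0, 1.0, size=4)
    else:
        cells = list(init)
        if len(cells) != n_cells:
            raise ConfigurationError("explicit cell list length != n_cells")
        return Population.from_cells(cells, topology=topology)
    pheno = rng.integers(0, 2, size=n_cells).astype(np.int8)
    traits = np.tile(tv, (n_cells, 1))
    return Population(pheno, traits, topology=topology)


def spawn_streams(seed: int, n_extra: int = 0) -> dict:
    """Root-seed contract: independent child generators for initialization,
    selection/evolution, and optional replicate streams."""
    ss = np.random.SeedSequence(seed)
    init_ss, evo_ss, rep_ss = ss.spawn(3)
    streams = {
        "init": np.random.default_rng(init_ss),
        "evolution": np.random.default_rng(evo_ss),
    }
    if n_extra:
        streams["replicates"] = [np.random.default_rng(s) for s in rep_ss.spawn(n_extra)]
    return streams


@dataclass
class ResourceLedger:
    """Per-cell resource accounting for one production/exchange phase.

    produced_c : carbohydrate produced (1 per photosynthetic cell).
    received_c : carbohydrate received by nitrogen-fixing cells (g).
    received_n : fixed nitrogen received by photosynthetic cells (h).
    fix_fraction : optimal fraction of received carbohydrate consumed in
                 nitrogen fixation (s*).
    avail_c / avail_n : resources available for the cell's own growth.
    fitness    : division propensity W.
    """

    produced_c: np.ndarray
    received_c: np.ndarray
    received_n: np.ndarray
    fix_fraction: np.ndarray
    avail_c: np.ndarray
    avail_n: np.ndarray
    fitness: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self, pop: Population):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": np.arange(len(pop)),
                "phenotype": [Phenotype(int(x)).short for x in pop.phenotype],
                "g": self.received_c,
                "h": self.received_n,
                "C": self.avail_c,
                "N": self.avail_n,
                "W": self.fitness,
            }
        )
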