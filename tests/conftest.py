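import numpy as np
import pytest

from germsoma import Cell, ModelParams, Phenotype, Population, TraitVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_params():
    return ModelParams(n_cells=10, sigma=3.0, k_range=2, topology="broken")


def alternating_population(n, traits=TraitVector(0.5, 0.1, 0.5, 0.1), topology="broken"):
    """Ring of n cells with phenotypes P, N, P, N, ..."""
    cells = [
        Cell(Phenotype.PHOTOSYNTHETIC if i % 2 == 0 else Phenotype.NITROGEN_FIXING, traits)
        for i in range(n)
    ]
    return Population.from_cells(cells, topology=topology)


def random_population(n, rng, topology="broken", p_break=0.0):
    """Random phenotypes, traits, and (optionally) chain breaks."""
    pop = Population(
        rng.integers(0, 2, n).astype(np.int8),
        rng.random((n, 4)),
        topology=topology,
    )
    if p_break:
        pop.break_after = (rng.random(n) < p_break).astype(np.uint8)
    return pop
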