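import numpy as np
import pytest

from germsoma import (
    Cell,
    ConfigurationError,
    ModelParams,
    Phenotype,
    Population,
    TraitVector,
    run_generation,
    run_simulation,
    step,
)
from germsoma import _kernel
from germsoma.evolution_engine import _Buffers

from _reference import ref_step, state_arrays, state_from_population
from conftest import alternating_population, random_population

P, N = Phenotype.PHOTOSYNTHETIC, Phenotype.NITROGEN_FIXING


class TestStep:
    def test_clone_daughter_without_mutation_or_differentiation(self, rng):
        traits = TraitVector(0.5, 0.0, 0.5, 0.0)
        pop = alternating_population(6, traits)
        params = ModelParams(n_cells=6, mu_mut=0.0)
        before = {tuple(t) for t in pop.traits}
        pop, event = step(pop, params, rng)
        assert len(pop) == 6
        assert not event.differentiated
        assert not any(event.mutated_traits)
        assert {tuple(t) for t in pop.traits} <= before

    def test_certain_differentiation_flips_daughter(self):
        # all-photosynthetic parents with p_diff=1: every daughter is a
        # nitrogen fixer carrying the pending cost when costs are active
        traits = TraitVector(0.5, 1.0, 0.5, 0.0)
        cells = [Cell(P, traits) for _ in range(6)]
        pop = Population.from_cells(cells)
        params = ModelParams(n_cells=6, mu_mut=0.0, cost_frac=0.2)
        u = np.zeros((1, _kernel.N_UNIFORMS))
        u[0, 1] = 0.9  # daughter to the right of parent 0
        u[0, 11] = 0.99  # death hits the last cell, not the daughter
        buf = _Buffers(pop)
        events = buf.run(params, u)
        buf.write_back(pop)
        assert events[0, 2] == 1  # differentiated
        assert pop.phenotype[1] == 0  # daughter is a nitrogen fixer
        assert pop.cost_pending[1] == 1  # carrying the pending cost

    def test_population_size_invariant(self, rng):
        pop = random_population(9, rng)
        params = ModelParams(n_cells=9)
        for _ in range(50):
            pop, _ = step(pop, params, rng)
            assert len(pop) == 9

    def test_broken_death_severs_adjacency(self):
        """Deterministic single event on a ring: daughter insertion then a
        death in broken mode leaves exactly one severed edge."""
        pop = alternating_population(6, topology="broken")
        params = ModelParams(n_cells=6, mu_mut=0.0)
        u = np.zeros((1, _kernel.N_UNIFORMS))
        u[0, 11] = 0.4  # death at index floor(0.4*7) = 2
        buf = _Buffers(pop)
        buf.run(params, u)
        buf.write_back(pop)
        assert pop.break_after.sum() == 1
        assert pop.n_fragments == 1  # one break turns the ring into a chain

    def test_connected_death_rejoins(self, rng):
        pop = alternating_population(6, topology="connected")
        params = ModelParams(n_cells=6, topology="connected")
        for _ in range(30):
            pop, _ = step(pop, params, rng)
            assert pop.n_fragments == 1
            assert pop.break_after.sum() == 0


class TestKernelAgainstReference:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"topology": "broken"},
            {"topology": "connected"},
            {"topology": "broken", "kernel": "gaussian", "gaussian_sd": 1.2},
            {"topology": "broken", "symmetric_variant": True, "sigma": 1.0},
            {"topology": "connected", "cost_frac": 0.3},
            {"topology": "broken", "cost_mode": "constant", "cost_const": 0.2},
            {"topology": "broken", "k_range": 6},
        ],
    )
    def test_exact_state_match_over_many_events(self, kwargs):
        """The numba kernel and the naive pure-Python step produce
        bit-identical states when fed the same uniform stream."""
        params = ModelParams(n_cells=24, mu_mut=0.2, **kwargs)
        rng = np.random.default_rng(99)
        pop = random_population(24, rng, topology=params.topology)
        state = state_from_population(pop)
        u = rng.random((250, _kernel.N_UNIFORMS))
        buf = _Buffers(pop)
        for t in range(u.shape[0]):
            buf.run(params, u[t : t + 1])
            ref_step(state, params, u[t])
        buf.write_back(pop)
        ref_pheno, ref_traits, ref_cost, ref_flags = state_arrays(state)
        np.testing.assert_array_equal(pop.phenotype, ref_pheno)
        np.testing.assert_array_equal(pop.cost_pending, ref_cost)
        np.testing.assert_array_equal(pop.break_after, ref_flags)
        np.testing.assert_allclose(pop.traits, ref_traits, atol=1e-14)


class TestRunGeneration:
    def test_one_generation_is_n_cells_events(self, rng):
        pop = alternating_population(8)
        params = ModelParams(n_cells=8)
        pop, summary = run_generation(pop, params, rng)
        assert summary["n_photo"] + summary["n_fixer"] == 8

    def test_frozen_rng_reproducible(self):
        params = ModelParams(n_cells=12)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            pop = alternating_population(12)
            _, summary = run_generation(pop, params, rng)
            outs.append(summary)
        assert outs[0] == outs[1]

    def test_all_photosynthetic_is_absorbing_and_starved(self, rng):
        traits = TraitVector(0.5, 0.0, 0.5, 0.0)
        pop = Population.from_cells([Cell(P, traits) for _ in range(8)])
        params = ModelParams(n_cells=8, mu_mut=0.0)
        for gen in range(3):
            pop, summary = run_generation(pop, params, rng, generation=gen)
            assert summary["n_fixer"] == 0
            assert summary["mean_fitness_photo"] == pytest.approx(params.eps_base)


class TestRunSimulation:
    def test_zero_generations_rejected(self):
        with pytest.raises(ConfigurationError):
            run_simulation(ModelParams(n_cells=8), 0)

    def test_trajectory_shape_and_determinism(self):
        params = ModelParams(n_cells=20, seed=3)
        a = run_simulation(params, 10)
        b = run_simulation(params, 10)
        assert len(a.trajectory) == 10
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.final_population.traits, b.final_population.traits)

    def test_different_seeds_diverge(self):
        params = ModelParams(n_cells=20)
        a = run_simulation(params.with_(seed=1), 20)
        b = run_simulation(params.with_(seed=2), 20)
        assert not a.trajectory.equals(b.trajectory)

    def test_connected_mode_keeps_single_fragment(self):
        params = ModelParams(n_cells=20, topology="connected", seed=1)
        res = run_simulation(params, 20)
        assert (res.trajectory["n_fragments"] == 1).all()

    def test_broken_mode_fragments_accumulate(self):
        params = ModelParams(n_cells=30, topology="broken", seed=1)
        res = run_simulation(params, 30)
        frags = res.trajectory["n_fragments"]
        assert frags.iloc[-1] > 1


class TestEvolutionInvariants:
    def test_heritability_without_mutation(self, rng):
        """Absent mutation, the set of distinct trait vectors can only
        shrink -- lineages are lost, never invented."""
        pop = random_population(15, rng)
        params = ModelParams(n_cells=15, mu_mut=0.0)
        initial = {tuple(t) for t in pop.traits}
        for _ in range(200):
            pop, _ = step(pop, params, rng)
        assert {tuple(t) for t in pop.traits} <= initial

    def test_trait_clipping_stress(self, rng):
        """No operation ever produces a trait outside [0, 1], even under
        extreme mutation pressure."""
        pop = random_population(12, rng)
        params = ModelParams(n_cells=12, mu_mut=1.0, delta_mut=1.0)
        for _ in range(300):
            pop, _ = step(pop, params, rng)
        assert np.all(pop.traits >= 0.0)
        assert np.all(pop.traits <= 1.0)

    def test_neutral_drift_unbiased(self):
        """sigma=1, symmetric fitness, no mutation, homogeneous traits:
        phenotype counts perform an unbiased random walk."""
        params = ModelParams(
            n_cells=100, sigma=1.0, symmetric_variant=True, mu_mut=0.0
        )
        drifts = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            pop = alternating_population(100, TraitVector(0.5, 0.5, 0.5, 0.5))
            start = int((pop.phenotype == 1).sum())
            buf = _Buffers(pop)
            u = rng.random((500, _kernel.N_UNIFORMS))
            buf.run(params, u)
            buf.write_back(pop)
            drifts.append(int((pop.phenotype == 1).sum()) - start)
        drifts = np.array(drifts, dtype=float)
        se = drifts.std(ddof=1) / np.sqrt(len(drifts))
        assert abs(drifts.mean()) <= 3 * max(se, 1e-9)
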