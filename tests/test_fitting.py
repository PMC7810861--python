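"""Objective decomposition, GA operators, and small-scale optimisation."""

import numpy as np
import pytest

from neurogrn.deterministic import Trajectory
from neurogrn.fitting import (
    FitConfig,
    WORST_FITNESS,
    decode_genome,
    decode_hill,
    encode_hill,
    encode_params,
    fitness,
    genome_spec,
    mutate,
    objective_terms,
    run_ga,
    smoothness_penalty,
    sse_term,
    stability_penalty,
    uniform_crossover,
)
from neurogrn.network import NetworkTopology, ParameterSet


class TestHillTransform:
    def test_midpoint(self):
        assert decode_hill(1.0) == pytest.approx(2.0)

    def test_bounded_above_by_four(self):
        for raw in (1e-6, 0.1, 1.0, 10.0, 1e6, 1e12):
            assert 0.0 < decode_hill(raw) < 4.0

    def test_unit_exponent_at_one_third(self):
        assert decode_hill(1.0 / 3.0) == pytest.approx(1.0)

    def test_monotone_increasing(self):
        raws = np.logspace(-3, 3, 50)
        decoded = [decode_hill(r) for r in raws]
        assert np.all(np.diff(decoded) > 0)

    def test_round_trip_with_encoder(self):
        for h in (0.2, 1.0, 2.0, 3.9):
            assert decode_hill(encode_hill(h)) == pytest.approx(h)

    def test_non_positive_raw_rejected(self):
        with pytest.raises(ValueError):
            decode_hill(0.0)


def _flat_dataset(nodes, value=1.0, offsets=None):
    """Synthetic dataset whose every anchor median equals ``value`` (+offset)."""
    import pandas as pd

    from neurogrn.synth import CANONICAL_ANCHORS, TimeSeriesDataset

    offsets = offsets or {}
    rows = []
    binding = {n: n for n in nodes}
    for n in nodes:
        for stage, t in CANONICAL_ANCHORS:
            for r in range(3):
                rows.append((n, stage, t, r, value + offsets.get(n, 0.0)))
    frame = pd.DataFrame(rows, columns=["factor", "stage", "time_h", "replicate", "value"])
    return TimeSeriesDataset(data=frame, binding=binding)


def _constant_trajectory(nodes, stage, duration, value=1.0, step=0.05):
    times = np.arange(0.0, duration + step / 2, step)
    values = np.full((len(times), len(nodes)), value)
    return Trajectory(times, values, tuple(nodes), stage=stage)


class TestSSETerm:
    NODES = ("A", "B")

    def _trajs(self, value):
        return {
            "fibroblast": _constant_trajectory(self.NODES, "fibroblast", 72.0, value),
            "rest_kd": _constant_trajectory(self.NODES, "rest_kd", 72.0, value),
            "conversion": _constant_trajectory(self.NODES, "conversion", 120.0, value),
        }

    def test_exact_match_scores_zero(self):
        assert sse_term(self._trajs(1.0), _flat_dataset(self.NODES)) == 0.0

    def test_six_comparisons_per_factor(self):
        # one factor offset by 0.1 at all six anchors: 6 * 0.01
        dataset = _flat_dataset(self.NODES, offsets={"A": -0.1})
        assert sse_term(self._trajs(1.0), dataset) == pytest.approx(0.06)

    def test_five_conversion_anchors(self):
        # mismatch of +1 only in the conversion stage for one factor
        trajs = self._trajs(1.0)
        trajs["conversion"] = _constant_trajectory(self.NODES, "conversion", 120.0, 2.0)
        dataset = _flat_dataset(self.NODES)
        # both factors mismatch at 5 conversion anchors each
        assert sse_term(trajs, dataset) == pytest.approx(10.0)

    def test_missing_anchor_names_factor_and_time(self):
        dataset = _flat_dataset(self.NODES)
        short = {
            **self._trajs(1.0),
            "conversion": _constant_trajectory(self.NODES, "conversion", 48.0),
        }
        with pytest.raises(KeyError):
            sse_term(short, dataset)


class TestSmoothnessPenalty:
    def test_linear_trajectory_has_zero_curvature(self):
        times = np.arange(0.0, 120.0 + 0.025, 0.05)
        values = np.outer(times, [0.3, -0.1]) + 1.0
        traj = Trajectory(times, values, ("A", "B"), stage="conversion")
        assert smoothness_penalty(traj, lam=1.0) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_trajectory_integrates_to_two_t(self):
        T = 120.0
        times = np.arange(0.0, T + 0.025, 0.05)
        traj = Trajectory(times, (times**2)[:, None], ("A",), stage="conversion")
        assert smoothness_penalty(traj, lam=1.0) == pytest.approx(2 * T, rel=1e-6)

    def test_zero_weight_short_circuits(self):
        times = np.arange(0.0, 120.0 + 0.025, 0.05)
        traj = Trajectory(times, np.sin(times)[:, None], ("A",), stage="conversion")
        assert smoothness_penalty(traj, lam=0.0) == 0.0

    def test_short_trajectory_rejected(self):
        traj = _constant_trajectory(("A",), "conversion", 24.0)
        with pytest.raises(ValueError):
            smoothness_penalty(traj, lam=1.0)


class TestStabilityPenalty:
    def _model(self, alpha, delta):
        topo = NetworkTopology(("X",), frozenset())
        params = ParameterSet(
            alpha={"X": alpha}, delta={"X": delta}, beta={}, k={}, h={},
            beta_resti=1.0, beta_vascl1=1.0,
        )
        return topo, params

    def test_steady_state_scores_zero(self):
        topo, params = self._model(0.5, 0.5)
        traj = _constant_trajectory(("X",), "fibroblast", 72.0, 1.0)
        assert stability_penalty(traj, 1.0, topo, params) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decay_scores_total_variation(self):
        # decay from 1 toward alpha/delta = 0.5: total variation ~ 0.4997
        from neurogrn.deterministic import integrate_stage
        from neurogrn.engine import compile_model

        topo, params = self._model(0.05, 0.1)
        traj = integrate_stage(compile_model(topo, params, ()), {"X": 1.0}, 72.0)
        expect = abs(traj.at(72.0, "X") - 1.0)
        assert stability_penalty(traj, 1.0, topo, params) == pytest.approx(expect, rel=1e-4)

    def test_zero_weight_short_circuits(self):
        topo, params = self._model(1.0, 0.1)
        traj = _constant_trajectory(("X",), "fibroblast", 72.0, 1.0)
        assert stability_penalty(traj, 0.0, topo, params) == 0.0

    def test_wrong_stage_rejected(self):
        topo, params = self._model(1.0, 1.0)
        traj = _constant_trajectory(("X",), "conversion", 72.0, 1.0)
        with pytest.raises(ValueError):
            stability_penalty(traj, 1.0, topo, params)


class TestFitness:
    def test_decomposition_is_exactly_minus_sum_of_terms(self, truth, noiseless_dataset):
        topo, params = truth
        dataset, _ = noiseless_dataset
        cfg = FitConfig()
        genome = encode_params(params, topo)
        sse, r1, r2 = objective_terms(params, topo, dataset, cfg)
        assert fitness(genome, topo, dataset, cfg) == pytest.approx(-(sse + r1 + r2))

    def test_self_consistency_on_noiseless_data(self, truth, noiseless_dataset):
        """The generating genome scores ~ -R1(truth): SSE = 0 and R2 ~ 0."""
        topo, params = truth
        dataset, _ = noiseless_dataset
        cfg = FitConfig()
        sse, r1, r2 = objective_terms(params, topo, dataset, cfg)
        assert sse == pytest.approx(0.0, abs=1e-12)
        assert r2 < 5e-3
        assert fitness(encode_params(params, topo), topo, dataset, cfg) == pytest.approx(
            -(r1 + r2)
        )

    def test_undecodable_genome_gets_worst_sentinel(self, truth, noiseless_dataset):
        topo, _ = truth
        dataset, _ = noiseless_dataset
        bad = np.full(len(genome_spec(topo)), -1.0)
        assert fitness(bad, topo, dataset, FitConfig()) == WORST_FITNESS


class TestGenomeCodec:
    def test_round_trip(self, nptb_topo, rng):
        from conftest import random_params

        params = random_params(nptb_topo, rng)
        genome = encode_params(params, nptb_topo)
        back = decode_genome(genome, nptb_topo)
        assert back.alpha == pytest.approx(params.alpha)
        assert back.k == pytest.approx(params.k)
        for pair in params.h:
            assert back.h[pair] == pytest.approx(params.h[pair])

    def test_literature_and_variant_lengths_differ_by_edge_parameters(
        self, lit_topo, nptb_topo
    ):
        # one extra edge adds k and h; the target also gains a background beta
        assert len(genome_spec(nptb_topo)) == len(genome_spec(lit_topo)) + 3


class TestMutation:
    def test_identity_when_no_component_fires(self, rng):
        genome = np.ones(10)
        # with all three hit probabilities ~ 0 the genome passes unchanged
        out = mutate(genome, np.random.default_rng(0))
        changed = np.sum(out != genome)
        assert changed <= 4  # sparse operator: a handful of genes at most

    def test_expected_fraction_touched_by_first_component(self):
        """m(2/n, 1.01): on average 2 genes per genome are rescaled."""
        n, trials = 30, 4000
        rng = np.random.default_rng(1)
        touched = 0
        for _ in range(trials):
            out = mutate(np.ones(n), rng)
            touched += np.sum(out != 1.0)
        per_genome = touched / trials
        # three components: expectation 2 + 2/3 + 1/5 genes per genome
        assert per_genome == pytest.approx(2 + 2 / 3 + 1 / 5, rel=0.1)

    def test_non_unit_factors_are_log_normal_at_the_requested_scale(self):
        """Mixture components draw log-normal factors at the given log-sigma;
        the coarse operator component uses geometric standard deviation 1.5."""
        from scipy import stats

        from neurogrn.fitting import _mixture_factors

        rng = np.random.default_rng(2)
        sigma = np.log(1.5)
        factors = _mixture_factors(100_000, p=1.0, sigma=sigma, rng=rng)
        logs = np.log(factors)
        assert logs.std() == pytest.approx(sigma, rel=0.02)
        _, pvalue = stats.kstest(logs / logs.std(), "norm")
        assert pvalue > 0.01

    def test_operator_step_scales_span_fine_to_coarse(self):
        """Non-unit mutation factors range from ~1% tweaks to ~50% jumps."""
        from neurogrn.fitting import mutate

        rng = np.random.default_rng(3)
        logs = []
        for _ in range(3000):
            out = mutate(np.ones(31), rng)
            logs.extend(np.log(out[out != 1.0]))
        logs = np.abs(logs)
        assert np.median(logs) < 0.05  # most hits come from the fine component
        assert logs.max() > 0.3  # coarse jumps do occur

    def test_mutation_preserves_positivity(self, rng):
        genome = np.full(31, 1e-8)
        for _ in range(100):
            genome = mutate(genome, rng)
            assert np.all(genome > 0)


def test_uniform_crossover_exchanges_genes_elementwise(rng):
    a, b = np.zeros(1000), np.ones(1000)
    c1, c2 = uniform_crossover(a, b, rng)
    assert np.all((c1 == 0) | (c1 == 1))
    np.testing.assert_array_equal(c1 + c2, np.ones(1000))
    assert 0.4 < c1.mean() < 0.6


class TestRunGA:
    def test_best_fitness_trace_is_monotone(self, truth, noiseless_dataset):
        topo, _ = truth
        dataset, _ = noiseless_dataset
        res = run_ga(topo, dataset, FitConfig(population=12, generations=5, seed=3))
        assert np.all(np.diff(res.trace) >= 0)

    def test_zero_generations_returns_best_of_initial_population(
        self, truth, noiseless_dataset
    ):
        topo, _ = truth
        dataset, _ = noiseless_dataset
        res = run_ga(topo, dataset, FitConfig(population=10, generations=0, seed=4))
        assert len(res.trace) == 1
        assert np.isfinite(res.best_fitness) or res.best_fitness == WORST_FITNESS

    def test_toy_objective_reaches_optimum(self, monkeypatch):
        """On the separable toy -(sum (g - c)^2) the GA gets within 1e-2."""
        import neurogrn.fitting as fitting_mod

        target = 0.37
        n_genes = 8

        def toy_fitness(genome, topology, dataset, config):
            return -float(np.sum((np.asarray(genome) - target) ** 2))

        monkeypatch.setattr(fitting_mod, "fitness", toy_fitness)
        monkeypatch.setattr(
            fitting_mod, "genome_spec", lambda topo: tuple(("g", i) for i in range(n_genes))
        )
        monkeypatch.setattr(fitting_mod, "decode_genome", lambda g, topo: None)
        res = fitting_mod.run_ga(None, None, FitConfig(population=60, generations=400, seed=5))
        assert res.best_fitness > -1e-2

    def test_seeding_with_truth_genome_dominates_random_start(
        self, truth, noiseless_dataset
    ):
        topo, params = truth
        dataset, _ = noiseless_dataset
        seeded = run_ga(
            topo,
            dataset,
            FitConfig(
                population=10,
                generations=2,
                seed=6,
                seed_genomes=(encode_params(params, topo),),
            ),
        )
        random_start = run_ga(topo, dataset, FitConfig(population=10, generations=2, seed=6))
        assert seeded.best_fitness >= random_start.best_fitness


class TestEmbedGenome:
    def test_embedding_is_near_equivalent_on_the_richer_topology(
        self, lit_topo, nptb_topo, rng, noiseless_dataset
    ):
        """A literature fit embedded into the nPTB -> PTB space scores nearly
        the same fitness: the added edge starts silent and the new background
        reproduces the pure-repression form."""
        from conftest import random_params
        from neurogrn.fitting import embed_genome

        dataset, _ = noiseless_dataset
        cfg = FitConfig()
        for _ in range(3):
            params = random_params(lit_topo, rng)
            g = encode_params(params, lit_topo)
            f_lit = fitness(g, lit_topo, dataset, cfg)
            f_emb = fitness(embed_genome(g, lit_topo, nptb_topo), nptb_topo, dataset, cfg)
            assert f_emb == pytest.approx(f_lit, rel=0.05, abs=0.05)

    def test_large_background_tightens_the_embedding(
        self, lit_topo, nptb_topo, rng, noiseless_dataset
    ):
        from conftest import random_params
        from neurogrn.fitting import embed_genome

        dataset, _ = noiseless_dataset
        cfg = FitConfig()
        params = random_params(lit_topo, np.random.default_rng(5))
        g = encode_params(params, lit_topo)
        f_lit = fitness(g, lit_topo, dataset, cfg)
        errs = [
            abs(fitness(embed_genome(g, lit_topo, nptb_topo, background=b),
                        nptb_topo, dataset, cfg) - f_lit)
            for b in (10.0, 1000.0)
        ]
        assert errs[1] <= errs[0]
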