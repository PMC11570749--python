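"""Degree-distribution constraints, fitness, evaluation, optimizers."""

import numpy as np
import pytest

from oligofountain.distributions import (
    DegreeDistribution,
    enforce_constraints,
    raptor_rfc5053,
    robust_soliton,
    builtin_distributions,
)
from oligofountain.optimize import (
    DistributionMetrics,
    FitnessWeights,
    OptimizerConfig,
    evaluate_distribution,
    fitness,
    optimize,
)
from oligofountain.rules import RuleSet


def assert_valid(dist: DegreeDistribution):
    p = dist.array
    assert p.shape == (40,)
    assert np.all(p >= 0) and np.all(p < 1)
    assert abs(p.sum() - 1) < 1e-9
    assert p[0] > 0
    assert np.count_nonzero(p) >= 2


class TestBuiltins:
    def test_raptor_table(self, raptor):
        assert_valid(raptor)
        assert raptor.prob(2) == 481341 / 1048576
        assert round((1 << 16) * raptor.prob(2)) == 30084
        assert sum(raptor.probs) == pytest.approx(1.0, abs=1e-12)

    def test_robust_soliton_closed_form(self):
        import math

        n, c, delta = 30, 0.1, 0.05
        dist = robust_soliton(n, c, delta)
        assert_valid(dist)
        # recompute rho + tau independently and compare after normalization
        R = c * math.log(n / delta) * math.sqrt(n)
        spike = min(max(int(round(n / R)), 1), n)
        mu = np.zeros(n + 1)
        mu[1] = 1 / n + R / n
        for d in range(2, n + 1):
            mu[d] = 1 / (d * (d - 1)) + (R / (d * n) if d < spike else 0.0)
        mu[spike] += R * math.log(R / delta) / n
        mu /= mu.sum()
        np.testing.assert_allclose(dist.array[:n], mu[1 : n + 1], atol=1e-12)

    def test_robust_soliton_normalizes_for_random_params(self):
        rng = np.random.RandomState(0)
        for _ in range(20):
            dist = robust_soliton(
                int(rng.randint(5, 500)), float(rng.uniform(0.01, 0.3)),
                float(rng.uniform(0.001, 0.5)),
            )
            assert_valid(dist)

    def test_invalid_soliton_params(self):
        with pytest.raises(ValueError):
            robust_soliton(1)
        with pytest.raises(ValueError):
            robust_soliton(100, c=-1)

    def test_builtin_registry(self):
        d = builtin_distributions(n=50)
        assert set(d) == {"raptor_rfc5053", "robust_soliton"}

    def test_json_roundtrip(self, tmp_path, raptor):
        raptor.to_json(tmp_path / "d.json")
        assert DegreeDistribution.from_json(tmp_path / "d.json") == raptor


class TestEnforceConstraints:
    def test_idempotent_on_valid(self, raptor):
        rng = np.random.RandomState(1)
        out = enforce_constraints(raptor.array, rng)
        np.testing.assert_allclose(out.array, raptor.array, atol=1e-9)

    def test_single_mass_gets_repaired(self):
        raw = np.zeros(40)
        raw[6] = 5.0
        out = enforce_constraints(raw, np.random.RandomState(2))
        assert out.prob(1) > 0 and np.count_nonzero(out.array) >= 2

    def test_random_vectors_all_pass(self):
        rng = np.random.RandomState(3)
        for _ in range(1000):
            raw = rng.normal(0, 1, 40) * rng.choice([0.01, 1, 100])
            assert_valid(enforce_constraints(raw, rng))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            enforce_constraints(np.full(40, np.nan), np.random.RandomState(0))


class TestFitness:
    def test_zero_metrics(self):
        m = DistributionMetrics(0, 0, 0, 0, 0)
        assert fitness(m, FitnessWeights()) == 0.0

    def test_reported_weights_weighted_sum(self):
        m = DistributionMetrics(
            overhead=2.0, avg_err=0.5, clean_avg_err=0.25,
            non_unique_packets=100, unrecovered_packets=7,
        )
        w = FitnessWeights(0.4, 0.1, 0.1, 0.3, 0.1)
        expected = 0.4 * 2 + 0.1 * 0.5 + 0.1 * 0.25 + 0.3 * 100 + 0.1 * 7
        assert fitness(m, w) == pytest.approx(expected)

    def test_linearity(self):
        m = DistributionMetrics(1.5, 0.3, 0.2, 10, 2)
        w1 = FitnessWeights(0.4, 0.1, 0.1, 0.3, 0.1)
        w2 = FitnessWeights(0.8, 0.2, 0.2, 0.6, 0.2)
        assert fitness(m, w2) == pytest.approx(2 * fitness(m, w1))

    def test_weight_guards(self):
        with pytest.raises(ValueError):
            FitnessWeights(0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            FitnessWeights(-1, 0, 0, 0, 1)


def _tiny_config(**kw):
    defaults = dict(
        files=[bytes(400)],
        chunk_sizes=(40,),
        population=6,
        generations=2,
        reps_per_decode=4,
        seed_range=(0, 512),
        rules=RuleSet(h_max=3),
        rng_seed=0,
    )
    defaults.update(kw)
    return OptimizerConfig(**defaults)


class TestEvaluate:
    def test_all_violating_pool_has_high_avg_err(self):
        # constant input, no masking: almost every packet is an A-run
        cfg = _tiny_config()
        m = evaluate_distribution(raptor_rfc5053(), cfg)
        assert m.avg_err >= 1.0

    def test_degree_one_forcing_pigeonhole(self):
        p = np.zeros(40)
        p[0] = 1 - 1e-9
        p[1] = 1e-9
        dist = DegreeDistribution(tuple(p / p.sum()))
        cfg = _tiny_config(files=[bytes(range(200))], chunk_sizes=(20,))
        m = evaluate_distribution(dist, cfg)
        # n=10 chunks, 512 seeds, all degree 1: only n unique payloads
        assert m.non_unique_packets == 512 - 10

    def test_deterministic(self):
        cfg = _tiny_config()
        a = evaluate_distribution(raptor_rfc5053(), cfg)
        b = evaluate_distribution(raptor_rfc5053(), cfg)
        assert (a.overhead, a.avg_err, a.non_unique_packets) == (
            b.overhead, b.avg_err, b.non_unique_packets
        )


class TestOptimize:
    @pytest.mark.parametrize("strategy", ["evolutionary", "differential"])
    def test_smoke_and_invariants(self, strategy):
        seen = []

        def on_gen(gen, pop, fits):
            for d in pop:
                assert_valid(d)
            seen.append(float(np.min(fits)))

        cfg = _tiny_config(strategy=strategy)
        best, history = optimize(cfg, on_generation=on_gen)
        assert_valid(best)
        assert len(history) == cfg.generations
        assert len(seen) == cfg.generations
        # elitism: best fitness trace is monotone non-increasing
        assert all(b <= a + 1e-12 for a, b in zip(seen, seen[1:]))
        np.testing.assert_allclose(history["fitness"].values, seen)

    def test_reproducible(self):
        cfg = _tiny_config()
        b1, h1 = optimize(cfg)
        b2, h2 = optimize(cfg)
        assert b1 == b2
        assert (h1["fitness"] == h2["fitness"]).all()

    def test_fitness_invariant_under_experiment_permutation(self):
        f1 = bytes(range(150))
        f2 = bytes(200)
        m_a = evaluate_distribution(raptor_rfc5053(), _tiny_config(files=[f1, f2]))
        m_b = evaluate_distribution(raptor_rfc5053(), _tiny_config(files=[f2, f1]))
        w = FitnessWeights()
        assert fitness(m_a, w) == pytest.approx(fitness(m_b, w), abs=1e-12)

    def test_nonunique_pressure_shifts_mass_to_higher_degrees(self):
        """With weight concentrated on duplicate payloads and few chunks,
        optimization moves probability mass above the Raptor mean degree
        (higher degrees have vastly larger uniqueness ceilings)."""
        wins = 0
        for seed in (0, 1, 2):
            cfg = _tiny_config(
                files=[bytes(range(200))], chunk_sizes=(20,),
                population=8, generations=6, seed_range=(0, 1024),
                weights=FitnessWeights(0.0, 0.0, 0.0, 1.0, 0.0),
                rng_seed=seed,
            )
            best, _ = optimize(cfg)
            # the duplicate-saturated low degrees (ceilings 10 and 45)
            # should lose mass relative to the Raptor start
            if best.array[:2].sum() < raptor_rfc5053().array[:2].sum():
                wins += 1
        assert wins >= 2
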