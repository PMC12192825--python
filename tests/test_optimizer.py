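"""Pareto machinery, DE operators, archive rules, and the full swarm loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anpmopso import (
    BenchmarkTask,
    SwarmConfig,
    benchmark_config,
    dominates,
    make_problem,
    nondominated_filter,
    run_anpmopso,
    update_archive,
)
from anpmopso.optimizer import (
    Archive,
    ParameterError,
    adaptive_K,
    adaptive_velocity_term,
    combined_score,
    de_mutant,
    harmonic_mean_distance,
    nondomination_ranks,
)


class TestDominance:
    def test_examples(self):
        assert dominates((1, 1), (2, 2))
        assert not dominates((1, 1), (1, 1))
        assert not dominates((1, 3), (2, 2))
        assert not dominates((2, 2), (1, 3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0, 10)), min_size=1, max_size=6))
    def test_antisymmetric_and_irreflexive(self, pts):
        for u in pts:
            assert not dominates(u, u)
            for v in pts:
                assert not (dominates(u, v) and dominates(v, u))

    def test_filter_inspection_example(self):
        pts = np.array([[1, 2], [2, 1], [2, 2]])
        assert nondominated_filter(pts).tolist() == [0, 1]

    def test_filter_keeps_identical_points(self):
        pts = np.ones((4, 3))
        assert nondominated_filter(pts).tolist() == [0, 1, 2, 3]

    def test_filter_matches_bruteforce_oracle(self, rng):
        """Vectorized filter equals the O(n^2) definition on random
        3-objective clouds (20 trials, n=200)."""
        for _ in range(20):
            pts = rng.random((200, 3))
            expected = [
                i for i in range(200)
                if not any(dominates(pts[j], pts[i]) for j in range(200) if j != i)
            ]
            assert nondominated_filter(pts).tolist() == expected

    def test_rank_peeling(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [0, 3]])
        assert nondomination_ranks(pts).tolist() == [1, 2, 3, 2]


class TestDEOperators:
    def test_mutant_arithmetic(self):
        out = de_mutant(np.array([1.0, 1.0]), np.array([2.0, 2.0]),
                        np.array([0.0, 0.0]), F=0.5)
        assert np.allclose(out, [2.0, 2.0])
        assert np.allclose(de_mutant(np.array([3.0]), np.array([9.0]),
                                     np.array([1.0]), F=0.0), [3.0])
        x = np.array([1.0, -2.0])
        assert np.allclose(de_mutant(x, np.array([5.0, 5.0]),
                                     np.array([5.0, 5.0]), F=0.77), x)

    def test_adaptive_term(self):
        x = np.array([1.0, 2.0])
        assert np.allclose(adaptive_velocity_term(x, x, K=0.5), 0.0)
        assert np.allclose(
            adaptive_velocity_term(np.array([2.0, 0.0]), np.array([1.0, 2.0]), K=1.0),
            [1.0, -2.0],
        )

    def test_rank_map_endpoints(self):
        assert adaptive_K(1, 7, 0.2, 0.8) == pytest.approx(0.2)
        assert adaptive_K(7, 7, 0.2, 0.8) == pytest.approx(0.8)
        assert adaptive_K(1, 1, 0.2, 0.8) == pytest.approx(0.2)


class TestHMDScore:
    def test_hmd_examples(self):
        # entry 0 at distance 1 from both others
        row = np.array([0.0, 1.0, 1.0])
        assert harmonic_mean_distance(0, row) == pytest.approx(1.0)
        row = np.array([0.0, 1.0, 2.0])
        assert harmonic_mean_distance(0, row) == pytest.approx(4.0 / 3.0)
        row = np.array([0.0, 0.7])
        assert harmonic_mean_distance(0, row) == pytest.approx(0.7)

    def test_duplicate_distance_collapses_to_zero(self):
        assert harmonic_mean_distance(0, np.array([0.0, 0.0, 3.0])) == 0.0

    def test_combined_score_endpoints(self):
        hmd = np.array([0.0, 1.0, 0.5])
        npq = np.array([0.4, 0.6, 0.2])
        # beta=1: pure inverted-HMD term (duplicates score worst)
        assert np.allclose(combined_score(hmd, npq, beta=1.0), [1.0, 0.0, 0.5])
        # beta=0: pure NP term
        assert np.allclose(combined_score(hmd, npq, beta=0.0), [0.5, 1.0, 0.0])
        # degenerate term contributes zero
        assert np.allclose(combined_score(np.ones(3), npq, beta=1.0), 0.0)


def _flat_np(positions):
    return np.zeros(positions.shape[0])


class TestArchive:
    def test_single_candidate(self):
        arch = update_archive(None, np.array([[0.5]]), np.array([[1.0, 2.0]]),
                              cap=5, beta=0.5, np_quality_fn=_flat_np)
        assert len(arch) == 1

    def test_dominated_candidate_rejected(self):
        arch = update_archive(None, np.array([[0.1]]), np.array([[1.0, 1.0]]),
                              cap=5, beta=0.5, np_quality_fn=_flat_np)
        arch = update_archive(arch, np.array([[0.9]]), np.array([[2.0, 2.0]]),
                              cap=5, beta=0.5, np_quality_fn=_flat_np)
        assert len(arch) == 1
        assert np.allclose(arch.objectives, [[1.0, 1.0]])

    def test_truncation_matches_bruteforce_rule(self, rng):
        """cap=5 with 10 mutually non-dominated candidates keeps exactly the
        5 lowest-S entries (re-implemented independently here)."""
        a = np.linspace(0, 1, 10)
        obj = np.column_stack([a, 1 - a])
        pos = rng.random((10, 3))
        npq = rng.random(10)
        fn = lambda p: npq[:p.shape[0]]
        arch = update_archive(None, pos, obj, cap=5, beta=0.5, np_quality_fn=fn)

        # independent re-implementation of the truncation rule
        from scipy.spatial.distance import pdist, squareform
        norm = (obj - obj.min(0)) / (obj.max(0) - obj.min(0))
        D = squareform(pdist(norm))
        hmd = np.array([harmonic_mean_distance(i, D[i]) for i in range(10)])
        S = combined_score(hmd, npq, beta=0.5)
        expected = np.sort(np.argsort(S, kind="stable")[:5])
        assert len(arch) == 5
        assert np.allclose(arch.objectives, obj[expected])

    def test_archive_always_mutually_nondominated(self, rng):
        arch = None
        for _ in range(10):
            pos = rng.random((20, 2))
            obj = rng.random((20, 2))
            arch = update_archive(arch, pos, obj, cap=8, beta=0.5,
                                  np_quality_fn=_flat_np)
            assert len(arch) <= 8
            assert len(nondominated_filter(arch.objectives)) == len(arch)


class _SingleObjectiveSphere:
    """Minimal task: f(x) = ||x||^2 as a 1-tuple objective."""

    is_gene_mode = False
    dim = 2
    lower = np.full(2, -5.0)
    upper = np.full(2, 5.0)

    def evaluate(self, X):
        return np.sum(np.asarray(X) ** 2, axis=1, keepdims=True)

    def np_quality(self, positions):
        return np.zeros(positions.shape[0])


def _plain_pso_sphere(seed, pop=40, iters=49):
    """Independent textbook PSO oracle on the same sphere problem."""
    rng = np.random.default_rng(seed)
    lo, hi = -5.0, 5.0
    x = rng.uniform(lo, hi, (pop, 2))
    v = np.zeros_like(x)
    f = (x**2).sum(1)
    pb, pbf = x.copy(), f.copy()
    g = x[np.argmin(f)].copy()
    gf = f.min()
    for _ in range(iters):
        r1, r2 = rng.random((pop, 2)), rng.random((pop, 2))
        v = 0.7298 * v + 1.49445 * r1 * (pb - x) + 1.49445 * r2 * (g - x)
        v = np.clip(v, -2.0, 2.0)
        x = np.clip(x + v, lo, hi)
        f = (x**2).sum(1)
        better = f < pbf
        pb[better], pbf[better] = x[better], f[better]
        if pbf.min() < gf:
            gf = pbf.min()
            g = pb[np.argmin(pbf)].copy()
    return gf


class TestRunLoop:
    def test_max_iter_zero_returns_initial_front(self):
        prob = make_problem("MMF1")
        cfg = SwarmConfig(pop_size=32, max_iter=0, seed=1)
        res = run_anpmopso(BenchmarkTask(prob), cfg)
        # archive equals the non-dominated subset of the Sobol population
        from anpmopso.sobol import scale_population, sobol_points
        pts = scale_population(sobol_points(32, 2), prob.lower, prob.upper)
        expected = prob.evaluate(pts)[nondominated_filter(prob.evaluate(pts))]
        got = res.archive.objectives
        assert sorted(map(tuple, got)) == pytest.approx(sorted(map(tuple, expected)))

    def test_fixed_seed_full_determinism(self):
        prob = make_problem("MMF5")
        cfg = SwarmConfig(pop_size=40, max_iter=8, seed=5)
        a = run_anpmopso(BenchmarkTask(prob), cfg)
        b = run_anpmopso(BenchmarkTask(prob), cfg)
        assert np.array_equal(a.archive.positions, b.archive.positions)
        assert np.array_equal(a.archive.objectives, b.archive.objectives)

    def test_positions_respect_bounds(self):
        prob = make_problem("MMF4")
        res = run_anpmopso(BenchmarkTask(prob), SwarmConfig(pop_size=30, max_iter=10, seed=2))
        pos = res.archive.positions
        assert np.all(pos >= prob.lower - 1e-12)
        assert np.all(pos <= prob.upper + 1e-12)

    def test_running_best_error_monotone_as_minimum(self):
        prob = make_problem("MMF1")
        res = run_anpmopso(BenchmarkTask(prob), SwarmConfig(pop_size=30, max_iter=12, seed=3))
        best_f1 = [h.best_objectives[0] for h in res.history]
        running = np.minimum.accumulate(best_f1)
        assert np.all(np.diff(running) <= 1e-12)

    def test_single_objective_no_de_degenerates_to_pso(self):
        """With the DE term disabled and one objective, the update reaches
        the sphere optimum like a textbook PSO (both within 1e-3 at ~2,000
        evaluations)."""
        cfg = SwarmConfig(pop_size=40, max_iter=49, seed=7, variant="no_de",
                          archive_cap=5)
        res = run_anpmopso(_SingleObjectiveSphere(), cfg)
        ours = float(res.archive.objectives.min())
        oracle = _plain_pso_sphere(seed=7)
        assert ours <= 1e-3
        assert oracle <= 1e-3

    @pytest.mark.parametrize("variant", ["full", "no_init", "no_de", "no_select"])
    def test_ablation_variants_run_and_tag(self, variant):
        prob = make_problem("MMF1")
        cfg = SwarmConfig(pop_size=20, max_iter=3, seed=1, variant=variant)
        res = run_anpmopso(BenchmarkTask(prob), cfg)
        assert res.config.variant == variant
        assert len(res.archive) >= 1

    def test_invalid_config_rejected_before_compute(self):
        with pytest.raises(ParameterError):
            SwarmConfig(beta=1.5).validate()
        with pytest.raises(ParameterError):
            SwarmConfig(variant="bogus").validate()

    def test_benchmark_protocol_budget(self):
        prob = make_problem("OMNI3")
        cfg = benchmark_config(prob, seed=0)
        assert cfg.pop_size == 300
        # initial sweep + iterations stays within 4000 x Nvar evaluations
        assert cfg.pop_size * (cfg.max_iter + 1) <= 4000 * prob.n_var
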