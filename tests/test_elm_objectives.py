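"""ELM classifier and the three-objective gene-subset fitness."""

import numpy as np
import pytest

from anpmopso import (
    FitnessEvaluator,
    ObjectivesConfig,
    SyntheticSpec,
    classification_accuracy,
    gene_count,
    generate_synthetic,
    neighborhood_preservation,
    train_elm,
)
from anpmopso.elm import ParameterError as ElmParameterError
from anpmopso.objectives import ContractError, ParameterError, anova_prefilter


def _two_gaussians(n=200, seed=0):
    r = np.random.default_rng(seed)
    X = np.vstack([r.normal(0, 1, (n // 2, 2)), r.normal(4, 1, (n // 2, 2))])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestELM:
    def test_separated_gaussians_high_accuracy(self):
        X, y = _two_gaussians()
        model = train_elm(X, y, n_hidden=50, seed=1)
        assert classification_accuracy(model, X, y) >= 95.0

    def test_same_seed_identical_predictions(self):
        X, y = _two_gaussians(seed=2)
        a = train_elm(X, y, n_hidden=30, seed=7).predict(X)
        b = train_elm(X, y, n_hidden=30, seed=7).predict(X)
        assert np.array_equal(a, b)

    def test_single_hidden_unit_cannot_solve_xor(self):
        """H=1 caps at the best monotone split of balanced XOR (~75%),
        averaged over 20 seeds."""
        r = np.random.default_rng(0)
        X = r.uniform(-1, 1, (200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        accs = [
            classification_accuracy(train_elm(X, y, n_hidden=1, seed=s), X, y)
            for s in range(20)
        ]
        assert np.mean(accs) <= 75.0 + 2.0

    def test_normal_equation_residual(self):
        X, y = _two_gaussians(seed=3)
        model = train_elm(X, y, n_hidden=40, seed=0, ridge=1e-6)
        G = model._hidden(X)
        T = np.zeros((len(y), 2))
        T[np.arange(len(y)), y] = 1.0
        resid = G.T @ (G @ model.output_weights - T) + 1e-6 * model.output_weights
        assert np.abs(resid).max() <= 1e-6 * max(1.0, np.abs(G.T @ T).max())

    def test_accuracy_arithmetic(self):
        X, y = _two_gaussians(seed=4)
        model = train_elm(X, y, n_hidden=40, seed=0)
        pred = model.predict(X)
        expected = 100.0 * np.mean(pred == y)
        assert classification_accuracy(model, X, y) == pytest.approx(expected)
        assert classification_accuracy(model, X, pred) == 100.0

    def test_permutation_null_accuracy(self):
        """Scoring shuffled labels on a balanced binary set stays at 50%
        (mean over 1,000 permutations within 3 SE)."""
        r = np.random.default_rng(5)
        y = np.repeat([0, 1], 50)
        pred = np.repeat([0, 1], 50)
        cas = []
        for _ in range(1000):
            cas.append(100.0 * np.mean(pred == r.permutation(y)))
        se = 100 * np.sqrt(0.25 / 100) / np.sqrt(1000)
        assert abs(np.mean(cas) - 50.0) < 3 * se

    def test_unseen_labels_counted_as_errors(self):
        X, y = _two_gaussians(seed=6)
        model = train_elm(X, y, n_hidden=20, seed=0)
        y_bad = y.copy()
        y_bad[:10] = 9
        with pytest.warns(UserWarning):
            ca = classification_accuracy(model, X, y_bad)
        assert ca <= 95.0  # the 10 relabeled instances are forced errors

    def test_zero_feature_input_rejected(self):
        with pytest.raises(ElmParameterError):
            train_elm(np.empty((5, 0)), np.zeros(5), n_hidden=3)


class TestGeneCount:
    def test_popcount_examples(self):
        assert gene_count(np.array([1, 0, 1, 1])) == 3
        assert gene_count(np.zeros(10)) == 0
        assert gene_count(np.ones(2000)) == 2000

    def test_non_binary_rejected(self):
        with pytest.raises(ContractError):
            gene_count(np.array([0.5, 1.0]))


class TestNeighborhoodPreservation:
    def test_identity_gives_zero(self, rng):
        coords = rng.normal(size=(30, 4))
        assert neighborhood_preservation(coords, coords.copy(), k=5) == 0.0

    def test_consistent_relabeling_invariance(self, rng):
        coords = rng.normal(size=(25, 3))
        perm = rng.permutation(25)
        a = neighborhood_preservation(coords, coords * 1.0, k=4)
        b = neighborhood_preservation(coords[perm], coords[perm], k=4)
        assert a == b == 0.0

    def test_hand_enumerated_1d_toy(self):
        """Points (0,1,2,10,11); the subset space swaps points 0 and 10.
        Expected value computed by brute-force enumeration of the formula."""
        ref = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        sub = ref.copy()
        sub[[0, 3]] = sub[[3, 0]]
        k = 1

        def brute(ref, sub, k):
            n = len(ref)
            total = 0.0
            for i in range(n):
                dr = [(np.linalg.norm(ref[i] - ref[j]), j) for j in range(n) if j != i]
                ds = [(np.linalg.norm(sub[i] - sub[j]), j) for j in range(n) if j != i]
                dr.sort(); ds.sort()
                for j in range(k):
                    total += np.linalg.norm(sub[dr[j][1]] - sub[ds[j][1]])
            return total / (n * k)

        expected = brute(ref, sub, k)
        assert neighborhood_preservation(ref, sub, k) == pytest.approx(expected)
        assert expected > 0

    def test_k_bounds(self, rng):
        coords = rng.normal(size=(6, 2))
        with pytest.raises(ParameterError):
            neighborhood_preservation(coords, coords, k=6)


@pytest.fixture(scope="module")
def synth_evaluator():
    spec = SyntheticSpec(n_genes=60, n_samples=80, n_classes=3, n_informative=3,
                         n_redundant=0, effect_size=5.0, seed=11)
    ds, truth = generate_synthetic(spec)
    return FitnessEvaluator(ds, ObjectivesConfig(base_seed=11)), truth


class TestFitnessEvaluator:
    def test_memoized_evaluations_identical(self, synth_evaluator):
        ev, truth = synth_evaluator
        mask = np.zeros(60, bool)
        mask[truth] = True
        a = ev.evaluate(mask)
        b = ev.evaluate(mask.copy())
        assert a == b
        assert a.NF == truth.size

    def test_empty_mask_gets_sentinel(self, synth_evaluator):
        ev, _ = synth_evaluator
        vec = ev.evaluate(np.zeros(60, bool))
        assert not vec.valid and vec.CA == 0.0 and np.isinf(vec.NP_dist)
        tup = vec.as_minimization()
        assert tup[0] == 100.0 and np.isfinite(tup[1])

    def test_truth_mask_beats_random_masks(self):
        """Ground-truth informative genes beat a random equal-size mask on
        held-out accuracy in at least 18 of 20 paired seeds."""
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(n_genes=60, n_samples=80, n_classes=3,
                                 n_informative=3, n_redundant=0,
                                 effect_size=5.0, seed=seed)
            ds, truth = generate_synthetic(spec)
            ev = FitnessEvaluator(ds, ObjectivesConfig(base_seed=seed))
            m_true = np.zeros(60, bool)
            m_true[truth] = True
            m_rand = np.zeros(60, bool)
            noise = np.random.default_rng(seed).choice(
                np.setdiff1d(np.arange(60), truth), truth.size, replace=False
            )
            m_rand[noise] = True
            if ev.evaluate(m_true).CA >= ev.evaluate(m_rand).CA:
                wins += 1
        assert wins >= 18

    def test_noise_genes_degrade_accuracy_directionally(self):
        """Adding 30 pure-noise genes to the informative mask does not help
        mean validation accuracy (paired over 15 seeds, binomial check)."""
        diffs = []
        for seed in range(15):
            spec = SyntheticSpec(n_genes=80, n_samples=80, n_classes=3,
                                 n_informative=3, n_redundant=0,
                                 effect_size=5.0, seed=200 + seed)
            ds, truth = generate_synthetic(spec)
            ev = FitnessEvaluator(ds, ObjectivesConfig(base_seed=seed))
            m_true = np.zeros(80, bool)
            m_true[truth] = True
            m_noisy = m_true.copy()
            noise = np.random.default_rng(seed).choice(
                np.arange(truth.size, 80), 30, replace=False
            )
            m_noisy[noise] = True
            diffs.append(ev.evaluate(m_true).CA - ev.evaluate(m_noisy).CA)
        assert np.mean(diffs) >= 0.0

    def test_prefilter_keeps_informative_and_maps_indices(self, synth_evaluator):
        _, _ = synth_evaluator
        spec = SyntheticSpec(n_genes=100, n_samples=90, n_classes=3,
                             n_informative=4, n_redundant=0,
                             effect_size=5.0, seed=3)
        ds, truth = generate_synthetic(spec)
        red, keep = anova_prefilter(ds, 20)
        assert red.n_genes == 20
        assert set(truth.tolist()) <= set(keep.tolist())
        assert [ds.gene_ids[i] for i in keep] == red.gene_ids
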