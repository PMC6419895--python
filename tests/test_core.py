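import numpy as np
import pytest

import sparcor.core as core
from sparcor import (
    EstimationConfig,
    ExclusionState,
    FractionMatrix,
    correlations_from_basis,
    draw_fractions,
    estimate_once,
    find_strongest_pair,
    infer_correlations,
    planted_pair_spec,
    simulate_counts,
    solve_basis_variances,
    variation_matrix,
)
from conftest import random_table


def t_from_null_basis(w):
    """Variation matrix of mutually uncorrelated taxa: t_ij = w_i + w_j."""
    w = np.asarray(w, dtype=float)
    t = w[:, None] + w[None, :]
    np.fill_diagonal(t, 0.0)
    return t


def brute_force_pipeline(fractions):
    """Literal nested-loop oracle for the unexcluded single pass.

    Computes the variation matrix, the t_row/M system, its solution and
    the correlation formula entirely with explicit loops, independent of
    the vectorized implementation it checks.
    """
    d, n = fractions.shape
    t = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i != j:
                lr = [np.log(fractions[i, s] / fractions[j, s]) for s in range(n)]
                mu = sum(lr) / n
                t[i, j] = sum((x - mu) ** 2 for x in lr) / (n - 1)
    t_row = np.zeros(d)
    m = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                m[i, j] = d - 1
            else:
                m[i, j] = 1.0
                t_row[i] += t[i, j]
    w = np.linalg.solve(m, t_row)
    w = np.array([max(x, 1e-6) for x in w])  # variance floor, part of the contract
    rho = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                rho[i, j] = 1.0
            else:
                r = (w[i] + w[j] - t[i, j]) / (2.0 * np.sqrt(w[i]) * np.sqrt(w[j]))
                rho[i, j] = min(1.0, max(-1.0, r))
    return w, rho


class TestSolveBasisVariances:
    def test_analytic_three_taxon_construction(self):
        # w = (1, 2, 3) and rho = 0 gives t_ij = w_i + w_j exactly
        t = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        w = solve_basis_variances(t, ExclusionState(3), min_active=3)
        np.testing.assert_allclose(w, [1, 2, 3], atol=1e-12)

    def test_null_construction_recovered_exactly(self, rng):
        w_true = rng.uniform(0.5, 3.0, size=5)
        w = solve_basis_variances(t_from_null_basis(w_true), ExclusionState(5))
        np.testing.assert_allclose(w, w_true, atol=1e-10)

    def test_excluded_pair_removes_perturbation(self, rng):
        w_true = rng.uniform(0.5, 3.0, size=5)
        t = t_from_null_basis(w_true)
        t_pert = t.copy()
        t_pert[0, 1] = t_pert[1, 0] = t[0, 1] + 5.0
        ex = ExclusionState(5)
        ex.exclude_pair(0, 1)
        w = solve_basis_variances(t_pert, ex)
        # brute-force reduced system: drop t_01 from both row sums and
        # decrement the affected entries of M
        m = np.ones((5, 5)) + 3 * np.eye(5)
        t_row = t_pert.sum(axis=1)
        t_row[0] -= t_pert[0, 1]
        t_row[1] -= t_pert[0, 1]
        m[0, 0] -= 1; m[1, 1] -= 1; m[0, 1] -= 1; m[1, 0] -= 1
        np.testing.assert_allclose(w, np.linalg.solve(m, t_row), atol=1e-12)
        # taxa untouched by the perturbed entry keep their true variances
        np.testing.assert_allclose(w[2:], w_true[2:], atol=1e-10)

    def test_variance_floor_clamps(self):
        t = t_from_null_basis([1e-12, 1e-12, 1.0, 1.0])
        w = solve_basis_variances(t, ExclusionState(4), variance_floor=1e-6)
        assert np.all(w >= 1e-6)

    def test_too_few_active_taxa(self):
        ex = ExclusionState(5)
        for i in (0, 1):
            ex.exclude_otu(i)
        with pytest.raises(ValueError, match="at least 4"):
            solve_basis_variances(t_from_null_basis(np.ones(5)), ex)


class TestCorrelationsFromBasis:
    def test_formula_and_clipping(self):
        w = np.array([1.0, 1.0, 2.0])
        t = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        rho = correlations_from_basis(t, w)
        assert rho[0, 1] == pytest.approx(0.5)          # (1+1-1)/2
        assert rho[0, 2] == pytest.approx(0.0)          # t = w_i + w_j
        # t_12 = 0 -> raw (1+2)/(2 sqrt 2) ~ 1.06 -> clipped
        assert rho[1, 2] == 1.0
        assert np.all(np.diag(rho) == 1.0)

    def test_negative_t_clips_at_one(self):
        t = np.array([[0.0, -0.8], [-0.8, 0.0]])
        rho = correlations_from_basis(t, np.array([1.0, 1.0]))
        assert rho[0, 1] == 1.0  # raw 1.4

    def test_nan_variance_propagates_whole_row(self):
        w = np.array([1.0, np.nan, 1.0, 1.0])
        rho = correlations_from_basis(t_from_null_basis([1, 1, 1, 1.0]), w)
        assert np.isnan(rho[1]).all() and np.isnan(rho[:, 1]).all()
        assert np.isnan(rho[1, 1])


class TestFindStrongestPair:
    def base(self, d=4):
        return np.eye(d), ExclusionState(d)

    def test_magnitude_wins_over_sign(self):
        corr, ex = self.base()
        corr[0, 1] = corr[1, 0] = 0.9
        corr[0, 2] = corr[2, 0] = -0.95
        assert find_strongest_pair(corr, ex, 0.1) == (0, 2)

    def test_threshold_is_strict(self):
        corr, ex = self.base()
        corr[0, 1] = corr[1, 0] = 0.1
        assert find_strongest_pair(corr, ex, 0.1) is None

    def test_tie_breaks_lexicographically(self):
        corr, ex = self.base(5)
        corr[0, 1] = corr[1, 0] = 0.8
        corr[2, 3] = corr[3, 2] = 0.8
        assert find_strongest_pair(corr, ex, 0.1) == (0, 1)

    def test_excluded_pairs_and_otus_skipped(self):
        corr, ex = self.base(5)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[2, 3] = corr[3, 2] = 0.5
        ex.exclude_pair(0, 1)
        assert find_strongest_pair(corr, ex, 0.1) == (2, 3)
        ex.exclude_otu(2)
        assert find_strongest_pair(corr, ex, 0.1) is None


class TestExclusionState:
    def test_pair_counts_track_membership(self):
        ex = ExclusionState(5)
        ex.exclude_pair(0, 1)
        ex.exclude_pair(1, 2)
        assert ex.pair_counts.tolist() == [1, 2, 1, 0, 0]
        ex.exclude_otu(1)
        assert ex.excluded_pairs == set()
        assert ex.pair_counts.tolist() == [0, 0, 0, 0, 0]
        assert ex.d_active == 4

    def test_duplicate_pair_ignored(self):
        ex = ExclusionState(4)
        ex.exclude_pair(2, 0)
        ex.exclude_pair(0, 2)
        assert ex.pair_counts.tolist() == [1, 0, 1, 0]


class TestEstimateOnce:
    def cfg(self, **kw):
        defaults = dict(iterations=1, exclusion_iterations=10,
                        exclusion_threshold=0.1)
        defaults.update(kw)
        return EstimationConfig(**defaults)

    def test_zero_exclusion_iterations_is_single_pass(self, rng):
        fr = draw_fractions(random_table(rng, 6, 10), rng=rng)
        res0 = estimate_once(fr, self.cfg(exclusion_iterations=0))
        w, rho = brute_force_pipeline(fr.fractions)
        np.testing.assert_allclose(res0.correlation, rho, atol=1e-10)
        np.testing.assert_allclose(np.diag(res0.covariance), w, atol=1e-10)

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(5):
            raw = rng.gamma(2.0, size=(6, 10))
            fr = FractionMatrix(
                tuple(f"O{i}" for i in range(6)),
                tuple(f"S{j}" for j in range(10)),
                raw / raw.sum(axis=0, keepdims=True),
            )
            res = estimate_once(fr, self.cfg(exclusion_iterations=0))
            _, rho = brute_force_pipeline(fr.fractions)
            np.testing.assert_allclose(res.correlation, rho, atol=1e-10)

    def test_null_data_rarely_triggers_exclusion(self):
        table, _ = simulate_counts(
            planted_pair_spec(d=8, n=400, rho=0.0, depth=50_000), seed=3
        )
        fr = draw_fractions(table, rng=np.random.default_rng(3))
        with_loop = estimate_once(fr, self.cfg())
        without = estimate_once(fr, self.cfg(exclusion_iterations=0))
        np.testing.assert_allclose(
            with_loop.correlation, without.correlation, atol=1e-12
        )

    def test_planted_strong_pair_is_excluded_first_but_still_reported(self):
        table, _ = simulate_counts(
            planted_pair_spec(d=8, n=500, rho=0.9, depth=50_000), seed=4
        )
        fr = draw_fractions(table, rng=np.random.default_rng(4))
        t = variation_matrix(fr)
        ex = ExclusionState(8)
        w = solve_basis_variances(t, ex)
        first = find_strongest_pair(
            correlations_from_basis(t, w), ex, 0.1
        )
        assert first == (0, 1)
        res = estimate_once(fr, self.cfg())
        assert res.correlation[0, 1] > 0.5  # exclusion does not erase the value

    def test_output_contract(self, rng):
        fr = draw_fractions(random_table(rng, 7, 200), rng=rng)
        res = estimate_once(fr, self.cfg())
        c = res.correlation
        assert np.array_equal(c, c.T)
        assert np.all(np.diag(c) == 1.0)
        assert np.all((c >= -1.0) & (c <= 1.0))
        np.testing.assert_allclose(
            res.covariance[0, 1],
            c[0, 1] * np.sqrt(res.covariance[0, 0] * res.covariance[1, 1]),
            atol=1e-12,
        )


class TestInferCorrelations:
    def test_single_iteration_equals_estimate_once(self, rng):
        table = random_table(rng, 6, 100)
        cfg = EstimationConfig(iterations=1, seed=9)
        res = infer_correlations(table, cfg)
        sub = np.random.default_rng(
            np.random.SeedSequence(entropy=9, spawn_key=(0,))
        )
        fr = draw_fractions(table, cfg.pseudocount, sub)
        direct = estimate_once(fr, cfg)
        assert np.array_equal(res.correlation, direct.correlation, equal_nan=True)

    def test_precomputed_fractions_are_deterministic(self, rng):
        table = random_table(rng, 6, 100)
        fr = draw_fractions(table, rng=rng)
        cfg = EstimationConfig(iterations=50)
        a = infer_correlations(table, cfg, seed=1, fractions=fr)
        b = infer_correlations(table, cfg, seed=999, fractions=fr)
        assert np.array_equal(a.correlation, b.correlation, equal_nan=True)
        assert np.array_equal(a.covariance, b.covariance, equal_nan=True)

    def test_median_of_identical_replicates(self, rng, monkeypatch):
        table = random_table(rng, 5, 10)
        frozen = draw_fractions(table, rng=np.random.default_rng(2))
        monkeypatch.setattr(core, "draw_fractions", lambda *a, **k: frozen)
        cfg = EstimationConfig(iterations=3)
        res = infer_correlations(table, cfg, seed=0)
        direct = estimate_once(frozen, cfg)
        np.testing.assert_array_equal(res.correlation, direct.correlation)

    def test_seed_reproducibility_across_thread_counts(self, rng):
        table = random_table(rng, 8, 30)
        base = EstimationConfig(iterations=6, seed=42, threads=1)
        threaded = EstimationConfig(iterations=6, seed=42, threads=4)
        a = infer_correlations(table, base)
        b = infer_correlations(table, threaded)
        assert np.array_equal(a.correlation, b.correlation)
        assert np.array_equal(a.covariance, b.covariance)

    def test_shape_mismatch_with_fractions_rejected(self, rng):
        table = random_table(rng, 6, 12)
        fr = draw_fractions(random_table(rng, 5, 12), rng=rng)
        with pytest.raises(ValueError, match="match"):
            infer_correlations(table, EstimationConfig(), fractions=fr)

    def test_planted_pair_recovery(self):
        table, truth = simulate_counts(
            planted_pair_spec(d=10, n=800, rho=0.8, depth=100_000), seed=21
        )
        res = infer_correlations(table, EstimationConfig(iterations=10), seed=22)
        assert res.correlation[0, 1] == pytest.approx(0.8, abs=0.15)
        null = res.correlation.copy()
        np.fill_diagonal(null, 0.0)
        null[0, 1] = null[1, 0] = 0.0
        assert np.abs(null).max() < 0.15
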