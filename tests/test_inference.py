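import numpy as np
import pytest

from biastruct.evaluation import squared_correlation
from biastruct.inference import (
    EPS,
    AdmixtureModel,
    EigenAncestryModel,
    admixture_em,
    align_clusters,
    eigen_ancestry,
    loglikelihood,
    project_ancestry,
)


def _random_genotypes(rng, n, m, missing=0.0):
    g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing:
        g[rng.random((n, m)) < missing] = 9
    return g


class TestLoglikelihood:
    def test_hand_computed_single_locus(self):
        # one heterozygote at p = 0.5: 1*log 0.5 + 1*log 0.5 = -1.386
        ll = loglikelihood(np.array([[1]]), np.array([[1.0]]), np.array([[0.5]]))
        assert ll == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_all_missing_scores_zero(self):
        g = np.full((3, 4), 9, dtype=np.int8)
        ll = loglikelihood(g, np.ones((3, 1)), np.full((1, 4), 0.3))
        assert ll == 0.0

    def test_weights_scale_linearly(self, rng):
        g = _random_genotypes(rng, 6, 20)
        Q = rng.dirichlet(np.ones(2), size=6)
        P = rng.uniform(0.1, 0.9, (2, 20))
        base = loglikelihood(g, Q, P, np.ones(6))
        assert loglikelihood(g, Q, P, np.full(6, 3.0)) == pytest.approx(3 * base)


class TestAdmixtureEM:
    def test_k1_closed_form(self, rng):
        g = _random_genotypes(rng, 10, 30)
        fit = admixture_em(g, K=1, tol=1e-10, max_iter=200, seed=0)
        np.testing.assert_allclose(fit.Q, 1.0)
        np.testing.assert_allclose(
            fit.P[0], np.clip(g.mean(axis=0) / 2, EPS, 1 - EPS), atol=1e-6
        )

    def test_two_point_toy_matches_grid_oracle(self):
        """On g = {(0,0), (2,2)} with K=2 the EM optimum matches a brute-force
        grid maximization over (q1, q2, p1, p2) (loci are exchangeable)."""
        g = np.array([[0, 0], [2, 2]], dtype=np.int8)
        fit = admixture_em(g, K=2, tol=1e-12, max_iter=3000, seed=1)
        # independent oracle: coarse-to-fine grid over the 4 free parameters
        grid = np.linspace(EPS, 1 - EPS, 51)
        q1, q2, p1, p2 = np.meshgrid(grid, grid, grid, grid, indexing="ij", sparse=True)
        pi1 = np.clip(q1 * p1 + (1 - q1) * p2, EPS / 2, 1 - EPS / 2)
        pi2 = np.clip(q2 * p1 + (1 - q2) * p2, EPS / 2, 1 - EPS / 2)
        # two identical loci: individual 1 has g=0, individual 2 has g=2
        ll = 2 * (2 * np.log1p(-pi1) + 2 * np.log(pi2))
        best = ll.max()
        assert fit.llf >= best - 0.01
        # solution is the two vertices (up to component swap)
        q = np.sort(fit.Q[:, 0])
        np.testing.assert_allclose(q, [0.0, 1.0], atol=1e-3)
        assert np.all((fit.P < 0.01) | (fit.P > 0.99))

    def test_loglik_trace_monotone(self, rng):
        for trial in range(3):
            g = _random_genotypes(rng, 15, 40, missing=0.05)
            w = rng.uniform(0.5, 2.0, 15)
            fit = admixture_em(g, K=2, weights=w, tol=1e-8, max_iter=300, seed=trial)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-6).all()

    def test_map_trace_monotone(self, rng):
        g = _random_genotypes(rng, 12, 30)
        fit = AdmixtureModel(g, K=2).fit(tol=1e-8, max_iter=300, seed=0, prior_strength=2.0)
        assert (np.diff(fit.loglik_trace) >= -1e-6).all()

    def test_integer_weights_equal_duplicated_rows(self, rng):
        """Weighted EM reproduces physically duplicated rows exactly."""
        g = _random_genotypes(rng, 6, 25)
        counts = np.array([1, 3, 2, 1, 2, 1])
        g_dup = np.repeat(g, counts, axis=0)
        Q0 = rng.dirichlet(np.ones(2), size=6)
        P0 = rng.uniform(0.2, 0.8, (2, 25))
        fit_w = AdmixtureModel(g, K=2, weights=counts.astype(float)).fit(
            tol=-1.0, max_iter=40, initial=(Q0, P0)
        )
        fit_d = AdmixtureModel(g_dup, K=2).fit(
            tol=-1.0, max_iter=40, initial=(np.repeat(Q0, counts, axis=0), P0)
        )
        np.testing.assert_allclose(fit_w.P, fit_d.P, atol=1e-10)
        # weighted loglik is the duplicated loglik rescaled by mean weight
        scale = counts.sum() / len(counts)
        np.testing.assert_allclose(
            fit_w.loglik_trace * scale, fit_d.loglik_trace, rtol=1e-10
        )

    def test_unweighted_equals_unit_weights(self, rng):
        g = _random_genotypes(rng, 8, 20)
        a = admixture_em(g, K=2, tol=1e-6, max_iter=100, seed=5)
        b = admixture_em(g, K=2, weights=np.ones(8), tol=1e-6, max_iter=100, seed=5)
        np.testing.assert_array_equal(a.Q, b.Q)
        np.testing.assert_array_equal(a.P, b.P)

    def test_semi_supervised_pins_vertices_but_learns_freqs(self, rng):
        g = np.vstack([np.zeros((4, 30)), np.full((4, 30), 2)]).astype(np.int8)
        fixed = np.array([0, 0, -1, -1, 1, 1, -1, -1])
        fit = AdmixtureModel(g, K=2, fixed_labels=fixed).fit(tol=1e-8, max_iter=500, seed=0)
        np.testing.assert_allclose(fit.Q[[0, 1], 0], 1.0)
        np.testing.assert_allclose(fit.Q[[4, 5], 1], 1.0)
        # frequencies separate the two genotype blocks
        assert (fit.P[0] < 0.1).all() and (fit.P[1] > 0.9).all()

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            AdmixtureModel(np.zeros((2, 5), dtype=np.int8), K=3)

    def test_parameter_recovery_on_study_population(self, tiny_cohort):
        """Unbiased subsample: EM K=2 tracks the true ancestry closely."""
        from biastruct.experiments import run_cell
        from biastruct.selection import SampleSpec

        r2s = [
            run_cell(tiny_cohort, SampleSpec(25, 25, 25), seed=s)["r2"] for s in (0, 1)
        ]
        assert min(r2s) > 0.9


class TestProjectAncestry:
    def test_recovers_vertex_for_pure_individuals(self):
        P = np.vstack([np.full(200, 0.05), np.full(200, 0.95)])
        rng = np.random.default_rng(0)
        g = np.vstack(
            [rng.binomial(2, P[0]), rng.binomial(2, P[1]), rng.binomial(2, P.mean(0))]
        )
        Q = project_ancestry(g, P)
        assert Q[0, 0] > 0.95
        assert Q[1, 1] > 0.95
        assert abs(Q[2, 0] - 0.5) < 0.15
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-6)


class TestEigenAncestry:
    def test_two_clusters_separate_perfectly(self):
        g = np.vstack([np.zeros((5, 40)), np.full((5, 40), 2)]).astype(np.int8)
        fit = eigen_ancestry(g, n_components=1)
        proj = fit.projections[:, 0]
        assert proj[:5].std() < 1e-8 and proj[5:].std() < 1e-8
        assert abs(proj[0] - proj[5]) > 1.0

    def test_matches_svd_oracle(self, rng):
        g = _random_genotypes(rng, 20, 50)
        fit = eigen_ancestry(g, n_components=3)
        phat = g.mean(axis=0) / 2
        keep = (phat > 0) & (phat < 1)
        x = (g[:, keep] - 2 * phat[keep]) / np.sqrt(phat[keep] * (1 - phat[keep]))
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        np.testing.assert_allclose(fit.eigenvalues[:3], s[:3] ** 2, rtol=1e-8)
        for c in range(3):
            got = fit.projections[:, c]
            want = u[:, c] * s[c]
            assert min(
                np.abs(got - want).max(), np.abs(got + want).max()
            ) < 1e-8  # sign is arbitrary

    def test_integer_weights_match_duplicated_rows(self, rng):
        g = _random_genotypes(rng, 8, 60)
        counts = np.array([2, 1, 3, 1, 1, 2, 1, 1])
        fit_w = EigenAncestryModel(g, n_components=2, weights=counts.astype(float)).fit()
        fit_d = EigenAncestryModel(np.repeat(g, counts, axis=0), n_components=2).fit()
        k = min(len(fit_w.eigenvalues), len(fit_d.eigenvalues))
        np.testing.assert_allclose(
            fit_w.eigenvalues[:8], fit_d.eigenvalues[:8], atol=1e-8
        )

    def test_locus_order_and_allele_coding_invariance(self, rng):
        g = _random_genotypes(rng, 12, 30)
        base = eigen_ancestry(g, n_components=2).projections
        perm = rng.permutation(30)
        reordered = eigen_ancestry(g[:, perm], n_components=2).projections
        flip = g.copy()
        flip[:, 3] = 2 - flip[:, 3]
        flipped = eigen_ancestry(flip, n_components=2).projections
        for other in (reordered, flipped):
            for c in range(2):
                assert min(
                    np.abs(base[:, c] - other[:, c]).max(),
                    np.abs(base[:, c] + other[:, c]).max(),
                ) < 1e-8

    def test_project_rows_consistent_with_fit(self, rng):
        g = _random_genotypes(rng, 15, 40)
        fit = eigen_ancestry(g, n_components=2)
        reproj = fit.project_rows(g)
        np.testing.assert_allclose(reproj, fit.projections, atol=1e-8)

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            eigen_ancestry(np.zeros((4, 10), dtype=np.int8))


class TestAlignClusters:
    def _fit(self, rng):
        g = np.vstack([np.zeros((4, 30)), np.full((4, 30), 2)]).astype(np.int8)
        return admixture_em(g, K=2, tol=1e-8, max_iter=300, seed=0)

    def test_aligned_fit_unchanged(self, rng):
        fit = self._fit(rng)
        ref = fit.Q[:, 0]
        aligned = align_clusters(fit, ref)
        np.testing.assert_array_equal(aligned.Q, fit.Q)

    def test_swapped_reference_swaps_columns(self, rng):
        fit = self._fit(rng)
        ref = fit.Q[:, 1]
        aligned = align_clusters(fit, ref)
        np.testing.assert_array_equal(aligned.Q[:, 0], fit.Q[:, 1])
        np.testing.assert_array_equal(aligned.P[0], fit.P[1])

    def test_alignment_never_changes_r2(self, rng):
        fit = self._fit(rng)
        ref = np.array([0.0] * 4 + [1.0] * 4)
        before = squared_correlation(ref, fit.Q[:, 0])
        after = squared_correlation(ref, align_clusters(fit, ref).Q[:, 0])
        assert after == pytest.approx(before)

    def test_summary_mentions_fit_dimensions(self, rng):
        fit = self._fit(rng)
        text = fit.summary()
        assert "Components (K):     2" in text
        assert "Log-likelihood" in text
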