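import numpy as np
import pytest

from xwaskit.concordance import (
    PatternFit,
    StudyMatrix,
    StudyMixture,
    em_pattern_weights,
    fit_concordance,
    fit_study_mixture,
    pattern_matrix,
    pattern_posteriors,
    transform_pvalues,
)
from xwaskit.synthetic_data import MultiStudySpec, simulate_pattern_pvalues


class TestTransform:
    def test_reference_values(self):
        t = transform_pvalues(np.array([1.0, np.exp(-1.0), 0.01]))
        assert t[0] == 0.0
        assert t[1] == pytest.approx(2.0)
        assert t[2] == pytest.approx(-2 * np.log(0.01), rel=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            transform_pvalues(np.array([0.0]))
        with pytest.raises(ValueError):
            transform_pvalues(np.array([1.1]))


class TestStudyMixture:
    def test_scale_floor_on_null_data(self):
        rng = np.random.default_rng(0)
        t = -2 * np.log(rng.uniform(size=10_000))
        mx = fit_study_mixture(t, alt_prop=1e-3)
        assert mx.scale > 1.0

    def test_constant_column_hits_floor(self):
        with pytest.warns(UserWarning):
            mx = fit_study_mixture(np.zeros(100), alt_prop=1e-3)
        assert mx.scale == pytest.approx(1.0 + 1e-6)

    def test_planted_scale_recovered(self):
        """Planted alternative with scale 8 at alt_prop = 1e-3, G = 2e4.

        The top-tail mean estimator carries an upward selection bias
        (null statistics enter the extreme tail), so it is checked two
        ways: agreement with an independently coded oracle of the same
        statistic on fresh seeds, and a factor-2 band around the truth.
        """
        true_scale = 8.0
        g, n_alt = 20_000, 20

        def column(rng):
            t = -2 * np.log(rng.uniform(size=g))
            t[:n_alt] = true_scale * rng.chisquare(2.0, size=n_alt)
            return t

        estimates = np.array(
            [fit_study_mixture(column(np.random.default_rng(s)), 1e-3).scale
             for s in range(50)]
        )
        # oracle: the same top-tail statistic, straight numpy, fresh seeds
        oracle = np.array(
            [np.sort(column(np.random.default_rng(1000 + s)))[-n_alt:].mean() / 2
             for s in range(200)]
        )
        se_mean = oracle.std() / np.sqrt(50)
        assert estimates.mean() == pytest.approx(oracle.mean(), abs=4 * se_mean)
        assert np.all((estimates > true_scale / 2) & (estimates < true_scale * 2))

    def test_alt_prop_bounds(self):
        with pytest.raises(ValueError):
            fit_study_mixture(np.ones(100), alt_prop=0.7)

    def test_null_density_is_chi2_2(self):
        mx = StudyMixture(scale=4.0)
        t = np.array([0.0, 2.0, 10.0])
        assert np.allclose(np.exp(mx.log_null(t)), np.exp(-t / 2) / 2)
        assert np.allclose(np.exp(mx.log_alt(t)), np.exp(-t / 8) / 8)


class TestEm:
    def test_all_null_data_concentrates_on_null_pattern(self):
        spec = MultiStudySpec(
            n_genes=5000, n_studies=2,
            pattern_probs=(1.0, 0.0, 0.0, 0.0), seed=3,
        )
        matrix, _ = simulate_pattern_pvalues(spec)
        t = transform_pvalues(matrix.P)
        mixtures = [StudyMixture(scale=10.0)] * 2
        pi, trace, converged, _ = em_pattern_weights(t, mixtures)
        assert pi[0] >= 0.98
        assert converged

    def test_pattern_weight_recovery_two_studies(self):
        """pi = (0.90, 0.04, 0.04, 0.02), alt scale 10: recovered within
        +/-0.02 per component across seeds."""
        true_pi = np.array([0.90, 0.04, 0.04, 0.02])
        for seed in range(20):
            spec = MultiStudySpec(
                n_genes=20_000, n_studies=2,
                pattern_probs=tuple(true_pi), alt_scale=10.0, seed=seed,
            )
            matrix, _ = simulate_pattern_pvalues(spec)
            q = pattern_matrix(2)
            fit, _post, _pp = fit_concordance(matrix, alt_props=true_pi @ q)
            assert np.max(np.abs(fit.pi - true_pi)) < 0.02

    def test_truth_is_em_fixed_point(self):
        """Starting EM from the generating weights with the generating
        densities moves pi by < 0.005 at large G."""
        true_pi = np.array([0.90, 0.04, 0.04, 0.02])
        spec = MultiStudySpec(
            n_genes=100_000, n_studies=2,
            pattern_probs=tuple(true_pi), alt_scale=10.0, seed=1,
        )
        matrix, _ = simulate_pattern_pvalues(spec)
        t = transform_pvalues(matrix.P)
        mixtures = [StudyMixture(scale=10.0)] * 2
        from xwaskit.concordance import _pattern_logliks
        from scipy.special import logsumexp

        L = _pattern_logliks(t, mixtures, pattern_matrix(2))
        log_num = np.log(true_pi)[None, :] + L
        post = np.exp(log_num - logsumexp(log_num, axis=1)[:, None])
        one_step = post.mean(axis=0)
        assert np.max(np.abs(one_step - true_pi)) < 0.005

    def test_loglik_monotone(self):
        spec = MultiStudySpec(n_genes=5000, n_studies=3, seed=7)
        matrix, _ = simulate_pattern_pvalues(spec)
        fit, _post, _pp = fit_concordance(matrix, alt_props=0.05)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_too_many_studies_rejected(self):
        with pytest.raises(ValueError):
            em_pattern_weights(np.zeros((10, 9)), [StudyMixture(2.0)] * 9)


class TestPosteriors:
    def fit_for(self, matrix, alt_props=0.05):
        return fit_concordance(matrix, alt_props=alt_props)

    def test_rows_sum_to_one(self):
        spec = MultiStudySpec(n_genes=1000, n_studies=3, seed=11)
        matrix, _ = simulate_pattern_pvalues(spec)
        _fit, post, pp = self.fit_for(matrix)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((pp >= 0) & (pp <= 1 + 1e-12))

    def test_no_evidence_gene_stays_below_threshold(self):
        spec = MultiStudySpec(n_genes=2000, n_studies=2, seed=13)
        matrix, _ = simulate_pattern_pvalues(spec)
        matrix.P[0, :] = 1.0  # worst possible evidence
        fit, _post, pp = self.fit_for(matrix)
        assert fit.pi[0] >= 0.5
        assert np.all(pp[0] < 0.95)

    def test_overwhelming_evidence_crosses_threshold(self):
        spec = MultiStudySpec(n_genes=2000, n_studies=3, seed=17)
        matrix, _ = simulate_pattern_pvalues(spec)
        matrix.P[0, :] = 1e-30
        _fit, _post, pp = self.fit_for(matrix)
        assert np.all(pp[0] > 0.95)

    def test_study_permutation_permutes_pp_columns(self):
        spec = MultiStudySpec(n_genes=4000, n_studies=3, seed=19)
        matrix, _ = simulate_pattern_pvalues(spec)
        perm = [2, 0, 1]
        permuted = StudyMatrix(
            genes=matrix.genes,
            studies=[matrix.studies[j] for j in perm],
            P=matrix.P[:, perm],
        )
        _f1, _p1, pp1 = self.fit_for(matrix)
        _f2, _p2, pp2 = self.fit_for(permuted)
        assert np.allclose(pp2, pp1[:, perm], atol=1e-9)

    def test_single_study_matches_two_group_posterior(self):
        """J = 1 reduces to the closed-form two-component posterior."""
        rng = np.random.default_rng(23)
        t = -2 * np.log(rng.uniform(size=(3000, 1)))
        t[:100, 0] = 12.0 * rng.chisquare(2.0, size=100)
        mixtures = [StudyMixture(scale=12.0)]
        pi, _trace, _conv, _ = em_pattern_weights(t, mixtures)
        fit = PatternFit(
            studies=["s1"], patterns=pattern_matrix(1), mixtures=mixtures,
            alt_props=np.array([0.03]), pi=pi, loglik_trace=[], converged=True,
            n_iter=1,
        )
        _post, pp = pattern_posteriors(fit, t)
        f0 = np.exp(mixtures[0].log_null(t[:, 0]))
        f1 = np.exp(mixtures[0].log_alt(t[:, 0]))
        closed = pi[1] * f1 / (pi[0] * f0 + pi[1] * f1)
        assert np.allclose(pp[:, 0], closed, atol=1e-9)


def test_study_matrix_validation():
    with pytest.raises(ValueError):
        StudyMatrix(genes=["g1"], studies=["a"], P=np.array([[0.5]]))
    with pytest.raises(ValueError):
        StudyMatrix(genes=["g1"], studies=["a", "b"], P=np.array([[0.5, 0.0]]))
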