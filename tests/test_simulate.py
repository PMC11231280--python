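"""Synthetic-cohort generator: ground-truth structure and sampling laws."""

import numpy as np
import pytest
from scipy import stats

from ordnet.datasets import DEFAULT_DOMAIN_SIZES
from ordnet.simulate import (
    PrecisionSpec,
    ThresholdSpec,
    balanced_thresholds,
    make_block_precision,
    make_sparse_precision,
    sample_ordinal,
    simulate_cohort,
)


class TestPrecision:
    def test_empty_graph_when_density_zero(self):
        truth = make_sparse_precision(PrecisionSpec(p=5, density=0.0, seed=0))
        assert np.count_nonzero(truth.W_true) == 0
        assert np.count_nonzero(truth.K - np.diag(np.diag(truth.K))) == 0

    def test_partial_correlation_formula_two_nodes(self):
        # K = [[2,-1],[-1,2]] forced by hand gives W01 = -K01/sqrt(K00*K11) = 0.5
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        from ordnet.glasso import to_partial_correlations

        W = to_partial_correlations(K)
        assert W[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("p,density,seed", [(7, 0.5, 0), (26, 0.2, 3), (10, 1.0, 5)])
    def test_positive_definite_and_density(self, p, density, seed):
        truth = make_sparse_precision(PrecisionSpec(p=p, density=density, seed=seed))
        eig = np.linalg.eigvalsh(truth.K)
        assert eig[0] > 0
        target = round(density * p * (p - 1) / 2)
        assert abs(truth.n_edges - target) <= 1
        # partial-correlation identity
        d = np.sqrt(np.diag(truth.K))
        expect = -truth.K / np.outer(d, d)
        np.fill_diagonal(expect, 0.0)
        np.testing.assert_allclose(truth.W_true, expect)
        assert np.all(np.abs(truth.W_true) < 1)

    def test_negative_fraction_of_edges(self):
        truth = make_sparse_precision(
            PrecisionSpec(p=10, density=0.5, neg_fraction=0.4, seed=2)
        )
        iu = np.triu_indices(10, 1)
        w = truth.W_true[iu]
        n_neg = int((w < 0).sum())
        assert n_neg == round(0.4 * truth.n_edges)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            make_sparse_precision(PrecisionSpec(p=5, density=1.5))
        with pytest.raises(ValueError):
            make_sparse_precision(PrecisionSpec(p=5, density=0.5, weight_range=(0.4, 0.2)))

    def test_block_structure_denser_within(self):
        truth = make_block_precision([5, 5, 5], within_density=0.8, between_density=0.05, seed=0)
        block = np.repeat([0, 1, 2], 5)
        within = between = 0
        for i, j in truth.edge_set:
            if block[i] == block[j]:
                within += 1
            else:
                between += 1
        assert within > between


class TestThresholds:
    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError):
            ThresholdSpec([np.array([0.5, 0.0])])

    def test_balanced_cutpoints_are_quantiles(self):
        thr = balanced_thresholds(1, 4)
        np.testing.assert_allclose(thr.cutpoints[0], stats.norm.ppf([0.25, 0.5, 0.75]))


class TestSampling:
    def test_single_item_median_split(self):
        truth = make_sparse_precision(PrecisionSpec(p=1, density=0.0, seed=0))
        thr = ThresholdSpec([np.array([0.0])])
        data = sample_ordinal(truth, thr, n=50_000, seed=0)
        prop = (data.responses[:, 0] == 0).mean()
        assert prop == pytest.approx(0.5, abs=0.01)

    def test_marginals_converge_to_threshold_gaps(self):
        # empirical category proportions -> Phi(cutpoint) differences
        truth = make_sparse_precision(PrecisionSpec(p=3, density=0.5, seed=4))
        thr = balanced_thresholds(3, [3, 4, 5])
        data = sample_ordinal(truth, thr, n=50_000, seed=7)
        for j, cuts in enumerate(thr.cutpoints):
            edges = np.concatenate([[-np.inf], cuts, [np.inf]])
            expect = np.diff(stats.norm.cdf(edges))
            got = np.bincount(data.responses[:, j], minlength=len(expect)) / data.n
            np.testing.assert_allclose(got, expect, atol=0.01)

    def test_latent_correlation_recovered_by_polychoric(self):
        # two items, latent rho = 0.5: the polychoric estimate lands within
        # Monte-Carlo error of the truth
        from ordnet.polychoric import polychoric_matrix

        K = np.linalg.inv(np.array([[1.0, 0.5], [0.5, 1.0]]))
        from ordnet.simulate import TrueNetwork, _assemble_truth

        truth = _assemble_truth(K)
        thr = balanced_thresholds(2, 5)
        data = sample_ordinal(truth, thr, n=10_000, seed=11)
        S = polychoric_matrix(data)
        assert S.S[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_same_seed_identical_draws(self):
        truth = make_sparse_precision(PrecisionSpec(p=4, density=0.5, seed=0))
        thr = balanced_thresholds(4, 5)
        a = sample_ordinal(truth, thr, n=200, seed=9)
        b = sample_ordinal(truth, thr, n=200, seed=9)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_threshold_coverage_required(self):
        truth = make_sparse_precision(PrecisionSpec(p=3, density=0.5, seed=0))
        with pytest.raises(ValueError):
            sample_ordinal(truth, balanced_thresholds(2, 5), n=10)


class TestDefaultCohort:
    def test_domain_structure_matches_questionnaire(self):
        data, truth = simulate_cohort(n=100, seed=0)
        assert data.p == 26
        assert len(data.domains) == 7
        sizes = [len(data.items_in_domain(d)) for d in data.domains]
        assert sizes == list(DEFAULT_DOMAIN_SIZES.values()) == [3, 3, 6, 4, 4, 4, 2]

    def test_default_n_matches_cohort(self):
        data, _ = simulate_cohort(seed=0)
        assert data.n == 4901
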