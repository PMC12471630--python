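"""SparCC estimator: filtering, fractions, variation matrix, basis solve,
median aggregation, bootstrap pseudo p-values."""

import numpy as np
import pandas as pd
import pytest

from karstnet import (
    OtuTable,
    SparCC,
    SparccParams,
    bootstrap_pvalues,
    estimate_basis,
    filter_otus,
    generate_basis_correlation,
    generate_otu_table,
    logratio_variance,
    sparcc,
    to_fractions,
)
from karstnet._utils import derive_seed
from karstnet.sparcc import EmptyFilterError


def _table(counts, samples=None):
    arr = np.asarray(counts)
    idx = samples or [f"s{i}" for i in range(arr.shape[0])]
    return OtuTable(pd.DataFrame(arr, index=idx, columns=[f"t{j}" for j in range(arr.shape[1])]))


class TestFilter:
    def test_strictly_greater_than(self):
        tab = _table(np.array([[500, 400, 399]]))
        kept = filter_otus(tab, min_total=400)
        assert kept.taxa == ["t0"]

    def test_zero_threshold_identity(self, small_table):
        kept = filter_otus(small_table, min_total=0)
        assert kept.taxa == small_table.taxa

    def test_empty_result_error(self):
        with pytest.raises(EmptyFilterError):
            filter_otus(_table(np.array([[1, 2, 3]])), min_total=1000)

    def test_matches_brute_force_recount(self, design40):
        truth = generate_basis_correlation(50, [])
        tab = generate_otu_table(design40, truth, seed=3)
        kept = filter_otus(tab, min_total=400)
        expected = [t for t in tab.taxa if tab.counts[t].sum() > 400]
        assert kept.taxa == expected
        assert kept.n_samples == tab.n_samples


class TestFractions:
    def test_zero_counts_symmetric_posterior(self):
        draws = np.vstack([to_fractions([[0, 0, 0]], seed=s) for s in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0), 1 / 3, atol=0.01)

    def test_rows_sum_to_one_and_positive(self, rng):
        counts = rng.integers(0, 50, size=(10, 8))
        frac = to_fractions(counts, seed=1)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)
        assert (frac > 0).all()

    def test_converges_to_true_proportions(self):
        p = np.array([0.5, 0.3, 0.2])
        frac = to_fractions((1e7 * p)[None, :], seed=2)
        np.testing.assert_allclose(frac[0], p, atol=1e-3)

    def test_determinism_and_row_keys(self):
        counts = np.arange(12).reshape(3, 4)
        a = to_fractions(counts, seed=5, row_keys=["a", "b", "c"])
        b = to_fractions(counts, seed=5, row_keys=["a", "b", "c"])
        np.testing.assert_array_equal(a, b)
        # row-keyed draws do not depend on sample order
        c = to_fractions(counts[::-1], seed=5, row_keys=["c", "b", "a"])
        np.testing.assert_array_equal(a, c[::-1])


class TestLogratioVariance:
    def test_hand_computed_example(self):
        frac = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]])
        t = logratio_variance(frac)
        # d = {ln 2, ln 0.5}, mean 0, ddof=1 variance = 2 ln(2)^2
        assert t[0, 1] == pytest.approx(2 * np.log(2) ** 2, abs=1e-12)
        assert t[0, 1] == pytest.approx(0.9609, abs=1e-4)

    def test_proportional_taxa_zero_variance(self, rng):
        x = rng.uniform(0.1, 1.0, size=20)
        frac = np.column_stack([x, 3 * x, rng.uniform(0.1, 1.0, size=20)])
        frac = frac / frac.sum(axis=1, keepdims=True)
        assert logratio_variance(frac)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_zero_diagonal_nonnegative(self, rng):
        frac = rng.dirichlet(np.ones(6), size=15)
        t = logratio_variance(frac)
        np.testing.assert_allclose(t, t.T)
        np.testing.assert_array_equal(np.diag(t), 0.0)
        assert (t >= 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            logratio_variance(np.array([[0.5, 0.5]]))


class TestEstimateBasis:
    def test_constant_variation_closed_form(self):
        D, c = 8, 0.4
        t = np.full((D, D), c)
        np.fill_diagonal(t, 0.0)
        omega, rho = estimate_basis(t)
        np.testing.assert_allclose(omega, c / 2, atol=1e-12)
        np.testing.assert_allclose(rho - np.eye(D), 0.0, atol=1e-12)

    def test_proportional_pair_pushes_rho_positive(self):
        # t_01 = 0 embedded in otherwise-constant t: perfect proportionality
        D, c = 4, 0.4
        t = np.full((D, D), c)
        np.fill_diagonal(t, 0.0)
        t[0, 1] = t[1, 0] = 0.0
        _, rho = estimate_basis(t)
        assert rho[0, 1] > 0

    def test_agrees_with_independent_dense_solve(self, rng):
        # 6-taxon, 30-sample instance; oracle builds the full linear system
        # directly from the row-sum derivation and solves by least squares
        frac = rng.dirichlet(np.ones(6) * 2, size=30)
        t = logratio_variance(frac)
        D = 6
        exclusions = {(0, 3), (2, 4)}
        M = np.ones((D, D)) + (D - 2) * np.eye(D)
        t_row = t.sum(axis=1)
        for i, j in exclusions:
            t_row[i] -= t[i, j]
            t_row[j] -= t[i, j]
            for a, b in ((i, i), (j, j), (i, j), (j, i)):
                M[a, b] -= 1
        expected = np.linalg.lstsq(M, t_row, rcond=None)[0]
        omega, _ = estimate_basis(t, exclusions)
        np.testing.assert_allclose(omega, np.maximum(expected, 1e-6), atol=1e-8)

    def test_rho_bounded_and_unit_diagonal(self, rng):
        frac = rng.dirichlet(np.ones(10), size=12)
        _, rho = estimate_basis(logratio_variance(frac))
        assert np.abs(rho).max() <= 1.0
        np.testing.assert_array_equal(np.diag(rho), 1.0)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            estimate_basis(np.zeros((3, 3)))


class TestSparcc:
    def test_single_resample_equals_direct_chain(self, small_table):
        params = SparccParams(dirichlet_resamples=1, exclusion_iterations=0, seed=42)
        res = sparcc(small_table, params)
        frac = to_fractions(
            small_table.counts.to_numpy(),
            seed=derive_seed(42, "dirichlet", 0),
            row_keys=small_table.samples,
        )
        _, rho = estimate_basis(logratio_variance(frac))
        np.testing.assert_allclose(res.rho.to_numpy(), rho, atol=1e-12)

    def test_seed_determinism(self, small_table):
        a = sparcc(small_table, SparccParams(seed=3))
        b = sparcc(small_table, SparccParams(seed=3))
        pd.testing.assert_frame_equal(a.rho, b.rho)

    def test_sample_order_invariance(self, small_table):
        params = SparccParams(seed=8)
        base = sparcc(small_table, params).rho
        perm = small_table.counts.sample(frac=1.0, random_state=0)
        shuffled = OtuTable(perm, small_table.metadata)
        np.testing.assert_allclose(
            sparcc(shuffled, params).rho.to_numpy(), base.to_numpy(), atol=1e-12
        )

    def test_taxon_order_invariance_up_to_noise(self, small_table):
        params = SparccParams(seed=8)
        base = sparcc(small_table, params).rho
        rev = small_table.select_taxa(small_table.taxa[::-1])
        back = sparcc(rev, params).rho.loc[base.index, base.columns]
        # Dirichlet draws attach to positions, so equality is distributional:
        # the two estimates differ only by posterior-resampling noise
        np.testing.assert_allclose(back.to_numpy(), base.to_numpy(), atol=0.1)
        iu = np.triu_indices(base.shape[0], 1)
        r = np.corrcoef(base.to_numpy()[iu], back.to_numpy()[iu])[0, 1]
        assert r > 0.99

    def test_monotone_in_planted_strength(self, design40):
        medians = []
        for rho_true in (0.3, 0.5, 0.8):
            ests = []
            for seed in range(10):
                truth = generate_basis_correlation(20, [(0, 1, rho_true)])
                tab = generate_otu_table(design40, truth, seed=1000 + seed)
                ests.append(sparcc(tab, SparccParams(seed=seed)).rho.iloc[0, 1])
            medians.append(np.median(ests))
        assert medians[0] < medians[1] < medians[2]

    def test_model_results_surface(self, small_table):
        res = SparCC(small_table, min_total=0, seed=1).fit()
        assert res.n_taxa == small_table.n_taxa
        assert (res.omega >= 0).all()
        text = res.summary()
        assert "SparCC" in text and "taxa" in text


class TestBootstrapPvalues:
    @pytest.fixture(scope="class")
    def strong_pair_pvals(self, design40):
        truth = generate_basis_correlation(10, [(0, 1, 0.9)])
        tab = generate_otu_table(design40, truth, seed=21)
        params = SparccParams(bootstrap_count=100, seed=21)
        rho = sparcc(tab, params).rho
        return sparcc(tab, params), bootstrap_pvalues(tab, rho, params)

    def test_minimum_p_is_add_one_bound(self, strong_pair_pvals):
        _, p = strong_pair_pvals
        assert p.min().min() == pytest.approx(1 / 101)
        assert p.iloc[0, 1] == pytest.approx(1 / 101)

    def test_symmetric_unit_diagonal(self, strong_pair_pvals):
        _, p = strong_pair_pvals
        arr = p.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_array_equal(np.diag(arr), 1.0)

    def test_determinism(self, design40):
        truth = generate_basis_correlation(8, [])
        tab = generate_otu_table(design40, truth, seed=5)
        params = SparccParams(bootstrap_count=10, seed=5)
        rho = sparcc(tab, params).rho
        a = bootstrap_pvalues(tab, rho, params)
        b = bootstrap_pvalues(tab, rho, params)
        pd.testing.assert_frame_equal(a, b)

    def test_results_object_caches_pvalues(self, design40):
        truth = generate_basis_correlation(8, [])
        tab = generate_otu_table(design40, truth, seed=6)
        res = SparCC(tab, min_total=0, bootstrap_count=10, seed=2).fit()
        assert res.pvalues() is res.pvalues()
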