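"""Treatment statistics: Shannon, factorial ANOVA, LSD letters, percent change,
Bray-Curtis and Mantel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karstnet import (
    bray_curtis,
    check_and_transform,
    env_distance,
    factorial_anova,
    generate_design,
    load_soil_reference,
    mantel,
    oneway_lsd,
    percent_change,
    percent_change_from_means,
    shannon,
    shannon_table,
)


class TestShannon:
    def test_uniform_counts(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([10, 0, 0]) == 0.0

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=30).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_and_bounds(self, counts):
        h = shannon(counts)
        assert h == pytest.approx(shannon([10 * c for c in counts]), abs=1e-9)
        richness = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= np.log(richness) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_table_wrapper(self, small_table):
        df = shannon_table(small_table)
        assert len(df) == small_table.n_samples
        assert (df["shannon"] >= 0).all()


class TestCheckAndTransform:
    def test_normal_data_untouched(self, design40, rng):
        y = rng.standard_normal(40)
        y2, applied = check_and_transform(y, design40)
        assert not applied
        np.testing.assert_array_equal(y, y2)

    def test_lognormal_data_transformed(self, design40, rng):
        y = np.exp(rng.standard_normal(40) * 3)
        y2, applied = check_and_transform(y, design40)
        assert applied
        np.testing.assert_allclose(y2, np.log1p(y))

    def test_negative_values_with_transform_rejected(self, design40, rng):
        y = np.exp(rng.standard_normal(40) * 3)
        y[0] = -5.0
        with pytest.raises(ValueError):
            check_and_transform(y, design40)


class TestFactorialAnova:
    def test_constant_response(self, design40):
        tab = factorial_anova(np.full(40, 3.0), design40, transform="none")
        terms = tab.drop(index="Residual")
        np.testing.assert_array_equal(terms["F"], 0.0)
        np.testing.assert_array_equal(terms["p"], 1.0)

    def test_pure_main_effect(self, design40):
        y = 5.0 + 2.0 * design40["W"].to_numpy()
        tab = factorial_anova(y, design40, transform="none")
        assert tab.loc["W", "sum_sq"] == pytest.approx(40.0)  # 2^2 * 40/4
        for term in ["N", "P", "W:N", "W:P", "N:P", "W:N:P"]:
            assert tab.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_sample_order_invariance(self, design40, rng):
        y = rng.standard_normal(40) + design40["N"].to_numpy()
        tab = factorial_anova(y, design40, transform="none")
        perm = rng.permutation(40)
        tab2 = factorial_anova(y[perm], design40.iloc[perm], transform="none")
        pd.testing.assert_frame_equal(tab, tab2)

    def test_total_ss_decomposition(self, design40, rng):
        y = rng.standard_normal(40)
        tab = factorial_anova(y, design40, transform="none")
        total = ((y - y.mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, abs=1e-9)

    def test_unbalanced_design_rejected(self, design40):
        with pytest.raises(ValueError):
            factorial_anova(np.ones(39), design40.iloc[:39], transform="none")

    def test_block_term_optional(self, design40, rng):
        y = rng.standard_normal(40)
        tab = factorial_anova(y, design40, include_block=True, transform="none")
        assert "block" in tab.index


class TestOnewayLSD:
    def test_identical_groups_share_letter(self, rng):
        y = np.concatenate([rng.standard_normal(5) for _ in range(4)])
        groups = np.repeat(["t1", "t2", "t3", "t4"], 5)
        y = (y - y.mean()) * 0.01  # all groups statistically equal
        out = oneway_lsd(y, groups)
        assert set(out["letters"]) == {"a"}

    def test_shifted_group_gets_unique_letter(self, rng):
        base = rng.standard_normal(15)
        y = np.concatenate([base, base[:5] + 100.0])
        groups = np.repeat(["a1", "a2", "a3", "hi"], 5)
        out = oneway_lsd(y, groups)
        hi_letters = set(out.loc["hi", "letters"])
        others = set("".join(out.drop(index="hi")["letters"]))
        assert hi_letters.isdisjoint(others)

    def test_letter_contract(self, design40, rng):
        # any two same-letter groups must have pairwise LSD p >= alpha
        import itertools

        import scipy.stats

        y = rng.standard_normal(40) + 0.8 * design40["W"].to_numpy()
        groups = design40["treatment"].to_numpy()
        out = oneway_lsd(y, groups, alpha=0.05)
        mse = out.attrs["mse"]
        dfr = out.attrs["df_resid"]
        for ga, gb in itertools.combinations(out.index, 2):
            shared = set(out.loc[ga, "letters"]) & set(out.loc[gb, "letters"])
            na, nb = out.loc[ga, "n"], out.loc[gb, "n"]
            t = (out.loc[ga, "mean"] - out.loc[gb, "mean"]) / np.sqrt(
                mse * (1 / na + 1 / nb)
            )
            p = 2 * scipy.stats.t.sf(abs(t), dfr)
            if shared:
                assert p >= 0.05
            else:
                assert p < 0.05

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            oneway_lsd([1.0, 2.0], ["a", "b"])


class TestPercentChange:
    def test_reference_table_nitrate_under_n(self):
        means, _ = load_soil_reference()
        pc = percent_change_from_means(means, "N", ["NO3"])
        assert pc["percent_change"].iloc[0] == pytest.approx(57.6, abs=0.5)

    def test_reference_table_swc_under_w(self):
        means, _ = load_soil_reference()
        pc = percent_change_from_means(means, "W", ["SWC"])
        assert pc["percent_change"].iloc[0] == pytest.approx(7.6, abs=0.1)

    def test_constant_variable_zero(self, design40):
        df = design40.copy()
        df["x"] = 4.2
        pc = percent_change(df, "W", ["x"])
        assert pc["percent_change"].iloc[0] == pytest.approx(0.0)

    def test_zero_baseline_missing(self, design40):
        df = design40.copy()
        df["x"] = df["W"].astype(float)  # -W mean is 0
        pc = percent_change(df, "W", ["x"])
        assert np.isnan(pc["percent_change"].iloc[0])

    def test_per_sample_matches_treatment_means(self, design40, rng):
        df = design40.copy()
        df["x"] = rng.uniform(1, 2, size=40)
        means = df.groupby("treatment")["x"].mean().to_frame().T
        a = percent_change(df, "P", ["x"])["percent_change"].iloc[0]
        b = percent_change_from_means(means.rename(index={"x": "x"}), "P", ["x"])
        assert a == pytest.approx(b["percent_change"].iloc[0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(pd.DataFrame([[3, 2, 1], [3, 2, 1]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(pd.DataFrame([[5, 0], [0, 7]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_example(self):
        d = bray_curtis(pd.DataFrame([[2, 0], [1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_bounds_symmetry(self, small_table):
        d = bray_curtis(small_table)
        arr = d.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_array_equal(np.diag(arr), 0.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[0, 0], [1, 2]]))


class TestMantel:
    @pytest.fixture()
    def dist_pair(self, rng):
        x = rng.uniform(size=(15, 3))
        y = rng.uniform(size=(15, 3))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(x)), squareform(pdist(y))

    def test_self_comparison_maximal(self, dist_pair):
        a, _ = dist_pair
        res = mantel(a, a, permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        from scipy.spatial.distance import pdist, squareform

        hits = 0
        for _ in range(20):
            a = squareform(pdist(rng.uniform(size=(20, 3))))
            b = squareform(pdist(rng.uniform(size=(20, 3))))
            if abs(mantel(a, b, permutations=99, seed=1).r) < 0.3:
                hits += 1
        assert hits >= 19

    def test_seed_determinism(self, dist_pair):
        a, b = dist_pair
        assert mantel(a, b, seed=7) == mantel(a, b, seed=7)

    def test_monotone_transform_invariance(self, dist_pair):
        a, b = dist_pair
        assert mantel(a, b, seed=1).r == pytest.approx(mantel(a, b**2, seed=1).r)

    def test_matches_skbio_statistic(self, dist_pair):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a, b = dist_pair
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a),
            skbio_distance.DistanceMatrix(b),
            method="spearman",
            permutations=0,
        )
        assert mantel(a, b, seed=0).r == pytest.approx(r_skbio, abs=1e-12)

    def test_size_mismatch(self, dist_pair):
        a, b = dist_pair
        with pytest.raises(ValueError):
            mantel(a, b[:10, :10])

    def test_constant_distances_yield_nan(self):
        a = np.zeros((5, 5))
        b = np.ones((5, 5)) - np.eye(5)
        res = mantel(a, b, seed=0)
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_env_distance_shape(self, design40):
        env = pd.DataFrame(
            np.random.default_rng(1).uniform(size=(40, 4)),
            index=design40.index,
            columns=list("abcd"),
        )
        d = env_distance(env, ["a", "b"])
        assert d.shape == (40, 40)
        np.testing.assert_array_equal(np.diag(d), 0.0)
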