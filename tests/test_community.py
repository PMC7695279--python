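import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phycodyn.community import (
    OtuTable,
    bray_curtis_matrix,
    cluster_simprof,
    dendrogram_newick,
    env_window_means,
    kendall_screen,
    relative_abundance,
    richness,
    shared_partition,
    simprof_test,
)
from tests.conftest import random_otu_counts


def _table(counts: pd.DataFrame, marker="16S") -> OtuTable:
    lineages = pd.Series(
        {c: f"k__Bacteria;p__P;c__C;o__O;f__F;g__G{c};s__G{c} sp" for c in counts.columns}
    )
    return OtuTable(counts=counts, lineages=lineages, marker=marker)


class TestRelativeAbundance:
    def test_single_otu_is_one_everywhere(self):
        t = _table(pd.DataFrame({"otu1": [5, 10]}, index=["a", "b"]))
        prof = relative_abundance(t, rank="otu", threshold=0.5)
        assert np.allclose(prof.data["otu1"], 1.0)

    def test_threshold_and_residual_pooling(self):
        t = _table(pd.DataFrame([[50, 30, 20]], index=["a"], columns=["o1", "o2", "o3"]))
        prof = relative_abundance(t, rank="otu", threshold=0.25)
        assert set(prof.taxa) == {"o1", "o2"}
        assert prof.data.loc["a", "o1"] == pytest.approx(0.5)
        assert prof.data.loc["a", "o2"] == pytest.approx(0.3)
        assert prof.data.loc["a", "other"] == pytest.approx(0.2)

    def test_rows_sum_to_one(self, toy_otu_table):
        prof = relative_abundance(toy_otu_table, rank="genus", threshold=0.1)
        assert np.allclose(prof.data.sum(axis=1), 1.0)

    def test_all_zero_sample_is_an_error(self):
        t = _table(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["o1", "o2"]))
        with pytest.raises(ValueError, match="zero total"):
            relative_abundance(t)

    def test_aggregate_then_threshold_differs_from_reverse_order(self):
        # two OTUs of the same genus each below 10% but jointly above it:
        # aggregating first keeps the genus, thresholding OTUs first would not.
        counts = pd.DataFrame([[6, 6, 88]], index=["a"], columns=["o1", "o2", "o3"])
        lineages = pd.Series(
            {
                "o1": "k__B;p__P;c__C;o__O;f__F;g__Shared",
                "o2": "k__B;p__P;c__C;o__O;f__F;g__Shared",
                "o3": "k__B;p__P;c__C;o__O;f__F;g__Dominant",
            }
        )
        t = OtuTable(counts=counts, lineages=lineages)
        agg_first = relative_abundance(t, rank="genus", threshold=0.10)
        assert "Shared" in agg_first.taxa  # 12% jointly
        otu_first = relative_abundance(t, rank="otu", threshold=0.10)
        assert {"o1", "o2"}.isdisjoint(otu_first.taxa)

    def test_unclassified_rank_fill(self, toy_otu_table):
        names = toy_otu_table.taxon_at_rank("genus")
        assert names["otu4"] == "unclassified"


class TestRichness:
    def test_presence_scan_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            counts = random_otu_counts(rng)
            t = _table(counts)
            r = richness(t)
            expected = (counts.values > 0).sum(axis=1)
            assert (r["per_sample"].values == expected).all()
            assert r["pooled"] == int((counts.values > 0).any(axis=0).sum())

    def test_empty_sample_counts_zero(self):
        counts = pd.DataFrame([[3, 1], [0, 0]], index=["a", "b"], columns=["o1", "o2"])
        # bypass zero-total error: richness works on raw counts
        t = _table(counts)
        assert richness(t)["per_sample"]["b"] == 0


class TestSharedPartition:
    def test_identical_tables_fully_shared(self, toy_otu_table):
        p = shared_partition(toy_otu_table, toy_otu_table, threshold=0.01)
        assert p.only_a == p.only_b == 0
        assert p.shared == p.total

    def test_set_algebra_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = _table(random_otu_counts(rng)), _table(random_otu_counts(rng))
            p = shared_partition(a, b, threshold=0.05)

            def dominant(t):
                rel = t.counts.div(t.counts.sum(axis=1), axis=0)
                return set(rel.columns[(rel > 0.05).any(axis=0)])

            sa, sb = dominant(a), dominant(b)
            assert p.shared == len(sa & sb)
            assert p.only_a == len(sa - sb)
            assert p.only_b == len(sb - sa)
            assert p.shared + p.only_a + p.only_b == p.total

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        a = _table(random_otu_counts(rng, n_samples=3, n_otus=8))
        b = _table(random_otu_counts(rng, n_samples=3, n_otus=8))
        p = shared_partition(a, b, threshold=0.02)
        assert p.shared + p.only_a + p.only_b == p.total

    def test_subset_filter(self, toy_otu_table):
        p = shared_partition(toy_otu_table, toy_otu_table, threshold=0.01,
                             subset={"otu1", "otu2"})
        assert p.total == 2


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis_matrix(df).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        df = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert bray_curtis_matrix(df).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        df = pd.DataFrame([[6, 0, 4], [0, 6, 4]], index=["a", "b"])
        # 1 - 2*min_sum/total = 1 - 2*4/20 = 0.6
        assert bray_curtis_matrix(df).loc["a", "b"] == pytest.approx(0.6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_semimetric_properties_and_rescale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(1, 50, size=(4, 5)).astype(float))
        m = bray_curtis_matrix(df)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert (m.values >= -1e-12).all() and (m.values <= 1 + 1e-12).all()
        df2 = df.copy()
        df2.iloc[0] *= 3.0
        # Bray-Curtis is NOT invariant to rescaling raw counts of one sample,
        # but is invariant when profiles are closed (relative abundances)
        rel = df.div(df.sum(axis=1), axis=0)
        rel2 = df2.div(df2.sum(axis=1), axis=0)
        assert np.allclose(bray_curtis_matrix(rel).values, bray_curtis_matrix(rel2).values)

    def test_all_zero_sample_error(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"])
        with pytest.raises(ValueError):
            bray_curtis_matrix(df)


class TestSimprof:
    def test_identical_samples_form_single_group(self):
        data = pd.DataFrame(np.tile([0.4, 0.3, 0.3], (6, 1)),
                            index=[f"s{i}" for i in range(6)])
        m = bray_curtis_matrix(data)
        res = cluster_simprof(m, data, n_perm=199, seed=1)
        assert len(res.groups) == 1
        assert sorted(res.groups[0]) == sorted(data.index)

    def test_two_planted_clusters_are_recovered(self):
        rng = np.random.default_rng(42)
        # disjoint dominant taxa: strong multivariate structure
        block1 = rng.dirichlet([20, 20, 1, 1], size=6)
        block2 = rng.dirichlet([1, 1, 20, 20], size=6)
        data = pd.DataFrame(np.vstack([block1, block2]),
                            index=[f"s{i}" for i in range(12)])
        m = bray_curtis_matrix(data)
        res = cluster_simprof(m, data, n_perm=999, seed=7)
        root = res.nodes[0]
        assert root.significant and root.p_value < 0.05
        labels = res.group_of()
        assert labels.iloc[:6].nunique() >= 1
        # the two planted blocks never share a group
        assert set(labels.iloc[:6]) & set(labels.iloc[6:]) == set()

    def test_groups_partition_samples(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.dirichlet(np.ones(5), size=8))
        m = bray_curtis_matrix(data)
        res = cluster_simprof(m, data, n_perm=199, seed=2)
        members = [s for g in res.groups for s in g]
        assert sorted(members) == sorted(data.index)

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="coarse"):
            simprof_test(rng.random((5, 4)), n_perm=20, rng=rng)

    def test_too_few_samples_or_variables(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simprof_test(rng.random((2, 4)), rng=rng)
        with pytest.raises(ValueError):
            simprof_test(rng.random((5, 1)), rng=rng)

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.dirichlet(np.ones(4), size=5),
                            index=[f"s{i}" for i in range(5)])
        m = bray_curtis_matrix(data)
        res = cluster_simprof(m, data, n_perm=199, seed=1)
        nwk = dendrogram_newick(res.linkage_matrix, [str(s) for s in res.sample_ids])
        assert nwk.endswith(";")
        for s in data.index:
            assert str(s) in nwk


class TestEnvWindowMeans:
    def test_constant_series(self):
        daily = pd.DataFrame({"T": np.full(30, 21.5)}, index=np.arange(30.0))
        means, n = env_window_means(daily, [10.0, 20.0])
        assert np.allclose(means["T"], 21.5)
        assert (n == 7).all()

    def test_arithmetic_mean_of_preceding_week(self):
        daily = pd.DataFrame({"x": np.arange(1.0, 11.0)}, index=np.arange(1.0, 11.0))
        means, n = env_window_means(daily, [7.0])
        # days 1..7 inclusive -> mean 4
        assert means.loc[7.0, "x"] == pytest.approx(4.0)

    def test_partial_window_flagged_by_count(self):
        daily = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=[0.0, 1.0, 2.0])
        means, n = env_window_means(daily, [2.0])
        assert n[2.0] == 3
        assert means.loc[2.0, "x"] == pytest.approx(2.0)

    def test_empty_window_error(self):
        daily = pd.DataFrame({"x": [1.0]}, index=[50.0])
        with pytest.raises(ValueError):
            env_window_means(daily, [10.0])


def _kendall_bruteforce(x, y):
    """O(n^2) concordant/discordant pair count with tau-b tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (c - d) / denom if denom > 0 else np.nan


class TestKendallScreen:
    def test_comonotone_pair_has_tau_one(self):
        data = pd.DataFrame({"taxon": [0.1, 0.2, 0.3, 0.4, 0.5]})
        env = pd.DataFrame({"T": [1.0, 2.0, 3.0, 4.0, 5.0]})
        screen = kendall_screen(data, env)
        assert screen.tau.loc["taxon", "T"] == pytest.approx(1.0)

    def test_tau_b_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(8)
        for n in (5, 8, 12):
            for _ in range(20):
                x = rng.integers(0, 4, n).astype(float)  # heavy ties
                y = rng.integers(0, 4, n).astype(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                expected = _kendall_bruteforce(x, y)
                got = stats.kendalltau(x, y, variant="b").statistic
                assert got == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_flagged(self):
        data = pd.DataFrame({"t1": [0.5] * 5, "t2": [0.1, 0.2, 0.3, 0.4, 0.5]})
        env = pd.DataFrame({"T": [1.0, 2.0, 3.0, 4.0, 5.0]})
        screen = kendall_screen(data, env)
        assert ("t1", "T") in screen.flagged_constant
        assert np.isnan(screen.tau.loc["t1", "T"])
        assert not screen.significant.loc["t1", "T"]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(rng.random((10, 6)))
        env = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        s5 = kendall_screen(data, env, alpha=0.05)
        s1 = kendall_screen(data, env, alpha=0.01)
        assert s1.significant.values.sum() <= s5.significant.values.sum()

    def test_too_few_observations(self):
        data = pd.DataFrame({"t": [0.1, 0.2, 0.3]})
        env = pd.DataFrame({"T": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            kendall_screen(data, env)
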