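"""ANOVA decomposition, multiplicity control, t maps, cluster permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from flavorsense.stats import (
    bh_fdr,
    build_adjacency,
    cluster_permutation,
    gg_epsilon,
    grid_adjacency,
    holm,
    mixed_anova,
    one_sample_t,
    paired_t,
    report_tables,
    rm_anova,
)


def long_table(rng, n=15, factors=("block",), levels=(7,), effect=None):
    rows = []
    for p in range(n):
        for combo in np.ndindex(*levels):
            val = rng.standard_normal()
            if effect:
                val += effect(*combo)
            row = {"participant": p, "value": val}
            row.update({f: c for f, c in zip(factors, combo)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_study_design_df_pairs(self):
        rng = np.random.default_rng(0)
        # block(7): (6, 84); location(4): (3, 42); block x location: (18, 252)
        r7 = rm_anova(long_table(rng, 15, ("block",), (7,)), within=["block"])[0]
        assert (r7.df1, r7.df2) == (6, 84)
        r4 = rm_anova(long_table(rng, 15, ("location",), (4,)), within=["location"])[0]
        assert (r4.df1, r4.df2) == (3, 42)
        both = rm_anova(
            long_table(rng, 15, ("block", "location"), (7, 4)),
            within=["block", "location"],
        )
        by = {r.effect: r for r in both}
        assert (by["block"].df1, by["block"].df2) == (6, 84)
        assert (by["location"].df1, by["location"].df2) == (3, 42)
        assert (by["block:location"].df1, by["block:location"].df2) == (18, 252)

    def test_constant_within_participant_gives_zero_f(self):
        rows = [
            {"participant": p, "block": b, "value": float(p)}
            for p in range(6)
            for b in range(4)
        ]
        r = rm_anova(pd.DataFrame(rows), within=["block"])[0]
        assert r.F == 0.0

    def test_f_equals_squared_paired_t_for_two_levels(self):
        rng = np.random.default_rng(1)
        tbl = long_table(rng, 12, ("block",), (2,), effect=lambda b: 0.4 * b)
        r = rm_anova(tbl, within=["block"])[0]
        piv = tbl.pivot(index="participant", columns="block", values="value")
        t_stat = sstats.ttest_rel(piv[0], piv[1]).statistic
        assert r.F == pytest.approx(t_stat**2, rel=1e-8)
        assert r.gg_epsilon == 1.0

    def test_matches_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        tbl = long_table(rng, 15, ("block",), (7,), effect=lambda b: 0.2 * b)
        mine = rm_anova(tbl, within=["block"])[0]
        ref = pg.rm_anova(
            data=tbl, dv="value", within="block", subject="participant",
            correction=True, detailed=True,
        ).iloc[0]
        assert mine.F == pytest.approx(ref["F"], rel=1e-9)
        assert mine.p_uncorrected == pytest.approx(ref["p_unc"], rel=1e-9)
        assert mine.gg_epsilon == pytest.approx(ref["eps"], rel=1e-9)
        assert mine.p_gg == pytest.approx(ref["p_GG_corr"], rel=1e-9)

    def test_matches_pingouin_two_way_f(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        tbl = long_table(
            rng, 10, ("block", "location"), (2, 4),
            effect=lambda b, l: 0.3 * b + 0.1 * l,
        )
        mine = {r.effect: r for r in rm_anova(tbl, within=["block", "location"])}
        ref = pg.rm_anova(
            data=tbl, dv="value", within=["block", "location"],
            subject="participant", detailed=True,
        )
        for src, key in (("block", "block"), ("location", "location"),
                         ("block * location", "block:location")):
            row = ref[ref["Source"] == src].iloc[0]
            assert mine[key].F == pytest.approx(row["F"], rel=1e-9)
            assert (mine[key].df1, mine[key].df2) == (row["ddof1"], row["ddof2"])

    def test_incomplete_design_listwise_then_error(self):
        rng = np.random.default_rng(4)
        tbl = long_table(rng, 5, ("block",), (3,))
        # one participant missing one cell -> dropped listwise
        tbl = tbl[~((tbl.participant == 0) & (tbl.block == 2))]
        r = rm_anova(tbl, within=["block"])[0]
        assert r.n_participants == 4
        # every participant missing some cell -> nobody survives deletion
        bad = tbl[tbl.participant % 3 != tbl.block]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(bad, within=["block"])


class TestGgEpsilon:
    def test_two_levels_exactly_one(self):
        rng = np.random.default_rng(0)
        tbl = long_table(rng, 10, ("f",), (2,))
        assert gg_epsilon(tbl, "f") == 1.0

    def test_compound_symmetry_near_one(self):
        # exchangeable covariance satisfies sphericity -> epsilon ~ 1
        rng = np.random.default_rng(1)
        n, k = 200, 5
        subj = rng.standard_normal((n, 1))
        data = subj + rng.standard_normal((n, k))
        rows = [
            {"participant": p, "f": j, "value": data[p, j]}
            for p in range(n)
            for j in range(k)
        ]
        eps = gg_epsilon(pd.DataFrame(rows), "f")
        assert eps == pytest.approx(1.0, abs=0.05)

    def test_rank_one_deviation_hits_lower_bound(self):
        # all within-subject variance on a single contrast -> eps -> 1/(k-1)
        rng = np.random.default_rng(2)
        n, k = 50, 4
        c = np.array([1.0, -1.0, 0.0, 0.0])
        data = rng.standard_normal((n, 1)) * c[None, :] + 1e-6 * rng.standard_normal((n, k))
        rows = [
            {"participant": p, "f": j, "value": data[p, j]}
            for p in range(n)
            for j in range(k)
        ]
        eps = gg_epsilon(pd.DataFrame(rows), "f")
        assert eps == pytest.approx(1.0 / (k - 1), abs=0.02)


class TestHolm:
    def test_single_p_unchanged(self):
        adj, rej = holm([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_step_down(self):
        # sorted: .01*3=.03, .02*2=.04, .04*1=.04 (monotone max)
        adj, rej = holm([0.01, 0.02, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])
        assert rej.all()

    def test_ties_block_rejection(self):
        adj, rej = holm([0.04, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.08, 0.08])
        assert not rej.any()

    def test_empty(self):
        adj, rej = holm([])
        assert adj.size == 0 and rej.size == 0

    def test_adjusted_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        adj, _ = holm(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestBhFdr:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        # .04*4/4=.04; .03*4/3=.04; .02*4/2=.04; .01*4/1=.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_member_family_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.007]), 0.007)

    def test_families_corrected_independently(self):
        p = [0.01, 0.02, 0.03, 0.04]
        fam = ["a", "a", "b", "b"]
        adj = bh_fdr(p, fam)
        np.testing.assert_allclose(adj[:2], [0.02, 0.02])
        np.testing.assert_allclose(adj[2:], [0.04, 0.04])

    def test_adjusted_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestTMaps:
    def test_hand_computed_one_sample(self):
        # values [1,2,3]: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 3.4641
        maps = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        t = one_sample_t(maps)
        assert t[0, 0] == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)

    def test_zero_variance_is_missing_not_inf(self):
        maps = np.zeros((4, 2, 3))
        t = one_sample_t(maps)
        assert np.isnan(t).all()

    def test_paired_identical_maps_missing(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 2, 4))
        t = paired_t(a, a)
        assert np.isnan(t).all()


class TestAdjacency:
    def test_edgeless_below_min_distance(self):
        pos = np.array([[0.0], [1.0], [2.0]])
        assert build_adjacency(pos, 0.5).edges == ()

    def test_collinear_path_graph(self):
        pos = np.array([[0.0], [1.0], [2.0]])
        g = build_adjacency(pos, 1.5)
        assert g.edges == ((0, 1), (1, 2))

    def test_complete_above_max_distance(self):
        pos = np.array([[0.0], [1.0], [2.0]])
        g = build_adjacency(pos, 10.0)
        assert len(g.edges) == 3

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency(np.array([[0.0], [np.nan]]), 1.0)


class TestClusterPermutation:
    def test_no_suprathreshold_points_no_clusters(self):
        rng = np.random.default_rng(0)
        x = 1e-3 * rng.standard_normal((8, 4, 20))
        x -= x.mean(axis=0, keepdims=True)  # kill any mean excursion
        res = cluster_permutation(
            x * 0.0 + 1e-12 * rng.standard_normal((8, 4, 20)),
            "one_sample_t",
            grid_adjacency(2, 2),
            n_permutations=128,
            seed=0,
        )
        # pure jitter: any clusters found must be non-significant
        assert all(c.p_value > 0.05 for c in res.clusters) or not res.clusters

    def test_injected_patch_reaches_p_floor(self):
        """A 10x-noise effect over a 5-channel, 20-sample patch is detected
        at the smallest attainable p."""
        rng = np.random.default_rng(1)
        a = rng.standard_normal((15, 16, 100))
        b = rng.standard_normal((15, 16, 100))
        b[:, 3:8, 40:60] += 10.0
        res = cluster_permutation(
            (b, a), "paired_t", grid_adjacency(4, 4), n_permutations=500, seed=2
        )
        assert res.clusters
        assert res.min_p == pytest.approx(1.0 / (res.n_permutations + 1))
        top = res.clusters[0]
        assert set(np.unique(top.channels)) >= set(range(3, 8))

    def test_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 4, 10))
        res = cluster_permutation(
            x, "one_sample_t", grid_adjacency(2, 2), n_permutations=100, seed=0
        )
        assert res.n_permutations == 64  # 2^6 sign patterns enumerated

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 4, 30))
        r1 = cluster_permutation(x, "one_sample_t", grid_adjacency(2, 2), 200, seed=9)
        r2 = cluster_permutation(x, "one_sample_t", grid_adjacency(2, 2), 200, seed=9)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
        np.testing.assert_array_equal(r1.max_mass_null, r2.max_mass_null)

    def test_channel_relabeling_invariance(self):
        """Permuting channel identities (and the graph with them) permutes
        clusters but leaves masses and p-values unchanged."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10, 4, 25))
        x[:, 1, 5:15] += 1.5
        pos = np.array([[0.0], [1.0], [2.0], [3.0]])
        g = build_adjacency(pos, 1.5)
        r1 = cluster_permutation(x, "one_sample_t", g, 300, seed=7)
        perm = np.array([2, 0, 3, 1])
        g2 = build_adjacency(pos[np.argsort(perm)], 1.5)
        r2 = cluster_permutation(x[:, perm, :], "one_sample_t", g2, 300, seed=7)
        m1 = sorted(round(c.mass, 9) for c in r1.clusters)
        m2 = sorted(round(c.mass, 9) for c in r2.clusters)
        assert m1 == m2
        p1 = sorted(c.p_value for c in r1.clusters)
        p2 = sorted(c.p_value for c in r2.clusters)
        assert p1 == p2

    def test_matches_mne_observed_clusters(self):
        """Cross-check observed cluster masses against the MNE implementation
        at an identical fixed threshold."""
        mne_stats = pytest.importorskip("mne.stats")
        from scipy import sparse as sp

        rng = np.random.default_rng(6)
        x = rng.standard_normal((12, 6, 40))
        x[:, 2:4, 10:20] += 1.2
        pos = np.arange(6, dtype=float)[:, None]
        g = build_adjacency(pos, 1.5)
        n = x.shape[0]
        thr = float(sstats.t.ppf(1 - 0.025, n - 1))

        adj_mat = sp.lil_matrix((6, 6), dtype=int)
        for i, j in g.edges:
            adj_mat[i, j] = adj_mat[j, i] = 1
        # mne expects (obs, time, space)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            x.transpose(0, 2, 1), threshold=thr, n_permutations=50,
            adjacency=sp.csr_matrix(adj_mat), out_type="mask", seed=0, verbose="error",
        )
        mne_masses = []
        for cl in clusters:
            mne_masses.append(float(np.abs(t_obs[cl]).sum()))
        res = cluster_permutation(x, "one_sample_t", g, 200, seed=0)
        mine = sorted(round(c.mass, 6) for c in res.clusters)
        assert mine == sorted(round(m, 6) for m in mne_masses)

    def test_one_way_f_design_detects_effect(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((12, 3, 4, 30))
        x[:, 2, 1:3, 10:20] += 2.0
        res = cluster_permutation(
            x, "one_way_F", grid_adjacency(2, 2), n_permutations=200, seed=1
        )
        assert res.clusters
        assert res.min_p < 0.05


class TestMixedAnova:
    def test_order_blocking_factor_null(self):
        rng = np.random.default_rng(9)
        rows = []
        for p in range(12):
            order = p % 4 + 1
            for b in range(1, 8):
                rows.append(
                    {
                        "participant": p,
                        "session_order": order,
                        "block": b,
                        "value": rng.standard_normal(),
                    }
                )
        res = mixed_anova(pd.DataFrame(rows), within="block", between="session_order")
        by = {r.effect: r for r in res}
        assert by["block"].df1 == 6
        assert by["session_order"].df1 == 3
        assert by["block:session_order"].df1 == 18
        assert by["block:session_order"].p_uncorrected > 0.01  # null interaction


class TestReportTables:
    def test_single_result_row(self):
        rng = np.random.default_rng(10)
        tbl = long_table(rng, 8, ("block",), (3,))
        df = report_tables(rm_anova(tbl, within=["block"]))
        assert len(df) == 1
        assert df["p_fdr"].iloc[0] >= df["p_gg"].iloc[0] - 1e-12

    def test_family_of_27_shares_family_id(self):
        rng = np.random.default_rng(11)
        results = []
        for i in range(27):
            tbl = long_table(rng, 6, ("f",), (3,))
            r = rm_anova(tbl, within=["f"])[0]
            r.effect = f"rating_{i}"
            r.family_id = "internal_state"
            results.append(r)
        df = report_tables(results)
        assert len(df) == 27
        assert (df["family_id"] == "internal_state").all()
        # BH within the family: adjusted >= raw, step-up monotone
        order = np.argsort(df["p_gg"].to_numpy())
        assert (np.diff(df["p_fdr"].to_numpy()[order]) >= -1e-12).all()

    def test_empty_results_header_only(self):
        df = report_tables([])
        assert len(df) == 0
        assert "p_fdr" in df.columns
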