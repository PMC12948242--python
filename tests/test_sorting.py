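"""Virtual sorting: exact 1-D two-cluster split, delta_ARS, Wilcoxon, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mescreen as ms
from mescreen.sorting import _split_costs


def _rank_matrix(rows: np.ndarray) -> ms.RankMatrix:
    rows = np.atleast_2d(rows)
    return ms.RankMatrix(
        pd.DataFrame(rows, index=[f"G{i}" for i in range(rows.shape[0])], columns=[f"S{j}" for j in range(rows.shape[1])])
    )


def wcss_split_oracle(vals: np.ndarray):
    """Brute-force best contiguous split of a sorted vector by direct WCSS."""
    s = np.sort(vals)
    best_cost, best_k = np.inf, None
    for k in range(1, s.size):
        if s[k - 1] == s[k]:
            continue  # not definable by a value threshold
        left, right = s[:k], s[k:]
        cost = left.size * left.var() + right.size * right.var()
        if cost < best_cost:
            best_cost, best_k = cost, k
    return best_cost, best_k


def wilcoxon_enumeration_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.sort(np.concatenate([x, y]))
    n, m = x.size, y.size
    u_obs = sum(np.sum(xi > y) for xi in x)
    center = n * m / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(np.sum(xi > ys) for xi in xs)
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up formula: sort, q_i = p_i * m / i, cumulative min, clip, unsort."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out


class TestPartitionSamples:
    def test_perfect_separation(self):
        g = ms.partition_samples(_rank_matrix(np.array([0.0, 0, 0, 100, 100])), "G0", min_group=1)
        assert g.n_low == 3 and g.n_high == 2
        assert set(g.high_samples) == {"S3", "S4"}

    def test_three_point_split_matches_wcss_scan(self):
        # splits: {10}|{12,90} cost 0+3042 vs {10,12}|{90} cost 2+0
        g = ms.partition_samples(_rank_matrix(np.array([10.0, 12, 90])), "G0", min_group=1)
        assert set(g.low_samples) == {"S0", "S1"}
        assert set(g.high_samples) == {"S2"}

    def test_constant_source_is_zero_plasticity_error(self):
        with pytest.raises(ms.ZeroPlasticityError, match="plasticity"):
            ms.partition_samples(_rank_matrix(np.full(4, 50.0)), "G0", min_group=1)

    def test_min_group_enforced(self):
        with pytest.raises(ValueError, match="min_group"):
            ms.partition_samples(_rank_matrix(np.array([0.0, 0, 0, 100, 100])), "G0", min_group=3)

    def test_absent_source(self):
        with pytest.raises(ValueError, match="MISSING"):
            ms.partition_samples(_rank_matrix(np.array([1.0, 2, 3])), "MISSING", min_group=1)

    def test_boundary_ties_assigned_by_value(self):
        vals = np.array([0.0, 0, 50, 50, 50, 100, 100, 100])
        g = ms.partition_samples(_rank_matrix(vals), "G0", min_group=1)
        labels = g.labels.to_numpy()
        for v in np.unique(vals):
            assert len(set(labels[vals == v])) == 1  # same value -> same side

    def test_high_group_strictly_above_low_group(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 100, rng.integers(4, 50))
            g = ms.partition_samples(_rank_matrix(vals), "G0", min_group=1)
            high = vals[(g.labels == "high").to_numpy()]
            low = vals[(g.labels == "low").to_numpy()]
            assert high.min() > low.max()

    def test_matches_brute_force_wcss_oracle(self, rng):
        for i in range(200):
            n = int(rng.integers(5, 601))
            vals = rng.uniform(0, 100, n)
            if i % 3 == 0:
                vals = np.round(vals / 10) * 10  # force ties
            g = ms.partition_samples(_rank_matrix(vals), "G0", min_group=1)
            oracle_cost, oracle_k = wcss_split_oracle(vals)
            assert g.n_low == oracle_k
            s = np.sort(vals)
            impl_cost = _split_costs(s)[g.n_low - 1]
            assert impl_cost == pytest.approx(oracle_cost, abs=1e-6)

    def test_matches_general_kmeans_solver(self, rng):
        """Exhaustive scan equals k-means run to convergence from every
        contiguous initialization (the globally optimal 1-D solution)."""
        pytest.importorskip("sklearn")
        from sklearn.cluster import KMeans

        for _ in range(10):
            vals = rng.uniform(0, 100, 60)
            g = ms.partition_samples(_rank_matrix(vals), "G0", min_group=1)
            best = None
            for k in range(1, 60):
                s = np.sort(vals)
                init = np.array([[s[:k].mean()], [s[k:].mean()]])
                km = KMeans(n_clusters=2, init=init, n_init=1).fit(vals.reshape(-1, 1))
                if best is None or km.inertia_ < best.inertia_:
                    best = km
            high_label = np.argmax(best.cluster_centers_.ravel())
            np.testing.assert_array_equal((g.labels == "high").to_numpy(), best.labels_ == high_label)


class TestDeltaArs:
    def test_extreme_and_constant_genes(self):
        rows = np.array([[100.0, 100, 0, 0], [50.0, 50, 50, 50], [100.0, 80, 20, 0]])
        r = _rank_matrix(rows)
        g = ms.partition_samples(r, "G2", min_group=1)
        table = ms.delta_ars(r, g)
        assert table.loc["G0", "delta"] == 100
        assert table.loc["G1", "delta"] == 0

    def test_matches_two_mean_oracle(self, rng):
        rows = rng.uniform(0, 100, size=(10, 30))
        r = _rank_matrix(rows)
        g = ms.partition_samples(r, "G0", min_group=1)
        table = ms.delta_ars(r, g)
        hi = (g.labels == "high").to_numpy()
        for i in range(10):
            expected = rows[i, hi].mean() - rows[i, ~hi].mean()
            assert table.iloc[i]["delta"] == pytest.approx(expected)
            assert table.iloc[i]["delta"] == pytest.approx(table.iloc[i]["ars_high"] - table.iloc[i]["ars_low"])

    def test_antisymmetric_under_label_swap(self, rng):
        rows = rng.uniform(0, 100, size=(5, 20))
        r = _rank_matrix(rows)
        g = ms.partition_samples(r, "G0", min_group=1)
        swapped = ms.GroupAssignment(
            source_gene=g.source_gene,
            labels=g.labels.map({"high": "low", "low": "high"}),
            boundary=g.boundary,
            n_high=g.n_low,
            n_low=g.n_high,
        )
        np.testing.assert_allclose(ms.delta_ars(r, g)["delta"], -ms.delta_ars(r, swapped)["delta"])


class TestRankSumTest:
    def test_worked_example(self):
        # most extreme of the C(6,3)=20 assignments, two-sided tail 2/20
        assert ms.rank_sum_test([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert ms.rank_sum_test([1, 2], [1, 2]) == pytest.approx(1.0, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ms.rank_sum_test([], [1.0])

    def test_exact_p_matches_enumeration_all_small_sizes(self, rng):
        """Exact two-sided p equals full enumeration for tie-free n, m <= 8."""
        for n in range(1, 9):
            for m in range(1, 9):
                vals = rng.permutation(np.arange(1.0, n + m + 1))  # distinct -> tie-free
                x, y = vals[:n], vals[n:]
                assert ms.rank_sum_test(x, y) == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_exact_matches_enumeration_random_5v5(self, rng):
        for _ in range(100):
            vals = rng.normal(size=10)
            assert ms.rank_sum_test(vals[:5], vals[5:]) == pytest.approx(
                wilcoxon_enumeration_oracle(vals[:5], vals[5:]), abs=1e-12
            )


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(ms.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ms.adjust_bh([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.adjust_bh([0.5, 1.5])

    def test_matches_formula_oracle_and_properties(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            adj = ms.adjust_bh(p)
            np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw-p order


class TestVirtualSort:
    def test_planted_partner_and_source_row(self, default_screen):
        table = default_screen.sorting
        truth = default_screen.truth
        partners = truth.hub_me_partners
        # planted partners sit in the far-negative delta tail with tiny p
        assert table.loc[partners, "delta"].max() <= -15
        assert table.loc[partners, "p_adj"].max() <= 0.01
        src = table.loc[truth.hub_gene]
        assert src["delta"] > 0
        assert src["p_adj"] <= 0.01
        # table is sorted by delta descending and delta = high - low exactly
        assert np.all(np.diff(table["delta"].to_numpy()) <= 1e-12)
        np.testing.assert_allclose(table["delta"], table["ars_high"] - table["ars_low"])
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-12)

    def test_pure_noise_bh_control(self, rng):
        """On matrices of exchangeable noise genes, BH keeps the fraction of
        p_adj <= 0.01 calls near zero."""
        n_sig = 0
        n_genes = 150
        for rep in range(20):
            vals = rng.lognormal(1, 1, size=(n_genes, 60))
            # source silent in half the samples, top-ranked in the rest:
            # a clean rank-space bimodality for the partition
            source = np.concatenate([np.zeros(30), rng.uniform(500, 1000, 30)])
            rows = np.vstack([source, vals])
            df = pd.DataFrame(rows, index=[f"G{i}" for i in range(n_genes + 1)], columns=[f"S{j}" for j in range(60)])
            r = ms.compute_rank_matrix(ms.ExpressionMatrix(df))
            table = ms.virtual_sort(r, "G0")
            n_sig += int((table.drop(index="G0")["p_adj"] <= 0.01).sum())
        assert n_sig / (20 * n_genes) < 0.01

    def test_invariant_under_sample_permutation(self, rng):
        vals = rng.lognormal(1, 1, size=(40, 50))
        vals[rng.random(vals.shape) < 0.3] = 0
        cols = [f"S{j}" for j in range(50)]
        df = pd.DataFrame(vals, index=[f"G{i}" for i in range(40)], columns=cols)
        r1 = ms.compute_rank_matrix(ms.ExpressionMatrix(df))
        perm = rng.permutation(50)
        df2 = df.iloc[:, perm]
        r2 = ms.compute_rank_matrix(ms.ExpressionMatrix(df2))
        try:
            t1 = ms.virtual_sort(r1, "G0", min_group=1)
            t2 = ms.virtual_sort(r2, "G0", min_group=1)
        except ms.ZeroPlasticityError:
            pytest.skip("degenerate random draw")
        np.testing.assert_allclose(t1["delta"], t2["delta"])
        np.testing.assert_allclose(t1["p_adj"], t2["p_adj"])

    def test_volcano_table_columns(self, default_screen):
        v = ms.volcano_table(default_screen.sorting)
        assert list(v.columns) == ["delta", "neg_log10_p_adj"]
        assert len(v) == len(default_screen.sorting)
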