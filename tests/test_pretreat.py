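"""Standardization, clustering of variables, homogeneity, summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import beeftradeoff as bt
from beeftradeoff.pretreat import (
    INDICATOR_LAYOUT,
    cluster_variables,
    homogeneity,
    standardize,
    summarize,
)


def _std(df):
    return standardize(pd.DataFrame(df))


class TestStandardize:
    def test_simple_column(self):
        out = _std({"x": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(out.values["x"], [-1.0, 0.0, 1.0])

    def test_zero_variance_errors_with_name(self):
        with pytest.raises(ValueError, match="const"):
            _std({"const": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(
            lambda xs: np.std(xs) > 1e-6
        )
    )
    def test_round_trip_property(self, xs):
        out = _std({"x": xs})
        np.testing.assert_allclose(out.back_transform()["x"], xs, rtol=1e-9, atol=1e-9)
        assert abs(out.values["x"].mean()) < 1e-10
        assert out.values["x"].std(ddof=1) == pytest.approx(1.0)

    def test_symmetric_column_scales_by_sd(self):
        c = 7.0
        col = np.array([c, -c, c, -c])
        out = _std({"x": col})
        np.testing.assert_allclose(out.values["x"], col / np.std(col, ddof=1))


def _planted(n, sizes, within=0.9, seed=0):
    """Variables in planted blocks with given within-block loading."""
    rng = np.random.default_rng(seed)
    cols, labels = {}, []
    lam = np.sqrt(within)
    v = 0
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n)
        for _ in range(size):
            cols[f"v{v}"] = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            labels.append(b)
            v += 1
    return pd.DataFrame(cols), labels


class TestClusterVariables:
    def test_perfect_two_block_recovery(self):
        df, labels = _planted(40, [3, 3], within=1.0 - 1e-12, seed=1)
        sol = cluster_variables(standardize(df), 2)
        found = [sol.membership[c] for c in df.columns]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_all_singletons_is_degenerate_partition(self):
        df, _ = _planted(30, [2, 2, 2], seed=2)
        sol = cluster_variables(standardize(df), 6)
        assert sol.k == 6
        assert sol.homogeneity_pct == pytest.approx(100.0)

    def test_k_out_of_range(self):
        df, _ = _planted(30, [2, 2], seed=3)
        with pytest.raises(ValueError):
            cluster_variables(standardize(df), 5)

    def test_matches_exhaustive_partition_search(self):
        """Hierarchical solution equals the brute-force homogeneity maximizer."""
        df, labels = _planted(50, [2, 2, 2], within=0.8, seed=4)
        std = standardize(df)
        R = np.corrcoef(std.values.to_numpy(), rowvar=False)

        def total_h(partition):
            return sum(
                np.linalg.eigvalsh(R[np.ix_(list(b), list(b))])[-1] for b in partition
            )

        # all partitions of 6 items into exactly 3 nonempty blocks
        def partitions_k(items, k):
            if len(items) == k:
                yield [[i] for i in items]
                return
            if k == 1:
                yield [list(items)]
                return
            first, rest = items[0], items[1:]
            for p in partitions_k(rest, k - 1):
                yield [[first]] + p
            for p in partitions_k(rest, k):
                for i in range(len(p)):
                    yield p[:i] + [[first] + p[i]] + p[i + 1:]

        all_parts = list(partitions_k(list(range(6)), 3))
        assert len(all_parts) == 90
        best = max(all_parts, key=total_h)
        sol = cluster_variables(std, 3)
        found = {}
        for j, c in enumerate(df.columns):
            found.setdefault(sol.membership[c], set()).add(j)
        assert {frozenset(b) for b in best} == {frozenset(s) for s in found.values()}
        assert adjusted_rand_score(labels, [sol.membership[c] for c in df.columns]) == 1.0
        assert sol.homogeneity_pct == pytest.approx(100.0 * total_h(best) / 6)

    def test_homogeneity_nonincreasing_in_merges(self):
        df, _ = _planted(40, [3, 3, 2], within=0.7, seed=5)
        std = standardize(df)
        h = [cluster_variables(std, k).homogeneity_pct for k in range(1, 9)]
        assert all(h[i] <= h[i + 1] + 1e-9 for i in range(len(h) - 1))

    def test_sign_convention_positive_on_top_member(self):
        df, _ = _planted(40, [4], within=0.8, seed=6)
        sol = cluster_variables(standardize(df), 1)
        top = sol.loadings.abs().idxmax()
        assert sol.loadings[top] > 0


class TestHomogeneity:
    def test_perfectly_correlated_pair_is_100(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        sol = cluster_variables(standardize(df), 1)
        assert homogeneity(sol, 2) == pytest.approx(100.0)

    def test_uncorrelated_pair_is_50(self):
        # orthogonalize exactly so lambda_1 = 1
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        y = y - x * np.dot(x - x.mean(), y - y.mean()) / np.dot(x - x.mean(), x - x.mean())
        sol = cluster_variables(standardize(pd.DataFrame({"a": x, "b": y})), 1)
        assert homogeneity(sol, 2) == pytest.approx(50.0, abs=1e-6)

    def test_two_blocks_at_r_08_gives_90(self):
        # analytic: each 2x2 block with r=0.8 has leading eigenvalue 1.8
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.8
        R[2, 3] = R[3, 2] = 0.8
        eig = np.linalg.eigvalsh(R[:2, :2])[-1]
        assert 100 * (2 * eig) / 4 == pytest.approx(90.0)


class TestSummarize:
    def test_singleton_latent_equals_variable_up_to_sign(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.standard_normal(25), "b": rng.standard_normal(25)})
        std = standardize(df)
        sol = cluster_variables(std, 2)
        out = summarize(sol, {sol.cluster_of("a"): ("latent", "ind")})
        r = np.corrcoef(out["ind"], std.values["a"])[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_representatives_split_a_cluster(self):
        """A carcass-weight-style cluster keeps two members and drops the rest."""
        rng = np.random.default_rng(4)
        f = rng.standard_normal(40)
        df = pd.DataFrame(
            {
                "carcass_weight": f + 0.1 * rng.standard_normal(40),
                "bone_proportion": -f + 0.1 * rng.standard_normal(40),
                "ph": f + 0.4 * rng.standard_normal(40),
            }
        )
        std = standardize(df)
        sol = cluster_variables(std, 1)
        out = summarize(
            sol, {0: ("representative", [("carcass_weight", "carcass weight"), ("ph", "pH")])}
        )
        assert list(out.columns) == ["carcass weight", "pH"]
        np.testing.assert_allclose(out["pH"], std.values["ph"])

    def test_representative_must_be_member(self):
        df, _ = _planted(30, [2, 2], seed=7)
        std = standardize(df)
        sol = cluster_variables(std, 2)
        other = [c for c in df.columns if sol.membership[c] != 0][0]
        with pytest.raises(ValueError):
            summarize(sol, {0: ("representative", [(other, "x")])})

    def test_rank_one_block_latent_correlates_unity(self):
        df, _ = _planted(30, [2], within=1.0 - 1e-12, seed=8)
        std = standardize(df)
        sol = cluster_variables(std, 1)
        out = summarize(sol, {0: ("latent", "z")})
        for c in df.columns:
            assert abs(np.corrcoef(out["z"], std.values[c])[0, 1]) == pytest.approx(1.0)


class TestPretreatHerd:
    def test_24_indicator_layout(self, indicators):
        assert indicators.values.shape[1] == 24
        counts = {g: len(indicators.group_indicators(g)) for g in ("AP", "CP", "NQ", "OQ")}
        assert counts == {"AP": 3, "CP": 7, "NQ": 7, "OQ": 7}

    def test_columns_restandardized(self, indicators):
        assert np.allclose(indicators.values.mean(), 0.0, atol=1e-10)
        assert np.allclose(indicators.values.std(ddof=1), 1.0, atol=1e-10)

    def test_planted_blocks_recovered_over_seeds(self):
        """Clustering recovers the planted blocks: ensemble mean adjusted Rand
        >= 0.9 over 20 seeds across the CP/NQ/OQ clusterings (generated
        variables; derived colour columns carry no generative block label)."""
        scores = {"CP": [], "NQ": [], "OQ": []}
        for seed in range(20):
            cfg = bt.default_config(seed=seed)
            herd = bt.generate_herd(cfg)
            std = standardize(herd)
            for group, k in (("CP", 6), ("NQ", 6), ("OQ", 5)):
                exclude = INDICATOR_LAYOUT[group]["exclude"]
                cols = [c for c in herd.group_columns(group) if c not in exclude]
                sol = cluster_variables(std.subset(cols), k)
                planted = {
                    v.name: b.name
                    for b in cfg.blocks if b.group == group
                    for v in b.variables if v.derived is None
                }
                ev = [c for c in cols if c in planted]
                scores[group].append(
                    adjusted_rand_score(
                        [planted[c] for c in ev], [sol.membership[c] for c in ev]
                    )
                )
        means = {g: np.mean(v) for g, v in scores.items()}
        overall = np.mean([s for v in scores.values() for s in v])
        assert overall >= 0.9, f"ensemble mean ARI {overall:.3f} ({means})"
        for group, m in means.items():
            assert m >= 0.85, f"{group}: mean ARI {m:.3f}"
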