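"""Group tests, window regression, correlation bands and the network."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytocyto.network import (
    band_classify,
    build_network,
    compare_groups,
    fit_window_regression,
    pairwise_correlations,
    significance_screen,
    write_graphml,
)
from phytocyto.synthetic import TraitSimSpec, gen_trait_table


def enumeration_oracle_p(a, b):
    """Independent exact two-sided Mann-Whitney P: enumerate every
    assignment of the pooled values to groups and compute U by direct
    pair counting (ties count half)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    mu = n1 * (len(pooled) - n1) / 2.0
    d_obs = abs(u_of(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(ga, gb) - mu) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestCompareGroups:
    def test_identical_groups_null(self):
        with pytest.warns(UserWarning):
            res = compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_t == 1.0 and res.p_u == 1.0
        assert res.u_stat == 4.5  # null mean n1*n2/2

    def test_textbook_separation(self):
        """{1,2,3} vs {4,5,6}: U=0 and exact two-sided P = 0.1
        (2 of 20 assignments as extreme)."""
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.u_stat == 0.0
        assert res.p_u == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n1, n2 = rng.integers(2, 5, 2)
            a = rng.integers(0, 4, n1).astype(float)
            b = rng.integers(0, 4, n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            res = compare_groups(a, b)
            assert res.p_u == pytest.approx(enumeration_oracle_p(a, b), abs=1e-12)

    def test_large_sample_power(self):
        """Shifted normals (3 SD, n=10/10): rejection rate at 0.05
        well above 0.95 over 200 seeds."""
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 1, 10)
            b = rng.normal(3, 1, 10)
            if compare_groups(a, b).p_u <= 0.05:
                rejections += 1
        assert rejections / 200 >= 0.95

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestWindowRegression:
    @staticmethod
    def _table(values_by_day, group="control"):
        rows = [dict(group=group, timepoint_d=d, y=v)
                for d, vals in values_by_day.items() for v in vals]
        return pd.DataFrame(rows)

    def test_perfect_linear_r2(self):
        table = self._table({4: [8.0], 5: [10.0], 6: [12.0], 7: [14.0]})
        res = fit_window_regression(table, "y")
        assert res.r_squared["control"] == pytest.approx(1.0)
        assert res.coefficients["control"][0] == pytest.approx(2.0)

    def test_constant_data_r2_zero(self):
        table = self._table({4: [3.0], 5: [3.0], 6: [3.0], 7: [3.0]})
        assert fit_window_regression(table, "y").r_squared["control"] == 0.0

    def test_insufficient_points_rejected(self):
        table = self._table({4: [1.0], 5: [2.0]})
        with pytest.raises(ValueError, match="need >= 3"):
            fit_window_regression(table, "y")

    def test_slope_recovery_monte_carlo(self):
        """Planted slope 1.5 + noise: mean fitted slope over 100 seeds
        within 2 SE of the planted value."""
        slopes = []
        for s in range(100):
            rng = np.random.default_rng(s)
            days = np.repeat([4.0, 5.0, 6.0, 7.0], 3)
            y = 1.5 * days + rng.normal(0, 1.0, days.size)
            table = pd.DataFrame(dict(group="control", timepoint_d=days, y=y))
            slopes.append(fit_window_regression(table, "y").coefficients["control"][0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.5) <= 2 * se + 1e-9

    def test_two_groups_compared(self):
        rows = []
        for d in (4, 5, 6, 7):
            rows += [dict(group="control", timepoint_d=d, y=d + 0.0)]
            rows += [dict(group="kinetin", timepoint_d=d, y=d + 10.0)]
        res = fit_window_regression(pd.DataFrame(rows), "y")
        assert res.p_u is not None and res.p_u < 0.05


class TestPairwiseCorrelations:
    def test_self_correlation_unity(self):
        df = pd.DataFrame(dict(a=[1.0, 2, 3, 4], b=[2.0, 1, 4, 3]))
        r = pairwise_correlations(df)
        assert r.loc["a", "a"] == 1.0

    def test_exact_anticorrelation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = pairwise_correlations(pd.DataFrame(dict(a=x, b=-x)))
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_missing(self):
        df = pd.DataFrame(dict(a=[1.0, 2, 3, 4], b=[5.0, 5, 5, 5]))
        assert np.isnan(pairwise_correlations(df).loc["a", "b"])

    def test_planted_block_recovered(self):
        """Planted r=0.9 at n=50: sample r within 0.9 +/- 0.1 in at
        least 95% of 200 seeds."""
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        hits = 0
        for s in range(200):
            table, _ = gen_trait_table(
                TraitSimSpec(traits=("a", "b"), n_samples=25, corr=corr, seed=s))
            r = pairwise_correlations(table, ["a", "b"]).loc["a", "b"]
            hits += abs(r - 0.9) <= 0.1
        assert hits / 200 >= 0.95

    def test_band_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        r1 = pairwise_correlations(df)
        df2 = df.copy()
        df2["a"] = 3.5 * df2["a"] - 100.0
        r2 = pairwise_correlations(df2)
        for x, y in itertools.combinations("abc", 2):
            assert band_classify(r1.loc[x, y]) == band_classify(r2.loc[x, y])


class TestBandClassify:
    @pytest.mark.parametrize("r, band", [
        (0.2, "none"), (-0.5, "moderate"), (0.85, "strong"),
        (0.3, "moderate"), (0.8, "moderate"), (-0.8, "moderate"),
        (0.299999, "none"), (0.800001, "strong"), (1.0, "strong"),
    ])
    def test_band_boundaries(self, r, band):
        assert band_classify(r) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            band_classify(1.2)


class TestBuildNetwork:
    def test_identity_matrix_no_edges(self):
        traits = ["a", "b", "c"]
        r = pd.DataFrame(np.eye(3), index=traits, columns=traits)
        g = build_network(r, {t: True for t in traits})
        assert sorted(g.nodes()) == traits and g.number_of_edges() == 0

    def test_single_trait_single_node(self):
        r = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        g = build_network(r, {"a": True})
        assert list(g.nodes()) == ["a"] and g.number_of_edges() == 0

    def test_no_significant_traits_warns(self):
        r = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.warns(UserWarning, match="significance"):
            g = build_network(r, {"a": False, "b": False})
        assert g.number_of_nodes() == 0

    def test_edge_attributes(self):
        traits = ["a", "b"]
        r = pd.DataFrame([[1.0, -0.6], [-0.6, 1.0]], index=traits, columns=traits)
        g = build_network(r, {t: True for t in traits})
        edge = g.get_edge_data("a", "b")
        assert edge == dict(r=-0.6, sign="negative", band="moderate")

    def test_graphml_deterministic(self, tmp_path):
        spec = TraitSimSpec(n_samples=24, seed=3,
                            effects={t: 1.0 for t in TraitSimSpec().traits})
        table, _ = gen_trait_table(spec)
        traits = list(spec.traits)
        paths = []
        for i in (1, 2):
            r = pairwise_correlations(table, traits)
            screen = significance_screen(table, traits)
            g = build_network(r, screen)
            p = tmp_path / f"net{i}.graphml"
            write_graphml(g, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        nx.read_graphml(paths[0])  # well-formed
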