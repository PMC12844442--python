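import numpy as np
import pytest
from scipy import stats

from microscale import (
    OtuTable,
    build_nar,
    build_network,
    fit_nar_breakpoint,
    nar_guild_fixture,
    network_properties,
    spearman_matrix,
)
from microscale.network import CorrelationMatrix, NarCurve

import pandas as pd


def table_from_columns(cols: dict[str, list]) -> OtuTable:
    names = list(cols)
    counts = np.array([cols[c] for c in names]).T
    return OtuTable(counts, [f"s{i}" for i in range(counts.shape[0])], names)


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        t = table_from_columns({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        c = spearman_matrix(t)
        assert np.allclose(np.diag(c.r), 1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = table_from_columns({"a": [1, 2, 3, 4, 5, 6], "b": [6, 5, 4, 3, 2, 1]})
        c = spearman_matrix(t)
        assert c.r[0, 1] == pytest.approx(-1.0)
        assert c.p[0, 1] == 0.0

    def test_textbook_rank_formula(self):
        # d = (0, 1, 1, 1, 1): r = 1 - 6*4 / (5*24) = 0.8
        t = table_from_columns({"x": [1, 2, 3, 4, 5], "y": [1, 3, 2, 5, 4]})
        c = spearman_matrix(t)
        assert c.r[0, 1] == pytest.approx(0.8)

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 5, size=(15, 20))
            counts[:, 0] += 1
            t = OtuTable(counts, [f"s{i}" for i in range(15)], [f"t{j}" for j in range(20)])
            c = spearman_matrix(t)
            ranks = stats.rankdata(counts, axis=0)
            oracle = np.corrcoef(ranks, rowvar=False)
            const = counts.std(axis=0) == 0
            oracle[const, :] = 0.0
            oracle[:, const] = 0.0
            np.fill_diagonal(oracle, 1.0)
            assert np.allclose(c.r, oracle, atol=1e-10)
            # p-values agree with the library implementation
            sp_r, sp_p = stats.spearmanr(counts)
            mask = ~(const[:, None] | const[None, :])
            np.fill_diagonal(mask, False)
            assert np.allclose(c.p[mask], sp_p[mask], atol=1e-10)

    def test_constant_taxon_flagged(self):
        t = table_from_columns({"flat": [3, 3, 3, 3, 3], "var": [1, 2, 3, 4, 5]})
        c = spearman_matrix(t)
        assert c.constant_taxa == ["flat"]
        assert c.r[0, 1] == 0.0 and c.p[0, 1] == 1.0

    def test_too_few_samples_rejected(self):
        t = table_from_columns({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError):
            spearman_matrix(t)


def _corr(r01: float, p01: float) -> CorrelationMatrix:
    r = np.array([[1.0, r01, 0.1], [r01, 1.0, 0.2], [0.1, 0.2, 1.0]])
    p = np.array([[0.0, p01, 0.9], [p01, 0.0, 0.8], [0.9, 0.8, 0.0]])
    return CorrelationMatrix(["t1", "t2", "t3"], r, p, n_samples=20)


class TestBuildNetwork:
    def test_all_weak_correlations_give_empty_network(self):
        net = build_network(_corr(0.5, 0.001))
        assert network_properties(net).n_nodes == 0

    def test_threshold_logic(self):
        net = build_network(_corr(0.95, 1e-5))
        assert sorted(net.nodes) == ["t1", "t2"]
        assert len(net.edges) == 1

    def test_raising_r_threshold_never_adds_edges(self, rng):
        counts = rng.integers(0, 20, size=(12, 15))
        t = OtuTable(counts, [f"s{i}" for i in range(12)], [f"t{j}" for j in range(15)])
        c = spearman_matrix(t)
        prev = None
        for r_thresh in (0.2, 0.4, 0.6, 0.8):
            edges = {frozenset(e) for e in build_network(c, r_thresh=r_thresh).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_bh_correction_is_conservative(self, rng):
        counts = rng.integers(0, 20, size=(10, 12))
        t = OtuTable(counts, [f"s{i}" for i in range(10)], [f"t{j}" for j in range(12)])
        c = spearman_matrix(t)
        raw = build_network(c, r_thresh=0.5, correction="none")
        bh = build_network(c, r_thresh=0.5, correction="bh")
        assert len(bh.edges) <= len(raw.edges)


class TestNetworkProperties:
    def test_empty_network_all_zero(self):
        net = build_network(_corr(0.1, 0.9))
        s = network_properties(net)
        assert (s.n_nodes, s.n_edges, s.pos_fraction, s.mean_degree, s.density, s.n_components) == (0, 0, 0, 0, 0, 0)

    def test_triangle(self):
        r = np.ones((3, 3)) * 0.9
        np.fill_diagonal(r, 1.0)
        p = np.zeros((3, 3))
        net = build_network(CorrelationMatrix(["a", "b", "c"], r, p, 10))
        s = network_properties(net)
        assert s.n_nodes == 3 and s.n_edges == 3
        assert s.mean_degree == pytest.approx(2.0)
        assert s.pos_fraction == 1.0
        assert s.n_components == 1

    def test_two_disjoint_edges_give_two_components(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[2, 3] = r[3, 2] = -0.9
        p = np.where(np.abs(r) > 0.5, 0.0, 1.0)
        np.fill_diagonal(p, 0.0)
        net = build_network(CorrelationMatrix(list("abcd"), r, p, 10))
        s = network_properties(net)
        assert s.n_components == 2
        assert s.pos_fraction == pytest.approx(0.5)


class TestBuildNar:
    def test_guild_fixture_rises_then_falls(self):
        table, frame = nar_guild_fixture(collapse_level=7, seed=11)
        curve = build_nar(table, frame)["G1"]
        nodes = curve.points["n_nodes"].to_numpy()
        peak = nodes.argmax()
        assert 1 < peak < len(nodes) - 1
        assert nodes[-1] < nodes[peak] * 0.6
        assert (curve.points["n_nodes"] <= curve.points["n_taxa_filtered"]).all()

    def test_collapsed_fixture_declines(self):
        table, frame = nar_guild_fixture(collapse_level=0, seed=11)
        curve = build_nar(table, frame)["G1"]
        nodes = curve.points["n_nodes"].to_numpy()
        assert nodes[0] == nodes.max()
        assert nodes[-1] <= 2

    def test_min_samples_gate(self):
        table, frame = nar_guild_fixture(collapse_level=7, seed=11)
        with pytest.raises(ValueError, match="min_samples"):
            build_nar(table, frame, min_samples=1000)


class TestFitNarBreakpoint:
    def _curve(self, nodes, levels=None):
        levels = levels if levels is not None else list(range(len(nodes)))
        areas = [(0.5 * 2**k) ** 2 for k in levels]
        return NarCurve(pd.DataFrame({"level": levels, "area": areas, "n_nodes": nodes}))

    def test_strictly_decreasing_is_monotonic(self):
        bp = fit_nar_breakpoint(self._curve([50, 40, 30, 20, 10, 5]))
        assert bp.shape == "monotonic-decreasing"
        assert bp.break_level is None

    def test_exact_piecewise_recovery(self):
        # apex at level 7 of 0..9, exact two-piece linear in log10(area)
        levels = list(range(10))
        x = np.log10([(0.5 * 2**k) ** 2 for k in levels])
        y = 10 + 5 * x - 12 * np.maximum(0, x - x[7])
        bp = fit_nar_breakpoint(self._curve(list(y), levels))
        assert bp.shape == "unimodal"
        assert bp.break_level == 7
        assert bp.slope_before == pytest.approx(5.0, abs=1e-8)
        assert bp.slope_after == pytest.approx(-7.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_nar_breakpoint(self._curve([1, 2, 3, 4]))
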