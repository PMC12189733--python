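import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from effbias import (
    PathwayGraph,
    ValidationError,
    cepa_ora,
    compute_centrality,
    map_selection,
    ora_hypergeometric,
    records_to_frame,
)
from effbias.io import MappingTable


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P(overlap >= k) by counting every size-n selection of the universe."""
    universe = range(N)
    members = set(range(K))
    hits = total = 0
    for sel in itertools.combinations(universe, n):
        total += 1
        hits += len(members & set(sel)) >= k
    return Fraction(hits, total)


class TestOra:
    def test_worked_example_66_over_252(self):
        universe = set(range(10))
        members = set(range(4))
        selected = {0, 1, 2, 4, 5}  # overlap 3
        rec = ora_hypergeometric(selected, members, universe)
        assert rec.overlap == 3
        assert rec.p == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        rec = ora_hypergeometric({4, 5}, {0, 1}, set(range(6)))
        assert rec.overlap == 0
        assert rec.p == 1.0

    def test_set_equal_to_universe_gives_p_one(self):
        universe = set(range(5))
        rec = ora_hypergeometric({0, 1}, universe, universe)
        assert rec.p == 1.0

    def test_empty_universe_and_selection_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            ora_hypergeometric({1}, {1}, set())
        with pytest.raises(ValidationError, match="selection"):
            ora_hypergeometric(set(), {1}, {1, 2})

    @pytest.mark.parametrize("N", [4, 6, 8])
    def test_matches_enumeration_oracle_small_universes(self, N):
        universe = set(range(N))
        for K in range(1, N + 1):
            members = set(range(K))
            for n in range(1, N + 1):
                for k in range(max(0, n - (N - K)), min(n, K) + 1):
                    selected = set(range(k)) | set(range(K, K + n - k))
                    rec = ora_hypergeometric(selected, members, universe)
                    assert rec.overlap == k
                    expected = float(hypergeom_tail_by_enumeration(N, K, n, k))
                    assert rec.p == pytest.approx(expected, abs=1e-12)


def betweenness_oracle(g):
    """Brute-force unnormalized betweenness via min-plus distances and
    shortest-path counting, independent of networkx's implementation."""
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    INF = np.inf
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0)
    for u, v in g.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1
    for mid in range(n):  # Floyd–Warshall
        d = np.minimum(d, d[:, [mid]] + d[[mid], :])
    # sigma[s][t]: number of shortest s-t paths, by DP over path length
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            sigma[s, t] = sum(
                sigma[s, idx[w]]
                for w in g.neighbors(nodes[t])
                if d[s, idx[w]] == d[s, t] - 1
            )
    bc = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t) or not np.isfinite(d[s, v]) or not np.isfinite(d[v, t]):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


class TestCentrality:
    def test_path_graph_betweenness_closed_form(self):
        g = nx.path_graph(["A", "B", "C"])
        w = compute_centrality(PathwayGraph("p", g), "betweenness")
        assert w == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_degree(self):
        g = nx.star_graph(["H", "a", "b", "c"])
        w = compute_centrality(PathwayGraph("p", g), "degree")
        assert w["H"] == 3.0 and w["a"] == w["b"] == w["c"] == 1.0

    def test_equal_weights_all_one_even_isolated(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        w = compute_centrality(PathwayGraph("p", g), "equal")
        assert set(w.values()) == {1.0}

    def test_isolated_node_zero_for_degree_and_betweenness(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        assert compute_centrality(PathwayGraph("p", g), "degree")["Z"] == 0.0
        assert compute_centrality(PathwayGraph("p", g), "betweenness")["Z"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_betweenness_matches_brute_force(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        w = compute_centrality(PathwayGraph("p", g), "betweenness")
        oracle = betweenness_oracle(g)
        for v in g.nodes:
            assert w[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="kind"):
            compute_centrality(PathwayGraph("p", nx.path_graph(3)), "pagerank")


class TestCepa:
    def _pathway(self, genes):
        g = nx.path_graph(genes)
        return PathwayGraph("pw", g)

    def test_disjoint_selection_gives_p_one(self):
        pg = self._pathway(["a", "b", "c"])
        universe = {"a", "b", "c", "x", "y", "z"}
        rec = cepa_ora(pg, {"x", "y"}, universe, n_perm=200, seed=0)
        assert rec.score == 0.0 and rec.p == 1.0

    def test_selection_equal_to_universe_gives_p_one(self):
        pg = self._pathway(["a", "b"])
        universe = {"a", "b", "c"}
        rec = cepa_ora(pg, universe, universe, n_perm=200, seed=0)
        assert rec.p == 1.0

    def test_deterministic_under_seed(self):
        pg = self._pathway([f"g{i}" for i in range(4)])
        universe = {f"g{i}" for i in range(10)}
        r1 = cepa_ora(pg, {"g0", "g1", "g9"}, universe, n_perm=500, seed=3)
        r2 = cepa_ora(pg, {"g0", "g1", "g9"}, universe, n_perm=500, seed=3)
        assert r1.p == r2.p and r1.score == r2.score

    def test_equal_weights_approximates_hypergeometric_tail(self):
        pg = self._pathway([f"g{i}" for i in range(4)])
        universe = {f"g{i}" for i in range(8)}
        diff = {"g0", "g1", "g7"}  # overlap 2 of 3
        exact = float(hypergeom_tail_by_enumeration(8, 4, 3, 2))
        rec = cepa_ora(pg, diff, universe, n_perm=20_000, seed=1)
        assert rec.p == pytest.approx(exact, abs=0.015)

    def test_oversized_selection_rejected(self):
        pg = self._pathway(["a", "b"])
        with pytest.raises(ValidationError, match="larger"):
            cepa_ora(pg, {"a", "b", "c"}, {"a", "b"}, n_perm=200)

    def test_too_few_permutations_rejected(self):
        pg = self._pathway(["a", "b"])
        with pytest.raises(ValidationError, match="n_perm"):
            cepa_ora(pg, {"a"}, {"a", "b"}, n_perm=10)

    def test_degree_weighting_changes_score_not_validity(self):
        pg = self._pathway(["a", "b", "c"])  # degrees 1, 2, 1
        universe = {"a", "b", "c", "x", "y"}
        rec = cepa_ora(pg, {"b"}, universe, n_perm=500, seed=0, centrality="degree")
        assert rec.score == 2.0
        assert 0 < rec.p <= 1


class TestMapSelection:
    def _verdicts(self):
        return pd.DataFrame(
            {"class": ["efficacy", "efficacy", "bias_up", "bias_down", "unclassified"]},
            index=pd.Index(["M1", "M2", "M3", "M4", "M5"], name="metabolite"),
        )

    def test_union_without_duplicates(self):
        mapping = MappingTable(pairs={"M1": {"G1", "G2"}, "M2": {"G2", "G3"}})
        genes, unmapped = map_selection(self._verdicts(), mapping, "efficacy")
        assert genes == {"G1", "G2", "G3"}
        assert unmapped == []

    def test_bias_pools_both_directions(self):
        mapping = MappingTable(pairs={"M3": {"Gu"}, "M4": {"Gd"}})
        genes, _ = map_selection(self._verdicts(), mapping, "bias")
        assert genes == {"Gu", "Gd"}

    def test_empty_class_warns_and_returns_empty(self):
        verdicts = pd.DataFrame({"class": ["unclassified"]}, index=pd.Index(["M1"]))
        with pytest.warns(UserWarning, match="no metabolites"):
            genes, _ = map_selection(verdicts, MappingTable(pairs={}), "efficacy")
        assert genes == set()

    def test_unmapped_metabolites_reported(self):
        mapping = MappingTable(pairs={"M1": {"G1"}})
        genes, unmapped = map_selection(self._verdicts(), mapping, "efficacy")
        assert genes == {"G1"}
        assert unmapped == ["M2"]


class TestRecordsFrame:
    def test_bh_adjustment_across_records(self):
        universe = set(range(20))
        recs = [
            ora_hypergeometric(set(range(5)), set(range(5)), universe, set_id="hit"),
            ora_hypergeometric(set(range(5)), set(range(15, 20)), universe, set_id="miss"),
        ]
        df = records_to_frame(recs)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()
        assert recs[0].p_adj is not None
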