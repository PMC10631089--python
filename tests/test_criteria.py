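"""SCIC, elbow, union-LLR criteria and optimal-MRCS selection."""

import math

import numpy as np
import pytest

from mnscan import (
    CaseTable,
    MergedClusterSet,
    elbow_select,
    llr_multinomial,
    merge_by_contiguity,
    report_at_mrcs,
    scan_once,
    scic,
    select_optimal_mrcs,
    union_llr,
)
from mnscan.criteria import DEFAULT_MRCS_GRID
from mnscan.geometry import Window
from mnscan.scan import ClusterReport


def make_report(regions, llr, n_cases, rank=1):
    w = Window(regions=tuple(regions), center=regions[0], size_frac=0.1)
    return ClusterReport(
        window=w, llr=llr, p_value=0.01, size_frac=0.1,
        n_cases=n_cases, rr=(1.0,), rank=rank,
    )


class TestScic:
    def test_empty_is_undefined(self):
        assert math.isnan(scic([], K=4, version=1))

    def test_single_cluster_substitution(self):
        c = make_report([0], llr=7.5, n_cases=100)
        assert scic([c], K=4, version=1) == pytest.approx(-15.0 + 4 * math.log(100))

    def test_two_cluster_version2(self):
        # independent evaluation: -2*(10+6) + 4*2*log(7) with 7 member regions
        c1 = make_report([0, 1, 2, 3], llr=10.0, n_cases=60)
        c2 = make_report([5, 6, 7], llr=6.0, n_cases=40, rank=2)
        assert scic([c1, c2], K=4, version=2) == pytest.approx(
            -32.0 + 8.0 * math.log(7), abs=1e-12
        )

    def test_penalty_monotone_in_argument(self):
        small = make_report([0], llr=5.0, n_cases=50)
        large = make_report([0], llr=5.0, n_cases=500)
        assert scic([small], K=4) < scic([large], K=4)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            scic([], K=1)
        with pytest.raises(ValueError):
            scic([], K=4, version=3)


class TestElbow:
    def test_collinear_returns_smallest(self):
        assert elbow_select([(1, 0.0), (2, -5.0), (3, -10.0)]) == 1

    def test_analytic_corner(self):
        assert elbow_select([(1, 0.0), (2, -10.0), (3, -10.0)]) == 2

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            elbow_select([(1, 0.0), (2, -1.0)])

    def test_plateau_onset_selected(self):
        # steep drop until m=8, flat afterwards: the knee is the onset
        pts = [(1, 0), (2, -30), (4, -60), (8, -90), (20, -92), (50, -95)]
        assert elbow_select(pts) == 8


class TestUnionLlr:
    def test_single_cluster_reduces_to_window_llr(self):
        rng = np.random.default_rng(1)
        ct = CaseTable(rng.integers(1, 10, size=(6, 4)))
        regs = (1, 2)
        merged = MergedClusterSet((frozenset(regs),))
        w = Window(regions=regs, center=1)
        assert union_llr(merged, ct) == pytest.approx(llr_multinomial(w, ct), abs=1e-10)

    def test_two_groups_against_direct_evaluation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 10, size=(8, 3))
        ct = CaseTable(counts)
        g1, g2 = frozenset({0, 1}), frozenset({4, 5, 6})
        got = union_llr(MergedClusterSet((g1, g2)), ct)
        # oracle: term-by-term evaluation of the heterogeneous-set display
        Ck, C = counts.sum(axis=0), counts.sum()
        expected = 0.0
        a_union = np.zeros(3)
        for g in (g1, g2):
            a = counts[sorted(g)].sum(axis=0)
            a_union += a
            for ak in a:
                if ak:
                    expected += ak * math.log(ak / a.sum())
        b = Ck - a_union
        B = C - a_union.sum()
        for bk in b:
            if bk:
                expected += bk * math.log(bk / B)
        for ck in Ck:
            expected -= ck * math.log(ck / C)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_contrast_is_zero(self):
        ct = CaseTable(np.full((6, 3), 4))
        merged = MergedClusterSet((frozenset({0}), frozenset({3, 4})))
        assert union_llr(merged, ct) == pytest.approx(0.0, abs=1e-12)

    def test_groups_covering_everything_rejected(self):
        ct = CaseTable(np.full((2, 2), 4))
        with pytest.raises(ValueError):
            union_llr(MergedClusterSet((frozenset({0, 1}),)), ct)


class TestMergeByContiguity:
    # path graph 0-1-2-3-4-5
    adj = frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)})

    def test_non_adjacent_stay_separate(self):
        clusters = [make_report([0], 1.0, 5), make_report([3], 1.0, 5, rank=2)]
        merged = merge_by_contiguity(clusters, self.adj)
        assert merged.n_groups == 2

    def test_chain_merges_transitively(self):
        clusters = [
            make_report([0], 1.0, 5),
            make_report([1], 1.0, 5, rank=2),
            make_report([2], 1.0, 5, rank=3),
        ]
        merged = merge_by_contiguity(clusters, self.adj)
        assert merged.n_groups == 1
        assert merged.groups[0] == frozenset({0, 1, 2})

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(9)
        n = 12
        adj = frozenset(
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.2
        )
        sets = []
        pool = list(range(n))
        rng.shuffle(pool)
        for chunk in np.array_split(pool, 4):
            if len(chunk):
                sets.append(sorted(int(c) for c in chunk))
        clusters = [make_report(s, 1.0, 5, rank=i + 1) for i, s in enumerate(sets)]
        merged = merge_by_contiguity(clusters, adj)
        # brute force: union-find over pairwise contact checks
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(sets)))
        neigh = {a: set() for a in range(n)}
        for a, b in adj:
            neigh[a].add(b)
            neigh[b].add(a)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                si, sj = set(sets[i]), set(sets[j])
                touch = bool(si & sj) or any(neigh[a] & sj for a in si)
                if touch:
                    g.add_edge(i, j)
        expected = {
            frozenset().union(*(frozenset(sets[i]) for i in comp))
            for comp in nx.connected_components(g)
        }
        assert set(merged.groups) == expected

    def test_missing_adjacency_instructive_error(self):
        with pytest.raises(ValueError, match="edge list"):
            merge_by_contiguity([make_report([0], 1.0, 5)], None)


class TestSelectOptimalMrcs:
    def _scan(self, counts, seed=0):
        ct = CaseTable(counts)
        total = ct.total
        wins = []
        n = counts.shape[0]
        for i in range(n):
            frac = counts[i].sum() / total
            if frac <= 0.5:
                wins.append(Window(regions=(i,), center=i, size_frac=frac))
        return ct, scan_once(ct, wins, replications=99, seed=seed)

    def test_default_grid_has_17_values(self):
        assert DEFAULT_MRCS_GRID == (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 35, 40, 45, 50)

    def test_none_when_nothing_significant(self):
        rng = np.random.default_rng(12)
        counts = rng.multinomial(20, [0.25] * 4, size=10)
        ct, res = self._scan(counts, seed=4)
        for method in ("scic1", "scic2", "mcsp"):
            sel, profile, final = select_optimal_mrcs(ct, res, method, alpha=1 / 200)
            if all(j == 0 for j in profile.j_m):
                assert sel is None and final == []

    def test_strong_singleton_selected_and_reported(self):
        counts = np.full((20, 4), 5)
        counts[3] = [100, 0, 0, 0]
        ct, res = self._scan(counts, seed=5)
        sel, profile, final = select_optimal_mrcs(ct, res, "scic1")
        assert sel is not None
        assert any(3 in c.window.regions for c in final)

    def test_mchsp_equals_mcsp_with_one_group(self):
        counts = np.full((20, 4), 5)
        counts[3] = [100, 0, 0, 0]
        ct, res = self._scan(counts, seed=6)
        # a complete adjacency graph forces W_m = 1 for any cluster set
        adj = frozenset((i, j) for i in range(20) for j in range(i + 1, 20))
        _, p_mcsp, _ = select_optimal_mrcs(ct, res, "mcsp")
        _, p_mchsp, _ = select_optimal_mrcs(ct, res, "mchsp", adjacency=adj)
        for v1, v2 in zip(p_mcsp.values, p_mchsp.values):
            if not (math.isnan(v1) or math.isnan(v2)):
                assert v1 == pytest.approx(v2, abs=1e-10)

    def test_category_relabel_invariance_of_selection(self):
        counts = np.full((20, 4), 5)
        counts[3] = [80, 5, 5, 10]
        ct, res = self._scan(counts, seed=7)
        sel1, _, _ = select_optimal_mrcs(ct, res, "scic1")
        perm = counts[:, [3, 1, 0, 2]]
        ct2, res2 = self._scan(perm, seed=7)
        sel2, _, _ = select_optimal_mrcs(ct2, res2, "scic1")
        assert sel1 == sel2

    def test_unknown_method_rejected(self):
        counts = np.full((6, 2), 5)
        ct, res = self._scan(counts, seed=8)
        with pytest.raises(ValueError):
            select_optimal_mrcs(ct, res, "gini")
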