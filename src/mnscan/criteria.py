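"""Criteria for choosing the maximum reported cluster size (MRCS).

The scan is run once at the maximum scanning window size (50% of cases) and
only the reporting bound ``m`` varies over a candidate grid.  For each ``m``
the significant non-overlapping clusters are collected and scored by one of:

* ``scic1`` / ``scic2`` — spatial cluster information criterion, a BIC-style
  penalized statistic ``-2 sum_j llr_j + K * J_m * log(penalty)`` where the
  penalty argument is the total cases (version 1) or total regions (version 2)
  inside the significant clusters; minimized.
* ``elbow`` — perpendicular distance of each ``(m, -sum llr)`` point from the
  chord joining the first and last grid points; maximized.
* ``mcsp`` — union log likelihood ratio treating all significant clusters as
  one homogeneous zone; maximized.
* ``mchsp`` — union log likelihood ratio after merging clusters into
  contiguity-connected heterogeneous zones; maximized.

Undefined values (no significant cluster at that ``m``) are excluded from the
arg-min/arg-max; ties are broken toward the smallest ``m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scan import CaseTable, ClusterReport, ScanResult, llr_from_inside, report_at_mrcs

__all__ = [
    "DEFAULT_MRCS_GRID",
    "METHODS",
    "MergedClusterSet",
    "CriterionProfile",
    "scic",
    "elbow_select",
    "union_llr",
    "merge_by_contiguity",
    "select_optimal_mrcs",
]

# the standard 17-value candidate grid, in percent of total cases
DEFAULT_MRCS_GRID: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 35, 40, 45, 50)

METHODS = ("scic1", "scic2", "elbow", "mcsp", "mchsp")


@dataclass(frozen=True)
class MergedClusterSet:
    """Significant clusters partitioned into contiguity-connected groups.

    Each group is the union of the member clusters' region sets; with a single
    group the set degenerates to the plain union used by the homogeneous
    (MCS-P) criterion.
    """

    groups: tuple[frozenset[int], ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("a merged cluster set needs at least one group")
        all_regions: set[int] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty merged group")
            if all_regions & g:
                raise ValueError("merged groups must be pairwise disjoint")
            all_regions |= g
        object.__setattr__(self, "groups", tuple(frozenset(g) for g in self.groups))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def union(self) -> frozenset[int]:
        return frozenset().union(*self.groups)


@dataclass
class CriterionProfile:
    """Per-grid-point bookkeeping for one selection method."""

    method: str
    grid: tuple[float, ...]
    j_m: tuple[int, ...]
    tau: tuple[int, ...]  # total cases inside significant clusters
    delta: tuple[int, ...]  # total regions inside significant clusters
    values: tuple[float, ...]  # criterion value, NaN when undefined
    selected_m: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "m": self.grid,
                "J_m": self.j_m,
                "tau": self.tau,
                "delta": self.delta,
                "value": self.values,
                "selected": [m == self.selected_m for m in self.grid],
            }
        )

    def plot(self, ax=None):
        """Criterion value against the candidate MRCS, optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.asarray(self.grid)
        values = np.asarray(self.values, dtype=float)
        ax.plot(grid, values, marker="o", label=self.method)
        if self.selected_m is not None:
            i = int(np.argmin(np.abs(grid - self.selected_m)))
            ax.axvline(self.selected_m, linestyle="--", color="grey")
            ax.plot([self.selected_m], [values[i]], marker="*", markersize=12)
        ax.set_xlabel("maximum reported cluster size (%)")
        ax.set_ylabel("criterion value")
        ax.set_title(f"{self.method}: selected MRCS = {self.selected_m}")
        return ax


def scic(clusters: Sequence[ClusterReport], K: int, version: int = 1) -> float:
    """Spatial cluster information criterion of a set of significant clusters.

    Returns ``-2 sum_j llr_j + K * J * log(arg)`` with ``arg`` the total cases
    inside the clusters (version 1) or the total number of member regions
    (version 2); NaN when there are no clusters.
    """
    if K < 2:
        raise ValueError("need at least 2 categories")
    if version not in (1, 2):
        raise ValueError("version must be 1 or 2")
    J = len(clusters)
    if J == 0:
        return math.nan
    llr_sum = sum(c.llr for c in clusters)
    if version == 1:
        arg = sum(c.n_cases for c in clusters)
    else:
        arg = sum(len(c.window) for c in clusters)
    if arg <= 0:
        raise ValueError("significant clusters with zero cases/regions")
    return -2.0 * llr_sum + K * J * math.log(arg)


def elbow_select(profile_points: Sequence[tuple[float, float]]) -> float:
    """The grid value maximizing orthogonal distance to the end-to-end chord.

    ``profile_points`` are ``(m, -sum llr)`` pairs ordered by ``m``.  Ties are
    broken toward the smallest ``m``; with all points collinear every distance
    is zero and the smallest ``m`` is returned.
    """
    pts = [(float(m), float(v)) for m, v in profile_points]
    if len(pts) < 3:
        raise ValueError("elbow selection needs at least 3 profile points")
    if any(pts[i][0] >= pts[i + 1][0] for i in range(len(pts) - 1)):
        raise ValueError("profile points must be strictly increasing in m")
    (x1, y1), (x2, y2) = pts[0], pts[-1]
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    best_m, best_d = pts[0][0], -1.0
    for x, y in pts:
        d = abs(dy * (x - x1) - dx * (y - y1)) / norm
        if d > best_d + 1e-12:
            best_d, best_m = d, x
    return best_m


def union_llr(union_sets: MergedClusterSet, cases: CaseTable) -> float:
    """Union log likelihood ratio of merged cluster groups.

    Each group ``w`` contributes its inside term ``sum_k a_kw log(a_kw/A_w)``;
    the outside term pools everything not in any group; the same null
    log-likelihood ``sum_k C_k log(C_k/C)`` as the single-window statistic is
    subtracted, so a single group holding exactly one cluster reproduces that
    cluster's ``log lambda_z``.
    """
    counts = cases.counts.astype(float)
    Ck = cases.category_totals.astype(float)
    C = float(cases.total)
    inside_total = 0.0
    a_union = np.zeros(cases.n_categories)
    ll = 0.0
    for g in union_sets.groups:
        regs = np.asarray(sorted(g))
        if regs.min() < 0 or regs.max() >= cases.n_regions:
            raise IndexError("merged group references regions outside the case table")
        a = counts[regs].sum(axis=0)
        A = a.sum()
        a_union += a
        inside_total += A
        if A > 0:
            pos = a > 0
            ll += float((a[pos] * np.log(a[pos] / A)).sum())
    B = C - inside_total
    if B <= 0:
        raise ValueError("merged groups cover all cases; no outside remains")
    b = Ck - a_union
    pos = b > 0
    ll += float((b[pos] * np.log(b[pos] / B)).sum())
    ll -= float((Ck[Ck > 0] * np.log(Ck[Ck > 0] / C)).sum())
    return ll


def merge_by_contiguity(
    clusters: Sequence[ClusterReport], adjacency: frozenset[tuple[int, int]]
) -> MergedClusterSet:
    """Partition clusters into groups connected under the adjacency relation.

    Two clusters fall in one group iff some region of one is adjacent to (or
    shared with) some region of the other, transitively closed — connected
    components of the cluster-level contact graph.
    """
    import networkx as nx

    if adjacency is None:
        raise ValueError(
            "contiguity merging needs region adjacency; supply an edge list "
            "or derive one (e.g. Delaunay triangulation of centroids)"
        )
    if not clusters:
        raise ValueError("no clusters to merge")
    neighbor = {}
    for a, b in adjacency:
        neighbor.setdefault(a, set()).add(b)
        neighbor.setdefault(b, set()).add(a)
    sets = [set(c.window.regions) for c in clusters]
    g = nx.Graph()
    g.add_nodes_from(range(len(sets)))
    for i in range(len(sets)):
        reach_i = sets[i] | set().union(*(neighbor.get(r, set()) for r in sets[i]))
        for j in range(i + 1, len(sets)):
            if reach_i & sets[j]:
                g.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(g):
        union: set[int] = set()
        for i in comp:
            union |= sets[i]
        groups.append(frozenset(union))
    groups.sort(key=lambda s: sorted(s))
    return MergedClusterSet(tuple(groups))


def _neg_lrt_point(result: ScanResult, clusters: Sequence[ClusterReport], m: float) -> float:
    """-LRT(m) for the elbow profile, with the no-significant-cluster fallback.

    With significant clusters the point is minus their summed log likelihood
    ratios; without, the maximum statistic among windows within the size bound
    stands in (zero if no window fits at all).
    """
    if clusters:
        return -sum(c.llr for c in clusters)
    sizes = np.array([w.size_frac for w in result.windows])
    within = sizes <= m / 100.0 + 1e-12
    if not within.any():
        return 0.0
    return -float(result.llr[within].max())


def select_optimal_mrcs(
    cases: CaseTable,
    scan: ScanResult,
    method: str,
    grid: Sequence[float] = DEFAULT_MRCS_GRID,
    alpha: float | None = None,
    adjacency: frozenset[tuple[int, int]] | None = None,
    reports_by_m: dict | None = None,
) -> tuple[float | None, CriterionProfile, list[ClusterReport]]:
    """Choose the optimal MRCS for one method over the candidate grid.

    Returns ``(selected_m, profile, reports_at_selected)``; ``selected_m`` is
    None when no grid value yields a significant cluster.  ``reports_by_m``
    can carry precomputed :func:`report_at_mrcs` output to share across
    methods.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    grid = tuple(sorted(float(m) for m in grid))
    if any(not (0 < m <= 50) for m in grid):
        raise ValueError("grid values must be in (0, 50]")
    if len(set(grid)) != len(grid):
        raise ValueError("grid values must be distinct")
    if alpha is None:
        alpha = scan.alpha
    K = cases.n_categories

    if reports_by_m is None:
        reports_by_m = {m: report_at_mrcs(scan, m, alpha) for m in grid}
    j_m, tau, delta, values = [], [], [], []
    for m in grid:
        clusters = reports_by_m[m]
        j_m.append(len(clusters))
        tau.append(sum(c.n_cases for c in clusters))
        delta.append(sum(len(c.window) for c in clusters))
        if method in ("scic1", "scic2"):
            values.append(scic(clusters, K, version=1 if method == "scic1" else 2))
        elif method == "elbow":
            values.append(_neg_lrt_point(scan, clusters, m))
        elif method == "mcsp":
            if clusters:
                union = frozenset().union(*(c.window.region_set for c in clusters))
                values.append(union_llr(MergedClusterSet((union,)), cases))
            else:
                values.append(math.nan)
        else:  # mchsp
            if clusters:
                merged = merge_by_contiguity(clusters, adjacency)
                values.append(union_llr(merged, cases))
            else:
                values.append(math.nan)

    if all(j == 0 for j in j_m):
        selected = None
    elif method == "elbow":
        selected = elbow_select(list(zip(grid, values)))
    else:
        defined = [(m, v) for m, v in zip(grid, values) if not math.isnan(v)]
        sign = 1.0 if method in ("scic1", "scic2") else -1.0
        best = min(sign * v for _, v in defined)
        selected = min(m for m, v in defined if abs(sign * v - best) <= 1e-9)

    profile = CriterionProfile(
        method=method,
        grid=grid,
        j_m=tuple(j_m),
        tau=tuple(tau),
        delta=tuple(delta),
        values=tuple(values),
        selected_m=selected,
    )
    final = reports_by_m[selected] if selected is not None else []
    return selected, profile, final
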