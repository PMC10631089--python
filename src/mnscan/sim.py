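"""Synthetic geographies, planted-cluster scenarios, and the evaluation study.

The generator emulates a district-level disease-subtype study: a lattice
geography stands in for an irregular administrative map, one or two contiguous
clusters are planted, and each dataset allocates a fixed number of cases to
regions and then to K categories — probability vector ``p0`` outside the
clusters, ``p1``/``p2`` inside.  Detection accuracy is scored region-wise by
sensitivity, positive predictive value, and misclassification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .criteria import DEFAULT_MRCS_GRID, METHODS, select_optimal_mrcs
from .geometry import (
    DEFAULT_ANGLES_PER_SHAPE,
    DEFAULT_SHAPES,
    RegionMap,
    enumerate_windows,
    scan_orderings,
)
from .scan import CaseTable, report_at_mrcs, scan_once

__all__ = [
    "Scenario",
    "PerformanceSummary",
    "make_grid_geography",
    "plant_true_clusters",
    "simulate_dataset",
    "performance_measures",
    "run_simulation_study",
    "table1_scenarios",
    "ALTERNATIVE_HYPOTHESES",
    "NULL_PROBS",
]

# the four-category null and the alternative category-probability settings
NULL_PROBS: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
ALTERNATIVE_HYPOTHESES: dict[int, tuple[float, ...]] = {
    1: (0.05, 0.15, 0.35, 0.45),
    2: (0.05, 0.25, 0.25, 0.45),
    3: (0.10, 0.10, 0.40, 0.40),
    4: (0.15, 0.15, 0.15, 0.55),
}
# heterogeneous two-cluster settings: (hypothesis for cluster 1, for cluster 2)
HETEROGENEOUS_PAIRS: dict[int, tuple[int, int]] = {5: (1, 2), 6: (1, 3), 7: (1, 4)}


def make_grid_geography(n_side: int, spacing: float = 1.0) -> RegionMap:
    """A square lattice of ``n_side**2`` regions with rook adjacency."""
    if n_side < 3:
        raise ValueError("lattice side must be at least 3")
    ids, coords, edges = [], [], set()
    for r in range(n_side):
        for c in range(n_side):
            ids.append(f"R{r * n_side + c}")
            coords.append((c * spacing, r * spacing))
    for r in range(n_side):
        for c in range(n_side):
            i = r * n_side + c
            if c + 1 < n_side:
                edges.add((i, i + 1))
            if r + 1 < n_side:
                edges.add((i, i + n_side))
    return RegionMap(tuple(ids), np.asarray(coords, dtype=float), adjacency=frozenset(edges))


def _is_connected(regions: set[int], adjacency: frozenset[tuple[int, int]]) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(regions)
    g.add_edges_from((a, b) for a, b in adjacency if a in regions and b in regions)
    return nx.is_connected(g)


def plant_true_clusters(
    region_map: RegionMap,
    shape: str = "circular",
    size_frac: float = 0.08,
    count: int = 1,
    rng=None,
    axis_ratio: float = 3.0,
) -> list[frozenset[int]]:
    """Plant ``count`` disjoint connected clusters covering ``size_frac`` each.

    The cluster size is ``size_frac`` of the regions rounded to the nearest
    integer (so 8% of 64 regions is a 5-region cluster).  Circular clusters
    take the nearest regions to a deterministic seed point under the Euclidean
    metric; elliptic clusters use an elongated metric with the given axis
    ratio; irregular clusters grow by a random contiguous walk and need an
    ``rng``.
    """
    if shape not in ("circular", "elliptic", "irregular"):
        raise ValueError("shape must be circular, elliptic, or irregular")
    if count not in (1, 2):
        raise ValueError("count must be 1 or 2")
    n = region_map.n_regions
    size = max(1, round(size_frac * n))
    if size * count > n // 2:
        raise ValueError("clusters would cover more than half the map")
    coords = region_map.coords
    lo, hi = coords.min(axis=0), coords.max(axis=0)

    def seed_region(fx: float, fy: float) -> int:
        target = lo + np.array([fx, fy]) * (hi - lo)
        return int(np.argmin(((coords - target) ** 2).sum(axis=1)))

    anchors = [(0.3, 0.3)] if count == 1 else [(0.2, 0.2), (0.8, 0.8)]
    clusters: list[frozenset[int]] = []
    taken: set[int] = set()
    for fx, fy in anchors:
        seed = seed_region(fx, fy)
        if shape == "irregular":
            if rng is None:
                raise ValueError("irregular clusters need an rng")
            members = _random_walk_cluster(region_map, seed, size, taken, rng)
        else:
            d = coords - coords[seed]
            if shape == "elliptic":
                metric = np.sqrt(d[:, 0] ** 2 / axis_ratio + d[:, 1] ** 2 * axis_ratio)
            else:
                metric = np.sqrt((d**2).sum(axis=1))
            metric = metric.copy()
            metric[list(taken)] = np.inf
            order = np.lexsort((np.arange(n), metric))
            members = set(int(r) for r in order[:size])
        if region_map.adjacency is not None and not _is_connected(members, region_map.adjacency):
            raise ValueError("planted cluster is not contiguous on this map")
        if taken & members:
            raise ValueError("cannot place disjoint clusters")
        taken |= members
        clusters.append(frozenset(members))
    return clusters


def _random_walk_cluster(
    region_map: RegionMap, seed: int, size: int, taken: set[int], rng
) -> set[int]:
    """Grow a connected cluster by repeatedly annexing a random frontier region."""
    if region_map.adjacency is None:
        raise ValueError("irregular clusters need region adjacency")
    neighbor: dict[int, set[int]] = {}
    for a, b in region_map.adjacency:
        neighbor.setdefault(a, set()).add(b)
        neighbor.setdefault(b, set()).add(a)
    members = {seed}
    while len(members) < size:
        frontier = sorted(
            set().union(*(neighbor.get(r, set()) for r in members)) - members - taken
        )
        if not frontier:
            raise ValueError("random walk ran out of frontier regions")
        members.add(int(rng.choice(frontier)))
    return members


@dataclass(frozen=True)
class Scenario:
    """A planted-cluster data-generating design.

    ``p_list`` holds one probability vector per true cluster; regions outside
    every cluster draw categories from ``p0``.  ``allocation`` spreads the
    fixed case total over regions (uniform when omitted).
    """

    region_map: RegionMap
    true_clusters: tuple[frozenset[int], ...]
    p0: tuple[float, ...] = NULL_PROBS
    p_list: tuple[tuple[float, ...], ...] = ()
    n_cases: int = 1000
    allocation: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        for p in (self.p0, *self.p_list):
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("probability vectors must be nonnegative and sum to 1")
            if p.shape[0] != len(self.p0):
                raise ValueError("all probability vectors must share one length K")
        if len(self.p_list) != len(self.true_clusters):
            raise ValueError("need one probability vector per true cluster")
        seen: set[int] = set()
        for cl in self.true_clusters:
            if not cl:
                raise ValueError("true clusters must be nonempty")
            if seen & cl:
                raise ValueError("true clusters must be disjoint")
            seen |= cl
        if self.allocation is not None:
            alloc = np.asarray(self.allocation, dtype=float)
            if alloc.shape != (self.region_map.n_regions,) or np.any(alloc < 0):
                raise ValueError("allocation must be a nonnegative per-region vector")
            object.__setattr__(self, "allocation", alloc / alloc.sum())
        if self.n_cases < 1:
            raise ValueError("need at least one case per dataset")

    @property
    def K(self) -> int:
        return len(self.p0)

    @property
    def truth_union(self) -> frozenset[int]:
        return frozenset().union(*self.true_clusters) if self.true_clusters else frozenset()

    def region_probs(self) -> np.ndarray:
        """Per-region category probability matrix implied by the design."""
        n = self.region_map.n_regions
        probs = np.tile(np.asarray(self.p0, dtype=float), (n, 1))
        for cl, p in zip(self.true_clusters, self.p_list):
            probs[sorted(cl)] = np.asarray(p, dtype=float)
        return probs


def simulate_dataset(scenario: Scenario, seed=None) -> CaseTable:
    """Draw one dataset: regions by allocation weight, categories by region.

    Equivalent to sampling each case's region then its category; implemented
    as a multinomial split of the case total over regions followed by a
    per-region multinomial over categories.  The grand total is exactly
    ``scenario.n_cases``.
    """
    rng = np.random.default_rng(seed)
    n = scenario.region_map.n_regions
    alloc = scenario.allocation
    if alloc is None:
        alloc = np.full(n, 1.0 / n)
    region_counts = rng.multinomial(scenario.n_cases, alloc)
    probs = scenario.region_probs()
    counts = np.zeros((n, scenario.K), dtype=np.int64)
    for i in range(n):
        if region_counts[i] > 0:
            counts[i] = rng.multinomial(region_counts[i], probs[i])
    return CaseTable(counts)


def performance_measures(
    detected: set[int] | frozenset[int],
    truth: set[int] | frozenset[int],
    n_regions: int,
    denominator: str = "regions",
) -> tuple[float, float, float]:
    """Region-level (sensitivity, PPV, misclassification) of a detection.

    Sensitivity is the detected share of the true cluster; PPV the true share
    of the detection (NaN when nothing was detected); misclassification the
    false positives plus false negatives over all regions, or over the union
    of true and detected regions when ``denominator='union'``.
    """
    detected, truth = set(detected), set(truth)
    if not truth:
        raise ValueError("the true cluster set is empty")
    if n_regions < len(detected | truth):
        raise ValueError("n_regions smaller than the sets it should contain")
    tp = len(detected & truth)
    fp = len(detected - truth)
    fn = len(truth - detected)
    sens = tp / len(truth)
    ppv = tp / len(detected) if detected else math.nan
    if denominator == "regions":
        mis = (fp + fn) / n_regions
    elif denominator == "union":
        mis = (fp + fn) / len(detected | truth)
    else:
        raise ValueError("denominator must be 'regions' or 'union'")
    return sens, ppv, mis


@dataclass
class PerformanceSummary:
    """Aggregated selection frequencies and accuracy of a simulation study."""

    records: pd.DataFrame = field(repr=False)
    grid: tuple[float, ...]
    methods: tuple[str, ...]
    n_datasets: int
    n_with_significant: int

    def to_frame(self) -> pd.DataFrame:
        """Selection-frequency / accuracy table: one block of rows per method.

        Columns are the MRCS grid values plus a ``default`` column (reporting
        at 50%) and an ``overall`` column (each dataset scored at its own
        selected value); rows are Freq, Sen, PPV, Mis.  Per-grid cells average
        only over the datasets that selected that value; default and overall
        average over all datasets with at least one significant cluster.
        """
        sig = self.records[self.records["any_significant"]]
        rows = []
        for method in self.methods:
            sel = sig[f"{method}_selected_m"]
            for stat, col in [
                ("Freq", None),
                ("Sen", f"{method}_sen"),
                ("PPV", f"{method}_ppv"),
                ("Mis", f"{method}_mis"),
            ]:
                row: dict = {"method": method, "stat": stat}
                for m in self.grid:
                    at_m = sig[sel == m]
                    if stat == "Freq":
                        row[m] = len(at_m)
                    else:
                        vals = at_m[col].dropna()
                        row[m] = float(vals.mean()) if len(vals) else math.nan
                if stat == "Freq":
                    row["default"] = len(sig)
                    row["overall"] = int(sel.notna().sum())
                else:
                    dvals = sig[f"default_{stat.lower()}"].dropna()
                    row["default"] = float(dvals.mean()) if len(dvals) else math.nan
                    ovals = sig[col].dropna()
                    row["overall"] = float(ovals.mean()) if len(ovals) else math.nan
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _detected_union(reports) -> frozenset[int]:
    return frozenset().union(*(set(r.window.regions) for r in reports)) if reports else frozenset()


def run_simulation_study(
    scenario: Scenario,
    n_reps: int,
    methods: Sequence[str] = METHODS,
    grid: Sequence[float] = DEFAULT_MRCS_GRID,
    replications: int = 999,
    alpha: float = 0.05,
    seed=None,
    msws_frac: float = 0.5,
    shapes: Sequence[float] = DEFAULT_SHAPES,
    angles_per_shape: Sequence[int] = DEFAULT_ANGLES_PER_SHAPE,
    mis_denominator: str = "regions",
) -> PerformanceSummary:
    """Simulate ``n_reps`` datasets, select the MRCS per method, score each.

    One scan is run per dataset at ``msws_frac``; every method then selects
    its MRCS from the shared cluster reports, and detection accuracy is scored
    against the union of the planted clusters both at the selected value and
    at the 50% default.  A master seed spawns one independent stream per
    replicate, so any replicate is reproducible in isolation.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    grid = tuple(sorted(float(m) for m in grid))
    rmap = scenario.region_map
    truth = set(scenario.truth_union)
    orderings = scan_orderings(rmap, shapes, angles_per_shape)
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_reps)

    rows = []
    for rep, stream in enumerate(streams):
        data_seed, scan_seed = stream.spawn(2)
        cases = simulate_dataset(scenario, seed=np.random.default_rng(data_seed))
        windows = enumerate_windows(
            rmap, cases, msws_frac=msws_frac, shapes=shapes,
            angles_per_shape=angles_per_shape, orderings=orderings,
        )
        result = scan_once(
            cases, windows, replications=replications, alpha=alpha,
            seed=np.random.default_rng(scan_seed),
        )
        reports_by_m = {m: report_at_mrcs(result, m, alpha) for m in grid}
        any_sig = any(len(r) > 0 for r in reports_by_m.values())
        row: dict = {"rep": rep, "any_significant": any_sig}

        default_reports = reports_by_m[max(grid)] if 50.0 in grid else report_at_mrcs(result, 50.0, alpha)
        d_def = _detected_union(default_reports)
        sen, ppv, mis = performance_measures(d_def, truth, rmap.n_regions, mis_denominator)
        row.update(default_sen=sen, default_ppv=ppv, default_mis=mis)

        for method in methods:
            sel, _, final = select_optimal_mrcs(
                cases, result, method, grid=grid, alpha=alpha,
                adjacency=rmap.adjacency, reports_by_m=reports_by_m,
            )
            det = _detected_union(final)
            if sel is None:
                row[f"{method}_selected_m"] = math.nan
                row[f"{method}_sen"] = math.nan
                row[f"{method}_ppv"] = math.nan
                row[f"{method}_mis"] = math.nan
            else:
                sen, ppv, mis = performance_measures(det, truth, rmap.n_regions, mis_denominator)
                row[f"{method}_selected_m"] = sel
                row[f"{method}_sen"] = sen
                row[f"{method}_ppv"] = ppv
                row[f"{method}_mis"] = mis
            # per-cluster sensitivities alongside the union score
            for j, cl in enumerate(scenario.true_clusters, start=1):
                row[f"{method}_sen_cluster{j}"] = (
                    len(det & cl) / len(cl) if sel is not None else math.nan
                )
        rows.append(row)

    records = pd.DataFrame(rows)
    return PerformanceSummary(
        records=records,
        grid=grid,
        methods=methods,
        n_datasets=n_reps,
        n_with_significant=int(records["any_significant"].sum()),
    )


def table1_scenarios(
    region_map: RegionMap | None = None,
    n_cases: int = 1000,
    irregular_seed: int = 20230101,
) -> list[Scenario]:
    """The full crossed simulation design: 26 planted-cluster scenarios.

    Three single-cluster models (circular 8%, elliptic 8%, irregular 15%)
    crossed with four alternative hypotheses, plus two two-cluster models
    (circular and elliptic, 8% each) crossed with four homogeneous and three
    heterogeneous hypothesis settings: 3*4 + 2*4 + 2*3 = 26 scenarios.
    """
    if region_map is None:
        region_map = make_grid_geography(8)
    rng = np.random.default_rng(irregular_seed)
    single_models = {
        "A": ("circular", 0.08),
        "B": ("elliptic", 0.08),
        "C": ("irregular", 0.15),
    }
    double_models = {"D": "circular", "E": "elliptic"}
    scenarios = []
    for model, (shape, frac) in single_models.items():
        clusters = plant_true_clusters(region_map, shape, frac, count=1, rng=rng)
        for h, p1 in ALTERNATIVE_HYPOTHESES.items():
            scenarios.append(
                Scenario(
                    region_map=region_map,
                    true_clusters=tuple(clusters),
                    p_list=(p1,),
                    n_cases=n_cases,
                    name=f"{model}{h}",
                )
            )
    for model, shape in double_models.items():
        clusters = plant_true_clusters(region_map, shape, 0.08, count=2, rng=rng)
        for h, p in ALTERNATIVE_HYPOTHESES.items():
            scenarios.append(
                Scenario(
                    region_map=region_map,
                    true_clusters=tuple(clusters),
                    p_list=(p, p),
                    n_cases=n_cases,
                    name=f"{model}{h}",
                )
            )
        for h, (h1, h2) in HETEROGENEOUS_PAIRS.items():
            scenarios.append(
                Scenario(
                    region_map=region_map,
                    true_clusters=tuple(clusters),
                    p_list=(ALTERNATIVE_HYPOTHESES[h1], ALTERNATIVE_HYPOTHESES[h2]),
                    n_cases=n_cases,
                    name=f"{model}{h}",
                )
            )
    return scenarios
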