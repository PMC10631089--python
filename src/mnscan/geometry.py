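"""Region maps and enumeration of circular/elliptic scanning windows.

A scanning window is a set of regions obtained by centering a metric at one
region's centroid and accumulating regions from nearest to farthest.  Circles
use the Euclidean metric; ellipses with axis ratio ``s`` use the
area-preserving metric ``sqrt(x'^2 / s + y'^2 * s)`` in a frame rotated by the
window angle, so that windows of equal size cover equal area regardless of
shape.  A window is admissible while the case fraction of its member regions
does not exceed the maximum scanning window size (MSWS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RegionMap",
    "Window",
    "build_region_map",
    "scan_orderings",
    "enumerate_windows",
    "DEFAULT_SHAPES",
    "DEFAULT_ANGLES_PER_SHAPE",
]

# Circle plus the standard elliptic battery: longer shapes get more angles so
# the angular resolution of the covered area stays roughly constant.
DEFAULT_SHAPES: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
DEFAULT_ANGLES_PER_SHAPE: tuple[int, ...] = (1, 4, 6, 9, 12, 15)


@dataclass(frozen=True)
class RegionMap:
    """An ordered collection of regions with planar centroid coordinates.

    Coordinates must be projected (planar); latitude/longitude input should be
    projected upstream.  ``adjacency`` is an optional set of undirected index
    pairs used for contiguity merging and for planting connected clusters.
    """

    region_ids: tuple
    coords: np.ndarray  # (n, 2) float
    population: np.ndarray | None = None
    adjacency: frozenset[tuple[int, int]] | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.region_ids) != coords.shape[0]:
            raise ValueError("region_ids and coords length mismatch")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region ids must be unique")
        if coords.shape[0] < 2:
            raise ValueError("a region map needs at least 2 regions")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.population is not None:
            pop = np.asarray(self.population, dtype=float)
            if pop.shape != (coords.shape[0],) or np.any(pop < 0):
                raise ValueError("population must be nonnegative, one per region")
            object.__setattr__(self, "population", pop)
        if self.adjacency is not None:
            n = coords.shape[0]
            edges = set()
            for a, b in self.adjacency:
                if a == b:
                    raise ValueError("adjacency must be irreflexive")
                if not (0 <= a < n and 0 <= b < n):
                    raise ValueError("adjacency index out of range")
                edges.add((min(a, b), max(a, b)))
            object.__setattr__(self, "adjacency", frozenset(edges))

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]

    def index_of(self, region_id) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region id {region_id!r}") from None

    def adjacency_graph(self):
        """Return the region adjacency as a networkx Graph (nodes = indices)."""
        import networkx as nx

        if self.adjacency is None:
            raise ValueError("region map has no adjacency information")
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.adjacency)
        return g


@dataclass(frozen=True, order=True)
class Window:
    """A candidate cluster: a canonically sorted set of region indices.

    ``shape`` is the ellipse axis ratio (1 = circle) and ``angle`` the
    orientation of the long axis in [0, pi).  ``size_frac`` is the fraction of
    all cases falling inside the window.
    """

    regions: tuple[int, ...]
    center: int
    shape: float = 1.0
    angle: float = 0.0
    size_frac: float = field(default=0.0, compare=False)

    def __post_init__(self):
        regs = tuple(sorted(self.regions))
        if not regs:
            raise ValueError("a window must contain at least one region")
        if self.center not in regs:
            raise ValueError("window center must be a member region")
        object.__setattr__(self, "regions", regs)

    @property
    def region_set(self) -> frozenset[int]:
        return frozenset(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def delaunay_adjacency(region_map: RegionMap) -> frozenset[tuple[int, int]]:
    """Derive a region adjacency from centroids via Delaunay triangulation.

    A fallback for maps shipped without an edge list (contiguity merging
    needs one); triangulation edges approximate rook/queen contiguity for
    reasonably regular centroid layouts but can bridge across gaps, so a
    true boundary-derived edge list is preferred when available.
    """
    from itertools import combinations

    from scipy.spatial import Delaunay

    tri = Delaunay(region_map.coords)
    edges = set()
    for simplex in tri.simplices:
        for a, b in combinations(map(int, simplex), 2):
            edges.add((min(a, b), max(a, b)))
    return frozenset(edges)


def build_region_map(records: Iterable[tuple]) -> RegionMap:
    """Build a RegionMap from ``(id, x, y[, population])`` records.

    Index order equals input order.  Raises on duplicate ids, non-numeric
    coordinates, or fewer than two records.
    """
    ids, xs, ys, pops = [], [], [], []
    has_pop = None
    for rec in records:
        rec = tuple(rec)
        if len(rec) not in (3, 4):
            raise ValueError(f"record must be (id, x, y[, population]): {rec!r}")
        rid, x, y = rec[0], rec[1], rec[2]
        if rid in ids:
            raise ValueError(f"duplicate region id {rid!r}")
        try:
            x, y = float(x), float(y)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric coordinate for region {rid!r}") from None
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"non-finite coordinate for region {rid!r}")
        row_has_pop = len(rec) == 4 and rec[3] is not None
        if has_pop is None:
            has_pop = row_has_pop
        elif has_pop != row_has_pop:
            raise ValueError("population must be given for all regions or none")
        if row_has_pop:
            pops.append(float(rec[3]))
        ids.append(rid)
        xs.append(x)
        ys.append(y)
    if len(ids) < 2:
        raise ValueError("need at least 2 regions")
    coords = np.column_stack([xs, ys])
    population = np.asarray(pops) if has_pop else None
    return RegionMap(tuple(ids), coords, population)


def elliptic_distances(
    coords: np.ndarray, center: int, shape: float, angle: float
) -> np.ndarray:
    """Distances from every region to ``center`` under the rotated metric.

    For axis ratio ``s`` the metric is ``sqrt(x'^2/s + y'^2 * s)`` with
    ``(x', y')`` the offset rotated so the long axis lies along x'.  The two
    scale factors multiply to one, so a level set of the metric encloses the
    same area as the circle of equal radius.
    """
    d = coords - coords[center]
    c, s_ = np.cos(angle), np.sin(angle)
    xr = c * d[:, 0] + s_ * d[:, 1]
    yr = -s_ * d[:, 0] + c * d[:, 1]
    return np.sqrt(xr * xr / shape + yr * yr * shape)


def scan_orderings(
    region_map: RegionMap,
    shapes: Sequence[float] = DEFAULT_SHAPES,
    angles_per_shape: Sequence[int] = DEFAULT_ANGLES_PER_SHAPE,
) -> list[tuple[int, float, float, np.ndarray]]:
    """Precompute nearest-first region orderings for every center/shape/angle.

    Returns ``(center, shape, angle, order)`` tuples where ``order`` ranks all
    regions by the elliptic metric (ties broken by region index).  Orderings
    depend only on the geometry, so they can be reused across datasets on the
    same map.
    """
    shapes = [float(s) for s in shapes]
    angles_per_shape = [int(a) for a in angles_per_shape]
    if len(shapes) != len(angles_per_shape):
        raise ValueError("shapes and angles_per_shape must have the same length")
    if any(s < 1 for s in shapes):
        raise ValueError("axis ratios must be >= 1")
    if any(a < 1 for a in angles_per_shape):
        raise ValueError("angle counts must be >= 1")
    if 1.0 not in shapes:  # the circle is always scanned
        shapes = [1.0] + shapes
        angles_per_shape = [1] + angles_per_shape
    coords = region_map.coords
    n = region_map.n_regions
    idx = np.arange(n)
    out = []
    for shape, n_angles in zip(shapes, angles_per_shape):
        angles = [0.0] if shape == 1.0 else [k * np.pi / n_angles for k in range(n_angles)]
        for angle in angles:
            for center in range(n):
                dist = elliptic_distances(coords, center, shape, angle)
                order = np.lexsort((idx, dist))
                out.append((center, shape, angle, order))
    return out


def enumerate_windows(
    region_map: RegionMap,
    cases,
    msws_frac: float = 0.5,
    shapes: Sequence[float] = DEFAULT_SHAPES,
    angles_per_shape: Sequence[int] = DEFAULT_ANGLES_PER_SHAPE,
    orderings: list | None = None,
) -> list["Window"]:
    """Enumerate all distinct scanning windows up to ``msws_frac`` of cases.

    For each precomputed ordering, prefixes are accumulated nearest-first and a
    window is emitted for every prefix whose case fraction is at most
    ``msws_frac``; windows are deduplicated on the region set (first geometry
    that produces a set wins).  A singleton whose own fraction already exceeds
    the bound is excluded.

    Parameters
    ----------
    cases : CaseTable
        Supplies the per-region case totals used to size windows.
    orderings : optional
        Output of :func:`scan_orderings` for this map/shape configuration,
        to amortize the geometry work across many datasets.
    """
    if not (0 < msws_frac <= 0.5):
        raise ValueError("msws_frac must be in (0, 0.5] (multiple-testing guard)")
    region_totals = np.asarray(cases.region_totals, dtype=float)
    if region_totals.shape[0] != region_map.n_regions:
        raise ValueError("case table and region map disagree on region count")
    total = region_totals.sum()
    if total <= 0:
        raise ValueError("case table is empty")
    frac = region_totals / total
    if orderings is None:
        orderings = scan_orderings(region_map, shapes, angles_per_shape)

    seen: dict[bytes, None] = {}
    windows: list[Window] = []
    tol = 1e-12
    for center, shape, angle, order in orderings:
        cum = np.cumsum(frac[order])
        n_adm = int(np.searchsorted(cum, msws_frac + tol, side="right"))
        for j in range(n_adm):
            members = np.sort(order[: j + 1])
            key = members.tobytes()
            if key in seen:
                continue
            seen[key] = None
            windows.append(
                Window(
                    regions=tuple(int(r) for r in members),
                    center=center,
                    shape=shape,
                    angle=angle,
                    size_frac=float(cum[j]),
                )
            )
    return windows
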