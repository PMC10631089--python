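"""File readers/writers and run configuration.

Primary formats are headered CSVs: region file ``id,x,y[,population]``, case
file ``region_id,category,count`` (long form), adjacency file ``id_a,id_b``
(undirected).  A shim imports SaTScan-style whitespace-delimited case and
coordinate files.  All numeric output is serialized at 6 significant digits
so diffs are stable.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .criteria import DEFAULT_MRCS_GRID, METHODS, CriterionProfile
from .geometry import (
    DEFAULT_ANGLES_PER_SHAPE,
    DEFAULT_SHAPES,
    RegionMap,
    build_region_map,
)
from .scan import CaseTable, ClusterReport

__all__ = [
    "RunConfig",
    "read_regions",
    "read_cases",
    "read_adjacency",
    "read_inputs",
    "frames_to_inputs",
    "reports_to_frame",
    "write_outputs",
    "read_satscan_inputs",
]

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Run settings shared by the CLI commands; loadable from YAML."""

    msws_frac: float = 0.5
    mrcs_grid: tuple[float, ...] = DEFAULT_MRCS_GRID
    alpha: float = 0.05
    replications: int = 999
    seed: int | None = None
    shapes: tuple[float, ...] = DEFAULT_SHAPES
    angles_per_shape: tuple[int, ...] = DEFAULT_ANGLES_PER_SHAPE
    methods: tuple[str, ...] = METHODS
    allocation: str = "uniform"  # or "population"
    mis_denominator: str = "regions"  # or "union"
    categories: tuple | None = None

    def __post_init__(self):
        if not (0 < self.msws_frac <= 0.5):
            raise ValueError("msws_frac must be in (0, 0.5]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if any(not (0 < m <= 50) for m in self.mrcs_grid):
            raise ValueError("MRCS grid values must be in (0, 50]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("mrcs_grid", "shapes", "angles_per_shape", "methods", "categories"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_regions(path) -> RegionMap:
    df = pd.read_csv(path)
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"region file needs columns {sorted(required)}")
    cols = ["id", "x", "y"] + (["population"] if "population" in df.columns else [])
    return build_region_map(list(df[cols].itertuples(index=False)))


def read_cases(path, region_map: RegionMap, categories: Sequence | None = None) -> CaseTable:
    df = pd.read_csv(path)
    return CaseTable.from_long(df, region_map.region_ids, categories)


def read_adjacency(path, region_map: RegionMap) -> frozenset[tuple[int, int]]:
    df = pd.read_csv(path)
    if not {"id_a", "id_b"}.issubset(df.columns):
        raise ValueError("adjacency file needs columns id_a, id_b")
    edges = set()
    for a, b in df[["id_a", "id_b"]].itertuples(index=False):
        ia, ib = region_map.index_of(a), region_map.index_of(b)
        if ia == ib:
            raise ValueError(f"self-adjacency for region {a!r}")
        edges.add((min(ia, ib), max(ia, ib)))
    return frozenset(edges)


def read_inputs(
    region_path, case_path, adjacency_path=None, categories: Sequence | None = None
) -> tuple[RegionMap, CaseTable]:
    """Read and cross-validate the region, case, and adjacency files."""
    region_map = read_regions(region_path)
    cases = read_cases(case_path, region_map, categories)
    if adjacency_path is not None:
        edges = read_adjacency(adjacency_path, region_map)
        region_map = RegionMap(
            region_map.region_ids, region_map.coords, region_map.population, edges
        )
    return region_map, cases


def frames_to_inputs(
    region_df: pd.DataFrame,
    case_df: pd.DataFrame,
    adjacency_df: pd.DataFrame | None = None,
    categories: Sequence | None = None,
) -> tuple[RegionMap, CaseTable]:
    """In-memory counterpart of :func:`read_inputs` for DataFrame callers."""
    required = {"id", "x", "y"}
    if not required.issubset(region_df.columns):
        raise ValueError(f"region frame needs columns {sorted(required)}")
    cols = ["id", "x", "y"] + (["population"] if "population" in region_df.columns else [])
    region_map = build_region_map(list(region_df[cols].itertuples(index=False)))
    cases = CaseTable.from_long(case_df, region_map.region_ids, categories)
    if adjacency_df is not None:
        edges = set()
        for a, b in adjacency_df[["id_a", "id_b"]].itertuples(index=False):
            ia, ib = region_map.index_of(a), region_map.index_of(b)
            edges.add((min(ia, ib), max(ia, ib)))
        region_map = RegionMap(
            region_map.region_ids, region_map.coords, region_map.population, frozenset(edges)
        )
    return region_map, cases


def read_satscan_inputs(case_path, geo_path) -> tuple[RegionMap, CaseTable]:
    """Import SaTScan-style whitespace-delimited case and coordinate files.

    The case file rows are ``location_id  count  category``; the coordinate
    file rows are ``location_id  x  y``.
    """
    geo = pd.read_csv(geo_path, sep=r"\s+", header=None, names=["id", "x", "y"])
    region_map = build_region_map(list(geo.itertuples(index=False)))
    cas = pd.read_csv(case_path, sep=r"\s+", header=None, names=["region_id", "count", "category"])
    cases = CaseTable.from_long(cas[["region_id", "category", "count"]], region_map.region_ids)
    return region_map, cases


def reports_to_frame(
    reports: Sequence[ClusterReport], region_map: RegionMap, categories: Sequence
) -> pd.DataFrame:
    """Cluster reports as a flat frame, one row per cluster."""
    rows = []
    for r in reports:
        row = {
            "rank": r.rank,
            "regions": ";".join(str(region_map.region_ids[i]) for i in r.window.regions),
            "n_regions": len(r.window),
            "n_cases": r.n_cases,
            "size_frac": r.size_frac,
            "llr": r.llr,
            "p_value": r.p_value,
        }
        for k, cat in enumerate(categories):
            row[f"rr_{cat}"] = r.rr[k]
        rows.append(row)
    columns = ["rank", "regions", "n_regions", "n_cases", "size_frac", "llr", "p_value"] + [
        f"rr_{cat}" for cat in categories
    ]
    return pd.DataFrame(rows, columns=columns)


def reports_to_geojson(
    reports: Sequence[ClusterReport], region_map: RegionMap
) -> dict:
    """Member-region centroids of all reported clusters as GeoJSON points."""
    features = []
    for r in reports:
        for i in r.window.regions:
            x, y = region_map.coords[i]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {
                        "region_id": str(region_map.region_ids[i]),
                        "cluster_rank": r.rank,
                        "llr": round(r.llr, 6),
                        "p_value": round(r.p_value, 6),
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}


def profiles_to_frame(profiles: Sequence[CriterionProfile]) -> pd.DataFrame:
    if not profiles:
        return pd.DataFrame(columns=["method", "m", "J_m", "tau", "delta", "value", "selected"])
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def write_outputs(
    out_dir,
    reports: Sequence[ClusterReport] | None = None,
    region_map: RegionMap | None = None,
    categories: Sequence | None = None,
    profiles: Sequence[CriterionProfile] | None = None,
    summary=None,
    config: RunConfig | None = None,
    geojson: bool = False,
) -> list[Path]:
    """Write cluster/profile/summary CSVs and a reproducibility manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if reports is not None:
        path = out_dir / "clusters.csv"
        reports_to_frame(reports, region_map, categories).to_csv(
            path, index=False, float_format=FLOAT_FMT
        )
        written.append(path)
        if geojson:
            gpath = out_dir / "clusters.geojson"
            gpath.write_text(json.dumps(reports_to_geojson(reports, region_map), indent=1))
            written.append(gpath)
    if profiles is not None:
        path = out_dir / "criterion_profile.csv"
        profiles_to_frame(profiles).to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)
    if summary is not None:
        path = out_dir / "summary.csv"
        summary.to_csv(path)
        written.append(path)
    manifest = {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config) if config is not None else None,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    written.append(path)
    return written
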