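"""Model/results interface over the scan pipeline.

``MultinomialScan`` is built from a region map and a case table; ``fit`` runs
the window enumeration and Monte Carlo inference once at the maximum scanning
window size and returns a results object from which cluster reports at any
maximum reported cluster size (MRCS), and the MRCS selection criteria, are
derived without rescanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .criteria import DEFAULT_MRCS_GRID, METHODS, CriterionProfile, select_optimal_mrcs
from .geometry import (
    DEFAULT_ANGLES_PER_SHAPE,
    DEFAULT_SHAPES,
    RegionMap,
    Window,
    enumerate_windows,
    scan_orderings,
)
from .scan import CaseTable, ClusterReport, ScanResult, report_at_mrcs, scan_once

__all__ = ["MultinomialScan", "MultinomialScanResults", "MrcsSelection"]


class MultinomialScan:
    """Multinomial spatial scan statistic for region-by-category case counts.

    Parameters
    ----------
    cases : CaseTable
        Region-by-category counts; rows must align with ``region_map``.
    region_map : RegionMap
        Region ids, projected centroid coordinates, optional adjacency.
    msws_frac : float
        Maximum scanning window size as a fraction of total cases, at most
        0.5 (scanning larger windows only repeats the complementary test).
    shapes, angles_per_shape
        The elliptic window battery: axis ratios and the number of evenly
        spaced orientations per ratio.  The circle is always included.
    """

    def __init__(
        self,
        cases: CaseTable,
        region_map: RegionMap,
        msws_frac: float = 0.5,
        shapes: Sequence[float] = DEFAULT_SHAPES,
        angles_per_shape: Sequence[int] = DEFAULT_ANGLES_PER_SHAPE,
    ):
        if cases.n_regions != region_map.n_regions:
            raise ValueError("case table and region map disagree on region count")
        self.cases = cases
        self.region_map = region_map
        self.msws_frac = float(msws_frac)
        self.shapes = tuple(shapes)
        self.angles_per_shape = tuple(angles_per_shape)
        self._orderings = None

    @classmethod
    def from_dataframes(
        cls,
        case_df: pd.DataFrame,
        region_df: pd.DataFrame,
        adjacency_df: pd.DataFrame | None = None,
        categories: Sequence | None = None,
        **kwargs,
    ) -> "MultinomialScan":
        """Build from long-form case, region, and optional adjacency frames.

        ``region_df`` needs columns id, x, y (optional population);
        ``case_df`` needs region_id, category, count; ``adjacency_df`` needs
        id_a, id_b.
        """
        from .io import frames_to_inputs

        region_map, cases = frames_to_inputs(region_df, case_df, adjacency_df, categories)
        return cls(cases, region_map, **kwargs)

    @property
    def windows(self) -> list[Window]:
        if self._orderings is None:
            self._orderings = scan_orderings(self.region_map, self.shapes, self.angles_per_shape)
        return enumerate_windows(
            self.region_map,
            self.cases,
            msws_frac=self.msws_frac,
            shapes=self.shapes,
            angles_per_shape=self.angles_per_shape,
            orderings=self._orderings,
        )

    def fit(
        self, replications: int = 999, alpha: float = 0.05, seed=None
    ) -> "MultinomialScanResults":
        """Scan all windows and run the Monte Carlo null; returns results."""
        result = scan_once(
            self.cases, self.windows, replications=replications, alpha=alpha, seed=seed
        )
        return MultinomialScanResults(self, result)


@dataclass
class MrcsSelection:
    """Outcome of MRCS selection for one method."""

    method: str
    selected_m: float | None
    profile: CriterionProfile
    clusters: list[ClusterReport]


class MultinomialScanResults:
    """Fitted scan: candidate statistics, null distribution, reporting."""

    def __init__(self, model: MultinomialScan, result: ScanResult):
        self.model = model
        self._result = result

    # thin accessors over the underlying ScanResult
    @property
    def scan_result(self) -> ScanResult:
        return self._result

    @property
    def llr(self) -> np.ndarray:
        return self._result.llr

    @property
    def p_values(self) -> np.ndarray:
        return self._result.p_values

    @property
    def null_max_llr(self) -> np.ndarray:
        return self._result.null_max_llr

    @property
    def most_likely_cluster(self) -> Window:
        return self._result.most_likely_cluster

    @property
    def alpha(self) -> float:
        return self._result.alpha

    def report(self, mrcs: float = 50.0, alpha: float | None = None) -> list[ClusterReport]:
        """Significant non-overlapping clusters at the given MRCS percent."""
        return report_at_mrcs(self._result, mrcs, alpha)

    def report_frame(self, mrcs: float = 50.0, alpha: float | None = None) -> pd.DataFrame:
        from .io import reports_to_frame

        return reports_to_frame(
            self.report(mrcs, alpha), self.model.region_map, self.model.cases.categories
        )

    def select_mrcs(
        self,
        method: str = "scic1",
        grid: Sequence[float] = DEFAULT_MRCS_GRID,
        alpha: float | None = None,
    ) -> MrcsSelection:
        """Run one selection criterion over the MRCS grid."""
        sel, profile, final = select_optimal_mrcs(
            self.model.cases,
            self._result,
            method,
            grid=grid,
            alpha=alpha,
            adjacency=self.model.region_map.adjacency,
        )
        return MrcsSelection(method=method, selected_m=sel, profile=profile, clusters=final)

    def select_all(
        self,
        methods: Sequence[str] = METHODS,
        grid: Sequence[float] = DEFAULT_MRCS_GRID,
        alpha: float | None = None,
    ) -> dict[str, MrcsSelection]:
        if alpha is None:
            alpha = self._result.alpha
        grid = tuple(sorted(float(m) for m in grid))
        reports_by_m = {m: report_at_mrcs(self._result, m, alpha) for m in grid}
        out = {}
        for method in methods:
            if method == "mchsp" and self.model.region_map.adjacency is None:
                continue
            sel, profile, final = select_optimal_mrcs(
                self.model.cases,
                self._result,
                method,
                grid=grid,
                alpha=alpha,
                adjacency=self.model.region_map.adjacency,
                reports_by_m=reports_by_m,
            )
            out[method] = MrcsSelection(method, sel, profile, final)
        return out

    def summary(self, mrcs: float = 50.0) -> str:
        """Plain-text summary of the scan and the clusters reported at MRCS."""
        res = self._result
        reports = self.report(mrcs)
        lines = [
            "Multinomial spatial scan statistic",
            "=" * 50,
            f"regions: {self.model.region_map.n_regions}"
            f"    categories: {self.model.cases.n_categories}"
            f"    cases: {self.model.cases.total}",
            f"candidate windows: {len(res.windows)}"
            f"    MSWS: {self.model.msws_frac:.0%} of cases",
            f"Monte Carlo replications: {res.replications}    alpha: {res.alpha}",
            f"max log likelihood ratio: {res.llr.max():.4f}",
            "",
            f"significant clusters at MRCS = {mrcs:g}%: {len(reports)}",
        ]
        ids = self.model.region_map.region_ids
        for r in reports:
            members = ",".join(str(ids[i]) for i in r.window.regions)
            lines.append(
                f"  #{r.rank}: LLR={r.llr:.4f} p={r.p_value:.4g} "
                f"cases={r.n_cases} regions=[{members}]"
            )
        return "\n".join(lines)
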