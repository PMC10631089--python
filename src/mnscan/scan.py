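"""Multinomial spatial scan statistic: likelihood ratio, Monte Carlo inference.

The test compares the category distribution inside a scanning window ``z``
against the distribution outside.  With ``a_k`` the category-``k`` cases
inside, ``A`` their total, ``b_k = C_k - a_k`` and ``B = C - A`` the outside
margins, the log likelihood ratio is

    log lambda_z = sum_k [ a_k log(a_k/A) + b_k log(b_k/B) ]
                   - sum_k C_k log(C_k/C)

with the convention ``0 log 0 = 0``.  The statistic is zero when the inside
and outside category proportions coincide, is symmetric between a window and
its complement, and is invariant to relabeling the categories.

Significance is assessed by Monte Carlo randomization under the null that all
regions share one category distribution: category labels are reshuffled over
cases holding both the per-region totals and the per-category totals fixed
(multivariate hypergeometric allocation), and each candidate is compared with
the null distribution of the maximum statistic over all windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Window

__all__ = [
    "CaseTable",
    "ClusterReport",
    "ScanResult",
    "llr_multinomial",
    "relative_risks",
    "scan_once",
    "report_at_mrcs",
]


@dataclass(frozen=True)
class CaseTable:
    """A region-by-category matrix of case counts ``c_ik``."""

    counts: np.ndarray
    categories: tuple = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d region x category matrix")
        if np.any(counts < 0):
            raise ValueError("case counts must be nonnegative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("case counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.shape[1] < 2:
            raise ValueError("need at least 2 categories")
        if counts.sum() < 1:
            raise ValueError("case table has no cases")
        object.__setattr__(self, "counts", counts)
        cats = self.categories
        if cats is None:
            cats = tuple(range(counts.shape[1]))
        cats = tuple(cats)
        if len(cats) != counts.shape[1]:
            raise ValueError("category labels do not match column count")
        object.__setattr__(self, "categories", cats)

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def region_totals(self) -> np.ndarray:
        """Per-region case totals ``c_i``."""
        return self.counts.sum(axis=1)

    @property
    def category_totals(self) -> np.ndarray:
        """Per-category case totals ``C_k``."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total ``C``."""
        return int(self.counts.sum())

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        region_ids: Sequence,
        categories: Sequence | None = None,
    ) -> "CaseTable":
        """Build from a long-form frame with columns region_id, category, count.

        Regions absent from ``df`` get zero rows; a region in ``df`` that is
        not in ``region_ids`` is an error.  Categories are taken in first
        appearance order unless given explicitly.
        """
        required = {"region_id", "category", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"case table needs columns {sorted(required)}")
        if (df["count"] < 0).any():
            raise ValueError("negative case count in case table")
        if categories is None:
            categories = list(dict.fromkeys(df["category"]))
        categories = list(categories)
        unknown_cat = set(df["category"]) - set(categories)
        if unknown_cat:
            raise ValueError(f"categories not in configured list: {sorted(map(str, unknown_cat))}")
        region_index = {rid: i for i, rid in enumerate(region_ids)}
        cat_index = {c: k for k, c in enumerate(categories)}
        counts = np.zeros((len(region_index), len(categories)), dtype=np.int64)
        for rid, cat, cnt in df[["region_id", "category", "count"]].itertuples(index=False):
            if rid not in region_index:
                raise ValueError(f"case row references unknown region id {rid!r}")
            counts[region_index[rid], cat_index[cat]] += int(cnt)
        return cls(counts, tuple(categories))

    def to_long(self, region_ids: Sequence | None = None) -> pd.DataFrame:
        ids = list(region_ids) if region_ids is not None else list(range(self.n_regions))
        rows = [
            (ids[i], self.categories[k], int(self.counts[i, k]))
            for i in range(self.n_regions)
            for k in range(self.n_categories)
            if self.counts[i, k] > 0
        ]
        return pd.DataFrame(rows, columns=["region_id", "category", "count"])


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * log(x) with 0 log 0 = 0, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _null_loglik(category_totals: np.ndarray, total: float) -> float:
    return float(_xlogx(category_totals).sum() - total * np.log(total))


def llr_from_inside(a: np.ndarray, category_totals: np.ndarray, total: float) -> float:
    """log lambda_z from the inside category counts of one window."""
    a = np.asarray(a, dtype=float)
    A = a.sum()
    b = category_totals - a
    B = total - A
    if A == 0 or B == 0:
        return 0.0
    ll_alt = _xlogx(a).sum() - A * np.log(A) + _xlogx(b).sum() - B * np.log(B)
    return max(0.0, ll_alt - _null_loglik(category_totals, total))


def llr_matrix(A_mat: np.ndarray, category_totals: np.ndarray, total: float) -> np.ndarray:
    """Vectorized log lambda for many windows; rows of ``A_mat`` are inside counts."""
    from scipy.special import xlogy

    A_mat = np.asarray(A_mat, dtype=float)
    Atot = A_mat.sum(axis=-1)
    Bmat = category_totals - A_mat
    Btot = total - Atot
    ll = xlogy(A_mat, A_mat).sum(axis=-1) + xlogy(Bmat, Bmat).sum(axis=-1)
    ll -= xlogy(Atot, Atot) + xlogy(Btot, Btot)
    ll -= _null_loglik(category_totals, total)
    ll[(Atot == 0) | (Btot == 0)] = 0.0
    return np.maximum(ll, 0.0)


def llr_multinomial(window: Window, cases: CaseTable) -> float:
    """Multinomial log likelihood ratio ``log lambda_z`` of one window."""
    regs = np.asarray(window.regions)
    if regs.min() < 0 or regs.max() >= cases.n_regions:
        raise IndexError("window references regions outside the case table")
    a = cases.counts[regs].sum(axis=0)
    return llr_from_inside(a, cases.category_totals.astype(float), float(cases.total))


def relative_risks(window: Window, cases: CaseTable) -> np.ndarray:
    """Per-category relative risks (inside rate / outside rate) of a window.

    Entries are 0 when the category is absent inside, and ``inf`` when present
    inside but absent outside.
    """
    regs = np.asarray(window.regions)
    a = cases.counts[regs].sum(axis=0).astype(float)
    A = a.sum()
    b = cases.category_totals - a
    B = cases.total - A
    if A == 0 or B == 0:
        raise ValueError("relative risks undefined for a degenerate window")
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (a / A) / (b / B)
    rr[a == 0] = 0.0
    rr[(b == 0) & (a > 0)] = np.inf
    return rr


@dataclass(frozen=True)
class ClusterReport:
    """One reported cluster: window, statistic, Monte Carlo p-value, risks."""

    window: Window
    llr: float
    p_value: float
    size_frac: float
    n_cases: int
    rr: tuple[float, ...]
    rank: int

    @property
    def regions(self) -> tuple[int, ...]:
        return self.window.regions


@dataclass
class ScanResult:
    """Everything produced by one scan at the maximum scanning window size.

    Holds the statistic of every candidate window and the Monte Carlo null
    distribution of the maximum, so cluster reports at any maximum reported
    cluster size (MRCS) can be derived without rescanning.
    """

    windows: list[Window]
    llr: np.ndarray
    p_values: np.ndarray
    null_max_llr: np.ndarray
    alpha: float
    seed: int | None
    cases: CaseTable = field(repr=False)

    @property
    def replications(self) -> int:
        return len(self.null_max_llr)

    @property
    def most_likely_index(self) -> int:
        return int(np.argmax(self.llr))

    @property
    def most_likely_cluster(self) -> Window:
        return self.windows[self.most_likely_index]

    def ranked_nonoverlapping(self, max_size_frac: float = 1.0) -> list[int]:
        """Greedy non-overlap ranking of candidate indices by descending llr.

        A window is kept iff its region set is disjoint from every window
        already kept.  ``max_size_frac`` restricts candidates before ranking,
        which is how MRCS-restricted reports are built.
        """
        sizes = np.array([w.size_frac for w in self.windows])
        eligible = np.flatnonzero(sizes <= max_size_frac + 1e-12)
        # stable deterministic order: llr desc, then fewer regions, then regions
        order = sorted(
            eligible,
            key=lambda i: (-self.llr[i], len(self.windows[i]), self.windows[i].regions),
        )
        kept: list[int] = []
        covered: set[int] = set()
        for i in order:
            regs = self.windows[i].regions
            if covered.isdisjoint(regs):
                kept.append(i)
                covered.update(regs)
        return kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regions": [w.regions for w in self.windows],
                "n_regions": [len(w) for w in self.windows],
                "size_frac": [w.size_frac for w in self.windows],
                "llr": self.llr,
                "p_value": self.p_values,
            }
        )


def membership_matrix(windows: Sequence[Window], n_regions: int) -> np.ndarray:
    """Boolean window-by-region membership matrix."""
    W = np.zeros((len(windows), n_regions), dtype=bool)
    for i, w in enumerate(windows):
        W[i, list(w.regions)] = True
    return W


def scan_once(
    cases: CaseTable,
    windows: Sequence[Window],
    replications: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> ScanResult:
    """Scan all candidate windows and run the Monte Carlo null.

    Null datasets permute category labels over cases with both margins fixed
    (multivariate hypergeometric tables via :func:`scipy.stats.random_table`);
    each replicate records the maximum statistic over the same window family,
    which is valid because the permutation preserves per-region totals and
    hence window sizes.  The p-value of every candidate is
    ``(1 + #{replicate maxima >= its llr}) / (R + 1)``.
    """
    if replications < 1:
        raise ValueError("need at least 1 Monte Carlo replication")
    if len(windows) == 0:
        raise ValueError("no candidate windows to scan")
    rng = np.random.default_rng(seed)
    Ck = cases.category_totals.astype(float)
    C = float(cases.total)
    W = membership_matrix(windows, cases.n_regions)
    A_obs = W @ cases.counts
    llr = llr_matrix(A_obs, Ck, C)

    dist = stats.random_table(cases.region_totals, cases.category_totals)
    null_tables = dist.rvs(replications, random_state=rng)
    null_tables = null_tables.reshape(replications, cases.n_regions, cases.n_categories)
    # batched (R, n_windows, K) inside counts, chunked to bound peak memory
    Wf = W.astype(np.float64)
    null_max = np.empty(replications)
    chunk = max(1, int(4e7 // max(1, W.shape[0] * cases.n_categories)))
    for start in range(0, replications, chunk):
        tables = null_tables[start : start + chunk].astype(np.float64)
        A_null = np.matmul(Wf, tables)  # (r, n_windows, K) via batched BLAS
        null_max[start : start + chunk] = llr_matrix(A_null, Ck, C).max(axis=1)

    exceed = (null_max[None, :] >= llr[:, None] - 1e-12).sum(axis=1)
    p_values = (1.0 + exceed) / (replications + 1.0)
    return ScanResult(
        windows=list(windows),
        llr=llr,
        p_values=p_values,
        null_max_llr=null_max,
        alpha=alpha,
        seed=seed if isinstance(seed, (int, np.integer)) or seed is None else None,
        cases=cases,
    )


def report_at_mrcs(
    result: ScanResult, m: float, alpha: float | None = None
) -> list[ClusterReport]:
    """Significant non-overlapping clusters at a maximum reported size of m%.

    Candidates are restricted to windows holding at most ``m`` percent of all
    cases, re-ranked greedily for non-overlap within that restriction, and
    filtered at level ``alpha``.  Small windows shadowed by a large cluster at
    the default setting can therefore surface at small ``m``.
    """
    if not (0 < m <= 50):
        raise ValueError("the reported-cluster size bound must be in (0, 50] percent")
    if alpha is None:
        alpha = result.alpha
    kept = result.ranked_nonoverlapping(max_size_frac=m / 100.0)
    reports = []
    for rank, i in enumerate(kept, start=1):
        if result.p_values[i] > alpha:
            continue
        w = result.windows[i]
        regs = np.asarray(w.regions)
        n_cases = int(result.cases.counts[regs].sum())
        reports.append(
            ClusterReport(
                window=w,
                llr=float(result.llr[i]),
                p_value=float(result.p_values[i]),
                size_frac=w.size_frac,
                n_cases=n_cases,
                rr=tuple(relative_risks(w, result.cases)),
                rank=rank,
            )
        )
    # ranks re-numbered over the significant subset, ordered by llr
    return [
        ClusterReport(
            window=r.window,
            llr=r.llr,
            p_value=r.p_value,
            size_frac=r.size_frac,
            n_cases=r.n_cases,
            rr=r.rr,
            rank=j,
        )
        for j, r in enumerate(reports, start=1)
    ]
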