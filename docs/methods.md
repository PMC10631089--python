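# Methods

## Model

For a study region partitioned into `n` areas with planar centroid
coordinates, the data are counts `c_ik` of cases of category `k` (of `K >= 2`
nominal categories) in area `i`. Under the null, every area draws categories
from one shared distribution; the alternative is that some zone `z` has a
different category distribution inside than outside. For a candidate zone the
test statistic is the multinomial log likelihood ratio

    log lambda_z = sum_k [ a_k log(a_k/A) + b_k log(b_k/B) ]
                   - sum_k C_k log(C_k/C)

with inside counts `a_k` (total `A`), outside counts `b_k = C_k - a_k`
(total `B = C - A`), and the convention `0 log 0 = 0`. The statistic is
nonnegative, zero exactly when the inside and outside proportions coincide,
symmetric between a zone and its complement, and invariant to category
relabeling. Degenerate windows (all cases or none) are assigned 0 — they
carry no contrast.

## Window enumeration

Candidate zones are generated by centering a metric at each region and
accumulating regions nearest-first. Circles use the Euclidean metric; an
ellipse of axis ratio `s` at orientation `theta` uses
`sqrt(x'^2/s + y'^2 * s)` in the rotated frame, whose scale factors multiply
to one so that equal metric radii enclose equal areas across shapes. Every
prefix whose case fraction is at most the maximum scanning window size
(MSWS, default 50% of cases) becomes a window; duplicates (same region set
from different geometries) are dropped; distance ties break by region index
so enumeration is deterministic. The default battery is the circle plus axis
ratios {1.5, 2, 3, 4, 5} with {4, 6, 9, 12, 15} evenly spaced orientations —
standard elliptic-scan practice; it is fully configurable. No
non-compactness penalty is applied to elongated windows. MSWS above 50% is
rejected: any larger window repeats the complementary test and inflates the
multiple-testing burden.

Window size is measured as a fraction of total cases. The multinomial model
has no separate population at risk; observed cases are the only universally
available denominator. A population column, when supplied, is carried on the
region map and can drive case allocation in simulations.

## Inference

Significance uses Monte Carlo randomization conditioning on both margins:
null datasets are multivariate-hypergeometric tables with the per-region
totals `c_i` and per-category totals `C_k` fixed (drawn via Patefield's
algorithm, `scipy.stats.random_table`). Because `c_i` is preserved, window
sizes — and hence the window family — are identical in every replicate, and
each replicate records the maximum statistic over that family. A candidate's
p-value is `(1 + #{replicate maxima >= its statistic}) / (R + 1)`; secondary
clusters are compared against the same max-statistic null distribution (the
conservative, standard scan convention). Defaults: `R = 999`,
`alpha = 0.05`.

## Reporting at a maximum reported cluster size (MRCS)

The scan runs once at the MSWS; only reporting varies with the MRCS `m`.
Candidates are first restricted to case fraction `<= m/100`, then ranked
greedily by descending statistic keeping only windows disjoint from all kept
windows, then filtered at `alpha`. Restricting *before* ranking lets small
windows shadowed by one large cluster at the default setting surface at
small `m` — the mechanism the selection criteria exploit.

## Selection criteria

For each `m` on the candidate grid (default
{1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 35, 40, 45, 50} percent) let
`Z_1 ... Z_Jm` be the significant clusters, `tau` their total cases, `delta`
their total regions.

- `SCIC_1(m) = -2 sum_j log lambda_j + K * J_m * log(tau)`; `SCIC_2` uses
  `delta` instead of `tau`. Minimized. With no significant clusters the
  value is undefined and excluded from the arg-min — treating the empty sum
  as 0 would make "no clusters" always optimal.
- Elbow: points `(m, -sum_j log lambda_j)`; when no cluster is significant
  at `m` the maximum statistic among windows within the size bound stands in
  (0 if no window fits). The selected `m` maximizes perpendicular distance
  to the chord through the first and last grid points.
- MCS-P: union log likelihood ratio treating the union of all significant
  clusters as a single homogeneous zone; maximized.
- MCHS-P: clusters are first merged into connected groups under the region
  adjacency relation (connected components of the cluster-level contact
  graph); each group contributes its own inside term while the outside is
  pooled; maximized. Adjacency comes from the user's edge list; for lattice
  geographies the generator provides rook adjacency.

The union statistic is defined so that a single group holding exactly one
cluster reproduces that cluster's `log lambda_z` (the null log-likelihood
term enters with a minus sign, keeping the union and single-window
statistics on one scale); with one connected group the heterogeneous and
homogeneous versions coincide. Ties everywhere break toward the smallest `m`
(parsimony). When no grid value yields any significant cluster, selection
returns none — the criteria never manufacture clusters.

The elbow profile sums *log* likelihood ratios rather than raw likelihood
ratios: raw `lambda` overflows at realistic statistics (log lambda > 700)
and reported scan statistics are conventionally on the log scale.

## Synthetic-data generator

`make_grid_geography(n_side)` builds an `n_side x n_side` lattice with rook
adjacency — a stand-in for an irregular administrative map (the default 8x8
= 64 regions approximates a ~69-district provincial study region). Planted
clusters are: circular — nearest regions to a deterministic anchor;
elliptic — nearest under an elongated metric (axis ratio 3, horizontal);
irregular — a seeded random contiguous walk. Cluster size is the stated
fraction of regions rounded to nearest (8% of 64 regions = 5; 15% = 10).
Each dataset spreads a fixed case total (default 1000) over regions
(uniform allocation by default; population-proportional optionally) and
draws each region's categories from `p0 = (0.25, 0.25, 0.25, 0.25)` outside
clusters and the scenario's `p1`/`p2` inside. The crossed design — three
single-cluster models (circular 8%, elliptic 8%, irregular 15%) x four
alternatives, plus two two-cluster models x (four homogeneous + three
heterogeneous) settings — yields 26 scenarios.

What the generator does *not* emulate: irregular region shapes and unequal
district populations, spatial autocorrelation in the background rates, and
overdispersion. Passing tests therefore demonstrate correctness of the
machinery and of the selection behavior under clean multinomial sampling,
not performance on any particular real map.

## Accuracy scoring

With detected set `D` (union of reported clusters) and true set `T` (union
of planted clusters): sensitivity `|D∩T|/|T|`, PPV `|D∩T|/|D|` (undefined
when `D` is empty, excluded from averages), misclassification
`(|D\T| + |T\D|) / n_regions`. The total-region denominator is the default
because it keeps misclassification bounded by the combined cluster share of
the map even when detection fails entirely; `|D∪T|` is available as an
option. Summary tables report, per method, the selection frequency of each
grid value and the mean accuracy among datasets selecting it, plus a
"default" column (every dataset scored at 50%) and an "overall" column
(every dataset scored at its own selected value); averages cover only
datasets with at least one significant cluster. Two-cluster scenarios score
the union by default and also record per-cluster sensitivities.

## Reproducibility and problem sizes

One master seed spawns an independent stream per simulated dataset (each
split again for data generation and the Monte Carlo null), so replicates
are reproducible in isolation and summaries are bytewise identical across
runs. The bundled validation runs use study sizes chosen to keep a desk
check quick: 200 null datasets and 100 planted-cluster datasets with
`R = 99` Monte Carlo replications, scanning circles for the null-calibration
check and the {1, 2, 3} x {1, 6, 9} shape/angle battery for the recovery
study (the axis-ratio-3 ellipse matches the planted elongation). With a
5-of-64-region planted cluster the expected case share (7.8%, sd 0.85%)
lies against the 8% grid point, so in the roughly 40% of datasets where the
cluster's realized share exceeds 8% the full cluster cannot be reported at
that bound and selection moves to 10%. Per-dataset selection therefore
concentrates on the adjacent 8% and 10% grid values in near-equal
proportion (8% slightly ahead when batches are pooled), and which of the
two is modal in any single 100-dataset batch depends on the seed.

## Numerical choices and edge cases

- `0 log 0 = 0` throughout (`scipy.special.xlogy`); statistics clamped at 0
  against rounding.
- Relative risks: 0 when a category is absent inside; `inf` when present
  inside but absent outside.
- Greedy non-overlap ranking breaks statistic ties by fewer regions, then
  lexicographic region tuple — fully deterministic.
- A singleton region whose case share alone exceeds the MSWS is excluded
  (strict rule, no special case).
- Monte Carlo p-values live on `{1/(R+1), ..., 1}`; comparisons use a
  `1e-12` slack so equal statistics count as ties.
- Criterion comparisons treat values within `1e-9` as tied (smallest `m`
  wins).

## Known limitations

- Coordinates are assumed planar/projected; no geodesic support.
- No covariate adjustment and no space-time scanning; the likelihood is the
  single model-specific plug point.
- Secondary-cluster p-values against the max-statistic null are
  conservative.
- The MCHS-P contact computation is quadratic in the number of reported
  clusters (harmless at realistic cluster counts).
- Irregular planted clusters depend on the walk seed; two-cluster
  placements use fixed opposite-corner anchors and may fail on very small
  maps.
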