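# Methods

## Data model

A measurement is a dense grid `intensity[n_rt, n_ik0]` with strictly
ascending physical axes: retention time in seconds (multi-capillary
column) and inverse reduced mobility 1/K0 in Vs/cm² (drift tube,
pressure/temperature normalised). All public coordinates are physical
units; grid indices stay internal, because clustering across
measurements with different grid resolutions only makes sense in
physical coordinates. Files are headered delimited text (first row =
1/K0 axis, first column = retention axis, corner cell an axis tag); a
transposed dialect and descending axes are normalised on read.
Zero-sized grids are rejected everywhere — an empty spectrum has no
meaning.

## Preprocessing

**Noise model.** Background level is estimated robustly as
`median + k · 1.4826 · MAD` over all cells (default k = 3, the
conventional three-sigma rule). Peaks occupy a small fraction of cells,
so both statistics are background-dominated; a single huge spike moves
the level by well under 1%.

**RIP compensation.** The reactant ion peak — ionised carrier gas — is
a high-intensity band at fixed drift position, constant across
retention times. The band is located as the argmax of column-wise
median intensity, extended over contiguous columns whose median exceeds
50% of that maximum. Within the band, each column's 25th percentile
across rows is taken as the RIP profile and subtracted, clamped at
zero: a robust per-column baseline removes the retention-invariant
artifact without erasing analyte peaks riding on it. Columns outside
the band are untouched.

**Smoothing.** Separable Savitzky-Golay filtering along both axes
(default window 5, order 2), nearest-edge extension at the borders so
no spurious curvature is introduced for the Laplacian picker. The
filter is linear and reproduces polynomial surfaces up to its order
exactly on interior cells — the basis of the analytic tests.

The pipeline order is RIP → smooth → pick; both steps are individually
switchable in configuration.

## Peak picking

All pickers run on the preprocessed grid and return peaks whose
position and intensity are those of a grid cell.

**RIP masking.** Rather than masking only the detected band, the
pipeline masks from candidacy every column whose median (of the
preprocessed grid) exceeds the noise level: an analyte peak spans a few
dozen rows out of hundreds and cannot raise a column median, so a high
median identifies retention-invariant structure — band residues and
uncompensated RIP tails alike.

**Relative floor.** All picker thresholds are floored at 1% of the
grid maximum (`rel_floor`). On normally noisy data the noise level
dominates and the floor is inactive; on an (exactly) noise-free grid
the MAD level is 0 and without a floor the pickers would promote
floating-point crumbs in far peak tails — and PDSA would chain distinct
peaks through their vanishing tails. One percent is far below any
plausible analyte amplitude ratio in these data.

**LM** — cells strictly exceeding the threshold and all eight
neighbours (exact-tie plateaus yield no candidate, the literal reading
of "exceeds"). Candidates within 3 grid cells (Chebyshev) are merged by
the weighted cluster-editing solver (weight = radius − distance); each
clique is represented by its highest-intensity cell. The threshold is
user-specified; when omitted, the estimated noise level is used.

**SGLTR** — curvature response `R = −(d²/drt² + d²/dik0²)` estimated by
SG second-derivative filters (default window 9, order 2), in grid-cell
units so the response scale is resolution-independent. Peak regions are
8-connected components (diagonal ridge continuity) of cells with
`R > noise_level(R)` **and** `intensity > noise_level(intensity)`;
regions smaller than 5 cells are dropped (a genuine smoothed peak
always covers several cells; singleton regions are noise coincidences).
Each region yields one peak at its maximum-intensity cell with the
region bounding box. On a unit grid the response of the paraboloid
−(r² + d²) is exactly 4.

**PDSA** — an online method: each drift spectrum (row) is scanned with
a sliding window (default 5 cells); a window is a segment when its
intensity sum is a local maximum over ±1 shifts and exceeds
window × noise level. Plateau ties keep the leftmost window — an apex
exactly between two columns otherwise produces two equal sums and no
strict maximum. Overlapping segments in a row are resolved by score.
Segments in adjacent rows chain when their drift intervals overlap by
at least half a window (the original merging criteria are not public;
this overlap rule is a documented, configurable stand-in). Each chain
gives one peak at its maximum-intensity cell; the bounding box is the
union of member segments.

## Peak clustering

Distances mix seconds and Vs/cm², so DBSCAN, CE and EM work in
normalised coordinates (class `Scaling`):

    d(u,v) = sqrt( (Δik0 / tol_ik0)² + (Δrt / (tol_rt_abs + tol_rt_rel · mean rt))² )

with defaults tol_ik0 = 0.003 Vs/cm², tol_rt_abs = 3 s,
tol_rt_rel = 0.01. The relative retention term reflects that retention
spread grows along the column. These scales are instrument-dependent
and fully configurable.

**GS** — rectangular binning (origin anchored at the global minimum
peak position for reproducibility); cells with ≥ min_count peaks give a
consensus at the mean member position, the rest is noise.

**DBSCAN** — standard density clustering on the normalised distance
matrix; peaks are processed in sorted id order so border-point
assignment is deterministic. Consensus = cluster centroid; unclustered
peaks are noise.

**CE** — weighted cluster editing: edge weight `threshold − d`,
objective = sum of |w| over deleted positive and inserted negative
edges. Connected components of the positive graph are independent;
components up to 12 peaks are solved exactly by branch-and-bound over
set partitions (the incumbent is seeded by a greedy agglomerative
heuristic, which also handles larger components). Twelve keeps the
worst-case Bell number (~4.2 M) tractable.

**EM** — mixture of axis-aligned Gaussians with *known* standard
deviations (default σ_rt = 3 s, σ_ik0 = 0.003 Vs/cm²): the E/M steps
update only means and mixture weights. Initialisation is a
deterministic coarse GS pass (cell 2σ, min_count 1), an overestimate of
K; after each iteration components closer than `merge_dist` (default 2,
in σ units — two components within two standard deviations describe the
same analyte) are merged with weight-averaged means, and components
whose weight falls below 20% of the uniform share 1/K are annihilated,
so single-outlier components do not survive as spurious consensus
peaks. Convergence: log-likelihood change < 1e-8 (checked only in
iterations without a merge) or 200 iterations, with a warning on
non-convergence. Assignment is by maximum responsibility; consensus
positions are the component means.

## Feature matrix

Entry (i, j) is the intensity of measurement i's peak nearest to
consensus j, provided the normalised distance is at most
`assign_radius` (default 1.0 — the tolerance ellipse); otherwise 0.
Zero encodes absence deliberately: no detected signal means no measured
analyte response. No cross-measurement intensity normalisation is
applied.

## Classification benchmark

Repeated stratified 10-fold cross-validation, 50 repetitions;
repetition r splits with seed `base_seed + r`. Classifiers with
hyperparameters are tuned per outer fold by an inner stratified 10-fold
CV **on the outer training set only**; the grid point with the best
mean inner AUC wins (first in deterministic grid order on ties). One
AUC per repetition is computed from the pooled out-of-fold scores —
with only 3–4 positives per fold, per-fold AUCs would be unstable.

Fixed choices: random forest 500 trees with √p candidate variables per
split and no tuning; GBM subsamples 50% of observations per boosting
iteration. Tuning grids (conventional ranges, configurable): SVM cost
{0.1, 1, 10, 100}, RBF γ ∈ {0.1, 1, 10}/p, kNN k ∈ {1, 3, 5, 7, 9, 15},
tree complexity (cost-complexity α) {0.001, 0.01, 0.1}, GBM trees
{50, 100, 500} × depth {1, 2, 3} × shrinkage {0.01, 0.1}. The
distance-based classifiers (SVMs, kNN) are standardised per training
fold; tree ensembles are scale-invariant and left raw. The class score
for AUC is the case-class probability, or the decision value for SVMs.

**Rank aggregation.** Per dataset, pipelines are ranked by median AUC
(rank 1 = best); ties share the minimum rank — the simplest reading
consistent with published tables of this design, where distinct
pipelines can occupy the same rank. A pipeline's rank sum across
datasets orders the final report, alongside the arithmetic mean of its
per-dataset median AUCs. For comparing clustering methods within a
picker, the ranks across the six classifiers are summed and divided by
the minimum possible rank sum (six — a method that wins under every
classifier scores exactly 1; with R competing clusterers the score lies
in [1, R]).

**Design enumeration.** The registry declares 6 pickers, 6 clusterers
and 6 classifiers with two feasibility rules (VisualNow clustering only
after VisualNow picking; the manual combined approach pairs only with
itself): 26 picker×clusterer combinations, 25 automated, 156 pipelines,
150 automated. VisualNow (commercial), the manual approach and the
model-based PME/OPME pickers are registry entries only, so the
bookkeeping covers the full design while the package implements the
three fully specified pickers and four clusterers.

## Synthetic cohorts

`generate_cohort` draws a two-class cohort deterministically from a
seed. Each measurement is: RIP band (Gaussian drift cross-section,
constant over retention) + one axis-aligned 2-D Gaussian per present
analyte (optional exponential retention tailing) + i.i.d. Gaussian
detector noise clamped at zero. True analyte positions are sampled
uniformly with a minimum pairwise separation (8 peak-σ) and clear of
grid margins and the RIP band; per measurement, each analyte is present
with probability 1 − dropout, its position jittered (σ 1 s / 0.001
Vs/cm²) and its amplitude multiplied by a mild lognormal subject effect
(log-σ 0.2). Per-analyte base amplitudes are lognormal with median 20×
the noise σ; differential analytes are scaled by the effect size
(default 2-fold) in cases only.

Defaults — 30 + 30 subjects, 20 shared + 5 differential analytes on a
600 × 400 grid (0–300 s, 0.4–1.0 Vs/cm²) — give ~25 peaks per
measurement, inside the 10–60 range reported for real devices, at a
desk-scale grid. A warning is raised if the drawn positions come closer
than 3 grid cells, where no picker can resolve them.

What the generator does **not** emulate: ion chemistry (monomer/dimer
peaks, competitive ionisation), humidity and temperature drift,
retention-time warping between measurements (jitter is i.i.d., not
monotone drift), and heavy-tailed detector artifacts. Passing tests
therefore demonstrate algorithmic correctness under the stated model,
not clinical performance.

`truth_match` scores any detection set against truth by greedy
one-to-one matching in ascending elliptical distance
(`sqrt((Δrt/rt_tol)² + (Δik0/ik0_tol)²) ≤ radius`); with zero
detections, precision is reported as 1.0 with a `zero_support` flag
(no false positives, but no evidence either).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is meaningfully
exercised: oracle comparisons on ≤ 20-peak (DBSCAN) and 8-peak (cluster
editing, 4140 partitions) instances over 50 seeds; recovery on
150 × 100 grids with 6 peaks over 100 seeds; classification sanity at
n = 30, p = 5 with the full 50 repetitions; the winning-pipeline
benchmark on the full default cohort with 10 repetitions. Ties are
broken deterministically throughout (sorted peak ids, leftmost plateau
element, first grid point); all randomness flows from explicit seeds.

## Known limitations

- The exact cluster-editing solver is exponential; components above
  `exact_limit` fall back to the greedy heuristic, which can be
  suboptimal (never better than exact — asserted in tests).
- EM with fixed sigmas mis-specifies clusters whose true spread differs
  strongly from the configured σ; merge/annihilation thresholds trade
  split clusters against lost rare analytes.
- The GS consensus position is the mean of in-cell members only; a
  cluster straddling a cell boundary may be split (inherent to the
  method).
- Pipelines are evaluated with peak picking and clustering performed
  once on the full cohort, outside the CV loop — feature definition is
  unsupervised (labels never enter picking/clustering), but fold-level
  feature redefinition is deliberately not attempted.
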