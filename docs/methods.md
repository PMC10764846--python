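# Methods

This note documents the models and procedures `collatil` implements, the
parameters that matter, the synthetic data the test suite runs on, and the
design choices made where the design was genuinely open.

## Coordinate and unit conventions

Pixels are 0-based; `x` is the column index (rightward), `y` the row index
(downward). Fiber orientations θ ∈ [0°, 180°) are measured counterclockwise
from +x on the conventionally displayed image (y up); the detector converts
from the y-down gradient frame internally. All geometry is computed in
pixels; thresholds given in microns are converted through
`microns_per_pixel` (default 0.25, i.e. 40× magnification; 20 µm → 80 px).
Tile size is not enforced — any tile at least as large as the largest
analysis window is accepted.

## Collagen fiber orientation disorder

**Orientation estimation.** The first derivative of a Gaussian is steerable:
the response of the filter oriented at angle a is cos(a)·Gx + sin(a)·Gy, so
the K-orientation bank needs two convolutions regardless of K. Per pixel the
bank's argmax over K = 12 equally spaced orientations (15° steps) gives the
gradient direction; the fiber axis is that direction rotated 90°. Defaults:
σ = 2 px (matches fiber widths of a few pixels at 0.25 µm/px; larger σ blurs
crossing fibers together), K = 12 (the smallest bank resolving 15° steps).
Fibers are the stromal pixels whose maximal absolute response exceeds the
0.75 quantile of stromal responses, subsampled on a 4-px lattice. The
quantile makes the detector contrast-invariant; the lattice bounds the
downstream O(n²)-pair work and keeps it deterministic. Nothing defines a
fiber "atom" uniquely in this setting; pixel samples of the orientation
field are the simplest choice and every downstream statistic only needs an
orientation sample with positions.

**Co-occurrence and entropy.** For every unordered pair of fibers within
`pair_radius` (default 50 px) the B×B count matrix is incremented
symmetrically (B = 36 bins of 5°; bin(θ) = ⌊θB/180⌋ with 180° wrapping to
bin 0). Entropy is Shannon entropy of the normalized matrix in bits (log
base 2; bits are conventional), 0 for an empty matrix, at most 2·log₂B.
Whether pairing should be radius-limited or all-pairs within the window is
an open choice; radius-limited is the default and `pair_radius=inf` gives
all-pairs.

**Feature maps.** Windows are non-overlapping, anchored at the tile origin;
partial edge windows are discarded (the literal reading of dividing a tile
into an array of neighborhoods). Windows with fewer than `min_fibers = 10`
fibers are skipped and counted. Per patient, windows are pooled across all
tiles per window size *before* taking mean/min/max — min and max are only
meaningful over the pooled set; per-tile-then-average would dilute them.
The eight emitted features are mean/min@200, max@250, min@350/400/450,
max@550/600 (pixels). A window size with zero evaluated windows yields NaN
and the patient is mean-imputed (and logged) at model time.

## TIL architecture

Nuclei take their compartment from the mask value at their centroid pixel.
The **invasive tumor front** is defined here as all tissue pixels within
`front_band_um = 100` µm of the epithelium–stroma contact layer, on both
sides, computed by a Euclidean distance transform of the contact set; the
band width is exposed in config because no canonical definition exists.

**Clusters** are connected components of the graph joining same-class nuclei
within `link_radius_um = 30` µm (20 µm is reserved for "surrounding"
proximity ε; the link radius is a separate knob). Singletons are size-1
clusters of area 0; hull areas come from the convex hull (collinear → 0).
Cluster-to-cluster distance is the minimum member-centroid distance — robust
for size-1/2 clusters that have no hull. A cluster belongs to the invasive
front when at least half its members do (a deterministic majority rule).

Feature interpretations where the written definitions are ambiguous, each
isolated in one function so alternates can be swapped:

- *non-TIL to surrounding TILs ratio* (epithelium): count of epithelial
  non-TILs divided by the count of TILs within ε of at least one of them,
  with a max(·, 1) guard on the denominator; 0 without epithelial non-TILs.
- *TIL clusters near a non-TIL cluster* (epithelium): mean over non-TIL
  clusters of the number of TIL clusters within ε.
- *presence percentage* (stromal non-TIL): fraction of clusters with another
  such cluster within ε; 0 with fewer than two clusters.
- Features 1–3 are computed tile-wide (the front restriction is explicit
  only for features 4–6); a front-only switch exists.
- *intersected area*: summed pairwise convex-hull intersection areas of
  in-front epithelial TIL × non-TIL clusters (shapely polygon clipping).
- *area statistics* consider clusters of size ≥ 3 only.

TIL density is TILs / all nuclei among stromal invasive-front nuclei, NaN
when that denominator is empty. Per-patient values are means over tiles with
non-missing values.

## Risk model

Features are z-scored with training means/SDs; missing values are imputed
with training means (logged, never silent); constant features are dropped
with a zero coefficient. The elastic-net Cox fit (L1 fraction
`alpha_ratio = 0.5`, Breslow ties) goes through scikit-survival's coordinate
descent; λ is chosen from a 30-point data-driven path by 5-fold
cross-validated Breslow partial log-likelihood with seeded fold assignment
(folds without enough events are skipped). `lambda_grid=[0]` fits the
unpenalized model. The risk score is the linear combination of z-scored
features; validation cohorts reuse the *training* standardization constants
and the *training* mean-score threshold (a per-cohort-mean mode exists
behind `threshold_mode="cohort_mean"` because "mean threshold" admits both
readings). Ties at the threshold go to low risk — arbitrary but fixed.

Group statistics: Kaplan–Meier product-limit curves and the two-sided
log-rank test; the univariable Cox hazard ratio with Wald 95% CI
(exp(β ± 1.96·SE)); Harrell's c-index with 0.5 for score ties and standard
censoring comparability (an event tied in time with a censored subject is
comparable). A group without events triggers the monotone-likelihood flag
and an unbounded CI instead of a spurious estimate. Risk-group value
comparisons use the two-sided Mann–Whitney rank-sum test: the compared
groups are independent patients, so a signed-rank (paired) test is not
applicable even where the name appears in that context.

## Genomic procedures

**Variant classification.** Mut if *any* annotation of a unique mutation is
non-synonymous (Missense, Frame-shift del/ins, Nonsense, In-frame del/ins,
Splice site, Translation start site, Nonstop); Wt only if all annotations
are synonymous (Silent, 3′/5′ UTR, RNA, Intron, 3′/5′ Flank). Unicode primes
are normalized to ASCII to tolerate MAF dialects; unrecognized strings raise
rather than being dropped.

**Depth/VAF filter.** A record is removed iff tumor depth < 30 OR normal
depth < 30 OR tumor VAF < 0.1 OR normal VAF > 0.05. The compound sentence
defining the rule admits more than one bracketing; removal on *any*
condition is the reading consistent with excluding likely false positives,
and equality passes under the strict "less/greater than" wording.

**Hypermutation.** Per cohort, samples with more retained mutations than
Q3 + 1.5·IQR are excluded; quartiles use linear interpolation between order
statistics (numpy's default; the convention is exposed). Counts are taken
*after* the depth/VAF filter by default (switchable), and cohorts under 4
samples are left untouched. Both choices are logged.

**ssGSEA.** Genes are ranked by descending expression with lexicographic
tie-breaks; rank-normalized values z = N…1 weight in-set genes as
z^exponent (default 0.25), the out-of-set CDF is uniform, and the score is
the running-sum difference summed over the ranking and divided by N so
values are comparable across set sizes. A set covering every profiled gene
is rejected (the out-of-set CDF is undefined).

## Synthetic data

The generator produces every input with known ground truth, at desk scale:

- **Tiles** (default 600×600 px, ≥ the largest entropy window, so a cohort
  renders in seconds; 3000×3000 works but is unnecessary for testing): one
  smooth epithelial blob (~a quarter of the tile), stroma elsewhere;
  anti-aliased bright line segments (20–40 px, ~15 000/mm² of stroma) at
  orientations drawn from an axial von Mises distribution — von Mises on the
  doubled angle, halved, the standard axial-statistics construction — with a
  per-patient concentration κ ~ U(0, 16) spanning fully disordered to
  strongly aligned collagen.
- **Nuclei**: a Thomas cluster process per compartment (parents Poisson at
  2 500/mm², ~7 Gaussian offspring with 12 px spread, thinned to the mask),
  TIL labels Bernoulli with a per-patient stromal TIL fraction
  ~ U(0.05, 0.65) and 0.15 in epithelium. At this tile size that yields a
  few hundred nuclei per tile — enough for every cluster feature to be
  exercised while keeping tests fast.
- **Survival**: event times exponential with rate λ₀·exp(risk), λ₀ = 0.02
  per month, where risk rises with collagen order (+0.8 per SD of log(1+κ))
  and falls with the stromal TIL fraction (−0.8 per SD) — the direction in
  which ordered collagen and immune exclusion are adverse. Censoring is
  uniform with its horizon calibrated by bisection to a 30% censored
  fraction.
- **Fixtures**: a MAF spanning every filter boundary (depths 29/30/31,
  tumor VAF 0.09/0.10/0.11, normal VAF 0.04/0.05/0.06, a multi-annotation
  locus, a planted hypermutated sample over a background whose counts are
  spread widely enough that only the plant exceeds the IQR cutoff), and an
  expression matrix with one gene set shifted +2 SD.

Everything is deterministic given the master seed (integer-keyed
`default_rng` streams per patient/tile; no hash-order dependence).

What the generator does **not** emulate: stain variation and color, nucleus
morphology, segmentation errors, fiber curvature and crossings, spatial
correlation between TIL infiltration and collagen alignment within a tile,
and cohort-level clinical covariates. Passing tests therefore demonstrate
that the feature definitions, model fitting and statistics are implemented
correctly and recover planted structure — not that the signature is
prognostic on real slides.

## Numerical choices and degenerate inputs

- Entropy of an empty co-occurrence matrix is 0; windows below `min_fibers`
  are skipped, not scored.
- Epithelium/stroma mask overlap is resolved to epithelium with a logged
  count; empty stroma yields no fibers plus a warning; empty compartments
  yield NaN densities.
- Collinear clusters get hull area 0 (Qhull failure handled explicitly).
- CV folds with fewer than 2 training or 1 test event are skipped; λ is
  chosen among candidates evaluated on the maximal number of folds.
- All-tied rank-sum comparisons return p = 1 with a warning rather than NaN.
- The acceptance script uses a 40-patient training and 30-patient validation
  cohort at 2 tiles each: large enough that cross-validated λ selection is
  stable (at 20 patients the selected model occasionally shrinks to zero —
  a property of CV on tiny cohorts, not of the implementation), small
  enough to run in about a minute.

## Known limitations

- The orientation bank quantizes to 15° steps; sub-step orientation accuracy
  is limited by design (B = 36 bins downstream are coarser still).
- Tiles are treated independently; no coordinates map back to slide space.
  All features are tile-local then patient-aggregated, so nothing requires
  the mapping.
- The per-window pairing cost grows quadratically with fiber density; the
  4-px sampling lattice is the guard. Extremely dense stroma may warrant a
  coarser lattice.
- EVG/IHC-stained or second-harmonic imagery, fiber tracing and length
  statistics, and macrophage or other immune subtypes are out of scope.
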