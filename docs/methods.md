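# Methods

This note documents the models, defaults and numerical choices behind
`kogbody`, and what the synthetic-data generators do and do not emulate.

## Band-shift scoring

A gel lane is reduced to a 1-D profile by averaging signal across the lane
width at each migration position; index 0 is the top of the gel, where the
slowest (most phosphorylated) species sit. The score of a profile *I* of
length *n* is the weighted sum Σᵢ wᵢ·Iᵢ with wᵢ interpolating linearly from
`weight_top` (default 100) at the first pixel to `weight_bottom` (default 0)
at the last, endpoints inclusive. Although such a statistic is often called
a position-weighted *mean*, the weighted sum of total-normalized intensities
is implemented literally: after each lane is rescaled so its total signal
matches the designated *t* = 0 reference lane, sums and means differ only by
the fixed total, and the sum keeps raw scores in transparent weight units.

Batch normalization is a two-point affine map: scale = 1/(raw_high −
raw_low), offset = −raw_low/(raw_high − raw_low), so the designated high
anchor (wild type in 2% glucose) maps exactly to 1.0 and the low anchor
(wild type at 60 min in 0% glucose) to 0.0. The same constants rescale every
lane in the batch, error bars included. Normalized scores are deliberately
not clamped to [0, 1]: the map is affine and values slightly outside the
anchors are informative drift, not errors. Background subtraction (constant
per-lane minimum) is available but off by default, and total-signal
normalization is per-batch (per-gel); neither choice has a field-standard
alternative and both are exposed.

Lane boundaries are caller-supplied (profiles or pixel windows); no
automatic lane finding or gel-warp correction is attempted.

## Kinetics

Per timepoint, the body-positive fraction is averaged across replicates
(sample SD with n−1 denominator; SD is reported missing for a single
replicate). The replicate-mean series is fit by unweighted nonlinear least
squares to

* formation: f(t) = A·(1 − e^(−t/τ)) + c
* dissociation: f(t) = A·e^(−t/τ) + c

with A, c ∈ [0, 1] and τ ∈ (0, 10·t_max]. A is the fraction of cells that
change state during the time course, τ the apparent time constant in
minutes, c the baseline fraction (start of a formation course, end of a
dissociation course). Fitting weights means rather than pooled counts,
matching how replicate-averaged figures are fit; per-point binomial
weighting would be a different estimator and is intentionally not the
default. Optimization is bounded trust-region least squares with
multi-start initialization at τ₀ ∈ {t_max/10, t_max/3, t_max} (A, c seeded
from the endpoint fractions); the best residual sum of squares wins, making
convergence reproducible. Standard errors are square roots of the diagonal
of the fit covariance. A constant series is not an error: it converges with
A ≈ 0, leaving τ unidentifiable (huge se_tau), which callers should treat
as "no kinetics". Conditions with no change are instead fit to an ordinary
least-squares line, again by caller choice; an F-test comparing the
exponential against the line is provided for exploration but never applied
automatically.

Monte-Carlo calibration (in the test suite) uses the design of the emulated
experiments: 3 replicates, 200 cells per timepoint, formation truth
(A = 0.49, τ = 11 min, c = 0.08) on the grid {0, 5, 10, 15, 20, 30, 45, 60}
min and dissociation truth (A = 0.5, τ = 48 min, c = 0.05) on
{0, 10, 20, 30, 45, 60, 90, 120} min. The dissociation grid is this
package's choice: it spans ≈2.5τ, the horizon over which repletion
experiments resolve the decay. Across 1000 simulated experiments the median
τ̂ lands within 10% of truth and τ_true falls inside τ̂ ± 3·se in ≥95% of
runs.

## Q/N motif analysis

Q/N composition of an interval is an exact count: residues ∈ {Q, N} over
the interval length, percentage to two decimals in reports. `X` and any
non-Q/N character count toward length, never toward the tally, so
percentages are conservative. Published quantitation tables give
(count, rounded percent) pairs without coordinates; the helper
`interval_length_from_report` brute-forces the interval lengths consistent
with such a pair, which is usually unique (e.g. 28 residues at 35.90% forces
length 78).

The scanner is a transparent compositional stand-in for HMM-based
prion-domain predictors, which are out of scope: windows of
`window_length` (default 20) with Q/N fraction ≥ `qn_threshold` (default
0.4) are flagged, runs of flagged windows separated by ≤ `merge_gap`
(default 10) residues are merged, and each merged interval is trimmed to
its outermost Q/N residues. Reported intervals are disjoint, sorted, and
begin/end on a Q/N residue. Published motif boundaries should be supplied
as explicit intervals rather than re-derived; the scanner makes no claim of
reproducing HMM boundaries. Coordinates are 0-based half-open in code and
1-based inclusive in files, flagged in headers.

## Foci counting

Detection operates on the per-channel maximum projection over z, mirroring
the projection-then-score workflow of the emulated experiments, and is an
explicit automated stand-in for manual scoring. The projection is
Gaussian-smoothed (`smoothing_sigma` = 1 px), thresholded, and 8-connected
components with area in [`min_area` = 4, `max_area` = 200] px are kept;
centroids are intensity-weighted. The threshold is median +
max(`threshold_k`·MAD, 1% of the dynamic range above the median) with
`threshold_k` = 5: the MAD term is the operative robust rule on real,
noisy images, while the dynamic-range floor handles the degenerate
noise-free case where the MAD collapses to ~0 and every faint Gaussian
tail would otherwise be flagged. A perfectly flat image yields no foci. A
consequence of the floor is that a single extreme outlier pixel can raise
the threshold; the area filter already rejects such outliers as foci.

Cell segmentation is out of scope: a labeled cell map is required (the
simulator emits ground-truth maps). Foci are assigned to the cell label
under their centroid; foci over background are dropped into a QC tally.
The body-positive fraction carries a Wilson score 95% interval. A cell
co-localizes when any focus-pair across the two channels within that cell
is ≤ `distance_px` apart; there is no field-standard distance, so the
threshold is a required parameter (examples use 3 px).

## Exact contingency inference

The Fisher p-value is computed from first principles: the hypergeometric
pmf C(K,k)·C(N−K,n−k)/C(N,n) is evaluated with exact integer combinatorics
and tail sums are accumulated as rationals before a single conversion to
float, so enumeration carries no rounding error. Above N = 10,000 a
log-space path via `lgamma` avoids huge integers. One-sided tails sum the
pmf over the support; the two-sided rule is minimum-likelihood (all tables
with pmf ≤ observed, with 10⁻⁷ relative slack for floating ties), the
dominant convention. The default alternative is `greater` — directional
for retained-mutation tables — because for tables whose observed cell is at
the edge of its support the one- and two-sided values coincide, as the
enumeration oracle confirms.

## Synthetic data

The generators define the study conditions for all tests:

* **Lanes** — two Gaussian bands (σ = 3 px on a 100-px lane, centers 30/70)
  whose areas split `total_signal` by the true phosphorylated fraction; each
  band is normalized on the pixel grid so the noiseless integral equals
  `total_signal` exactly. Noise is additive Gaussian truncated at zero —
  the simplest model consistent with non-negative intensities; truncation
  biases dark pixels upward by ≈ sd/√(2π), which derived tolerances account
  for.
* **Time courses** — body-positive counts ~ Binomial(n, p(t)) per replicate
  and timepoint, with p(t) from the exponential models; n defaults to 200
  cells per timepoint and 3 replicates, the design of the emulated
  experiments (reported as ">200 cells per time-point" there; 200 is the
  conservative default).
* **Sequences** — background residues drawn from caller weights (default:
  uniform over the 18 non-Q/N amino acids, so planted motifs are the only
  Q/N signal); each planted motif receives exactly round(qn_fraction·length)
  Q/N residues at random positions.
* **Cell fields** — cells on a square grid (28 px pitch, 5 z-planes, 1 µm
  spacing emulated), each a membrane ring (radius 6 px) in one channel;
  with probability `body_probability` a cell carries k foci (default
  distribution heavily favors k = 1, reflecting the one-body-per-cell
  phenotype) as 3-D Gaussian spots (peak 150, σ = 1.3 px, truncated at 3σ)
  planted in the annulus 1.5–3.5 px outside the ring — near the vacuole
  edge — so detection also exercises localization. Same-cell foci are
  re-drawn until ≥12 px apart, which keeps noiseless connected components
  disjoint and makes the exact per-cell-count contract well-defined; out-of-
  bounds placements are re-drawn, never clipped. With probability
  `colocalization_probability` a body-positive cell gets a marker-channel
  focus coincident with one body.

Seeding is hierarchical (`seed` plus a per-replicate/per-cell stream index),
so identical spec + seed is bitwise reproducible and adding replicates never
perturbs earlier ones.

What the simulations do **not** capture: point-spread-function shape,
photobleaching, camera noise statistics, cell-to-cell intensity variation,
gel smiling/warping, lane cross-talk, or real sequence composition biases.
Passing tests therefore demonstrate that the estimators are correct and
calibrated under their stated models — not that detection thresholds or
scan parameters transfer unchanged to real micrographs and gels, which
retain free parameters (notably the co-localization distance and detection
threshold) that must be set against the data at hand.

## Problem sizes

Test and acceptance workloads are desk-scale by design: 1000 Monte-Carlo
experiments per kinetic model, 100-cell fields over 10 seeds (plus one
noiseless 49-cell field and one 500-cell co-localization field), 100
random stacks for the projection oracle, and lane batches of ≤5 lanes.
These sizes give the calibration assertions comfortable statistical margin
while keeping the full suite fast.
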