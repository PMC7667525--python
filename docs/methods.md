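# Methods

## Model and procedure

The pipeline estimates, for every microarray probe and every statistical
brain map, a spatially-adjusted rank correlation between regional gene
expression and the map's voxel values, separately per donor, and combines
the donor-level evidence into one signed meta-statistic per probe.

**Sample and probe selection.** Donor bundles are filtered to
left-hemisphere samples with slab type `cortex`, within 3 mm (inclusive) of
a cortical region of interest, excluding samples whose structure label is
in a caller-supplied non-cortical set.  Probes must be uniquely mapped to a
single gene (multi-gene, intergenic and unmapped probes are excluded) and
flagged "expressed" in at least 300 of the retained cortical samples
(strictly fewer than 300 is removed; exactly 300 is kept).  All filters are
pure predicates: order-preserving, idempotent, and conserving counts.

**Map lookup.** Each sample's world coordinate is mapped through the
volume's inverse affine and rounded to the nearest voxel index — a lookup,
not an interpolation.  Rounding is half-away-from-zero per axis; at an
exact half-voxel boundary this differs from banker's rounding, so the
convention is explicit and configurable (`rounding="half-even"`).  Indices
are 0-based; out-of-bounds coordinates raise with the offending coordinate
named.

**Spatial weights and eigenvector basis.** Per donor, a k = 10
nearest-neighbour graph is built from geodesic-surrogate distances, with
union symmetrisation (i ~ j if either is among the other's k nearest; ties
at the k-th distance break by smallest index) and row-standardised binary
weights.  The Moran eigenvector basis diagonalises C·W̃·C with
C = I − 11ᵀ/n and W̃ = (W + Wᵀ)/2; eigenvectors are sorted by eigenvalue
descending (smoothest patterns first) and eigenvalues below 1e−12 of the
largest magnitude are dropped, which removes the centered-out constant
direction.  Negative-eigenvalue vectors stay at the tail of the ordering;
under the escalation cap they are effectively never used.  The weight
style, the randomisation variance of the Moran test and the eligibility of
negative-eigenvalue vectors are all conventions of the standard spatial
tooling rather than uniquely determined choices; each is configurable.

**Per-donor fit.** Response is rank(atrophy t), predictor rank(expression),
with the first m eigenvectors as covariates.  m starts at 0; whenever the
one-sided Moran randomisation test on the residuals rejects (p < 0.05), m
advances along the schedule 0, 1, 5, 10, 15, …, 150 — a single vector
first, then multiples of five.  Escalation also stops when the basis or the
residual degrees of freedom run out.  Orientation matters once covariates
enter; regressing atrophy on expression treats the map as the quantity
being explained and keeps a single shared response per donor-map, and is
configurable.  Because the basis is orthonormal and centered, each fit is
computed by projecting both ranked variables off the active eigenvectors
(Frisch–Waugh); this reproduces the full OLS coefficient, its t-statistic
(df = n − 2 − m) and residuals exactly, and with m = 0 is numerically
identical to the classical Spearman t-test.

**Combination and calls.** Donor two-sided p-values are clamped to
[1e−300, 1 − 1e−16], converted to magnitudes Z = Φ⁻¹(1 − p/2), and combined
with weights w = sign(coefficient t): z_meta = Σ wZ / √(Σ w²).  Probes with
zero expression variance in a donor are skipped there, and the combination
runs over the remaining donors (at least two).  Benjamini–Hochberg FDR is
applied per map across all combined probes of that map.  Gene lists use the
any-probe rule — one significant probe of the right sign suffices, and a
gene with discordant significant probes legitimately appears in both lists.
Consensus lists are plain intersections across exactly three maps.

**Overrepresentation.** One-sided (greater) Fisher's exact tests of a gene
list against each set of a collection, with the declared background as
universe: sets are intersected with the background, list members outside it
are dropped (count logged).  p is the upper hypergeometric tail; the odds
ratio is the sample (cross-product) estimator with a Haldane 0.5 added to
every cell iff any cell is zero — some Fisher implementations report the
conditional-MLE odds ratio instead, a known, direction-unsigned deviation.
BH correction spans the whole collection in one pass.  Cell-type marker
sets come from a genes × cell-types mean-FPKM table: a gene marks a type
when its FPKM there strictly exceeds 2.5 and is at least 3.0 times the
arithmetic mean of the other types.

## Synthetic data: what it emulates and what it does not

The generator stands in for two large external resources: donor microarray
bundles and voxel-wise atrophy t-maps.

* **Geometry.** Samples are scattered on a gently curved 60 mm sheet
  embedded in 3-D; inter-sample distances are shortest paths over a dense
  Euclidean neighbour mesh on the sheet.  This reproduces the operative
  property of surface geodesics — distances along, not through, the sheet —
  without any cortical anatomy.  Externally supplied distance matrices are
  accepted everywhere a geometry is.
* **Expression.** Each gene's latent profile is a unit-variance Gaussian
  process over the geodesic surrogate (squared-exponential covariance,
  default length-scale 15 mm ≈ 6× the median nearest-neighbour spacing)
  plus white noise (default SD 1.5, i.e. the spatial component carries
  ≈ 31 % of the latent variance — moderate autocorrelation, of the order
  expected for probe-level microarray data, and strong enough that the
  unadjusted test rejects half of all null genes).  Planted genes mix in
  the normal scores of the atrophy ranks with weight 2·sin(π·ρ/6), the
  Gaussian-copula weight whose marginal *Spearman* correlation is ρ; the
  injection is therefore monotone and rank-calibrated.  Probes add
  independent noise (SD 0.25) around their gene's latent; a probe is
  "expressed" where it exceeds its own 25th percentile — an arbitrary but
  fixed stand-in for the atlas's binary presence calls.  The kernel over
  geodesic distances need not be positive semi-definite, so sampling uses
  an eigenvalue-clipped factor rescaled to unit marginal variance.
* **Atrophy.** Volumes are radial Gaussian bumps, t(v) = peak ·
  exp(−‖world(v) − c‖²/2s²), written on a proper voxel grid with an
  affine.  Real VBM t-maps carry fine spatial texture that a radial bump
  lacks; in rank space the bump is globally smooth, so per-fit eigenvector
  counts concentrate at 20–25 here, whereas on real data most fits need
  far fewer.  Passing tests therefore validate the machinery under a
  *harder* residual-autocorrelation regime than real maps produce, but say
  nothing about atlas normalisation, batch effects, or registration error,
  all of which are upstream and out of scope.
* **Annotation fixtures.** Probe-annotation tables with exact per-category
  counts, marker tables with designated high-FPKM blocks, and random GMT
  collections; all pure functions of their seeds.

## Reference studies and problem sizes

`gxmap.studies` packages the two simulation studies the test-suite and the
acceptance script run:

* **Type-I** — one donor, 200 samples, 200 null genes, three replicate
  seeds: rejection at p < 0.05 with the adaptive adjustment versus with m
  forced to 0.  Typical values ≈ 0.05–0.07 adjusted versus ≈ 0.5 raw.
* **Recovery** — six donors × 200 samples, 500 genes, 50 planted at
  |Spearman| 0.6 with alternating signs, against three overlapping maps
  (planting targets the mean of the three fields, so each map sees a
  slightly attenuated signal).  Three replicate datasets are run and true/
  false positives pooled per map before forming sensitivity and the
  false-discovery proportion — with ~50 planted genes per replicate a
  single run's FDP is dominated by a handful of counts, and pooling is the
  stable estimator.  Typical pooled values: sensitivity 1.0, FDP 0.06–0.09,
  consensus recovery 1.0.

These sizes keep a full run of everything in well under an hour on one
core while leaving the per-fit escalation genuinely exercised.

## Numerical choices and degenerate inputs

* Moran's I uses the randomisation (permutation-moment) variance and a
  one-sided greater alternative — residual positive autocorrelation is the
  alarmed direction; constant vectors raise a degenerate-input error, and
  constant *residuals* are treated as spatially unstructured.
* The escalation reports the final residual Moran p as-is when the cap is
  reached; every completed fit satisfies "residual p ≥ α or m is the
  largest scheduled value", an assertable invariant.
* Rank-deficiency (expression ranks numerically inside the span of
  intercept + eigenvectors) raises an error naming the offending m.
* p-value clamps: donor p in [1e−300, 1 − 1e−16] before quantile
  inversion; Moran p clipped away from exact 0/1.
* BH-FDR delegates to `statsmodels` (`fdr_bh`) after validating p ∈ [0, 1].

## Known limitations

* The adaptive stop "first m whose residuals pass Moran's test" is known to
  under-correct when the predictor's spatial structure is very strong and
  mid-frequency: the leading eigenvectors absorb exactly the patterns the
  global Moran statistic is most sensitive to, so the test goes quiet
  before the dependence is gone.  At the defaults this residual inflation
  is small (type-I ≈ 0.05–0.07 at nominal 0.05), but with a heavier
  spatial fraction of expression variance it grows, and fixed large m
  out-performs the adaptive rule there.
* Stouffer with ±1 weights discards magnitude differences between donors
  by design; a donor with many samples counts no more than a small one.
* The any-probe gene rule is deliberately permissive: one discordant
  significant probe places a gene on both lists.
* The sample odds ratio with Haldane correction differs from the
  conditional-MLE odds ratio on zero-cell tables; p-values are unaffected.
* Nearest-voxel lookup is exact only at voxel centres; no partial-volume
  handling is attempted.
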