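# Methods

## Scope and data model

`maveimpute` operates on a single protein's variant-effect (VE) map:
the L×21 matrix of function scores over all positions and substitutions
(20 amino acids plus stop; the cell where the substitution equals the
wild-type residue is the synonymous cell, written `=`). Scores are
unitless function scores where 0 means stop-like (null) and 1 means
wild-type-like. Positions are 1-based (HGVS convention); variant tokens
are accepted in compact (`R123H`, `W10*`, `L7=`) and HGVS-p three-letter
(`p.Arg123His`, `p.Trp10Ter`, `p.Leu7=`) forms, with `alt == wt`
canonicalized to `=`.

The score-table dialect (CSV/TSV, auto-detected delimiter; columns
`variant, score, sd, n_reps, quality`) is this package's own standard.
Missing `sd` is treated as unmeasured dispersion (the error model
supplies the prior); missing `quality` defaults to the replicate count,
since library/read coverage is the dominant quality driver in MAVE
data. Duplicate variant rows — common when MAVE exports shard by
mutagenesis tile — are merged by replicate-count-weighted mean, with
pooled within+between dispersion and summed replicate counts.

## Normalization and adaptive correction

Anchors are the medians (midpoint convention for even counts) of the
raw stop and synonymous score distributions; every score and sd is then
mapped through the affine rescaling. Because the map is affine,
rescaled class medians land on 0 and 1 exactly, which the tests assert
to machine precision. Users with pre-normalized data can skip this
stage (`prenormalized`); the reciprocal correction of
apparently-adaptive scores (`X > 1 → 1/X`) is an independent switch
(`flip`) and is applied once, before modeling — refined scores are not
re-corrected. sd propagates through the reciprocal by the first-order
delta method (`sd' = sd/X²`); the rescaling step divides sd by the
absolute anchor span. Whether the original service rescales sd is not
something we inherit; doing so keeps uncertainties on the same scale as
the scores, which the inverse-variance refinement requires.

## Feature table

One row per missense target. Stop and synonymous variants are never
modeling targets: their values are fixed by the normalization anchors.

* `pos_mean_score` — unweighted mean of measured missense scores at the
  target's position. For a measured target its own score is excluded,
  so the feature cannot leak the training label (a property test
  perturbs the target's score and asserts the feature is unchanged).
  At prediction time for unmeasured targets all measured missense
  records at the position contribute. The positional mean is computed
  over all measured missense records rather than only those passing the
  quality cutoff, because the cutoff search itself consumes the feature
  table; averaging makes the feature robust to the low-quality tail.
* Physicochemical features — Kyte–Doolittle hydropathy, Zamyatnin
  residue volume, formal charge at pH 7 (His neutral) and binary
  polarity, each for the wild-type residue, the substituted residue and
  their difference. These four scales nearly uniquely identify a
  residue, so tree ensembles can learn arbitrary per-residue effects
  from them.
* `blosum62` — the BLOSUM62 entry for the substitution (from
  Biopython's substitution-matrix collection).
* Optional externals — PolyPhen-2, PROVEAN and SIFT scores consumed as
  input columns (never computed here), and per-position secondary
  structure (H/E/C one-hot) and relative solvent accessibility.

Absent optional inputs yield missing values, never errors; with
everything absent the model still trains on sequence-derived features
plus the positional mean.

## Model

A scikit-learn `GradientBoostingRegressor` retrained per protein.
Hyperparameters (500 trees, learning rate 0.05, depth 3, subsample 0.8)
are conservative defaults for small-n tabular regression and are
config-exposed. Missing values are median-filled with per-feature
missingness-indicator columns appended; the fill values are frozen into
the trained bundle so prediction uses the training medians. An
indicator column's importance is folded back into its base feature when
reported. Feature importance is the boosted-tree convention — split
counts weighted by squared error improvement, averaged over trees —
normalized to sum to 1.

Quality-cutoff selection holds out the top 20% of measured missense
variants ranked by quality (size `ceil(0.2·n)`, boundary ties broken by
variant-key order) as a fixed test set; candidate cutoffs are the
deciles of the remaining pool's quality distribution (≤ 10 trainings),
and the cutoff minimizing test RMSE wins, ties to the smaller cutoff
(more data). Cross-validated RMSE (`cv_rmse`) is the out-of-fold RMSE
of a shuffled 10-fold partition of the post-cutoff training records;
the same seeded partition is reused verbatim for every method in
`compare_methods` (GBT, random forest, ordinary least squares and a
positional-mean baseline; an SVM comparator is omitted by default as
scale-sensitive and slow at typical n). A single pipeline seed fans out
to the fold partition and every ensemble.

## Error model

The prior is a replicate-count-weighted linear least-squares regression
of sd on function score, evaluated with the score clamped to the
observed range and the output floored at 1e−6 (monotone-safe
extrapolation). A plain linear fit (rather than log-linear) is used
because the relationship being regularized is the overall trend of σ
with score, and a linear form recovers linear heteroskedastic truth
exactly; the constant-sd case reduces to a constant prior. With fewer
than 10 usable records the prior degrades to the median sd with a
warning.

Regularization pools in variance space with `prior_df` (default 2)
pseudo-degrees of freedom against the measured variance's `n_reps − 1`.
Limits: `n_reps ≥ K` (default K = 4) returns the measured σ unchanged;
`n_reps = 1` or missing sd returns the prior; otherwise the estimate is
a convex combination in variance space. The exact regularization used
by the original service is defined in its antecedent map-refinement
work; the pooling above is this package's concrete formulation with the
same limiting behavior.

Imputed scores receive the global cross-validation RMSE as their
standard error, optionally inflated (config
`low_coverage_inflation`) at positions with fewer than 3 surviving
measurements, and floored at 1e−6 so inverse-variance weights stay
finite. Per-variant predictive intervals are out of scope.

## Refinement and assembly

Measured missense cells whose quality passes the cutoff are combined
with their model prediction by inverse-variance weighting (provenance
`refined`); the refined score always lies between its inputs and its
standard error is below the smaller input error. Measurements below
the cutoff are excluded from training and, by default, replaced by pure
imputation (provenance `imputed`) — the conservative choice, since such
measurements were deemed unreliable; `below_cutoff = "refine"` exposes
the alternative. Stop and synonymous cells are never model-predicted:
synonymous cells are fixed at 1 and stop cells carry their measured
rescaled value where a measurement exists (provenance `measured`,
retained regardless of the cutoff since these cells anchor the scale),
and are left blank (`undefined`) otherwise.

## Visualization

The map renders as one rectangle per cell (21 rows: amino acids grouped
hydrophobic → special → polar → charged, stop last; synonymous cells
sit on the wild-type residue's row), colored by a monotone palette from
dark (#08306b) at 0 to white at 1, grey for undefined cells, with a dot
overlay on imputed cells. Layers: `refined` (everything), `measured`
(blanks where no measurement backs the cell) and `predictors` (an
external predictor column, min–max scaled). SVG output is
byte-deterministic (fixed hash salt, no timestamp metadata) and each
cell carries an `id="cell-<pos>-<alt>"` attribute, so figures are
testable by parsing.

## Synthetic data

The generator emulates a MAVE upload, not sequencing reads: no
selection dynamics, no count-level noise, no codon structure. Truth is
additive — per-position sensitivity ~ U(0.05, 1), per-substitution
effect ~ N(0, 0.15), clipped to [0, 1] — with 3% of missense cells made
apparently adaptive (truth in 1.05–1.5) to exercise the reciprocal
correction. Raw scores are emitted on a deliberately shifted axis
(stop anchor 0.15, synonymous anchor 1.6) so rescaling is non-trivial
in every test. Each present variant gets 1–6 replicates drawn with sd
0.1 (a 20% minority gets 5× that, emulating badly covered variants);
quality is `n_reps / (1 + replicate sd)`, so the quality axis genuinely
separates clean from noisy measurements and the cutoff search has
something to find. 30% of missense cells are censored by default
("poorly represented in the library"); stop/synonymous anchors are
present at 90% of positions. Optional structure (RSA anti-correlated
with positional sensitivity) and predictor tables (noisy monotone
transforms of truth) emulate the external inputs.

What passing tests on these data do show: the pipeline's algebraic
contracts, determinism, leakage-freedom, and that the model recovers
additive position/substitution structure well above a positional-mean
baseline. What they do not show: performance on real assays with
epistatic or bimodal score distributions, non-additive position ×
substitution interactions, or miscalibrated experimental quality
scores.

## Problem sizes and numerics

Tests run the full model on maps of 25–100 residues (up to ~1500
training records), which exercises every code path at sub-minute cost;
contract-level tests shrink the ensemble to 60 trees since they assert
structure, not accuracy. Medians use the midpoint convention; RMSE ties
in the cutoff search resolve to the smaller cutoff; equal qualities at
the test-set boundary resolve by (position, substitution) order; map
files store floats as shortest round-trip decimals and are re-read with
round-trip parsing, so write → read is lossless and reruns are
byte-identical.
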