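# maveimpute

Imputation and refinement of missense variant-effect maps from
multiplexed assays of variant effect (MAVEs).

MAVEs score thousands of protein variants in a single selection
experiment, but many missense variants end up poorly represented in the
mutagenized library: their function scores are missing or unreliable.
`maveimpute` completes such maps. Given a per-variant score table and
the wild-type sequence (plus optional external predictor scores and
structure annotations), it:

1. **Normalizes** scores so the median of stop (nonsense) variants is 0
   (null-like) and the median of synonymous variants is 1
   (wild-type-like):
   `rescaled = (score − stop_median) / (syn_median − stop_median)`.
2. **Corrects apparently-adaptive variants**: scores `X > 1` are
   reciprocal-transformed to `1/X` (above-wild-type function in a
   complementation assay usually signals a deleterious variant).
3. **Trains a gradient-boosted-tree (GBT) regressor** on well-measured
   missense variants. Features: the average function score at each
   position, physicochemical properties of the wild-type and substituted
   residues and their differences, the BLOSUM62 substitution score, and
   optional PolyPhen-2/PROVEAN/SIFT scores and secondary-structure /
   solvent-accessibility annotations. The quality cutoff for training
   can be fixed by the user or selected automatically by minimizing RMSE
   on a held-out test set — the top 20% of variants ranked by quality
   score. Missing features never abort training.
4. **Imputes** every unmeasured missense cell with the trained model.
5. **Estimates uncertainty**: with `K` or more replicates the measured
   standard error `σ` is used directly; with fewer it is shrunk toward a
   prior from an overall regression of `σ` against function score:
   `σ_reg² = (ν·σ_prior² + (n−1)·σ_meas²) / (ν + n − 1)`.
6. **Refines** each measured score `m` against its model prediction `i`
   by inverse-variance weighting:
   `refined = (m/σ_m² + i/σ_i²) / (1/σ_m² + 1/σ_i²)`,
   `σ = (1/σ_m² + 1/σ_i²)^(−1/2)`.
7. **Renders** the completed L×21 map (20 substitutions + stop per
   position) as a deterministic SVG heatmap with per-cell provenance
   (measured / imputed / refined) marked.

A seeded synthetic-data generator with known ground truth
(`maveimpute synth`) emulates all inputs, so the whole pipeline is
testable without experimental data.

## Worked example

```sh
maveimpute synth --length 50 --seed 1 -o demo
maveimpute impute --scores demo/scores.tsv --fasta demo/wt.fasta \
    --structure demo/structure.tsv --predictors demo/predictors.tsv \
    --auto-cutoff --seed 1 -o demo/out
```

prints

```
wrote 759 records for a length-50 protein: demo/scores.tsv, demo/truth.tsv, demo/wt.fasta, demo/structure.tsv, demo/predictors.tsv
map complete: L=50, cutoff=0.9091, cv_rmse=0.0968, cells {'refined': 646, 'imputed': 304, 'measured': 88, 'undefined': 12}
```

Reading: of the 50×21 = 1050 map cells, 646 measured missense variants
passed the automatically selected quality cutoff (0.9091) and were
refined against their model predictions; 304 missense cells had no
surviving measurement and carry pure imputations (standard error =
the model's 10-fold cross-validation RMSE, 0.0968 on the 0–1 function
score scale); 88 stop/synonymous anchor cells carry measurements; 12
anchor cells were never measured and stay blank. `demo/out/` contains
the complete map (`map.tsv`, one row per cell with score, standard
error and provenance), the heatmap (`map.svg`), the serialized model
(`model.joblib`) and a run report (`report.json`) with the resolved
configuration, anchors (here stop median 0.152, synonymous median
1.601 on the raw axis), selected cutoff and feature importances.

Individual stages are available as `maveimpute normalize`,
`maveimpute features` and `maveimpute plot`, and programmatically via
`maveimpute.pipeline.impute_map`.

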