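"""End-to-end imputation pipeline driver.

Stages, in order: read inputs -> normalize to stop/synonymous anchors ->
correct apparently-adaptive scores -> build the feature table -> select
or apply the quality cutoff -> train the gradient-boosted-tree model ->
predict every missense cell -> estimate and regularize errors -> refine
measured scores by inverse-variance weighting -> assemble and write the
complete map (TSV + optional SVG) and a machine-readable run report.

The pipeline is a pure function of (input files, config, seed): the run
report captures the fully resolved configuration and every run with the
same inputs produces a byte-identical map file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import error_model, features, io_variants, model, normalize, refine, viz
from .exceptions import InputError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for one imputation run."""

    scores: str
    fasta: str
    outdir: str
    predictors: Optional[str] = None
    structure: Optional[str] = None
    prenormalized: bool = False
    flip: bool = True
    quality_cutoff: Optional[float] = None  # None => automatic selection
    seed: int = 42
    error_K: int = error_model.DEFAULT_K
    error_prior_df: float = error_model.DEFAULT_PRIOR_DF
    low_coverage_inflation: float = 1.0
    min_position_count: int = 3
    below_cutoff: str = "impute"
    hyperparameters: Optional[dict] = None
    make_plot: bool = True
    compare: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def impute_map(
    scores: pd.DataFrame,
    context: io_variants.ProteinContext,
    predictors: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[refine.VEMap, model.ModelBundle, dict]:
    """In-memory pipeline core: score table in, complete map out.

    Returns ``(map, trained bundle, report dict)``. ``scores`` must be a
    parsed/merged score table (as from
    :func:`maveimpute.io_variants.read_score_table`).
    """
    cfg = config or PipelineConfig(scores="<memory>", fasta="<memory>", outdir=".")
    report: dict = {"config": cfg.to_dict(), "version": __version__, "stages": {}}

    io_variants.validate_against_sequence(scores, context)
    report["stages"]["read"] = {"n_records": len(scores)}

    # -- normalize ---------------------------------------------------------
    if cfg.prenormalized:
        anchors = None
        df = scores.copy()
    else:
        anchors = normalize.fit_anchors(scores)
        df = normalize.rescale_frame(scores, anchors)
        report["stages"]["normalize"] = {
            "stop_median": anchors.stop_median, "syn_median": anchors.syn_median,
        }
    if cfg.flip:
        n_flipped = int((df["score"] > 1.0).sum())
        df = normalize.correct_adaptive_frame(df)
        report["stages"]["flip"] = {"n_flipped": n_flipped}

    # -- features ----------------------------------------------------------
    targets = features.all_missense_targets(context)
    feature_table = features.build_feature_table(df, context, targets, predictors)
    report["stages"]["features"] = {
        "n_targets": len(feature_table), "schema": features.feature_schema(),
    }

    # -- cutoff + training -------------------------------------------------
    if cfg.quality_cutoff is None:
        cutoff = model.select_quality_cutoff(
            df, feature_table, seed=cfg.seed, hyperparameters=cfg.hyperparameters
        )
        report["stages"]["cutoff"] = {"mode": "auto", "selected": cutoff}
    else:
        cutoff = float(cfg.quality_cutoff)
        report["stages"]["cutoff"] = {"mode": "user", "selected": cutoff}

    bundle = model.train(
        df, feature_table, cutoff, seed=cfg.seed, hyperparameters=cfg.hyperparameters
    )
    report["stages"]["train"] = {
        "n_training": int(
            (features._missense_mask(df) & (df["quality"] >= cutoff)).sum()
        ),
        "cv_rmse": bundle.cv_rmse,
        "importances": bundle.importances,
    }
    if cfg.compare:
        comparison = model.compare_methods(
            df, feature_table, seed=cfg.seed, cutoff=cutoff,
            hyperparameters=cfg.hyperparameters,
        )
        report["stages"]["compare"] = comparison.to_dict(orient="records")

    # -- predict -----------------------------------------------------------
    predictions = model.predict(bundle, feature_table)
    report["stages"]["predict"] = {"n_predictions": len(predictions)}

    # -- error model -------------------------------------------------------
    prior = error_model.fit_sigma_prior(df)
    errors = {
        row.variant: error_model.regularize_sigma(
            row, prior, K=cfg.error_K, prior_df=cfg.error_prior_df
        )
        for row in df.itertuples()
    }
    surviving = df.loc[features._missense_mask(df) & (df["quality"] >= cutoff)]
    pos_counts = surviving.groupby("position")["variant"].count().to_dict()
    imputed_sigmas = {
        row.variant: error_model.imputed_sigma(
            bundle,
            n_measured_at_position=int(pos_counts.get(row.position, 0)),
            low_coverage_inflation=cfg.low_coverage_inflation,
            min_position_count=cfg.min_position_count,
        )
        for row in feature_table.itertuples()
    }
    report["stages"]["error"] = {
        "prior_slope": prior.slope, "prior_intercept": prior.intercept,
        "K": cfg.error_K, "prior_df": cfg.error_prior_df,
        "low_coverage_inflation": cfg.low_coverage_inflation,
    }

    # -- refine + assemble -------------------------------------------------
    vemap = refine.assemble_map(
        df, predictions.to_dict(), errors, imputed_sigmas, context,
        anchors=anchors, quality_cutoff=cutoff, below_cutoff=cfg.below_cutoff,
        metadata={
            "seed": cfg.seed, "quality_cutoff": cutoff, "cv_rmse": bundle.cv_rmse,
            "version": __version__,
        },
    )
    report["stages"]["assemble"] = {"provenance": vemap.provenance_counts()}
    return vemap, bundle, report


def run_pipeline(config: PipelineConfig) -> tuple[refine.VEMap, dict]:
    """File-level pipeline: read inputs, impute, write outputs.

    Writes ``map.tsv``, ``report.json``, ``model.joblib`` and (unless
    disabled) ``map.svg`` into ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scores = io_variants.read_score_table(config.scores)
    context = io_variants.read_fasta(config.fasta)
    if config.structure:
        context.structure = io_variants.read_structure(config.structure)
        context.__post_init__()  # re-validate against sequence range
    predictors = (
        io_variants.read_predictors(config.predictors) if config.predictors else None
    )

    vemap, bundle, report = impute_map(scores, context, predictors, config)

    map_path = outdir / "map.tsv"
    io_variants.write_vemap(vemap, map_path)
    bundle.save(outdir / "model.joblib")
    report["outputs"] = {"map": str(map_path), "model": str(outdir / "model.joblib")}
    if config.make_plot:
        svg = viz.render_map(vemap, outdir / "map.svg")
        report["outputs"]["plot"] = svg
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    report["outputs"]["report"] = str(report_path)
    log.info("pipeline complete: %s", map_path)
    return vemap, report
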