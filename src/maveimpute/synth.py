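"""Seeded synthetic MAVE datasets with known ground truth.

The generator emulates the inputs a multiplexed assay of variant effect
produces: a per-variant score table on an arbitrary raw axis (stop
variants near a low anchor, synonymous near a high one, so that
normalization is always non-trivial), replicate dispersion, replicate
counts, a quality score correlated with replicate count and inversely
with noise, and censoring of a fraction of missense cells (variants
poorly represented in the mutagenized library). The noiseless truth for
every cell is returned alongside, so imputation error is measurable
exactly.

Ground-truth structure is additive — a per-position sensitivity effect
plus a per-substitution effect (optional interaction noise) clipped to
[0, 1] — with a small fraction of cells made apparently adaptive
(truth > 1) to exercise the reciprocal correction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .aminoacids import AA_ALPHABET, STOP, SYNONYMOUS
from .io_variants import ProteinContext, VariantKey, write_score_table

DEFAULT_NOISE_SD = 0.1


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generative settings; identical config + seed => identical dataset."""

    length: int = 50
    seed: int = 42
    missingness: float = 0.3          # fraction of missense cells censored
    replicate_sd: float = DEFAULT_NOISE_SD  # raw-scale per-replicate noise
    noisy_fraction: float = 0.2       # variants measured with inflated noise
    noisy_multiplier: float = 5.0
    adaptive_fraction: float = 0.03   # cells with truth > 1 (apparently adaptive)
    substitution_sd: float = 0.15     # spread of per-substitution effects
    interaction_sd: float = 0.0       # optional position x substitution noise
    position_effect_low: float = 0.05
    position_effect_high: float = 1.0
    stop_raw: float = 0.15            # raw-scale anchor for null function
    syn_raw: float = 1.6              # raw-scale anchor for wild-type function
    min_reps: int = 1
    max_reps: int = 6
    anchor_coverage: float = 0.9      # fraction of positions with stop/syn measured
    with_structure: bool = True
    with_predictors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        if self.length < 2:
            raise ValueError("length must be >= 2")


@dataclasses.dataclass
class SynthDataset:
    """Generated inputs plus the noiseless truth table."""

    scores: pd.DataFrame      # canonical score-table columns
    truth: pd.DataFrame       # position, wt, alt, variant, score_true(+corrected)
    context: ProteinContext
    predictors: Optional[pd.DataFrame]
    config: SynthConfig

    def parsed_scores(self) -> pd.DataFrame:
        """Score table with position/wt/alt columns, as read_score_table
        would return it (the in-memory shortcut past a file round trip)."""
        from .io_variants import parse_variant

        keys = [parse_variant(t) for t in self.scores["variant"]]
        out = self.scores.copy()
        out.insert(1, "position", [k.position for k in keys])
        out.insert(2, "wt", [k.wt for k in keys])
        out.insert(3, "alt", [k.alt for k in keys])
        return out[["variant", "position", "wt", "alt", "score", "sd", "n_reps", "quality"]]


def _truth_scores(cfg: SynthConfig, rng: np.random.Generator, sequence: str):
    L = cfg.length
    pos_effect = rng.uniform(cfg.position_effect_low, cfg.position_effect_high, L)
    sub_effect = {aa: rng.normal(0.0, cfg.substitution_sd) for aa in AA_ALPHABET}
    truth: dict[str, float] = {}
    missense_tokens = []
    for p in range(1, L + 1):
        wt = sequence[p - 1]
        for alt in AA_ALPHABET:
            if alt == wt:
                continue
            t = pos_effect[p - 1] + sub_effect[alt]
            if cfg.interaction_sd > 0:
                t += rng.normal(0.0, cfg.interaction_sd)
            tok = VariantKey(p, wt, alt).token
            truth[tok] = float(np.clip(t, 0.0, 1.0))
            missense_tokens.append(tok)
        truth[VariantKey(p, wt, SYNONYMOUS).token] = 1.0
        truth[VariantKey(p, wt, STOP).token] = 0.0
    # a fraction of missense cells appear adaptive (> wild type)
    n_adaptive = int(round(cfg.adaptive_fraction * len(missense_tokens)))
    if n_adaptive:
        chosen = rng.choice(len(missense_tokens), size=n_adaptive, replace=False)
        for idx in chosen:
            truth[missense_tokens[idx]] = float(rng.uniform(1.05, 1.5))
    return truth, pos_effect


def generate(config: SynthConfig) -> SynthDataset:
    """Generate a complete synthetic dataset for ``config``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sequence = "".join(rng.choice(list(AA_ALPHABET), size=cfg.length))
    truth, pos_effect = _truth_scores(cfg, rng, sequence)
    scale = cfg.syn_raw - cfg.stop_raw

    rows = []
    for p in range(1, cfg.length + 1):
        wt = sequence[p - 1]
        cell_keys = [VariantKey(p, wt, alt) for alt in AA_ALPHABET if alt != wt]
        for key in cell_keys:
            if rng.uniform() < cfg.missingness:
                continue
            rows.append(key)
        if rng.uniform() < cfg.anchor_coverage:
            rows.append(VariantKey(p, wt, SYNONYMOUS))
        if rng.uniform() < cfg.anchor_coverage:
            rows.append(VariantKey(p, wt, STOP))

    records = []
    for key in rows:
        tok = key.token
        raw_true = cfg.stop_raw + truth[tok] * scale
        n_reps = int(rng.integers(cfg.min_reps, cfg.max_reps + 1))
        rep_sd = cfg.replicate_sd
        if cfg.noisy_fraction > 0 and rng.uniform() < cfg.noisy_fraction:
            rep_sd *= cfg.noisy_multiplier
        draws = raw_true + rng.normal(0.0, rep_sd, n_reps) if rep_sd > 0 else np.full(n_reps, raw_true)
        score = float(draws.mean())
        sd = float(draws.std(ddof=1)) if n_reps > 1 else np.nan
        quality = n_reps / (1.0 + rep_sd)
        records.append((tok, score, sd, n_reps, quality))

    scores = pd.DataFrame(
        records, columns=["variant", "score", "sd", "n_reps", "quality"]
    )

    truth_rows = []
    for p in range(1, cfg.length + 1):
        wt = sequence[p - 1]
        for alt in list(AA_ALPHABET) + [STOP]:
            key = VariantKey(p, wt, SYNONYMOUS if alt == wt else alt)
            t = truth[key.token]
            corrected = 1.0 / t if t > 1.0 else t
            truth_rows.append((p, wt, key.alt, key.token, t, corrected))
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["position", "wt", "alt", "variant", "score_true", "score_true_corrected"],
    )

    structure = None
    if cfg.with_structure:
        ss = rng.choice(["H", "E", "C"], size=cfg.length, p=[0.35, 0.2, 0.45])
        # buried positions tend to be the sensitive ones
        rsa = np.clip(1.0 - pos_effect + rng.normal(0, 0.1, cfg.length), 0.0, 1.0)
        structure = pd.DataFrame(
            {"position": np.arange(1, cfg.length + 1), "ss_class": ss,
             "rsa": np.round(rsa, 4)}
        )
    context = ProteinContext(sequence=sequence, uniprot_id="SYNTH", structure=structure)

    predictors = None
    if cfg.with_predictors:
        miss = truth_df.loc[
            truth_df["alt"].isin(set(AA_ALPHABET)) & (truth_df["alt"] != truth_df["wt"])
        ]
        t = miss["score_true_corrected"].to_numpy()
        n = len(miss)
        predictors = pd.DataFrame(
            {
                "variant": miss["variant"].to_numpy(),
                "polyphen2": np.round(np.clip(1 - t + rng.normal(0, 0.15, n), 0, 1), 4),
                "provean": np.round(-6.0 * (1 - t) + rng.normal(0, 0.8, n), 4),
                "sift": np.round(np.clip(t + rng.normal(0, 0.15, n), 0, 1), 4),
            }
        )

    return SynthDataset(
        scores=scores, truth=truth_df, context=context,
        predictors=predictors, config=cfg,
    )


def write_dataset(dataset: SynthDataset, outdir) -> dict[str, str]:
    """Write the dataset's files into ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    scores_path = out / "scores.tsv"
    write_score_table(dataset.scores, scores_path)
    paths["scores"] = str(scores_path)

    truth_path = out / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)

    fasta_path = out / "wt.fasta"
    fasta_path.write_text(
        f">{dataset.context.uniprot_id or 'synthetic'} synthetic wild-type\n"
        f"{dataset.context.sequence}\n"
    )
    paths["fasta"] = str(fasta_path)

    if dataset.context.structure is not None:
        structure_path = out / "structure.tsv"
        dataset.context.structure.to_csv(structure_path, sep="\t", index=False)
        paths["structure"] = str(structure_path)

    if dataset.predictors is not None:
        pred_path = out / "predictors.tsv"
        dataset.predictors.to_csv(pred_path, sep="\t", index=False)
        paths["predictors"] = str(pred_path)

    return paths
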