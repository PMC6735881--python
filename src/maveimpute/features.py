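"""Per-variant feature table for the imputation model.

Each missense target variant receives one row with:

* ``pos_mean_score`` — average measured missense score at the variant's
  position (the single most informative feature for imputation). For a
  measured target the target's own score is excluded from the average,
  so the feature never leaks the training label.
* physicochemical values of the wild-type and substituted residues
  (hydropathy, volume, charge, polarity) and their alt - wt deltas;
* the BLOSUM62 substitution score;
* optional external predictor scores (PolyPhen-2, PROVEAN, SIFT);
* optional per-position structure features (secondary-structure one-hot,
  relative solvent accessibility).

Missing optional inputs yield missing values, never errors; the model
module owns the missing-value policy. Stop and synonymous variants are
not modeling targets (their scores are anchored by normalization).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .aminoacids import AA_ALPHABET, PROPERTY_SCALES, blosum62
from .exceptions import InputError
from .io_variants import ProteinContext, VariantKey

_PROPERTY_NAMES = [name for name, _ in PROPERTY_SCALES]

_SCHEMA = (
    ["pos_mean_score"]
    + [f"{p}_wt" for p in _PROPERTY_NAMES]
    + [f"{p}_alt" for p in _PROPERTY_NAMES]
    + [f"{p}_delta" for p in _PROPERTY_NAMES]
    + ["blosum62"]
    + ["polyphen2", "provean", "sift"]
    + ["ss_H", "ss_E", "ss_C", "rsa"]
)

ID_COLUMNS = ["variant", "position", "wt", "alt"]


def feature_schema() -> list[str]:
    """Stable ordered list of feature column names."""
    return list(_SCHEMA)


def _missense_mask(df: pd.DataFrame) -> pd.Series:
    return df["alt"].isin(set(AA_ALPHABET)) & (df["alt"] != df["wt"])


def positional_mean(
    df: pd.DataFrame, position: int, exclude: Optional[VariantKey] = None
) -> float:
    """Mean measured missense score at ``position``.

    Stop and synonymous records are excluded; ``exclude``, when given,
    omits that variant from the average (used for measured training
    targets). Returns NaN when no qualifying record remains.
    """
    sel = df.loc[_missense_mask(df) & (df["position"] == position)]
    if exclude is not None:
        sel = sel.loc[sel["variant"] != exclude.token]
    if sel.empty:
        return math.nan
    return float(sel["score"].mean())


def build_feature_table(
    df: pd.DataFrame,
    context: ProteinContext,
    targets: Sequence[VariantKey],
    predictors: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Build one feature row per target variant.

    ``df`` is the measured score table on the rescaled (and, when
    enabled, adaptive-corrected) scale. Targets may mix measured
    variants (training) and unmeasured ones (prediction); measured
    targets get a self-excluded positional mean.
    """
    L = len(context)
    for key in targets:
        if not key.is_missense:
            raise InputError(
                f"{key.token}: only missense variants are modeling targets"
            )
        if key.position > L:
            raise InputError(
                f"{key.token}: position outside the {L}-residue sequence"
            )
        if context.wt_at(key.position) != key.wt:
            raise InputError(
                f"{key.token}: wild-type residue disagrees with sequence "
                f"({context.wt_at(key.position)} at {key.position})"
            )

    missense = df.loc[_missense_mask(df)]
    pos_sum = missense.groupby("position")["score"].sum()
    pos_count = missense.groupby("position")["score"].count()
    measured_score = dict(zip(missense["variant"], missense["score"]))

    pred_lookup: dict[str, pd.Series] = {}
    if predictors is not None:
        pred_lookup = {row.variant: row for row in predictors.itertuples()}

    struct_lookup: dict[int, tuple[str, float]] = {}
    if context.structure is not None:
        struct_lookup = {
            int(r.position): (r.ss_class, float(r.rsa))
            for r in context.structure.itertuples()
        }

    rows = []
    for key in targets:
        tok = key.token
        s = pos_sum.get(key.position, 0.0)
        c = int(pos_count.get(key.position, 0))
        if tok in measured_score:
            s -= measured_score[tok]
            c -= 1
        pm = s / c if c > 0 else math.nan

        row: dict[str, object] = {
            "variant": tok, "position": key.position, "wt": key.wt, "alt": key.alt,
            "pos_mean_score": pm,
        }
        for name, scale in PROPERTY_SCALES:
            w, a = scale[key.wt], scale[key.alt]
            row[f"{name}_wt"] = w
            row[f"{name}_alt"] = a
            row[f"{name}_delta"] = a - w
        row["blosum62"] = float(blosum62(key.wt, key.alt))

        pred = pred_lookup.get(tok)
        for col in ("polyphen2", "provean", "sift"):
            val = getattr(pred, col, math.nan) if pred is not None else math.nan
            row[col] = float(val) if pd.notna(val) else math.nan

        if key.position in struct_lookup:
            ss, rsa = struct_lookup[key.position]
            row["ss_H"] = 1.0 if ss == "H" else 0.0
            row["ss_E"] = 1.0 if ss == "E" else 0.0
            row["ss_C"] = 1.0 if ss == "C" else 0.0
            row["rsa"] = rsa
        else:
            row["ss_H"] = row["ss_E"] = row["ss_C"] = row["rsa"] = math.nan
        rows.append(row)

    out = pd.DataFrame(rows, columns=ID_COLUMNS + feature_schema())
    return out


def all_missense_targets(context: ProteinContext) -> list[VariantKey]:
    """Every missense substitution cell of the map, in map order."""
    targets = []
    for pos in range(1, len(context) + 1):
        wt = context.wt_at(pos)
        for alt in AA_ALPHABET:
            if alt != wt:
                targets.append(VariantKey(pos, wt, alt))
    return targets
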