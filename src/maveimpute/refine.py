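"""Inverse-variance refinement and assembly of the complete map.

A measured score m with standard error sigma_m and its model prediction
i with standard error sigma_i are combined by precision weighting:

    refined = (m / sigma_m^2 + i / sigma_i^2) / (1 / sigma_m^2 + 1 / sigma_i^2)
    sigma   = (1 / sigma_m^2 + 1 / sigma_i^2) ** -0.5

so the refined score always lies between its inputs and its standard
error never exceeds the smaller input error. The assembled map covers
all L x 21 cells (19 missense + synonymous + stop per position) with
per-cell provenance:

* ``refined``   — measured, passed the quality cutoff, combined with the
  model prediction;
* ``imputed``   — no measurement survived the cutoff; pure prediction;
* ``measured``  — stop/synonymous anchor cells carrying a measurement;
* ``undefined`` — stop/synonymous cells never measured (left blank; the
  model does not predict them).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .aminoacids import AA_ALPHABET, STOP, SYNONYMOUS
from .error_model import ErrorEstimate
from .exceptions import AssemblyError
from .io_variants import ProteinContext, VariantKey
from .normalize import ScaleAnchors

PROVENANCE_VALUES = ("measured", "imputed", "refined", "undefined")

MAP_COLUMNS = ["position", "wt", "alt", "score", "stderr", "provenance"]


@dataclasses.dataclass
class VEMap:
    """A complete position x substitution variant-effect map.

    ``frame`` is long-format with one row per cell and columns
    ``position, wt, alt, score, stderr, provenance``; ``alt`` uses
    ``'='`` for the synonymous cell and ``'*'`` for stop.
    """

    frame: pd.DataFrame
    anchors: Optional[ScaleAnchors] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def length(self) -> int:
        return int(self.frame["position"].max())

    def to_frame(self) -> pd.DataFrame:
        return self.frame[MAP_COLUMNS]

    def cell(self, position: int, alt: str) -> pd.Series:
        sel = self.frame.loc[
            (self.frame["position"] == position) & (self.frame["alt"] == alt)
        ]
        if sel.empty:
            raise KeyError(f"no cell at position {position}, substitution {alt!r}")
        return sel.iloc[0]

    def provenance_counts(self) -> dict[str, int]:
        return self.frame["provenance"].value_counts().to_dict()

    def validate(self) -> None:
        """Assert the map's structural invariants."""
        frame = self.frame
        expected = 21 * self.length
        if len(frame) != expected:
            raise AssemblyError(f"map has {len(frame)} cells, expected {expected}")
        bad_prov = set(frame["provenance"]) - set(PROVENANCE_VALUES)
        if bad_prov:
            raise AssemblyError(f"unknown provenance values {sorted(bad_prov)}")
        missense = frame["alt"].isin(set(AA_ALPHABET)) & (frame["alt"] != frame["wt"])
        scores = frame.loc[missense, "score"].to_numpy(dtype=float)
        errs = frame.loc[missense, "stderr"].to_numpy(dtype=float)
        if not (np.isfinite(scores).all() and np.isfinite(errs).all()):
            raise AssemblyError("a missense cell has a non-finite score or stderr")

    def equals(self, other: "VEMap") -> bool:
        return self.to_frame().equals(other.to_frame()) and self.anchors == other.anchors


def refine_score(
    m: float, sigma_m: float, i: float, sigma_i: float
) -> tuple[float, float]:
    """Inverse-variance-weighted combination of a measured and an
    imputed score; returns ``(refined score, refined sigma)``."""
    if sigma_m <= 0 or sigma_i <= 0:
        raise ValueError(
            f"standard errors must be positive (got {sigma_m}, {sigma_i})"
        )
    wm, wi = 1.0 / sigma_m**2, 1.0 / sigma_i**2
    score = (wm * m + wi * i) / (wm + wi)
    sigma = (wm + wi) ** -0.5
    return score, sigma


def assemble_map(
    df: pd.DataFrame,
    predictions: Mapping[str, float],
    errors: Mapping[str, ErrorEstimate],
    imputed_sigmas: Mapping[str, float],
    context: ProteinContext,
    anchors: Optional[ScaleAnchors] = None,
    quality_cutoff: Optional[float] = None,
    below_cutoff: str = "impute",
    metadata: Optional[dict] = None,
) -> VEMap:
    """Assemble the complete variant-effect map.

    ``df`` holds all measured records on the normalized corrected scale;
    ``predictions`` and ``imputed_sigmas`` must cover every missense
    cell (keyed by compact variant token); ``errors`` maps measured
    tokens to their regularized error estimates. Measured missense cells
    passing the cutoff are refined; below-cutoff measurements are
    replaced by pure imputation unless ``below_cutoff='refine'``.
    Stop/synonymous cells carry measured values regardless of cutoff.
    """
    if below_cutoff not in ("impute", "refine"):
        raise ValueError("below_cutoff must be 'impute' or 'refine'")
    cutoff = -math.inf if quality_cutoff is None else quality_cutoff

    measured = {row.variant: row for row in df.itertuples()}
    rows = []
    missing_cells = []
    for pos in range(1, len(context) + 1):
        wt = context.wt_at(pos)
        for alt in AA_ALPHABET + STOP:
            if alt == wt:
                # synonymous cell, anchored at wild-type function
                tok = VariantKey(pos, wt, SYNONYMOUS).token
                rec = measured.get(tok)
                if rec is not None:
                    err = errors[tok].sigma_regularized
                    rows.append((pos, wt, SYNONYMOUS, 1.0, err, "measured"))
                else:
                    rows.append((pos, wt, SYNONYMOUS, math.nan, math.nan, "undefined"))
                continue
            if alt == STOP:
                tok = VariantKey(pos, wt, STOP).token
                rec = measured.get(tok)
                if rec is not None:
                    err = errors[tok].sigma_regularized
                    rows.append((pos, wt, STOP, float(rec.score), err, "measured"))
                else:
                    rows.append((pos, wt, STOP, math.nan, math.nan, "undefined"))
                continue

            tok = VariantKey(pos, wt, alt).token
            if tok not in predictions or tok not in imputed_sigmas:
                missing_cells.append(tok)
                continue
            pred = float(predictions[tok])
            sig_i = float(imputed_sigmas[tok])
            rec = measured.get(tok)
            if rec is not None and (rec.quality >= cutoff or below_cutoff == "refine"):
                sig_m = errors[tok].sigma_regularized
                score, sigma = refine_score(float(rec.score), sig_m, pred, sig_i)
                rows.append((pos, wt, alt, score, sigma, "refined"))
            else:
                rows.append((pos, wt, alt, pred, sig_i, "imputed"))

    if missing_cells:
        raise AssemblyError(
            f"{len(missing_cells)} missense cells lack predictions, "
            f"e.g. {missing_cells[:5]}"
        )
    frame = pd.DataFrame(rows, columns=MAP_COLUMNS)
    vemap = VEMap(frame=frame, anchors=anchors, metadata=dict(metadata or {}))
    vemap.validate()
    return vemap
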