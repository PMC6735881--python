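"""Function-score normalization to the stop/synonymous anchor scale.

MAVE function scores arrive on an arbitrary assay-specific axis. The
pipeline rescales them so that the median score of stop (nonsense)
variants is 0 — complete loss of function — and the median score of
synonymous variants is 1 — wild-type-like function:

    rescaled = (score - stop_median) / (syn_median - stop_median)

Variants that appear to exceed wild-type function (rescaled score > 1)
are treated as likely deleterious and reciprocal-transformed to 1/score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .aminoacids import STOP, SYNONYMOUS
from .exceptions import AnchorError


@dataclasses.dataclass(frozen=True)
class ScaleAnchors:
    """Raw-scale medians of the two anchor variant classes."""

    stop_median: float
    syn_median: float

    def __post_init__(self) -> None:
        if self.syn_median == self.stop_median:
            raise AnchorError(
                "stop and synonymous medians coincide; rescaling is undefined"
            )

    @property
    def scale(self) -> float:
        return self.syn_median - self.stop_median


def fit_anchors(df: pd.DataFrame) -> ScaleAnchors:
    """Fit normalization anchors from a raw score table.

    Requires at least one stop and one synonymous variant; medians use
    the midpoint convention for even counts.
    """
    stops = df.loc[df["alt"] == STOP, "score"]
    syns = df.loc[df["alt"] == SYNONYMOUS, "score"]
    if stops.empty or syns.empty:
        missing = "stop" if stops.empty else "synonymous"
        raise AnchorError(
            f"no {missing} variants in the score table; normalization anchors "
            "cannot be fit — pre-normalize the scores and pass "
            "prenormalized=True"
        )
    return ScaleAnchors(float(stops.median()), float(syns.median()))


def rescale(score, anchors: ScaleAnchors):
    """Rescale a raw score (scalar or array) to the anchor scale."""
    arr = (np.asarray(score, dtype=float) - anchors.stop_median) / anchors.scale
    return float(arr) if np.isscalar(score) else arr


def rescale_frame(df: pd.DataFrame, anchors: ScaleAnchors) -> pd.DataFrame:
    """Rescale the ``score`` and ``sd`` columns of a score table.

    sd is divided by ``|syn_median - stop_median|`` (an affine map scales
    dispersion by the absolute slope).
    """
    out = df.copy()
    out["score"] = rescale(out["score"].to_numpy(), anchors)
    out["sd"] = out["sd"].to_numpy(dtype=float) / abs(anchors.scale)
    return out


def correct_adaptive(score):
    """Reciprocal-transform apparently-adaptive scores.

    Scores exceeding the wild-type score of 1 map to their reciprocal;
    scores <= 1 are unchanged. Idempotent and continuous at 1.
    """
    arr = np.asarray(score, dtype=float)
    out = arr.copy()
    np.divide(1.0, arr, out=out, where=arr > 1.0)
    return float(out) if np.isscalar(score) else out


def correct_adaptive_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`correct_adaptive` to a rescaled score table.

    sd is propagated through the reciprocal by the first-order delta
    method: sd' = sd / score**2 for score > 1.
    """
    out = df.copy()
    score = out["score"].to_numpy(dtype=float)
    sd = out["sd"].to_numpy(dtype=float)
    flip = score > 1.0
    new_sd = sd.copy()
    np.divide(sd, score**2, out=new_sd, where=flip)
    new_score = score.copy()
    np.divide(1.0, score, out=new_score, where=flip)
    out["sd"] = new_sd
    out["score"] = new_score
    return out
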