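"""Regularized standard errors for measured and imputed scores.

With enough replicates (K or more) the per-variant standard error is
taken directly from the replicates. With fewer, the measured dispersion
is unreliable, so it is shrunk toward a prior expectation obtained from
an overall regression of dispersion against function score across the
whole dataset. The shrinkage pools in variance space:

    sigma_reg^2 = (prior_df * sigma_prior^2 + (n_reps - 1) * sigma_meas^2)
                  / (prior_df + n_reps - 1)

which returns the prior at n_reps = 1 (no within-variant dispersion
information) and lies between the two inputs otherwise. Imputed scores
receive the model's cross-validation RMSE as their standard error,
optionally inflated at sparsely measured positions.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError, ModelError
from .io_variants import MeasuredRecord, VariantKey
from .model import ModelBundle

log = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_PRIOR_DF = 2.0
SIGMA_FLOOR = 1e-6
MIN_PRIOR_RECORDS = 10


@dataclasses.dataclass(frozen=True)
class ErrorEstimate:
    """Per-variant uncertainty before and after regularization."""

    sigma_measured: float
    sigma_prior: float
    sigma_regularized: float
    n_reps: int


@dataclasses.dataclass(frozen=True)
class SigmaPrior:
    """Clamped linear map from function score to expected dispersion.

    Evaluable at any finite score: the input is clamped to the observed
    score range and the output floored at a small positive value, so the
    prior is monotone-safe under extrapolation.
    """

    slope: float
    intercept: float
    score_min: float
    score_max: float
    floor: float = SIGMA_FLOOR

    def __call__(self, score):
        x = np.clip(np.asarray(score, dtype=float), self.score_min, self.score_max)
        out = np.maximum(self.slope * x + self.intercept, self.floor)
        return float(out) if np.isscalar(score) else out


def fit_sigma_prior(df: pd.DataFrame, floor: float = SIGMA_FLOOR) -> SigmaPrior:
    """Fit the dispersion-vs-score prior by weighted least squares.

    Records with finite sd contribute, weighted by replicate count. With
    fewer than 10 usable records the prior degrades to a constant (the
    median sd) with a warning.
    """
    score = df["score"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float)
    w = df["n_reps"].to_numpy(dtype=float)
    ok = np.isfinite(score) & np.isfinite(sd)
    if not ok.any():
        raise InputError(
            "no records carry a finite sd; cannot fit the error prior — "
            "supply per-variant sd values"
        )
    score, sd, w = score[ok], sd[ok], w[ok]
    lo, hi = float(score.min()), float(score.max())
    if len(score) < MIN_PRIOR_RECORDS or lo == hi:
        warnings.warn(
            f"only {len(score)} records with sd; using a constant error prior",
            stacklevel=2,
        )
        return SigmaPrior(0.0, float(np.median(sd)), lo, hi, floor)
    slope, intercept = np.polyfit(score, sd, 1, w=w)
    return SigmaPrior(float(slope), float(intercept), lo, hi, floor)


def regularize_sigma(
    record,
    prior: SigmaPrior,
    K: int = DEFAULT_K,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> ErrorEstimate:
    """Regularized standard error for one measured record.

    ``record`` may be a :class:`MeasuredRecord` or a score-table row
    (anything with ``score``, ``sd`` and ``n_reps`` attributes). With
    n_reps >= K the measured sd is returned unchanged; with missing sd
    or a single replicate the prior is returned; otherwise the pooled
    estimate lies between the two in variance space.
    """
    if K < 2:
        raise InputError(f"K must be >= 2, got {K}")
    score = float(record.score)
    sd = float(record.sd)
    n = int(record.n_reps)
    sigma_prior = float(prior(score))
    sigma_measured = sd if math.isfinite(sd) and sd >= 0 else math.nan

    if math.isnan(sigma_measured) or n < 2:
        sigma_reg = sigma_prior
    elif n >= K:
        sigma_reg = sigma_measured
    else:
        var = (prior_df * sigma_prior**2 + (n - 1) * sigma_measured**2) / (
            prior_df + n - 1
        )
        sigma_reg = math.sqrt(var)
    return ErrorEstimate(
        sigma_measured=sigma_measured,
        sigma_prior=sigma_prior,
        sigma_regularized=sigma_reg,
        n_reps=n,
    )


def imputed_sigma(
    bundle: ModelBundle,
    key: Optional[VariantKey] = None,
    n_measured_at_position: Optional[int] = None,
    low_coverage_inflation: float = 1.0,
    min_position_count: int = 3,
    floor: float = SIGMA_FLOOR,
) -> float:
    """Standard error assigned to an imputed (model-predicted) score.

    The global cross-validation RMSE of the trained bundle, inflated by
    ``low_coverage_inflation`` at positions with fewer than
    ``min_position_count`` measured variants, and floored to stay
    usable as an inverse-variance weight.
    """
    if bundle.regressor is None or not math.isfinite(bundle.cv_rmse):
        raise ModelError("model bundle is not trained; no imputation error available")
    sigma = bundle.cv_rmse
    if (
        n_measured_at_position is not None
        and n_measured_at_position < min_position_count
    ):
        sigma *= low_coverage_inflation
    return max(sigma, floor)
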