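"""Gradient-boosted-tree imputation model.

The regressor is retrained per protein on measured missense variants
whose quality passes a cutoff. The cutoff may be user-supplied or
selected automatically: the top 20% of variants ranked by quality score
are held out as a fixed test set, candidate cutoffs (deciles of the
remaining pool's quality distribution) are each used to train a model on
the pool, and the cutoff minimizing test RMSE wins (ties go to the
smaller cutoff, i.e. more data).

Feature importance follows the boosted-tree convention: the number of
times a feature is used for splitting, weighted by the squared
improvement in error attributable to the split, averaged over trees and
normalized to sum to 1.

Missing feature values never abort training or prediction: the design
matrix is median-filled with per-feature missingness indicator columns
appended, and the fill values are frozen into the trained bundle.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .exceptions import ModelError
from .features import feature_schema, _missense_mask
from .io_variants import VariantKey

log = logging.getLogger(__name__)

#: Conservative defaults for small-n tabular regression.
DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 500,
    "learning_rate": 0.05,
    "max_depth": 3,
    "subsample": 0.8,
}

MIN_TRAINING_RECORDS = 10
TEST_FRACTION = 0.2
N_CV_FOLDS = 10

BUNDLE_FORMAT_VERSION = 1


@dataclasses.dataclass
class ModelBundle:
    """A trained regressor plus the metadata needed to reuse it."""

    regressor: GradientBoostingRegressor
    schema: list[str]
    quality_cutoff: float
    cv_rmse: float
    importances: dict[str, float]
    seed: int
    fill_values: dict[str, float]
    hyperparameters: dict[str, float]

    def save(self, path) -> None:
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "regressor": self.regressor,
            "schema": self.schema,
            "quality_cutoff": self.quality_cutoff,
            "cv_rmse": self.cv_rmse,
            "importances": self.importances,
            "seed": self.seed,
            "fill_values": self.fill_values,
            "hyperparameters": self.hyperparameters,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        payload = joblib.load(path)
        version = payload.pop("format_version", None)
        if version != BUNDLE_FORMAT_VERSION:
            raise ModelError(f"unsupported model bundle version {version!r}")
        return cls(**payload)


def _sorted_missense(df: pd.DataFrame) -> pd.DataFrame:
    """Measured missense records in deterministic quality-then-key order."""
    sel = df.loc[_missense_mask(df)].copy()
    return sel.sort_values(
        ["quality", "position", "alt"], ascending=[False, True, True], kind="mergesort"
    )


def select_test_set(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split measured missense records into (test, pool).

    The test set is the top 20% of variants ranked by quality score
    (size ``ceil(0.2 n)``); quality ties at the boundary are broken
    deterministically by variant key order. Used as the fixed evaluation
    set for automatic quality-cutoff selection.
    """
    sel = _sorted_missense(df)
    n = len(sel)
    if n < MIN_TRAINING_RECORDS:
        raise ModelError(
            f"only {n} measured missense records; too few for automatic "
            "cutoff selection — supply a quality cutoff explicitly"
        )
    n_test = math.ceil(TEST_FRACTION * n)
    test = sel.iloc[:n_test].reset_index(drop=True)
    pool = sel.iloc[n_test:].reset_index(drop=True)
    return test, pool


def make_folds(n: int, seed: int, n_splits: int = N_CV_FOLDS):
    """Deterministic shuffled K-fold partition of ``range(n)``.

    The same (n, seed) always yields the same folds, so every method in a
    comparison sees identical train/validation partitions.
    """
    kf = KFold(n_splits=min(n_splits, n), shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _design_matrix(features: pd.DataFrame, schema: Sequence[str]) -> np.ndarray:
    return features.loc[:, list(schema)].to_numpy(dtype=float)


def _fit_fill(X: np.ndarray, schema: Sequence[str]) -> dict[str, float]:
    fills = {}
    for j, name in enumerate(schema):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        fills[name] = float(np.median(finite)) if finite.size else 0.0
    return fills


def _transform(X: np.ndarray, schema: Sequence[str], fills: dict[str, float]) -> np.ndarray:
    miss = ~np.isfinite(X)
    filled = X.copy()
    for j, name in enumerate(schema):
        filled[miss[:, j], j] = fills[name]
    return np.hstack([filled, miss.astype(float)])


def _align(df: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Feature rows for the records in ``df``, in ``df`` order."""
    feats = features.set_index("variant")
    missing = [v for v in df["variant"] if v not in feats.index]
    if missing:
        raise ModelError(
            f"no feature rows for {len(missing)} records, e.g. {missing[:5]}"
        )
    return feats.loc[df["variant"]].reset_index()


def _new_regressor(seed: int, hyperparameters: dict) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(random_state=seed, **hyperparameters)


def _fit_predict(
    reg, Xtr, ytr, Xval, schema, fills=None
) -> np.ndarray:
    fills = fills if fills is not None else _fit_fill(Xtr, schema)
    reg.fit(_transform(Xtr, schema, fills), ytr)
    return reg.predict(_transform(Xval, schema, fills))


def _rmse(y, yhat) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


def select_quality_cutoff(
    df: pd.DataFrame,
    features: pd.DataFrame,
    candidate_cutoffs: Optional[Sequence[float]] = None,
    seed: int = 42,
    hyperparameters: Optional[dict] = None,
) -> float:
    """Choose the quality cutoff that best predicts the held-out test set.

    For each candidate cutoff (default: deciles of the pool quality
    distribution) a model is trained on pool records with quality >=
    cutoff and scored by RMSE on the fixed top-20%-quality test set.
    Candidates leaving fewer than 10 training records are skipped; RMSE
    ties resolve to the smaller cutoff.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {}))
    test, pool = select_test_set(df)
    if candidate_cutoffs is None:
        qs = np.quantile(pool["quality"].to_numpy(), np.arange(0.0, 1.0, 0.1))
        candidate_cutoffs = sorted(set(float(q) for q in qs))
    schema = feature_schema()
    Xtest = _design_matrix(_align(test, features), schema)
    ytest = test["score"].to_numpy(dtype=float)

    best_cutoff, best_rmse = None, math.inf
    for c in sorted(candidate_cutoffs):
        train_df = pool.loc[pool["quality"] >= c]
        if len(train_df) < MIN_TRAINING_RECORDS:
            log.info("cutoff %.4g skipped: %d records", c, len(train_df))
            continue
        X = _design_matrix(_align(train_df, features), schema)
        y = train_df["score"].to_numpy(dtype=float)
        pred = _fit_predict(_new_regressor(seed, hp), X, y, Xtest, schema)
        rmse = _rmse(ytest, pred)
        log.info("cutoff %.4g: n=%d test RMSE %.5f", c, len(train_df), rmse)
        if rmse < best_rmse:
            best_cutoff, best_rmse = float(c), rmse
    if best_cutoff is None:
        raise ModelError(
            "every candidate quality cutoff left fewer than "
            f"{MIN_TRAINING_RECORDS} training records"
        )
    return best_cutoff


def train(
    df: pd.DataFrame,
    features: pd.DataFrame,
    cutoff: float,
    seed: int = 42,
    hyperparameters: Optional[dict] = None,
) -> ModelBundle:
    """Train the gradient-boosted-tree model on records passing ``cutoff``.

    ``cv_rmse`` is the out-of-fold RMSE of a 10-fold cross-validation on
    the training records (fold fills refit per fold); importances are
    averaged over trees and normalized to sum to 1, with each feature's
    missingness-indicator importance folded into the feature itself.
    Deterministic for a fixed seed.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {}))
    sel = df.loc[_missense_mask(df) & (df["quality"] >= cutoff)]
    sel = sel.sort_values(["position", "alt"], kind="mergesort").reset_index(drop=True)
    if len(sel) < MIN_TRAINING_RECORDS:
        raise ModelError(
            f"{len(sel)} records pass quality cutoff {cutoff}; "
            f"at least {MIN_TRAINING_RECORDS} required"
        )
    bad = sel.loc[~np.isfinite(sel["score"].to_numpy(dtype=float)), "variant"]
    if len(bad):
        raise ModelError(f"non-finite training scores for {bad.tolist()[:5]}")

    schema = feature_schema()
    X = _design_matrix(_align(sel, features), schema)
    y = sel["score"].to_numpy(dtype=float)

    oof = np.full(len(y), np.nan)
    for tr_idx, val_idx in make_folds(len(y), seed):
        oof[val_idx] = _fit_predict(
            _new_regressor(seed, hp), X[tr_idx], y[tr_idx], X[val_idx], schema
        )
    cv_rmse = _rmse(y, oof)

    fills = _fit_fill(X, schema)
    reg = _new_regressor(seed, hp)
    reg.fit(_transform(X, schema, fills), y)

    raw_imp = reg.feature_importances_
    m = len(schema)
    agg = raw_imp[:m] + raw_imp[m:]
    total = agg.sum()
    if total > 0:
        agg = agg / total
    importances = {name: float(v) for name, v in zip(schema, agg)}

    log.info("trained GBT on %d records (cutoff %.4g), CV RMSE %.5f",
             len(sel), cutoff, cv_rmse)
    return ModelBundle(
        regressor=reg, schema=list(schema), quality_cutoff=float(cutoff),
        cv_rmse=cv_rmse, importances=importances, seed=seed,
        fill_values=fills, hyperparameters=hp,
    )


def predict(bundle: ModelBundle, features: pd.DataFrame) -> pd.Series:
    """Predict function scores for the feature rows in ``features``.

    Returns a Series indexed by variant token; raises on schema
    mismatch, listing missing and extra feature columns.
    """
    feat_cols = [c for c in features.columns if c not in ("variant", "position", "wt", "alt")]
    missing = [c for c in bundle.schema if c not in feat_cols]
    extra = [c for c in feat_cols if c not in bundle.schema]
    if missing or extra:
        raise ModelError(
            f"feature schema mismatch: missing {missing}, unexpected {extra}"
        )
    X = _design_matrix(features, bundle.schema)
    pred = bundle.regressor.predict(_transform(X, bundle.schema, bundle.fill_values))
    return pd.Series(pred, index=pd.Index(features["variant"], name="variant"))


def _positional_mean_predict(
    train_pos: np.ndarray, train_y: np.ndarray, val_pos: np.ndarray
) -> np.ndarray:
    """Leave-fold-out positional-mean baseline predictor."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p, y in zip(train_pos, train_y):
        sums[p] = sums.get(p, 0.0) + y
        counts[p] = counts.get(p, 0) + 1
    global_mean = float(np.mean(train_y))
    return np.array(
        [sums[p] / counts[p] if counts.get(p) else global_mean for p in val_pos]
    )


def compare_methods(
    df: pd.DataFrame,
    features: pd.DataFrame,
    seed: int = 42,
    cutoff: Optional[float] = None,
    hyperparameters: Optional[dict] = None,
) -> pd.DataFrame:
    """10-fold CV RMSE of GBT, random forest, linear regression and the
    positional-mean baseline on identical folds.

    Returns a DataFrame (method, cv_rmse) sorted ascending by RMSE; no
    winner is asserted.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {}))
    sel = df.loc[_missense_mask(df)]
    if cutoff is not None:
        sel = sel.loc[sel["quality"] >= cutoff]
    sel = sel.sort_values(["position", "alt"], kind="mergesort").reset_index(drop=True)
    if len(sel) < MIN_TRAINING_RECORDS:
        raise ModelError(f"{len(sel)} records; at least {MIN_TRAINING_RECORDS} required")

    schema = feature_schema()
    X = _design_matrix(_align(sel, features), schema)
    y = sel["score"].to_numpy(dtype=float)
    pos = sel["position"].to_numpy(dtype=int)
    folds = make_folds(len(y), seed)

    def model_factory(name):
        if name == "gbt":
            return _new_regressor(seed, hp)
        if name == "random_forest":
            return RandomForestRegressor(
                n_estimators=hp["n_estimators"], random_state=seed, n_jobs=1
            )
        if name == "linear_regression":
            return LinearRegression()
        raise ValueError(name)

    rows = []
    for name in ("gbt", "random_forest", "linear_regression"):
        oof = np.full(len(y), np.nan)
        for tr, val in folds:
            oof[val] = _fit_predict(model_factory(name), X[tr], y[tr], X[val], schema)
        rows.append((name, _rmse(y, oof)))

    oof = np.full(len(y), np.nan)
    for tr, val in folds:
        oof[val] = _positional_mean_predict(pos[tr], y[tr], pos[val])
    rows.append(("positional_mean", _rmse(y, oof)))

    out = pd.DataFrame(rows, columns=["method", "cv_rmse"])
    return out.sort_values("cv_rmse", kind="mergesort").reset_index(drop=True)
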