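"""Test-set selection, cutoff search, training, comparison and prediction."""

import numpy as np
import pandas as pd
import pytest

from conftest import FAST_HP, normalized_scores
from maveimpute import ModelError, VariantKey
from maveimpute.features import all_missense_targets, build_feature_table, feature_schema
from maveimpute.io_variants import MeasuredRecord, records_to_frame
from maveimpute.model import (
    compare_methods,
    make_folds,
    predict,
    select_quality_cutoff,
    select_test_set,
    train,
)
from maveimpute import synth


def _records(n, quality=None, scores=None):
    """n missense records at distinct positions of an all-Ala protein."""
    recs = []
    for i in range(n):
        q = quality[i] if quality is not None else float(i)
        s = scores[i] if scores is not None else 0.5
        recs.append(
            MeasuredRecord(VariantKey(i + 1, "A", "V"), s, sd=0.1, n_reps=3, quality=q)
        )
    return records_to_frame(recs)


class TestSelectTestSet:
    def test_top_20_percent_by_quality(self):
        test, pool = select_test_set(_records(100))
        assert len(test) == 20
        assert len(pool) == 80
        assert test["quality"].min() > pool["quality"].max()
        assert set(test["variant"]).isdisjoint(pool["variant"])

    def test_ceil_sizing_and_highest_quality(self):
        test, pool = select_test_set(_records(10))
        assert len(test) == 2
        assert sorted(test["quality"]) == [8.0, 9.0]

    def test_equal_qualities_split_deterministically(self):
        df = _records(10, quality=[1.0] * 10)
        t1, p1 = select_test_set(df)
        t2, p2 = select_test_set(df.sample(frac=1.0, random_state=0))
        assert list(t1["variant"]) == list(t2["variant"])

    def test_too_few_records(self):
        with pytest.raises(ModelError, match="cutoff"):
            select_test_set(_records(5))


class TestFolds:
    def test_folds_partition_exactly(self):
        folds = make_folds(57, seed=3)
        assert len(folds) == 10
        seen = np.concatenate([val for _, val in folds])
        assert sorted(seen) == list(range(57))
        for tr, val in folds:
            assert set(tr).isdisjoint(val)
            assert len(tr) + len(val) == 57

    def test_folds_deterministic(self):
        a = make_folds(40, seed=9)
        b = make_folds(40, seed=9)
        for (ta, va), (tb, vb) in zip(a, b):
            assert (ta == tb).all() and (va == vb).all()


@pytest.fixture(scope="module")
def trained(small_dataset, small_scores):
    targets = all_missense_targets(small_dataset.context)
    feats = build_feature_table(
        small_scores, small_dataset.context, targets, small_dataset.predictors
    )
    bundle = train(small_scores, feats, cutoff=0.0, seed=5, hyperparameters=FAST_HP)
    return small_dataset, small_scores, feats, bundle


class TestTrain:
    def test_determinism(self, trained):
        ds, scores, feats, bundle = trained
        again = train(scores, feats, cutoff=0.0, seed=5, hyperparameters=FAST_HP)
        p1 = predict(bundle, feats)
        p2 = predict(again, feats)
        assert (p1.to_numpy() == p2.to_numpy()).all()
        assert bundle.importances == again.importances

    def test_importances_normalized_nonnegative(self, trained):
        *_, bundle = trained
        vals = np.array(list(bundle.importances.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0)
        assert set(bundle.importances) == set(feature_schema())

    def test_cv_rmse_nonnegative_finite(self, trained):
        *_, bundle = trained
        assert np.isfinite(bundle.cv_rmse) and bundle.cv_rmse >= 0

    def test_too_few_training_records(self, trained):
        ds, scores, feats, _ = trained
        with pytest.raises(ModelError):
            train(scores, feats, cutoff=1e9, seed=5, hyperparameters=FAST_HP)

    def test_bundle_round_trip(self, tmp_path, trained):
        ds, scores, feats, bundle = trained
        path = tmp_path / "model.joblib"
        bundle.save(path)
        from maveimpute.model import ModelBundle

        back = ModelBundle.load(path)
        assert back.schema == bundle.schema          # schema round-trips
        assert back.importances == bundle.importances
        assert (predict(back, feats).to_numpy() == predict(bundle, feats).to_numpy()).all()


class TestPredict:
    def test_prediction_completeness_and_finiteness(self, trained):
        ds, scores, feats, bundle = trained
        preds = predict(bundle, feats)
        assert len(preds) == 19 * len(ds.context)
        assert np.isfinite(preds.to_numpy()).all()

    def test_row_order_invariance(self, trained):
        ds, scores, feats, bundle = trained
        shuffled = feats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p1 = predict(bundle, feats).sort_index()
        p2 = predict(bundle, shuffled).sort_index()
        assert (p1.to_numpy() == p2.to_numpy()).all()

    def test_schema_mismatch_reported(self, trained):
        ds, scores, feats, bundle = trained
        broken = feats.drop(columns=["blosum62"]).assign(bogus=1.0)
        with pytest.raises(ModelError, match="blosum62"):
            predict(bundle, broken)


def test_auto_cutoff_excludes_pure_noise_quality_band():
    """When low-quality records are pure noise, the selected cutoff moves
    above the minimum quality (checked against a brute-force grid scan)."""
    rng = np.random.default_rng(0)
    n_pos = 40
    recs = []
    pos_effect = rng.uniform(0.0, 1.0, n_pos)
    for i in range(n_pos):
        for j, alt in enumerate("VLIMFW"):
            clean = j < 4
            score = pos_effect[i] if clean else float(rng.uniform(-1, 2))
            q = 5.0 if clean else 1.0
            recs.append(
                MeasuredRecord(
                    VariantKey(i + 1, "A", alt), score, sd=0.05, n_reps=3, quality=q
                )
            )
    df = records_to_frame(recs)
    ctx_seq = "A" * n_pos
    from maveimpute import ProteinContext

    feats = build_feature_table(
        df, ProteinContext(sequence=ctx_seq), [VariantKey(int(p), "A", a) for p, a in zip(df.position, df.alt)]
    )
    cutoff = select_quality_cutoff(df, feats, seed=0, hyperparameters=FAST_HP)
    assert cutoff > df["quality"].min()


def test_user_supplied_cutoff_bypasses_search(small_dataset, small_scores):
    """train honors an explicit cutoff: only records above it are used."""
    targets = all_missense_targets(small_dataset.context)
    feats = build_feature_table(small_scores, small_dataset.context, targets)
    q75 = float(small_scores["quality"].quantile(0.75))
    bundle = train(small_scores, feats, cutoff=q75, seed=2, hyperparameters=FAST_HP)
    assert bundle.quality_cutoff == q75


def test_degenerate_quality_grid_returns_single_cutoff():
    df = _records(30, quality=[2.0] * 30, scores=list(np.linspace(0, 1, 30)))
    seq = "A" * 30
    from maveimpute import ProteinContext

    feats = build_feature_table(
        df, ProteinContext(sequence=seq),
        [VariantKey(int(p), "A", a) for p, a in zip(df.position, df.alt)],
    )
    cutoff = select_quality_cutoff(df, feats, seed=0, hyperparameters=FAST_HP)
    assert cutoff == 2.0


class TestCompareMethods:
    def test_reports_all_methods_nonnegative(self, trained):
        ds, scores, feats, _ = trained
        out = compare_methods(scores, feats, seed=3, hyperparameters=FAST_HP)
        assert sorted(out["method"]) == [
            "gbt", "linear_regression", "positional_mean", "random_forest"
        ]
        assert (out["cv_rmse"] >= 0).all()
        assert out["cv_rmse"].is_monotonic_increasing

    def test_positional_mean_matches_brute_force_oracle(self):
        """The baseline row must equal a hand-computed leave-fold-out
        positional-mean predictor on a 3-position toy dataset."""
        rng = np.random.default_rng(4)
        recs = []
        alts = "CDEFGHIKLMNPQRSTVWY"
        for pos, base in ((1, 0.2), (2, 0.5), (3, 0.8)):
            for alt in alts[:12]:
                recs.append(
                    MeasuredRecord(
                        VariantKey(pos, "A", alt),
                        base + float(rng.normal(0, 0.05)),
                        sd=0.05, n_reps=3, quality=3.0,
                    )
                )
        df = records_to_frame(recs)
        from maveimpute import ProteinContext

        feats = build_feature_table(
            df, ProteinContext(sequence="AAA"),
            [VariantKey(int(p), "A", a) for p, a in zip(df.position, df.alt)],
        )
        out = compare_methods(df, feats, seed=4, hyperparameters=FAST_HP)
        reported = float(out.loc[out["method"] == "positional_mean", "cv_rmse"].iloc[0])

        # independent brute-force oracle over the same deterministic folds
        sel = df.sort_values(["position", "alt"], kind="mergesort").reset_index(drop=True)
        y = sel["score"].to_numpy()
        pos = sel["position"].to_numpy()
        oof = np.full(len(y), np.nan)
        for tr, val in make_folds(len(y), seed=4):
            for v in val:
                mask = pos[tr] == pos[v]
                oof[v] = y[tr][mask].mean() if mask.any() else y[tr].mean()
        oracle = float(np.sqrt(np.mean((y - oof) ** 2)))
        assert reported == pytest.approx(oracle, abs=1e-12)


def test_positional_truth_puts_top_importance_on_positional_mean():
    ds = synth.generate(
        synth.SynthConfig(length=40, seed=13, substitution_sd=0.0,
                          adaptive_fraction=0.0)
    )
    scores = normalized_scores(ds)
    feats = build_feature_table(
        scores, ds.context, all_missense_targets(ds.context), ds.predictors
    )
    bundle = train(scores, feats, cutoff=0.0, seed=13, hyperparameters=FAST_HP)
    assert max(bundle.importances, key=bundle.importances.get) == "pos_mean_score"
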