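"""Inverse-variance refinement and map assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import FAST_HP
from maveimpute import ProteinContext, VariantKey, refine_score
from maveimpute.aminoacids import AA_ALPHABET
from maveimpute.error_model import fit_sigma_prior, imputed_sigma, regularize_sigma
from maveimpute.exceptions import AssemblyError
from maveimpute.features import all_missense_targets, build_feature_table
from maveimpute.io_variants import MeasuredRecord, records_to_frame
from maveimpute.model import predict, train
from maveimpute.refine import assemble_map


class TestRefineScore:
    def test_worked_example(self):
        score, sigma = refine_score(0.4, 0.1, 0.8, 0.2)
        assert score == pytest.approx(0.48)
        assert sigma == pytest.approx(0.0894427, abs=1e-6)

    def test_equal_sigmas_average(self):
        score, _ = refine_score(0.3, 0.15, 0.7, 0.15)
        assert score == pytest.approx(0.5)

    def test_infinite_imputed_sigma_recovers_measurement(self):
        score, sigma = refine_score(0.4, 0.1, 0.8, 1e9)
        assert score == pytest.approx(0.4)
        assert sigma == pytest.approx(0.1)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            refine_score(0.4, 0.0, 0.8, 0.2)
        with pytest.raises(ValueError):
            refine_score(0.4, 0.1, 0.8, -1.0)

    @given(
        m=st.floats(-1, 2), i=st.floats(-1, 2),
        sm=st.floats(0.01, 1), si=st.floats(0.01, 1),
    )
    def test_refined_lies_between_inputs_with_smaller_sigma(self, m, i, sm, si):
        score, sigma = refine_score(m, sm, i, si)
        assert min(m, i) - 1e-12 <= score <= max(m, i) + 1e-12
        if m != i:
            assert min(m, i) < score < max(m, i) or math.isclose(m, i)
        assert sigma < min(sm, si)


@pytest.fixture(scope="module")
def assembled(small_dataset, small_scores):
    ds, df = small_dataset, small_scores
    feats = build_feature_table(df, ds.context, all_missense_targets(ds.context),
                                ds.predictors)
    cutoff = float(df["quality"].quantile(0.25))
    bundle = train(df, feats, cutoff=cutoff, seed=3, hyperparameters=FAST_HP)
    preds = predict(bundle, feats)
    prior = fit_sigma_prior(df)
    errors = {r.variant: regularize_sigma(r, prior) for r in df.itertuples()}
    sigmas = {v: imputed_sigma(bundle) for v in feats["variant"]}
    vemap = assemble_map(
        df, preds.to_dict(), errors, sigmas, ds.context, quality_cutoff=cutoff,
        metadata={"seed": 3},
    )
    return ds, df, cutoff, errors, sigmas, preds, vemap


class TestAssembleMap:
    def test_complete_over_all_cells(self, assembled):
        ds, *_, vemap = assembled
        assert len(vemap.to_frame()) == 21 * len(ds.context)
        vemap.validate()

    def test_missense_cells_finite(self, assembled):
        ds, *_, vemap = assembled
        frame = vemap.to_frame()
        missense = frame["alt"].isin(set(AA_ALPHABET)) & (frame["alt"] != frame["wt"])
        assert np.isfinite(frame.loc[missense, "score"]).all()
        assert np.isfinite(frame.loc[missense, "stderr"]).all()

    def test_provenance_rules(self, assembled):
        ds, df, cutoff, *_, vemap = assembled
        frame = vemap.to_frame()
        measured = df.set_index("variant")
        for row in frame.itertuples():
            if row.alt in ("=", "*"):
                continue
            tok = f"{row.wt}{row.position}{row.alt}"
            if tok in measured.index and measured.loc[tok, "quality"] >= cutoff:
                assert row.provenance == "refined"
            else:
                assert row.provenance == "imputed"

    def test_below_cutoff_measurement_is_imputed(self, assembled):
        ds, df, cutoff, *_, vemap = assembled
        below = df.loc[
            (df["quality"] < cutoff) & df["alt"].isin(set(AA_ALPHABET))
            & (df["alt"] != df["wt"])
        ]
        assert len(below) > 0
        for row in below.itertuples():
            assert vemap.cell(row.position, row.alt)["provenance"] == "imputed"

    def test_refined_stderr_below_both_inputs(self, assembled):
        ds, df, cutoff, errors, sigmas, preds, vemap = assembled
        frame = vemap.to_frame()
        refined = frame.loc[frame["provenance"] == "refined"]
        for row in refined.head(50).itertuples():
            tok = f"{row.wt}{row.position}{row.alt}"
            assert row.stderr < min(errors[tok].sigma_regularized, sigmas[tok])

    def test_refined_score_between_measured_and_imputed(self, assembled):
        ds, df, cutoff, errors, sigmas, preds, vemap = assembled
        measured = df.set_index("variant")["score"]
        frame = vemap.to_frame()
        refined = frame.loc[frame["provenance"] == "refined"]
        for row in refined.head(50).itertuples():
            tok = f"{row.wt}{row.position}{row.alt}"
            m, i = float(measured[tok]), float(preds[tok])
            assert min(m, i) - 1e-12 <= row.score <= max(m, i) + 1e-12

    def test_anchor_cells_measured_or_undefined(self, assembled):
        ds, df, *_ , vemap = assembled
        frame = vemap.to_frame()
        anchor = frame.loc[frame["alt"].isin(["=", "*"])]
        assert set(anchor["provenance"]) <= {"measured", "undefined"}
        syn = anchor.loc[(anchor["alt"] == "=") & (anchor["provenance"] == "measured")]
        assert (syn["score"] == 1.0).all()   # synonymous fixed at wild type

    def test_conservation_of_cells(self, assembled):
        ds, *_ , vemap = assembled
        counts = vemap.provenance_counts()
        total_defined = sum(v for k, v in counts.items() if k != "undefined")
        assert total_defined + counts.get("undefined", 0) == 21 * len(ds.context)
        missense_total = 19 * len(ds.context)
        assert counts.get("refined", 0) + counts.get("imputed", 0) == missense_total

    def test_missing_prediction_raises(self, assembled):
        ds, df, cutoff, errors, sigmas, preds, _ = assembled
        incomplete = dict(preds.to_dict())
        victim = next(iter(incomplete))
        del incomplete[victim]
        with pytest.raises(AssemblyError, match=victim):
            assemble_map(df, incomplete, errors, sigmas, ds.context,
                         quality_cutoff=cutoff)


def test_below_cutoff_refine_mode():
    """The config alternative refines even below-cutoff measurements."""
    ctx = ProteinContext(sequence="AC")
    recs = [
        MeasuredRecord(VariantKey(1, "A", "V"), 0.4, sd=0.1, n_reps=4, quality=0.5),
    ]
    df = records_to_frame(recs)
    preds = {VariantKey(p, w, a).token: 0.8
             for p, w in ((1, "A"), (2, "C")) for a in AA_ALPHABET if a != w}
    sigmas = {k: 0.2 for k in preds}

    class FlatPrior:
        def __call__(self, s):
            return 0.1

    errors = {r.variant: regularize_sigma(r, FlatPrior()) for r in df.itertuples()}
    vemap = assemble_map(df, preds, errors, sigmas, ctx, quality_cutoff=1.0,
                         below_cutoff="refine")
    cell = vemap.cell(1, "V")
    assert cell["provenance"] == "refined"
    assert cell["score"] == pytest.approx(0.48)
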