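"""LOESS drift correction, span selection and median normalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidqc import (
    RunParameters,
    build_injection_sequence,
    correct_batch_drift,
    cv_rsd,
    extract_run,
    loess_predict,
    make_synthetic_database,
    median_normalize_batches,
    normalize,
    select_span_loocv,
    simulate_run,
)
from lipidqc.filtering import qc_rsd_per_ion
from lipidqc.normalization import DEFAULT_SPAN_GRID


class TestLoessPredict:
    @given(
        st.floats(1e-3, 1e6),
        st.sampled_from([0.3, 0.5, 0.8, 1.0]),
    )
    def test_constants_are_reproduced(self, c, span):
        x = np.arange(10.0)
        pred = loess_predict(x, np.full(10, c), span, x)
        assert np.allclose(pred, c, rtol=1e-9)

    @pytest.mark.parametrize("span", [0.3, 0.6, 1.0])
    def test_linear_data_fitted_exactly(self, span):
        x = np.arange(12.0)
        y = 3.0 * x + 7.0
        x_new = np.array([0.5, 4.2, 11.0])
        assert np.allclose(
            loess_predict(x, y, span, x_new), 3.0 * x_new + 7.0, atol=1e-8
        )

    def test_extrapolation_clamps_to_boundary(self):
        x = np.arange(8.0)
        y = 2.0 * x + 1.0
        left = loess_predict(x, y, 1.0, -5.0)
        right = loess_predict(x, y, 1.0, 50.0)
        assert left == pytest.approx(1.0, abs=1e-8)
        assert right == pytest.approx(15.0, abs=1e-8)

    def test_agrees_with_statsmodels_on_linear_data(self):
        """Independent implementation check: on globally linear data both
        local-linear smoothers are exact, hence identical."""
        sm = pytest.importorskip("statsmodels.api")
        x = np.arange(15.0)
        y = -1.7 * x + 40.0
        xq = np.linspace(1.0, 13.0, 7)
        ours = loess_predict(x, y, 0.7, xq)
        theirs = sm.nonparametric.lowess(y, x, frac=0.7, it=0, xvals=xq)
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_input_validation(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            loess_predict(x[:3], x[:3], 0.5, 1.0)  # too few points
        with pytest.raises(ValueError):
            loess_predict(x, x, 1.5, 1.0)  # span out of range
        with pytest.raises(ValueError):
            loess_predict(np.full(10, 2.0), x, 0.5, 1.0)  # degenerate x


class TestSpanSelection:
    def test_noiseless_linear_selects_largest_span(self):
        x = np.arange(10.0)
        assert select_span_loocv(x, 2.0 * x + 5.0) == max(DEFAULT_SPAN_GRID)

    def test_matches_brute_force_loo_scan(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        y = np.sin(x / 6.0) + rng.normal(0.0, 0.05, 20)
        chosen = select_span_loocv(x, y)

        mses = {}
        for span in DEFAULT_SPAN_GRID:
            errs = []
            for i in range(len(x)):
                keep = np.arange(len(x)) != i
                errs.append(y[i] - loess_predict(x[keep], y[keep], span, x[i]))
            mses[span] = np.mean(np.square(errs))
        best = min(mses.values())
        tol = 1e-10 * (best + float(np.mean(y**2)))
        assert chosen == max(s for s in DEFAULT_SPAN_GRID if mses[s] <= best + tol)

    def test_too_few_points_raise(self):
        x = np.arange(4.0)
        with pytest.raises(ValueError):
            select_span_loocv(x, 2.0 * x)


@pytest.fixture(scope="module")
def drifting_run():
    db = make_synthetic_database(n_lipids=8, n_internal_standards=3, seed=21)
    plan = build_injection_sequence(
        n_study=60, n_batches=2, qc_interval=5, blank_interval=5,
        n_duplicate_pairs=0, seed=21,
    )
    params = RunParameters(
        noise_cv=0.0, baseline_noise=0.0, carryover_fraction=0.0,
        rt_quad_sd=0.0, rt_slope_sd=0.0, rt_shift_sd=0.0,
        rt_grid_step=0.01, seed=21,
    )
    truth, eics = simulate_run(db, plan, params)
    fm, _ = extract_run(eics, plan, db)
    return db, plan, params, truth, fm


class TestDriftCorrection:
    def test_drift_free_run_passes_through(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        quiet = dataclasses.replace(params, drift_amplitude=0.0, batch_scale_sigma=0.0)
        truth0, eics0 = simulate_run(db, plan, quiet)
        fm0, _ = extract_run(eics0, plan, db)
        corrected, audit = correct_batch_drift(fm0)
        nonblank = fm0.samples["sample_type"] != "blank"
        assert np.allclose(
            corrected.values.loc[nonblank], fm0.values.loc[nonblank], rtol=1e-9
        )
        assert (audit["fallback"] == "").all()

    def test_smooth_drift_removed_exactly_when_noise_free(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        normalized, audit = normalize(fm)
        post = qc_rsd_per_ion(normalized)
        assert post.max() <= 1e-6  # percent

    def test_qc_median_is_preserved_within_batch(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        corrected, _ = correct_batch_drift(fm)
        for batch, grp in fm.samples.groupby("batch"):
            qc_idx = grp.index[grp["sample_type"] == "qc"]
            for ion in fm.ion_ids:
                before = fm.values.loc[qc_idx, ion].median()
                after = corrected.values.loc[qc_idx, ion].median()
                assert after == pytest.approx(before, rel=1e-12)

    def test_scale_equivariance(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        ion = fm.ion_ids[0]
        scaled = fm.copy_with(values=fm.values.copy())
        scaled.values[ion] = scaled.values[ion] * 37.0
        base, _ = correct_batch_drift(fm)
        out, _ = correct_batch_drift(scaled)
        assert np.allclose(out.values[ion], base.values[ion] * 37.0, rtol=1e-9)

    def test_blanks_never_corrected(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        normalized, _ = normalize(fm)
        blanks = fm.samples.index[fm.samples["sample_type"] == "blank"]
        pd.testing.assert_frame_equal(
            normalized.values.loc[blanks], fm.values.loc[blanks]
        )

    def test_three_qcs_take_audited_fallback(self):
        db = make_synthetic_database(n_lipids=4, n_internal_standards=3, seed=22)
        plan = build_injection_sequence(
            n_study=9, n_batches=1, qc_interval=3, blank_interval=9,
            n_duplicate_pairs=0, seed=22,
        )
        params = RunParameters(rt_grid_step=0.02, seed=22)
        _, eics = simulate_run(db, plan, params)
        fm, _ = extract_run(eics, plan, db)
        corrected, audit = correct_batch_drift(fm)
        assert (audit["fallback"] == "too_few_qc").all()
        nonblank = fm.samples["sample_type"] != "blank"
        pd.testing.assert_frame_equal(
            corrected.values.loc[nonblank], fm.values.loc[nonblank]
        )


class TestMedianNormalization:
    def test_single_batch_is_unchanged(self):
        db = make_synthetic_database(n_lipids=4, n_internal_standards=3, seed=23)
        plan = build_injection_sequence(
            n_study=20, n_batches=1, qc_interval=5, blank_interval=5,
            n_duplicate_pairs=0, seed=23,
        )
        params = RunParameters(rt_grid_step=0.02, seed=23)
        _, eics = simulate_run(db, plan, params)
        fm, _ = extract_run(eics, plan, db)
        out, flagged = median_normalize_batches(fm)
        pd.testing.assert_frame_equal(out.values, fm.values)
        assert not flagged

    def test_batches_equalized_exactly(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        out, flagged = median_normalize_batches(fm)
        qc = out.qc_values()
        batches = out.samples.loc[qc.index, "batch"]
        for ion in out.ion_ids:
            if ion in flagged:
                continue
            per_batch = qc[ion].groupby(batches).median()
            assert np.allclose(per_batch, per_batch.iloc[0], rtol=1e-12)

    def test_constructed_two_to_one_ratio_halved(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        doctored = fm.copy_with(values=fm.values.copy())
        ion = fm.ion_ids[0]
        b2 = fm.samples.index[fm.samples["batch"] == 2]
        qc1 = fm.samples.index[
            (fm.samples["batch"] == 1) & (fm.samples["sample_type"] == "qc")
        ]
        qc2 = fm.samples.index[
            (fm.samples["batch"] == 2) & (fm.samples["sample_type"] == "qc")
        ]
        m1 = doctored.values.loc[qc1, ion].median()
        doctored.values.loc[b2, ion] = 1.0
        doctored.values.loc[qc2, ion] = 2.0 * m1
        out, _ = median_normalize_batches(doctored)
        # the doubled batch is rescaled so both batch QC medians coincide
        assert out.values.loc[qc2, ion].median() == pytest.approx(
            out.values.loc[qc1, ion].median(), rel=1e-12
        )
        study2 = fm.samples.index[
            (fm.samples["batch"] == 2) & (fm.samples["sample_type"] == "study")
        ]
        scale = out.values.loc[qc2, ion].median() / (2.0 * m1)
        assert np.allclose(out.values.loc[study2, ion], scale, rtol=1e-12)

    def test_zero_ion_flagged_and_unchanged(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        doctored = fm.copy_with(values=fm.values.copy())
        ion = fm.ion_ids[0]
        doctored.values[ion] = 0.0
        out, flagged = median_normalize_batches(doctored)
        assert ion in flagged
        assert (out.values[ion] == 0.0).all()


class TestCvRsd:
    def test_noise_free_cv_rsd_is_zero(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        quiet = dataclasses.replace(params, drift_amplitude=0.0, batch_scale_sigma=0.0)
        _, eics0 = simulate_run(db, plan, quiet)
        fm0, _ = extract_run(eics0, plan, db)
        cv = cv_rsd(fm0, k=4)
        assert cv.max() <= 1e-6

    def test_more_folds_than_qcs_raise(self, drifting_run):
        db, plan, params, truth, fm = drifting_run
        with pytest.raises(ValueError):
            cv_rsd(fm, k=1000)

    def test_held_out_score_not_better_than_in_sample(self, default_matrices):
        """Refitting without each QC fold cannot beat the in-sample fit on
        average: CV RSD >= in-sample post-correction RSD over ions."""
        raw, normalized, audit, _ = default_matrices
        cv = cv_rsd(raw, k=5)
        in_sample = qc_rsd_per_ion(normalized)
        assert cv.mean() >= in_sample.mean()
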