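"""Synthetic-study generator: determinism, truth consistency, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from petrt.kinetics import TwoTissueParams, compute_vt, forward_2tc
from petrt.plasma import fit_parent_fraction
from petrt.synthstudy import (StudyDesign, TRUE_HILL, generate_input_curve,
                              generate_study, generate_tac, sample_subject_params,
                              true_input_function, write_study)


class TestDesignValidation:
    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            StudyDesign(frame_schedule=((0.0, 2.0), (1.0, 3.0)))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            StudyDesign(n_subjects=1)

    def test_missing_cerebellum_rejected(self):
        with pytest.raises(ValueError, match="[Cc]erebellum"):
            StudyDesign(region_names=("Temporal Cortex", "Parietal Cortex"))

    def test_nonpositive_population_mean_rejected_naming_region(self):
        from petrt.synthstudy import default_param_means
        means = default_param_means()
        means["Cerebellum"] = TwoTissueParams(0.3, 0.12, 0.0, 0.025)
        with pytest.raises(ValueError, match="k3.*Cerebellum"):
            StudyDesign(true_param_means=means)


class TestParameterSampling:
    def test_zero_variance_returns_population_means(self):
        design = StudyDesign(between_subject_cv=0.0, within_subject_cv=0.0, seed=2)
        for subj in (0, 3):
            for sess in (0, 1):
                params = sample_subject_params(design, subj, sess)
                assert params == design.true_param_means

    def test_same_seed_same_draws(self):
        d1 = StudyDesign(seed=42)
        d2 = StudyDesign(seed=42)
        assert sample_subject_params(d1, 4, 1) == sample_subject_params(d2, 4, 1)

    def test_zero_within_cv_makes_sessions_identical(self):
        design = StudyDesign(within_subject_cv=0.0, seed=6)
        assert sample_subject_params(design, 2, 0) == sample_subject_params(design, 2, 1)

    def test_between_multiplier_shared_within_subject(self):
        design = StudyDesign(within_subject_cv=0.0, between_subject_cv=0.25, seed=8)
        p0 = sample_subject_params(design, 0, 0)["Cerebellum"]
        p1 = sample_subject_params(design, 1, 0)["Cerebellum"]
        assert p0.K1 != p1.K1  # subjects differ
        # within a subject the K1/k3 scaling is consistent across regions
        params = sample_subject_params(design, 0, 0)
        scales = {r: p.K1 / design.true_param_means[r].K1 for r, p in params.items()}
        assert len(set(np.round(list(scales.values()), 12))) == 1

    def test_rate_constants_positive(self):
        design = StudyDesign(between_subject_cv=0.5, within_subject_cv=0.5, seed=3)
        for subj in range(design.n_subjects):
            for p in sample_subject_params(design, subj, 0).values():
                assert min(p.K1, p.k2, p.k3, p.k4) > 0


class TestInputCurve:
    def test_noiseless_identity_total_times_fraction(self):
        design = StudyDesign(noise_scale=0.0, seed=1)
        inp, plasma, _ = generate_input_curve(design, np.random.default_rng(0))
        t = plasma.time_min.to_numpy()
        parent = plasma.total_activity.to_numpy() * TRUE_HILL.parent_fraction(t)
        np.testing.assert_allclose(parent, np.atleast_1d(inp(t)), rtol=1e-12)

    def test_monoexponential_tail_auc_closed_form(self):
        from petrt.plasma import InputFunction
        inp = InputFunction(peak_time=0.0, amplitudes=np.array([12.0]),
                            rates=np.array([0.03]))
        assert inp.auc(extrapolate=True) == pytest.approx(12.0 / 0.03, rel=1e-12)

    def test_parent_fraction_round_trip_through_hill_fit(self):
        design = StudyDesign(noise_scale=0.0, seed=1)
        _, _, parent = generate_input_curve(design, np.random.default_rng(0))
        fit = fit_parent_fraction(parent.time_min, parent.parent_fraction)
        assert fit.a == pytest.approx(TRUE_HILL.a, rel=1e-6)
        assert fit.b == pytest.approx(TRUE_HILL.b, rel=1e-6)
        assert fit.c == pytest.approx(TRUE_HILL.c, rel=1e-6)

    def test_curve_shape_single_early_peak_then_decay(self):
        design = StudyDesign(seed=1)
        inp = true_input_function(design)
        t = np.linspace(0, 90, 2000)
        c = inp(t)
        ipk = int(np.argmax(c))
        assert t[ipk] == pytest.approx(inp.peak_time, abs=0.1)
        assert np.all(np.diff(c[t >= inp.peak_time]) <= 1e-9)


class TestTacGeneration:
    def test_no_delivery_gives_all_zero_tac(self, frames):
        design = StudyDesign(seed=1)
        inp = true_input_function(design)
        params = {"R": TwoTissueParams(0.0, 0.1, 0.01, 0.01)}
        tac = generate_tac(params, inp, frames, 0.1, np.random.default_rng(0))
        assert np.all(tac["R"] == 0.0)

    def test_noiseless_tac_is_forward_model(self, frames):
        design = StudyDesign(seed=1)
        inp = true_input_function(design)
        p = TwoTissueParams(0.3, 0.12, 0.05, 0.025)
        tac = generate_tac({"R": p}, inp, frames, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(tac["R"].to_numpy(), forward_2tc(p, inp, frames))

    def test_doubling_k1_doubles_noiseless_tac(self, frames):
        design = StudyDesign(seed=1)
        inp = true_input_function(design)
        rng = np.random.default_rng(0)
        a = generate_tac({"R": TwoTissueParams(0.2, 0.12, 0.04, 0.02)}, inp, frames, 0.0, rng)
        b = generate_tac({"R": TwoTissueParams(0.4, 0.12, 0.04, 0.02)}, inp, frames, 0.0, rng)
        np.testing.assert_allclose(b["R"], 2.0 * a["R"], rtol=1e-12)


class TestStudyGeneration:
    def test_same_design_bit_identical(self, small_design):
        s1 = generate_study(small_design)
        s2 = generate_study(small_design)
        for a, b in zip(s1.scans, s2.scans):
            pd.testing.assert_frame_equal(a.plasma, b.plasma)
            pd.testing.assert_frame_equal(a.parent, b.parent)
            pd.testing.assert_frame_equal(a.tac, b.tac)
            assert a.true_vt == b.true_vt

    def test_truth_record_self_consistent(self, small_design):
        study = generate_study(small_design)
        for sc in study.scans:
            cer = sc.true_vt["Cerebellum"]
            for region, p in sc.true_params.items():
                assert sc.true_vt[region] == pytest.approx(compute_vt(p), rel=1e-12)
                assert sc.true_bpnd[region] == pytest.approx(
                    (sc.true_vt[region] - cer) / cer, rel=1e-12)
                assert sc.true_bpp[region] == pytest.approx(
                    sc.true_vt[region] - cer, rel=1e-12)

    def test_write_and_reload_round_trip(self, small_design, tmp_path):
        from petrt.synthstudy import load_study_dir
        study = generate_study(small_design)
        manifest = write_study(study, tmp_path)
        assert "truth.csv" in manifest and "design.yaml" in manifest
        loaded = load_study_dir(tmp_path)
        assert len(loaded["data"]) == 2 * small_design.n_subjects
        sc = study.scans[0]
        pd.testing.assert_frame_equal(
            loaded["data"][(sc.subject, sc.session)]["tac"], sc.tac)

    def test_population_mean_vt_matches_published_anchors(self):
        from petrt import published
        design = StudyDesign(between_subject_cv=0.0, within_subject_cv=0.0,
                             noise_scale=0.0, seed=0)
        params = sample_subject_params(design, 0, 0)
        for region, p in params.items():
            assert compute_vt(p) == pytest.approx(
                published.REGIONAL_VT_MEAN[region], rel=1e-12)
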