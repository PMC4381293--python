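import numpy as np
import pytest

from urinorm.diagnostics import compute_rsd, extract_profile
from urinorm.normalise import (normalise_area_percent, normalise_assay_creatinine,
                               normalise_pooled_creatinine)
from urinorm.synthetic_data import (SimConfig, SyntheticError, generate,
                                    null_dataset, truth_recovery_score)


class TestGenerate:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_stable=5, n_spike=3, n_diurnal=2, n_erratic=1)
        p1, s1, a1, t1 = generate(cfg, seed=1)
        p2, s2, a2, t2 = generate(cfg, seed=1)
        assert p1.values.equals(p2.values)
        assert a1.concentrations.equals(a2.concentrations)
        assert t1.dilution.equals(t2.dilution)
        p3, _, _, _ = generate(cfg, seed=2)
        assert not p1.values.equals(p3.values)

    def test_noiseless_all_stable_is_constant(self):
        cfg = SimConfig(n_stable=4, n_spike=0, n_diurnal=0, n_erratic=0,
                        sigma_dilution=0.0, sigma_baseline=0.0, sigma_noise=0.0)
        peaks, _, _, _ = generate(cfg, seed=0)
        stable = peaks.values.drop(index="M_creatinine")
        assert (stable.nunique(axis=1) == 1).all()

    def test_exact_decomposition(self):
        peaks, sheet, _, truth = generate(SimConfig(), seed=3)
        assert peaks.values.equals(truth.reconstruct(sheet))

    def test_spike_analytic_true_fold(self):
        # A = 9 with negligible decay over PT1 - P1 -> fold = 1 + 9 = 10
        cfg = SimConfig(n_stable=0, n_spike=1, n_diurnal=0, n_erratic=0,
                        spike_amplitude=(9.0, 9.0), spike_tau=(1e9, 1e9),
                        sigma_noise=0.0, sigma_dilution=0.0, sigma_baseline=0.0)
        _, _, _, truth = generate(cfg, seed=0)
        assert truth.true_fold["M_spike_001"] == pytest.approx(10.0, rel=1e-8)

    def test_spike_profile_peaks_at_first_post_exercise_sample(self):
        cfg = SimConfig(n_stable=0, n_spike=5, n_diurnal=0, n_erratic=0,
                        sigma_noise=0.0, sigma_dilution=0.0)
        peaks, sheet, _, _ = generate(cfg, seed=4)
        ap = normalise_area_percent(peaks, sheet)
        for mid in [f"M_spike_{k:03d}" for k in range(1, 6)]:
            prof = extract_profile(ap, sheet, mid, "S1")
            assert prof.timepoint_labels[int(np.nanargmax(prof.values))] == "PT1"

    def test_creatinine_row_annotated(self):
        peaks, _, _, _ = generate(SimConfig(n_stable=1, n_spike=0, n_diurnal=0,
                                            n_erratic=0), seed=0)
        assert peaks.annotations.loc["M_creatinine", "name"] == "creatinine"
        assert peaks.annotations.loc["M_creatinine", "mass"] == pytest.approx(113.050)

    def test_creatinine_rsd_tracks_configured_target(self):
        """Raw-scale creatinine RSD (dilution included) should land near
        the configured target on average."""
        cfg = SimConfig(n_stable=2, n_spike=0, n_diurnal=0, n_erratic=0,
                        sigma_dilution=0.05, creatinine_rsd_target=20.0)
        rsds = []
        for seed in range(20):
            peaks, _, _, _ = generate(cfg, seed=seed)
            rec = compute_rsd(peaks)
            rsds.append(rec.set_index("metabolite_id")
                        .loc["M_creatinine", "rsd_percent"])
        assert np.mean(rsds) == pytest.approx(20.0, rel=0.3)

    def test_mask_rate_spares_creatinine(self):
        cfg = SimConfig(mask_rate=0.2)
        peaks, _, _, _ = generate(cfg, seed=6)
        assert peaks.values.loc["M_creatinine"].notna().all()
        frac = peaks.values.drop(index="M_creatinine").isna().to_numpy().mean()
        assert 0.1 < frac < 0.3

    def test_invalid_config_rejected_before_drawing(self):
        with pytest.raises(SyntheticError):
            generate(SimConfig(sigma_noise=-0.1))
        with pytest.raises(SyntheticError):
            SimConfig(mask_rate=1.5).validate()


class TestNullDataset:
    def test_true_fold_is_one_everywhere(self):
        _, _, _, truth = null_dataset(SimConfig(), seed=1)
        assert np.allclose(truth.true_fold, 1.0)
        assert (truth.classes.drop("M_creatinine") == "stable").all()

    def test_noiseless_area_percent_is_flat_at_100_over_T(self):
        cfg = SimConfig(sigma_dilution=0.0, sigma_baseline=0.0, sigma_noise=0.0,
                        n_stable=3, n_spike=0, n_diurnal=0, n_erratic=0)
        peaks, sheet, _, _ = null_dataset(cfg, seed=0)
        ap = normalise_area_percent(peaks, sheet)
        stable = ap.values.drop(index="M_creatinine")
        assert np.allclose(stable, 10.0, rtol=1e-9)

    def test_multiplicative_noise_sets_mean_rsd(self):
        """With no structure and sigma_dilution = 0, mean metabolite RSD
        ~ 100 * sigma_noise (small-sigma log-normal CV)."""
        cfg = SimConfig(n_stable=200, n_spike=0, n_diurnal=0, n_erratic=0,
                        sigma_dilution=0.0, sigma_baseline=0.0, sigma_noise=0.1)
        peaks, _, _, _ = null_dataset(cfg, seed=2)
        rec = compute_rsd(peaks)
        mean_rsd = rec[rec["metabolite_id"] != "M_creatinine"]["rsd_percent"].mean()
        assert mean_rsd == pytest.approx(10.0, rel=0.1)

    def test_additive_mode_noise_is_gaussian_relative(self):
        cfg = SimConfig(n_stable=500, n_spike=0, n_diurnal=0, n_erratic=0,
                        sigma_noise=0.1)
        peaks, sheet, _, truth = null_dataset(cfg, seed=3, noise="additive")
        assert peaks.values.equals(truth.reconstruct(sheet))
        rel = truth.epsilon.to_numpy() - 1.0
        assert abs(rel.mean()) < 0.005
        assert rel.std() == pytest.approx(0.1, rel=0.05)


class TestTruthRecovery:
    def test_noiseless_area_percent_correlation_is_one(self):
        cfg = SimConfig(sigma_dilution=0.0, sigma_noise=0.0,
                        n_stable=0, n_spike=5, n_diurnal=5, n_erratic=2)
        peaks, sheet, _, truth = generate(cfg, seed=1)
        score = truth_recovery_score(truth, normalise_area_percent(peaks, sheet), sheet)
        ok = score.per_subject[score.per_subject["flag"] == "ok"]
        assert (ok["pearson_r"] >= 1 - 1e-12).all()

    def test_flat_truth_profiles_flagged_not_scored(self):
        cfg = SimConfig(n_stable=3, n_spike=0, n_diurnal=0, n_erratic=0)
        peaks, sheet, _, truth = generate(cfg, seed=1)
        score = truth_recovery_score(truth, normalise_area_percent(peaks, sheet), sheet)
        assert (score.per_subject["flag"] == "flat").all()

    def test_assay_tracking_dilution_removes_it_exactly(self):
        """With assay proportional to the true dilution and no measurement
        noise, assay normalisation recovers profiles perfectly even under
        strong dilution variation."""
        cfg = SimConfig(sigma_dilution=0.4, sigma_noise=0.0, sigma_assay=0.0,
                        n_stable=0, n_spike=5, n_diurnal=5, n_erratic=0)
        peaks, sheet, assay, truth = generate(cfg, seed=2)
        score = truth_recovery_score(
            truth, normalise_assay_creatinine(peaks, assay), sheet)
        ok = score.per_subject[score.per_subject["flag"] == "ok"]
        assert (ok["pearson_r"] >= 1 - 1e-9).all()

    def test_area_percent_beats_pooled_when_baselines_dominate(self):
        """Across-subject profile correlation: area% cancels subject x
        metabolite baselines exactly; a per-subject constant divisor
        cannot."""
        cfg = SimConfig(sigma_baseline=0.6, sigma_dilution=0.0, sigma_noise=0.05,
                        n_stable=0, n_spike=10, n_diurnal=5, n_erratic=0)
        means = {"area": [], "pooled": []}
        for seed in range(5):
            peaks, sheet, _, truth = generate(cfg, seed=seed)
            pooled = {s: float(peaks.values.loc["M_creatinine",
                                                sheet.samples_of(s)].mean())
                      for s in sheet.subjects}
            ap = truth_recovery_score(
                truth, normalise_area_percent(peaks, sheet), sheet)
            pl = truth_recovery_score(
                truth, normalise_pooled_creatinine(peaks, sheet, pooled), sheet)
            means["area"].append(ap.mean_correlation("across_subjects"))
            means["pooled"].append(pl.mean_correlation("across_subjects"))
        assert np.mean(means["area"]) > np.mean(means["pooled"])

    def test_spike_fold_report_shape(self):
        cfg = SimConfig(n_stable=2, n_spike=4, n_diurnal=0, n_erratic=0,
                        sigma_dilution=0.0, sigma_noise=0.05)
        peaks, sheet, _, truth = generate(cfg, seed=9)
        score = truth_recovery_score(truth, normalise_area_percent(peaks, sheet), sheet)
        assert len(score.folds) == 4
        assert score.folds["relative_error"].notna().all()
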