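"""Synthetic-cohort generator: envelope statistics, band limits, planted effects."""

import numpy as np
import pytest
from scipy.signal import welch

from oscillome.bands import DEFAULT_BANDS, get_band
from oscillome.stats import feature_ttest
from oscillome.synth import (
    EffectSpec,
    SynthCohortConfig,
    gen_cohort,
    gen_correlated_envelopes,
    gen_subject,
    make_band_oscillation,
    one_over_f_noise,
    project_to_sensors,
)


class TestCorrelatedEnvelopes:
    def test_identity_target_gives_near_zero_log_envelope_correlation(self):
        vals = [
            np.corrcoef(np.log(gen_correlated_envelopes(np.eye(2), 300, 100, seed=s)))[0, 1]
            for s in range(20)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_planted_correlation_is_recovered(self):
        target = np.array([[1.0, 0.6], [0.6, 1.0]])
        vals = [
            np.corrcoef(np.log(gen_correlated_envelopes(target, 300, 100, seed=s)))[0, 1]
            for s in range(20)
        ]
        assert 0.5 <= np.mean(vals) <= 0.7

    def test_envelopes_strictly_positive_and_spectrally_slow(self):
        env = gen_correlated_envelopes(np.eye(3), 60, 100, bandwidth=1.0, seed=0)
        assert (env > 0).all()
        f, p = welch(np.log(env), fs=100, nperseg=2048, axis=-1)
        frac_slow = p[:, f <= 2.0].sum() / p.sum()
        assert frac_slow > 0.95

    def test_non_psd_target_rejected_with_eigenvalue_diagnostic(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            gen_correlated_envelopes(bad, 10, 100, seed=0)

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            gen_correlated_envelopes(np.eye(2), 0.0, 100, seed=0)

    def test_seeded_calls_are_deterministic(self):
        a = gen_correlated_envelopes(np.eye(2), 5, 100, seed=3)
        b = gen_correlated_envelopes(np.eye(2), 5, 100, seed=3)
        np.testing.assert_array_equal(a, b)


class TestBandOscillation:
    def test_theta_carrier_peaks_inside_band(self):
        osc = make_band_oscillation(get_band("theta"), np.ones(10_000), 500, seed=0)
        f, p = welch(osc, fs=500, nperseg=1000)
        assert 5.0 <= f[np.argmax(p)] <= 7.0

    def test_zero_envelope_gives_zero_output(self):
        osc = make_band_oscillation(get_band("alpha"), np.zeros(5_000), 500, seed=0)
        assert not osc.any()

    @pytest.mark.parametrize("band_name", ["delta", "theta", "alpha", "beta", "low_gamma", "high_gamma"])
    def test_at_least_90pct_power_in_band(self, band_name):
        band = get_band(band_name)
        osc = make_band_oscillation(band, np.ones(20_000), 500, seed=1)
        f, p = welch(osc, fs=500, nperseg=2000)
        inband = p[(f >= band.f_lo) & (f <= band.f_hi)].sum()
        assert inband / p.sum() >= 0.90

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_band_oscillation(get_band("high_gamma"), np.ones(100), 120, seed=0)


def test_one_over_f_noise_spectrum_slopes_down():
    x = one_over_f_noise((2, 100_000), 500, exponent=1.0, seed=0)
    f, p = welch(x, fs=500, nperseg=4096, axis=-1)
    sel = (f >= 1) & (f <= 100)
    slope = np.polyfit(np.log(f[sel]), np.log(p[:, sel].mean(axis=0)), 1)[0]
    assert -1.3 < slope < -0.7


class TestGenSubject:
    def test_unknown_group_label_rejected(self, tiny_cfg):
        with pytest.raises(ValueError, match="unknown group"):
            gen_subject(tiny_cfg, "nosuch", 0)

    def test_null_config_calibrates_the_t_test(self):
        # no planted effects: per-feature rejection rate ~ alpha
        cfg = SynthCohortConfig(
            n_per_group={"HC": 12, "PKD": 12}, duration=20.0, n_regions=20, seed=42
        )
        children = np.random.SeedSequence(42).spawn(24)
        from oscillome.spectral import band_power, welch_psd, znorm_psd

        feats, labels = [], []
        for i, ch in enumerate(children):
            g = "HC" if i < 12 else "PKD"
            s = gen_subject(cfg, g, ch)
            feats.append(band_power(znorm_psd(welch_psd(s))).ravel())
            labels.append(g)
        X = np.asarray(feats)
        labels = np.asarray(labels)
        _, p = feature_ttest(X[labels == "HC"], X[labels == "PKD"])
        m = p.size  # 120 features
        k = int((p < 0.05).sum())
        # 95% binomial interval around alpha = 0.05
        lo, hi = 0, m * 0.05 + 1.96 * np.sqrt(m * 0.05 * 0.95)
        assert lo <= k <= np.ceil(hi)

    def test_band_power_effect_shifts_target_regions(self):
        n = 10
        cfg = SynthCohortConfig(
            n_per_group={"HC": n, "PKD": n}, duration=30.0, n_regions=8, seed=5
        )
        targets = tuple(cfg.region_names[:3])
        cfg.effects = (EffectSpec("band_power", "theta", targets, 2.5, "PKD"),)
        from oscillome.spectral import band_power, welch_psd, znorm_psd

        children = np.random.SeedSequence(5).spawn(2 * n)
        theta = {"HC": [], "PKD": []}
        for i, ch in enumerate(children):
            g = "HC" if i < n else "PKD"
            s = gen_subject(cfg, g, ch)
            theta[g].append(band_power(znorm_psd(welch_psd(s)))[:, 1])
        hc, pkd = np.asarray(theta["HC"]), np.asarray(theta["PKD"])
        assert (pkd[:, :3].mean(axis=0) > hc[:, :3].mean(axis=0)).all()

    def test_coupling_effect_lowers_target_pair_envelope_correlation(self):
        cfg = SynthCohortConfig(
            n_per_group={"A": 2, "B": 2}, duration=60.0, n_regions=4, seed=9
        )
        # favourable band SNR so the mechanism (not the detector) is under test
        cfg.baseline_power = dict(cfg.baseline_power, high_gamma=1.0)
        cfg.noise_scale = 0.3
        pair = (cfg.region_names[0], cfg.region_names[1])
        cfg.effects = (EffectSpec("envelope_coupling", "high_gamma", (pair,), -0.4, "B"),)
        from oscillome.bands import get_band
        from oscillome.spectral import band_envelope_coefficients

        diffs = []
        for s_idx in range(6):
            a = gen_subject(cfg, "A", 100 + s_idx)
            b = gen_subject(cfg, "B", 200 + s_idx)
            ca = band_envelope_coefficients(a, get_band("high_gamma"))
            cb = band_envelope_coefficients(b, get_band("high_gamma"))
            ra = np.corrcoef(np.log(np.abs(ca[0]) ** 2 + 1e-12), np.log(np.abs(ca[1]) ** 2 + 1e-12))[0, 1]
            rb = np.corrcoef(np.log(np.abs(cb[0]) ** 2 + 1e-12), np.log(np.abs(cb[1]) ** 2 + 1e-12))[0, 1]
            diffs.append(rb - ra)
        # directional: coupling drops for the target pair in every replicate
        assert np.mean(diffs) < -0.05
        assert max(diffs) < 0


class TestGenCohort:
    def test_same_seed_gives_bit_identical_cohorts(self, tiny_cfg):
        subs1, meta1 = gen_cohort(tiny_cfg)
        subs2, meta2 = gen_cohort(tiny_cfg)
        assert meta1.equals(meta2)
        for a, b in zip(subs1, subs2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_metadata_row_count_matches_subjects(self):
        cfg = SynthCohortConfig(
            n_per_group={"HC": 30, "PKD": 30}, duration=2.0, n_regions=3, seed=1
        )
        subs, meta = gen_cohort(cfg)
        assert len(subs) == len(meta) == 60

    def test_three_study_arms_give_three_labeled_strata(self):
        cfg = SynthCohortConfig(
            n_per_group={"HC": 3, "PKD_remission": 2, "PKD_nonremission": 3},
            duration=2.0,
            n_regions=3,
            seed=2,
        )
        _, meta = gen_cohort(cfg)
        assert set(meta["group"]) == {"HC", "PKD_remission", "PKD_nonremission"}
        assert len(meta) == 8

    def test_group_of_one_rejected(self):
        cfg = SynthCohortConfig(
            n_per_group={"HC": 1, "PKD": 3}, duration=2.0, n_regions=3, seed=3
        )
        with pytest.raises(ValueError, match="n_per_group"):
            gen_cohort(cfg)


class TestProjectToSensors:
    def test_identity_leadfield_infinite_snr_reproduces_sources(self, tiny_cfg):
        roi = gen_subject(tiny_cfg, "HC", 0)
        rec = project_to_sensors(roi, np.eye(roi.n_regions), snr=np.inf)
        np.testing.assert_allclose(rec.data, roi.data)

    def test_single_source_two_sensors_are_scaled_copies(self):
        cfg = SynthCohortConfig(n_per_group={"HC": 2}, duration=5.0, n_regions=1, seed=4)
        roi = gen_subject(cfg, "HC", 0)
        rec = project_to_sensors(roi, np.array([[1.0], [0.5]]), snr=np.inf)
        np.testing.assert_allclose(rec.data[1], 0.5 * rec.data[0])
        np.testing.assert_allclose(rec.data[0], roi.data[0])

    def test_unit_snr_gives_unit_noise_to_signal_variance_ratio(self):
        cfg = SynthCohortConfig(n_per_group={"HC": 2}, duration=60.0, n_regions=2, seed=6)
        roi = gen_subject(cfg, "HC", 0)
        G = np.array([[1.0, 0.3], [0.2, 0.9]])
        clean = G @ roi.data
        rec = project_to_sensors(roi, G, snr=1.0, seed=11)
        noise = rec.data - clean
        ratio = clean.var(axis=1) / noise.var(axis=1)
        assert np.all(np.abs(ratio - 1.0) < 0.1)

    def test_dimension_mismatch_rejected(self, tiny_cfg):
        roi = gen_subject(tiny_cfg, "HC", 0)
        with pytest.raises(ValueError, match="incompatible|blocks"):
            project_to_sensors(roi, np.ones((4, roi.n_regions + 1)))


def test_default_bands_are_the_six_canonical_ones():
    names = [b.name for b in DEFAULT_BANDS]
    assert names == ["delta", "theta", "alpha", "beta", "low_gamma", "high_gamma"]
    edges = [(b.f_lo, b.f_hi) for b in DEFAULT_BANDS]
    assert edges == [(2, 4), (5, 7), (8, 12), (13, 29), (30, 59), (60, 90)]
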