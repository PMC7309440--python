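import numpy as np
import pytest

from eegboost.spectral import (
    BAND_ORDER,
    CANONICAL_BANDS,
    EEGRecording,
    FeatureCombination,
    MONTAGE_26,
    PowerSpectrum,
    RATIO_SENTINEL,
    alpha_asymmetry,
    band_power,
    band_ratio,
    beta_alpha_ratio,
    cohort_band_powers,
    extract_features,
    features_from_band_powers,
    relative_power,
    resolve_site,
    welch_psd,
)

FS = 250.0


def sinusoid(freq, amp=1.0, seconds=60.0, fs=FS, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestWelch:
    def test_white_noise_integrates_to_variance(self):
        integrals = []
        for seed in range(8):
            x = np.random.default_rng(seed).standard_normal(int(120 * FS))
            integrals.append(welch_psd(x, FS).total_power())
        assert abs(np.mean(integrals) - 1.0) < 0.05

    def test_zero_signal_gives_zero_density(self):
        spec = welch_psd(np.zeros(int(10 * FS)), FS)
        assert np.all(spec.density == 0)

    def test_sinusoid_power_is_half_amplitude_squared(self):
        for amp in (1.0, 3.0):
            spec = welch_psd(sinusoid(10.0, amp, seconds=120), FS)
            assert spec.total_power() == pytest.approx(amp**2 / 2, rel=0.02)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), FS, window_seconds=2.0)

    def test_frequencies_span_zero_to_nyquist(self):
        spec = welch_psd(sinusoid(10.0), FS)
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[-1] == pytest.approx(FS / 2)


class TestBandPower:
    def test_constant_density_integrates_exactly(self):
        f = np.linspace(0.0, 20.0, 201)
        h = 0.7
        spec = PowerSpectrum(frequencies=f, density=np.full_like(f, h))
        theta = band_power(spec, CANONICAL_BANDS["theta"])
        assert theta == pytest.approx(4 * h, abs=1e-12)

    def test_sinusoid_concentrates_in_alpha(self):
        amp = 2.0
        spec = welch_psd(sinusoid(10.0, amp, seconds=120), FS)
        alpha = band_power(spec, CANONICAL_BANDS["alpha"])
        assert alpha == pytest.approx(amp**2 / 2, rel=0.02)
        for name in ("delta", "theta", "beta", "gamma"):
            assert band_power(spec, CANONICAL_BANDS[name]) < 0.05 * alpha

    def test_matches_refined_trapezoid_on_smooth_density(self):
        # smooth bump; Simpson on the coarse (odd-length) grid should agree
        # with a 100x-refined trapezoid quadrature of the same shape
        f = np.arange(8.0, 12.0 + 1e-9, 0.5)  # 9 points
        dens = np.exp(-((f - 10.0) ** 2) / 8.0)
        spec = PowerSpectrum(frequencies=f, density=dens)
        got = band_power(spec, CANONICAL_BANDS["alpha"])
        fine = np.linspace(8.0, 12.0, 801)
        want = np.trapezoid(np.exp(-((fine - 10.0) ** 2) / 8.0), fine)
        assert got == pytest.approx(want, rel=1e-3)

    def test_band_outside_support_rejected(self):
        spec = PowerSpectrum(frequencies=np.linspace(0, 10, 11), density=np.ones(11))
        with pytest.raises(ValueError, match="support"):
            band_power(spec, CANONICAL_BANDS["gamma"])


class TestDerivedFeatures:
    def test_relative_power_normalises(self):
        assert np.allclose(relative_power([1, 1, 1, 1, 1]), 0.2)
        assert np.allclose(relative_power([0, 0, 4, 0, 0]), [0, 0, 1, 0, 0])
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0.01, 5.0, size=5)
            assert relative_power(p).sum() == pytest.approx(1.0, abs=1e-9)

    def test_relative_power_needs_positive_total(self):
        with pytest.raises(ValueError):
            relative_power([0, 0, 0, 0, 0])

    def test_alpha_asymmetry_is_right_minus_left(self):
        assert alpha_asymmetry({"F3": 0.5, "F4": 2.0}) == pytest.approx(1.5)
        assert alpha_asymmetry({"F3": 1.0, "F4": 1.0}) == 0.0
        # swapping the channels negates the value
        assert alpha_asymmetry({"F3": 2.0, "F4": 0.5}) == pytest.approx(-1.5)

    def test_asymmetry_requires_both_sites(self):
        with pytest.raises(KeyError):
            alpha_asymmetry({"F3": 1.0})

    def test_beta_alpha_ratio(self):
        assert beta_alpha_ratio({"beta": 3.0, "alpha": 1.5}) == pytest.approx(2.0)
        assert beta_alpha_ratio({"beta": 0.8, "alpha": 0.8}) == pytest.approx(1.0)

    def test_zero_alpha_gets_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert band_ratio({"beta": 1.0, "alpha": 0.0}, "beta", "alpha") == RATIO_SENTINEL

    def test_pure_alpha_sinusoid_has_tiny_beta_alpha_ratio(self):
        spec = welch_psd(sinusoid(10.0, 2.0, seconds=60), FS)
        powers = {n: band_power(spec, b) for n, b in CANONICAL_BANDS.items()}
        assert beta_alpha_ratio(powers) < 0.05


class TestMontage:
    def test_legacy_aliases_resolve(self):
        assert resolve_site("T3") == "T7"
        assert resolve_site("T6") == "P8"
        assert resolve_site("Oz") == "Oz"

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            resolve_site("XX9")


class TestFeatureTables:
    def test_occipital_alpha_absolute_has_three_columns(self, tiny_recordings):
        combo = FeatureCombination(power_type="absolute", bands=("alpha",), region_filter="occipital")
        table = extract_features(tiny_recordings, combo)
        assert list(table.columns) == [
            "O1 alpha absolute",
            "Oz alpha absolute",
            "O2 alpha absolute",
        ]
        assert len(table) == len(tiny_recordings)
        assert not table.isna().any().any()

    def test_all_bands_all_sites_relative_has_130_columns(self, tiny_recordings):
        combo = FeatureCombination(power_type="relative", bands=BAND_ORDER, region_filter="all")
        table = extract_features(tiny_recordings, combo)
        assert table.shape[1] == 26 * 5

    def test_asymmetry_adds_exactly_one_column(self, tiny_recordings):
        bp = cohort_band_powers(tiny_recordings)
        base = FeatureCombination(power_type="absolute", bands=("alpha", "beta"), region_filter="frontal")
        plus = FeatureCombination(
            power_type="absolute", bands=("alpha", "beta"), region_filter="frontal",
            include_asymmetry=True,
        )
        t0 = features_from_band_powers(bp, base)
        t1 = features_from_band_powers(bp, plus)
        assert t1.shape[1] == t0.shape[1] + 1
        assert "frontal alpha asymmetry absolute" in t1.columns

    def test_relative_rows_sum_to_one_per_site(self, tiny_recordings):
        combo = FeatureCombination(power_type="relative", bands=BAND_ORDER, region_filter="occipital")
        table = extract_features(tiny_recordings, combo)
        for site in ("O1", "Oz", "O2"):
            cols = [f"{site} {b} relative" for b in BAND_ORDER]
            assert np.allclose(table[cols].sum(axis=1), 1.0, atol=1e-9)


class TestInvariants:
    def test_scale_equivariance(self, tiny_recordings):
        sid, rec = next(iter(tiny_recordings.items()))
        c = 3.7
        scaled = EEGRecording(rec.site_labels, rec.data * c, rec.sampling_rate)
        bp = cohort_band_powers({sid: rec})
        bp_scaled = cohort_band_powers({sid: scaled})
        assert np.allclose(bp_scaled.to_numpy(), c**2 * bp.to_numpy(), rtol=1e-6)
        combo = FeatureCombination(
            power_type="relative", bands=BAND_ORDER, region_filter="occipital",
            include_beta_alpha_ratio=True,
        )
        rel = features_from_band_powers(bp, combo)
        rel_scaled = features_from_band_powers(bp_scaled, combo)
        assert np.allclose(rel.to_numpy(), rel_scaled.to_numpy(), rtol=1e-6)

    def test_band_power_sum_approximates_total_power(self, tiny_recordings):
        # signal energy lies within 0.5-100 Hz, so the five bands nearly
        # exhaust the integrated density
        rec = next(iter(tiny_recordings.values()))
        x = rec.data[0]
        spec = welch_psd(x, rec.sampling_rate)
        total = spec.total_power()
        bands = sum(band_power(spec, b) for b in CANONICAL_BANDS.values())
        assert bands <= total * 1.001
        assert bands == pytest.approx(total, rel=0.03)

    def test_circular_shift_leaves_band_power_unchanged_in_expectation(self):
        # shift invariance holds in expectation: individual Welch estimates
        # fluctuate with segment placement, but the seed-averaged signed
        # change is below 1%
        diffs = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(120 * FS))
            a = band_power(welch_psd(x, FS), CANONICAL_BANDS["alpha"])
            b = band_power(welch_psd(np.roll(x, 1234), FS), CANONICAL_BANDS["alpha"])
            diffs.append((a - b) / a)
        assert abs(np.mean(diffs)) < 0.01


class TestCSVMatrix:
    def test_recording_round_trips_through_csv(self, tmp_path, tiny_recordings):
        rec = next(iter(tiny_recordings.values()))
        path = tmp_path / "eeg.csv"
        rec.to_csv(path)
        back = EEGRecording.from_csv(path)
        assert back.site_labels == rec.site_labels
        assert back.sampling_rate == pytest.approx(rec.sampling_rate, rel=1e-6)
        assert np.allclose(back.data, rec.data, atol=1e-5)
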