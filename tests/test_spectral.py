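import numpy as np
import pandas as pd
import pytest

from ctcgamma import spectral
from ctcgamma.preprocess import CANONICAL_BANDS, Band, EpochSet
from ctcgamma.spectral import (
    band_power,
    baseline_ratio,
    epoch_spectrum,
    induced_band_power,
    normalized_power,
)

from conftest import FS

GAMMA = CANONICAL_BANDS["gamma"]
BETA = CANONICAL_BANDS["beta"]


def _epochs(trials, label="late"):
    window = (0.2, 0.7) if label == "late" else (-0.5, 0.0)
    return EpochSet("L6", "saline", np.asarray(trials), label, window, FS)


class TestEpochSpectrum:
    def test_zero_epoch_gives_zero_spectrum(self):
        spec = epoch_spectrum(np.zeros(500), FS)
        assert np.allclose(spec.power, 0.0)
        assert spec.frequencies[1] - spec.frequencies[0] == pytest.approx(2.0)

    def test_sine_on_grid_concentrates_in_its_bin(self):
        t = np.arange(500) / FS
        spec = epoch_spectrum(np.sin(2 * np.pi * 40.0 * t), FS)
        # 40 Hz sits exactly on the 2 Hz grid; Hamming leakage stays local
        peak = np.argmax(spec.power)
        assert spec.frequencies[peak] == 40.0
        near = np.abs(spec.frequencies - 40.0) <= 4.0
        assert spec.power[near].sum() / spec.power.sum() > 0.99

    def test_parseval_energy_identity(self, rng):
        from scipy.signal import windows
        for _ in range(5):
            x = rng.standard_normal(500)
            spec = epoch_spectrum(x, FS, demean=False)
            xw = x * windows.hamming(500, sym=False)
            assert spec.power.sum() == pytest.approx(np.sum(xw**2), rel=1e-6)

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError, match="500"):
            epoch_spectrum(np.zeros(400), FS)


class TestBandPower:
    def test_unit_bins_sum_over_gamma(self):
        freqs = np.arange(0, 251) * 2.0
        spec = spectral.BandSpectrum(freqs, np.ones_like(freqs))
        # 30..80 Hz inclusive on the 2 Hz grid = 26 bins
        assert band_power(spec, GAMMA) == 26.0

    def test_power_outside_band_ignored(self):
        freqs = np.arange(0, 251) * 2.0
        p = np.zeros_like(freqs)
        p[freqs == 40.0] = 5.0
        spec = spectral.BandSpectrum(freqs, p)
        assert band_power(spec, BETA) == 0.0
        assert band_power(spec, GAMMA) == 5.0

    def test_band_partition_bounded_by_total(self, rng):
        freqs = np.arange(0, 251) * 2.0
        spec = spectral.BandSpectrum(freqs, rng.random(freqs.size))
        parts = sum(band_power(spec, b) for b in CANONICAL_BANDS.values())
        assert parts <= spec.power.sum() + 1e-12

    def test_empty_band_rejected(self):
        spec = spectral.BandSpectrum(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="no spectral bins"):
            band_power(spec, GAMMA)


def _table(pe, pb, band="gamma"):
    n = len(pe)
    return pd.DataFrame(dict(
        trial=np.arange(1, n + 1), band=band, channel="L6", condition="saline",
        P_b=pb, P_e=pe,
    ))


class TestNormalizedPower:
    def test_equal_powers_give_one(self):
        assert normalized_power(_table([3.0, 5.0], [3.0, 5.0])) == 1.0

    def test_mean_of_ratios_not_ratio_of_means(self):
        # (2/1 + 4/2) / 2 = 2, whereas ratio of means would be 6/3 = 2 here,
        # so also check an asymmetric case where the two disagree
        assert normalized_power(_table([2.0, 4.0], [1.0, 2.0])) == 2.0
        assert normalized_power(_table([2.0, 2.0], [1.0, 4.0])) == pytest.approx(1.25)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalized_power(_table([1.0, 1.0], [1.0, 0.0]))

    def test_matches_brute_force_on_random_tables(self, rng):
        pe = rng.random(40) + 0.1
        pb = rng.random(40) + 0.1
        expected = sum(e / b for e, b in zip(pe, pb)) / 40
        assert normalized_power(_table(pe, pb)) == pytest.approx(expected, rel=1e-12)


class TestBaselineRatio:
    def test_identical_tables_give_one(self):
        t = _table([2.0, 3.0], [1.0, 2.0])
        assert baseline_ratio(t, t, "gamma") == 1.0

    def test_common_gain_invariance(self, rng):
        pb = rng.random(10) + 0.5
        sal = _table(pb * 2, pb)
        ket = _table(pb * 6, pb * 3)
        r = baseline_ratio(ket, sal, "gamma")
        sal2 = _table(pb * 20, pb * 10)
        ket2 = _table(pb * 60, pb * 30)
        assert baseline_ratio(ket2, sal2, "gamma") == pytest.approx(r, rel=1e-12)
        assert r == pytest.approx(3.0)

    def test_unpaired_tables_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            baseline_ratio(_table([1.0], [1.0]), _table([1, 1], [1, 1]), "gamma")


class TestInducedBandPower:
    def test_pure_evoked_yields_zero_induced(self, rng):
        # identical late epochs across trials: total == evoked by construction
        t = np.arange(500) / FS
        wave = np.sin(2 * np.pi * 40 * t) * np.hanning(500)
        late = _epochs(np.tile(wave, (10, 1)))
        base = _epochs(np.zeros((10, 500)), "baseline")
        out = induced_band_power(late, base, GAMMA)
        total = out["total"].to_numpy()
        assert np.all(np.abs(out["induced"]) <= 1e-6 * total)

    def test_no_response_mean_induced_near_zero(self, rng):
        # baseline and late drawn from the same process: E[induced] = 0
        late = _epochs(rng.standard_normal((40, 500)))
        base = _epochs(rng.standard_normal((40, 500)), "baseline")
        out = induced_band_power(late, base, GAMMA)
        se = out["induced"].std(ddof=1) / np.sqrt(40)
        assert abs(out["induced"].mean()) < 2 * se + 1e-12

    def test_burst_power_additivity(self, rng):
        # doubling an added random-phase burst's power doubles mean induced
        base_tr = rng.standard_normal((40, 500)) * 0.1
        noise = rng.standard_normal((40, 500)) * 0.1
        t = np.arange(500) / FS
        phases = rng.uniform(0, 2 * np.pi, 40)
        burst = np.array([np.sin(2 * np.pi * 50 * t + ph) for ph in phases])
        means = []
        for amp in (0.5, 0.5 * np.sqrt(2)):
            late = _epochs(noise + amp * burst)
            out = induced_band_power(late, _epochs(base_tr, "baseline"), GAMMA)
            means.append(out["induced"].mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.1)

    def test_figure3_variant_omits_evoked_term(self, rng):
        late = _epochs(rng.standard_normal((10, 500)))
        base = _epochs(rng.standard_normal((10, 500)) * 0.5, "baseline")
        methods = induced_band_power(late, base, GAMMA, definition="methods")
        fig3 = induced_band_power(late, base, GAMMA, definition="figure3")
        evoked = methods["evoked"].iloc[0]
        assert np.allclose(fig3["induced"], methods["induced"] + evoked)

    def test_single_trial_rejected(self):
        late = _epochs(np.ones((1, 500)))
        base = _epochs(np.ones((1, 500)), "baseline")
        with pytest.raises(ValueError, match="2 trials"):
            induced_band_power(late, base, GAMMA)

    def test_evoked_power_bounded_by_mean_total(self, rng):
        # periodogram of the mean never exceeds the mean of periodograms
        for _ in range(5):
            late = _epochs(rng.standard_normal((20, 500)))
            base = _epochs(np.zeros((20, 500)), "baseline")
            out = induced_band_power(late, base, GAMMA)
            assert out["evoked"].iloc[0] <= out["total"].mean() + 1e-12
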