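"""Feature extraction: grids, analytic values, and oracle equivalence."""

import numpy as np
import pytest

from painfnirs import (
    Epoch,
    SpectralGrid,
    WaveletGrid,
    biomarker_subset,
    extract_all,
    extract_freq,
    extract_time,
    extract_wavelet,
)
from painfnirs.core import BIOMARKER_13, FEATURE_NAMES, METADATA_COLUMNS
from painfnirs.features import morlet_cwt
from painfnirs.simulate import SimulationConfig, simulate_subject
from painfnirs import extract_epochs

FS = 10.0
N = 900  # 90 s epoch at 10 Hz


def time_oracle(x, fs):
    """Direct-summation reference for the 9 time features (plain loops)."""
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / (n - 1)
    sigma = var**0.5
    skew = sum(((v - mu) / sigma) ** 3 for v in x) / (n - 1) if sigma > 0 else 0.0
    kurt = sum(((v - mu) / sigma) ** 4 for v in x) / (n - 1) if sigma > 0 else 0.0
    t = [i / fs for i in range(n)]
    tbar = sum(t) / n
    slope = sum((ti - tbar) * (vi - mu) for ti, vi in zip(t, x)) / sum(
        (ti - tbar) ** 2 for ti in t
    )
    auc = sum((x[i] + x[i + 1]) / 2 / fs for i in range(n - 1))
    rms = (sum(v**2 for v in x) / n) ** 0.5
    imax = max(range(n), key=lambda i: (x[i], -i))
    first_max = next(i for i in range(n) if x[i] == max(x))
    return {
        "mean": mu, "var": var, "skew": skew, "kurt": kurt,
        "peak": max(x), "slope": slope, "auc": auc, "rms": rms,
        "timepeak": first_max / fs,
    }


class TestGrids:
    def test_spectral_grid_structure(self):
        g = SpectralGrid()
        assert g.delta_f_hz == pytest.approx(1 / 90)
        assert len(g.bin_freqs_hz) == 15
        assert len(g.vlfo_bins) == 8 and len(g.lfo_bins) == 7
        assert np.all(np.diff(g.bin_freqs_hz) > 0)

    def test_wavelet_grid_structure(self):
        g = WaveletGrid()
        assert len(g.freqs_hz) == 30
        assert len(g.vlfo_scales) == 21 and len(g.lfo_scales) == 9
        # adjacent scales are one tenth of an octave apart
        np.testing.assert_allclose(g.freqs_hz[:-1] / g.freqs_hz[1:], 2 ** 0.1)
        # scale 11 is exactly one octave below the top
        assert g.freqs_hz[10] == pytest.approx(g.f_top_hz / 2)

    @pytest.mark.parametrize(
        "kind,index,printed",
        [
            ("fourier", 11, 0.122),
            ("wavelet", 5, 0.113),
            ("wavelet", 11, 0.0746),
            ("wavelet", 21, 0.0373),
            ("wavelet", 25, 0.0283),
            ("wavelet", 29, 0.0214),
        ],
    )
    def test_grid_reproduces_reference_frequencies(self, kind, index, printed):
        if kind == "fourier":
            f = SpectralGrid().bin_freqs_hz[index - 1]
        else:
            f = WaveletGrid().freqs_hz[index - 1]
        decimals = len(str(printed).split(".")[1])
        assert round(f, decimals) == pytest.approx(printed)


class TestTimeFeatures:
    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=50)
            got = extract_time(x, fs=FS)
            want = time_oracle(list(x), FS)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_constant_epoch_closed_forms(self):
        c = 2.5
        got = extract_time(np.full(N, c), fs=FS)
        assert got["mean"] == c
        assert got["var"] == 0.0
        assert got["skew"] == 0.0 and got["kurt"] == 0.0  # zero-variance convention
        assert got["peak"] == c
        assert got["slope"] == pytest.approx(0.0, abs=1e-12)
        assert got["auc"] == pytest.approx(c * 89.9)
        assert got["rms"] == pytest.approx(abs(c))
        assert got["timepeak"] == 0.0

    def test_linear_ramp_slope_in_units_per_second(self):
        x = np.arange(N) / FS
        got = extract_time(x, fs=FS)
        assert got["slope"] == pytest.approx(1.0)
        assert got["timepeak"] == pytest.approx((N - 1) / FS)

    def test_first_maximum_wins_ties(self):
        x = np.zeros(100)
        x[[30, 60]] = 5.0
        assert extract_time(x, fs=FS)["timepeak"] == pytest.approx(3.0)


class TestFreqFeatures:
    def test_onbin_sinusoid_closed_form(self):
        g = SpectralGrid()
        A = 2.0
        x = A * np.sin(2 * np.pi * g.bin_freqs_hz[4] * np.arange(N) / FS)
        got = extract_freq(x, g, fs=FS)
        assert got["F5"] == pytest.approx(A * N / 2, rel=1e-6)
        others = [got[f"F{j}"] for j in range(1, 16) if j != 5]
        assert max(others) < 1e-6 * A * N
        assert got["fmaxvl"] == pytest.approx(5 * g.delta_f_hz)
        assert got["maxevl"] == pytest.approx((A * N / 2) ** 2, rel=1e-6)

    def test_constant_epoch_zero_after_mean_removal(self):
        got = extract_freq(np.full(N, 7.0), fs=FS)
        assert max(got[f"F{j}"] for j in range(1, 16)) < 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            extract_freq(np.zeros(800), fs=FS)


class TestWaveletFeatures:
    @pytest.mark.parametrize("k", [5, 11, 21, 29])
    def test_scale_response_peaks_at_matching_scale(self, k):
        g = WaveletGrid()
        x = np.sin(2 * np.pi * g.freqs_hz[k - 1] * np.arange(N) / FS)
        got = extract_wavelet(x, g, fs=FS)
        wbar = np.array([got[f"W{j}"] for j in range(1, 31)])
        assert int(np.argmax(wbar)) + 1 == k

    def test_zero_epoch_all_zero(self):
        got = extract_wavelet(np.zeros(N), fs=FS)
        assert all(v == 0.0 for v in got.values())

    def test_symmetric_band_power_gives_small_amr(self):
        g = WaveletGrid()
        # one tone per band, placed at each band's geometric centre scale
        f_l = g.freqs_hz[4]    # scale 5, LFO
        f_v = g.freqs_hz[19]   # scale 20, VLFO
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * f_l * t) + np.sin(2 * np.pi * f_v * t)
        got = extract_wavelet(x, g, fs=FS)
        mean_level = 0.5 * (got["mwvl"] + got["mwl"])
        assert got["amr"] < 0.35 * mean_level

    def test_streaming_batch_agrees_with_full_field(self, rng):
        g = WaveletGrid()
        x = rng.normal(size=N)
        got = extract_wavelet(x, g, fs=FS)
        W = np.abs(morlet_cwt(x, FS, g))
        np.testing.assert_allclose(
            [got[f"W{j}"] for j in range(1, 31)], W.mean(axis=1), rtol=1e-10
        )
        assert got["wpsvl"] == pytest.approx(np.sum(W[g.vlfo_scales] ** 2), rel=1e-10)

    def test_profile_proportional_to_pywt_reference(self):
        # Independent cross-check: pywt's cmor CWT with matching scales.
        # Restricted to the upper half of the scale grid on a long signal:
        # pywt samples the integrated wavelet on a fixed coarse grid, which
        # biases its deepest scales, and edge truncation differs there too.
        import pywt

        g = WaveletGrid()
        rs = np.random.default_rng(3)
        x = rs.normal(size=6000)
        dt = 1 / FS
        # pywt cmorB-C: bandwidth B=2 gives the exp(-t^2/2) envelope and
        # centre frequency C = omega0 / (2 pi) cycles per scaled unit
        C = g.omega0 / (2 * np.pi)
        scales = C / (g.freqs_hz * dt)
        coef, _ = pywt.cwt(x, scales, f"cmor2.0-{C}", sampling_period=dt)
        ref = np.abs(coef).mean(axis=1)
        W = np.abs(morlet_cwt(x, FS, g))
        mine = W.mean(axis=1)
        ratio = (mine / ref)[:15]
        # same shape up to one global normalisation constant
        assert ratio.std() / ratio.mean() < 0.05


class TestAssembly:
    def test_full_table_shape_and_finiteness(self, small_sim_cfg):
        rec, _ = simulate_subject(small_sim_cfg, 0)
        epochs = extract_epochs(rec, small_sim_cfg.epoch_len_s)
        table = extract_all(epochs)
        assert table.shape == (len(epochs), 4 + 69)
        assert list(table.columns) == METADATA_COLUMNS + FEATURE_NAMES
        assert np.all(np.isfinite(table[FEATURE_NAMES].to_numpy()))

    def test_biomarker_subset_order_and_errors(self, small_sim_cfg):
        rec, _ = simulate_subject(small_sim_cfg, 0)
        table = extract_all(extract_epochs(rec, small_sim_cfg.epoch_len_s))
        sub = biomarker_subset(table)
        assert list(sub.columns) == METADATA_COLUMNS + BIOMARKER_13
        with pytest.raises(ValueError, match="unknown"):
            biomarker_subset(table, names=["timepeak", "nosuch"])
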