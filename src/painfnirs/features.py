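"""Extraction of the 69 per-epoch HbO features in three domains.

Time domain (9): mean, variance (N-1 denominator), skewness and kurtosis
(both with 1/(N-1) normalisation and the sample standard deviation; kurtosis
is raw, not excess), peak amplitude, least-squares slope over time in
seconds, trapezoidal area under the curve, RMS, and time to the first
maximum.

Frequency domain (23): magnitudes of the DFT of the mean-removed epoch at
bins j = 1..15 of the Delta-f = 1/90 Hz grid (F1..F8 labelled VLFO, F9..F15
LFO), then per band the mean and variance of |F|, the maximum energy |F|^2
and the frequency at which it occurs.

Wavelet domain (37): a Morlet (omega0 = 6) continuous wavelet transform at
30 scales placed on a 10-voice-per-octave geometric frequency grid from
f_top = 0.1492 Hz downward (W1..W9 LFO, W10..W30 VLFO); W-bar_k is the
time-mean of |W(s_k, .)|, and per band the mean of the W-bar_k, the variance
of all |coefficients|, the summed power |W|^2, plus the absolute difference
of the two band means (AMR).

The CWT is computed by FFT convolution of the sampled, truncated Morlet
kernel at each scale, batched over epochs, and reduced scale-by-scale so the
full coefficient field is never materialised for a whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import (
    BIOMARKER_13,
    FEATURE_NAMES,
    METADATA_COLUMNS,
    Epoch,
    validate_feature_table,
)

__all__ = [
    "SpectralGrid",
    "WaveletGrid",
    "extract_time",
    "extract_freq",
    "extract_wavelet",
    "extract_wavelet_batch",
    "extract_all",
    "biomarker_subset",
    "morlet_cwt",
]


# --------------------------------------------------------------------------
# Grids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralGrid:
    """15 DFT bins at multiples of 1/epoch_len_s Hz, split 8 VLFO + 7 LFO.

    Bin 8 sits at 0.0889 Hz, marginally above the nominal 0.08 Hz VLFO edge,
    but is grouped with VLFO to honour the fixed 8 + 7 band split.
    """

    epoch_len_s: float = 90.0
    n_bins: int = 15
    n_vlfo: int = 8

    @property
    def delta_f_hz(self) -> float:
        return 1.0 / self.epoch_len_s

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.arange(1, self.n_bins + 1) * self.delta_f_hz

    @property
    def vlfo_bins(self) -> np.ndarray:
        """0-based indices into the 15 bins belonging to the VLFO group."""
        return np.arange(self.n_vlfo)

    @property
    def lfo_bins(self) -> np.ndarray:
        return np.arange(self.n_vlfo, self.n_bins)


@dataclass(frozen=True)
class WaveletGrid:
    """30 CWT scales on a geometric frequency grid, split 9 LFO + 21 VLFO.

    Centre frequencies f_k = f_top * 2**(-(k-1)/voices), k = 1..30, indexed
    from high to low frequency; with 10 voices per octave and
    f_top = 0.1492 Hz this grid reproduces the reference per-scale
    frequencies (e.g. scale 11 at 0.0746 Hz, scale 21 at 0.0373 Hz).
    """

    n_scales: int = 30
    voices_per_octave: int = 10
    f_top_hz: float = 0.1492
    n_lfo: int = 9
    omega0: float = 6.0   # Morlet centre frequency parameter

    @property
    def freqs_hz(self) -> np.ndarray:
        k = np.arange(self.n_scales)
        return self.f_top_hz * 2.0 ** (-k / self.voices_per_octave)

    @property
    def lfo_scales(self) -> np.ndarray:
        """0-based indices of the LFO group (the first, high-frequency scales)."""
        return np.arange(self.n_lfo)

    @property
    def vlfo_scales(self) -> np.ndarray:
        return np.arange(self.n_lfo, self.n_scales)

    def scales_s(self) -> np.ndarray:
        """Morlet scale (seconds) targeting each centre frequency."""
        return self.omega0 / (2.0 * np.pi * self.freqs_hz)


# --------------------------------------------------------------------------
# Time domain
# --------------------------------------------------------------------------

def _epoch_signal(epoch: Epoch | np.ndarray, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(epoch, Epoch):
        return epoch.x, epoch.fs
    if fs is None:
        raise ValueError("fs is required when passing a raw sample vector")
    return np.asarray(epoch, dtype=float), float(fs)


def extract_time(epoch: Epoch | np.ndarray, fs: float | None = None) -> dict[str, float]:
    """The 9 time-domain features of one epoch."""
    x, fs = _epoch_signal(epoch, fs)
    n = len(x)
    if n < 2:
        raise ValueError("epoch must hold at least 2 samples")
    t = np.arange(n) / fs
    mu = x.mean()
    dev = x - mu
    var = float(dev @ dev / (n - 1))
    sigma = np.sqrt(var)
    if sigma > 0:
        skew = float(np.sum((dev / sigma) ** 3) / (n - 1))
        kurt = float(np.sum((dev / sigma) ** 4) / (n - 1))
    else:  # zero-variance epoch: moments undefined, reported as 0
        skew = 0.0
        kurt = 0.0
    slope = float(np.polyfit(t, x, 1)[0])
    return {
        "mean": float(mu),
        "var": var,
        "skew": skew,
        "kurt": kurt,
        "peak": float(x.max()),
        "slope": slope,
        "auc": float(np.trapezoid(x, dx=1.0 / fs)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "timepeak": float(np.argmax(x) / fs),   # first maximum wins
    }


# --------------------------------------------------------------------------
# Frequency domain
# --------------------------------------------------------------------------

def extract_freq(
    epoch: Epoch | np.ndarray,
    grid: SpectralGrid | None = None,
    fs: float | None = None,
) -> dict[str, float]:
    """The 23 frequency-domain features of one epoch.

    The epoch length must equal ``epoch_len_s * fs`` so that DFT bin j sits
    exactly at j * delta_f; no silent re-gridding is performed.
    """
    grid = grid or SpectralGrid()
    x, fs = _epoch_signal(epoch, fs)
    n = len(x)
    expected = int(round(grid.epoch_len_s * fs))
    if n != expected:
        raise ValueError(
            f"epoch length {n} does not match the grid resolution "
            f"({grid.epoch_len_s} s at {fs} Hz = {expected} samples)"
        )
    spec = np.fft.rfft(x - x.mean())
    mags = np.abs(spec[1 : grid.n_bins + 1])   # bins j = 1..15
    freqs = grid.bin_freqs_hz

    out = {f"F{j}": float(mags[j - 1]) for j in range(1, grid.n_bins + 1)}
    for suffix, idx in (("vl", grid.vlfo_bins), ("l", grid.lfo_bins)):
        band = mags[idx]
        energy = band**2
        imax = int(np.argmax(energy))          # earliest bin wins ties
        out[f"meanf{suffix}"] = float(band.mean())
        out[f"var{suffix}"] = float(band.var(ddof=1))
        out[f"maxe{suffix}"] = float(energy[imax])
        out[f"fmax{suffix}"] = float(freqs[idx][imax])
    return out


# --------------------------------------------------------------------------
# Wavelet domain
# --------------------------------------------------------------------------

def _morlet_kernel(scale_s: float, fs: float, omega0: float, support: float = 4.0) -> np.ndarray:
    """Sampled, truncated complex Morlet convolution kernel at one scale.

    psi(u) = pi^(-1/4) exp(i omega0 u) exp(-u^2 / 2); the convolution kernel
    is psi(m dt / s) dt / sqrt(s), truncated at |u| <= ``support`` standard
    widths of the Gaussian envelope.
    """
    dt = 1.0 / fs
    half = int(np.ceil(support * scale_s / dt))
    u = (np.arange(-half, half + 1) * dt) / scale_s
    psi = np.pi**-0.25 * np.exp(1j * omega0 * u) * np.exp(-(u**2) / 2.0)
    return psi * (dt / np.sqrt(scale_s))


def morlet_cwt(
    x: np.ndarray, fs: float, grid: WaveletGrid | None = None
) -> np.ndarray:
    """Full CWT coefficient field of one epoch: (n_scales, n_samples) complex.

    Edge effects from the finite epoch are accepted (no padding); intended
    for inspection and cross-checking, not for bulk extraction.
    """
    grid = grid or WaveletGrid()
    x = np.asarray(x, dtype=float)
    out = np.empty((grid.n_scales, len(x)), dtype=complex)
    for i, s in enumerate(grid.scales_s()):
        kern = _morlet_kernel(s, fs, grid.omega0)
        out[i] = fftconvolve(x, kern, mode="same")
    return out


def extract_wavelet_batch(
    X: np.ndarray,
    fs: float,
    grid: WaveletGrid | None = None,
    chunk: int = 512,
) -> pd.DataFrame:
    """The 37 wavelet features for a stack of epochs (n_epochs, n_samples).

    Streams scale by scale, accumulating per-band sums so that the full
    (epochs x scales x samples) coefficient field never exists in memory.
    """
    grid = grid or WaveletGrid()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_epochs, n_samples = X.shape
    scales = grid.scales_s()

    wbar = np.zeros((n_epochs, grid.n_scales))
    band_sum = {"vl": np.zeros(n_epochs), "l": np.zeros(n_epochs)}
    band_sumsq = {"vl": np.zeros(n_epochs), "l": np.zeros(n_epochs)}
    band_count = {"vl": 0, "l": 0}
    band_of = {int(k): "l" for k in grid.lfo_scales}
    band_of.update({int(k): "vl" for k in grid.vlfo_scales})

    for k in range(grid.n_scales):
        kern = _morlet_kernel(scales[k], fs, grid.omega0)[None, :]
        for lo in range(0, n_epochs, chunk):
            sl = slice(lo, min(lo + chunk, n_epochs))
            w = np.abs(fftconvolve(X[sl], kern, mode="same", axes=1))
            wbar[sl, k] = w.mean(axis=1)
            b = band_of[k]
            band_sum[b][sl] += w.sum(axis=1)
            band_sumsq[b][sl] += (w**2).sum(axis=1)
        band_count[band_of[k]] += n_samples

    out: dict[str, np.ndarray] = {f"W{k + 1}": wbar[:, k] for k in range(grid.n_scales)}
    mw = {}
    for suffix, idx in (("vl", grid.vlfo_scales), ("l", grid.lfo_scales)):
        m = band_count[suffix]
        mean_abs = band_sum[suffix] / m
        # sample variance of all |coefficients| in the band (N-1 denominator)
        var = (band_sumsq[suffix] - m * mean_abs**2) / (m - 1)
        mw[suffix] = wbar[:, idx].mean(axis=1)
        out[f"mw{suffix}"] = mw[suffix]
        out[f"vw{suffix}"] = np.maximum(var, 0.0)
        out[f"wps{suffix}"] = band_sumsq[suffix]
    out["amr"] = np.abs(mw["vl"] - mw["l"])
    return pd.DataFrame(out)


def extract_wavelet(
    epoch: Epoch | np.ndarray,
    grid: WaveletGrid | None = None,
    fs: float | None = None,
) -> dict[str, float]:
    """The 37 wavelet-domain features of one epoch."""
    x, fs = _epoch_signal(epoch, fs)
    row = extract_wavelet_batch(x[None, :], fs, grid).iloc[0]
    return {k: float(v) for k, v in row.items()}


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

def extract_all(
    epochs: list[Epoch],
    spectral_grid: SpectralGrid | None = None,
    wavelet_grid: WaveletGrid | None = None,
) -> pd.DataFrame:
    """One 69-column row per epoch, with subject/trial/channel/label metadata."""
    spectral_grid = spectral_grid or SpectralGrid()
    wavelet_grid = wavelet_grid or WaveletGrid()
    if not epochs:
        return pd.DataFrame(columns=METADATA_COLUMNS + FEATURE_NAMES)

    meta = pd.DataFrame(
        {
            "subject": [e.subject_id for e in epochs],
            "trial": [e.trial_id for e in epochs],
            "channel": [e.channel for e in epochs],
            "label": [e.label for e in epochs],
        }
    )
    rows = []
    for e in epochs:
        row = extract_time(e)
        row.update(extract_freq(e, spectral_grid))
        rows.append(row)
    tf = pd.DataFrame(rows)

    X = np.stack([e.x for e in epochs])
    wav = extract_wavelet_batch(X, epochs[0].fs, wavelet_grid)

    table = pd.concat([meta, tf, wav], axis=1)[METADATA_COLUMNS + FEATURE_NAMES]
    validate_feature_table(table)
    return table


def biomarker_subset(table: pd.DataFrame, names: list[str] | None = None) -> pd.DataFrame:
    """Select the 13-feature pain-biomarker columns, in their rank order."""
    names = names if names is not None else BIOMARKER_13
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s) in preset: {unknown}")
    keep = [c for c in METADATA_COLUMNS if c in table.columns] + list(names)
    missing = [c for c in keep if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks column(s): {missing}")
    return table[keep]
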