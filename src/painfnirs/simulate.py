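"""Synthetic multi-subject fNIRS HbO generator.

Emulates the statistical structure the downstream analysis assumes: a
baseline rest segment followed by randomised-order thermal-pain trials
(three per class by default), where every channel is a sum of

* systemic physiology shared across channels with random per-channel gains —
  cardiac (~1.25 Hz), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz)
  sinusoids plus a slow linear drift;
* an event-locked haemodynamic response (double-gamma difference: small
  initial dip, rise to a peak, decay back to baseline) whose amplitude and
  latency depend on the pain class;
* class-dependent narrowband oscillations in the VLFO (0.01-0.08 Hz) or LFO
  (0.08-0.15 Hz) band — cold conditions carry extra VLFO power, heat
  conditions extra LFO power;
* white measurement noise and Poisson-placed motion-artifact transients
  (sharp spike plus a decaying step).

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .core import Recording

__all__ = [
    "ClassParams",
    "NoiseParams",
    "SimulationConfig",
    "GroundTruth",
    "hrf_kernel",
    "simulate_subject",
    "simulate_dataset",
]


@dataclass
class ClassParams:
    """Signal parameters for one pain class.

    ``hrf_amplitude`` is the peak HbO excursion (concentration units),
    ``vlfo_power`` / ``lfo_power`` are narrowband oscillation amplitudes in
    the same units, and the ``*_peak_freq_hz`` fields place the oscillation
    inside its band.
    """

    hrf_amplitude: float
    hrf_peak_latency_s: float
    vlfo_power: float
    lfo_power: float
    vlfo_peak_freq_hz: float
    lfo_peak_freq_hz: float


@dataclass
class NoiseParams:
    cardiac_freq_hz: float = 1.25
    cardiac_amp: float = 0.25
    resp_freq_hz: float = 0.3
    resp_amp: float = 0.15
    mayer_freq_hz: float = 0.1
    mayer_amp: float = 0.15
    drift_slope: float = 0.002      # concentration units per second
    white_sigma: float = 0.1
    artifact_rate_per_min: float = 0.3
    artifact_amp: float = 4.0


def _default_class_params() -> dict[int, ClassParams]:
    # Cold conditions carry extra VLFO power, heat extra LFO power; high
    # pain roughly doubles the activation peak and band power of its
    # low-pain counterpart, shifts the within-band oscillation peak upwards
    # and shortens the response latency (stronger stimuli evoke faster,
    # larger responses).  Latency and peak frequency are gain-invariant, so
    # intensity stays decodable despite between-subject gain variability.
    return {
        1: ClassParams(1.0, 8.5, 0.8, 0.05, 0.035, 0.12),   # Low-Cold
        2: ClassParams(1.4, 6.0, 0.05, 0.8, 0.05, 0.10),    # Low-Heat
        3: ClassParams(2.2, 7.0, 1.8, 0.05, 0.070, 0.12),   # High-Cold
        4: ClassParams(3.0, 4.5, 0.05, 1.8, 0.05, 0.14),    # High-Heat
    }


@dataclass
class SimulationConfig:
    n_subjects: int = 18
    n_trials_per_class: int = 3
    n_channels: int = 24
    fs: float = 10.0
    epoch_len_s: float = 90.0
    rest_len_s: float = 60.0
    inter_stimulus_rest_s: float = 30.0
    class_params: dict[int, ClassParams] = field(default_factory=_default_class_params)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    subject_effect_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_params = {
            int(k): (v if isinstance(v, ClassParams) else ClassParams(**v))
            for k, v in self.class_params.items()
        }
        if not isinstance(self.noise_params, NoiseParams):
            self.noise_params = NoiseParams(**self.noise_params)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if sorted(self.class_params) != [1, 2, 3, 4]:
            raise ValueError("class_params must cover codes 1..4")
        np_ = self.noise_params
        for name in ("cardiac_freq_hz", "resp_freq_hz", "mayer_freq_hz"):
            f = getattr(np_, name)
            if not 0 < f < self.fs / 2:
                raise ValueError(f"{name}={f} outside (0, fs/2)")
        for code, cp in self.class_params.items():
            for name in ("hrf_amplitude", "vlfo_power", "lfo_power"):
                if getattr(cp, name) < 0:
                    raise ValueError(f"class {code}: {name} must be >= 0")
            if cp.hrf_peak_latency_s <= 0:
                raise ValueError(f"class {code}: hrf_peak_latency_s must be positive")

    # YAML plumbing -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_params"] = {int(k): asdict(v) for k, v in self.class_params.items()}
        d["noise_params"] = asdict(self.noise_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_class

    @property
    def duration_s(self) -> float:
        return self.rest_len_s + self.n_trials * (
            self.epoch_len_s + self.inter_stimulus_rest_s
        )


@dataclass
class GroundTruth:
    """Latent per-trial state aligned one-to-one with the emitted events."""

    trials: pd.DataFrame      # trial, onset_s, label, amplitude
    artifacts: pd.DataFrame   # channel, time_s


def hrf_kernel(
    t_grid: np.ndarray,
    amplitude: float,
    peak_latency_s: float,
    dip_ratio: float = 0.15,
    dip_latency_s: float | None = None,
) -> np.ndarray:
    """Canonical activation curve: initial dip, single peak, decay to ~0.

    A difference of two gamma-shaped bumps: the main bump peaks at
    ``peak_latency_s`` with value 1; an earlier bump (mode
    ``dip_latency_s``, default a third of the peak latency) is subtracted
    with weight ``dip_ratio``, producing the small initial negative dip.
    The result is rescaled so its maximum equals ``amplitude``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be non-negative and increasing")
    if peak_latency_s <= 0:
        raise ValueError("peak_latency_s must be positive")
    if dip_latency_s is None:
        dip_latency_s = peak_latency_s / 3.0
    if dip_latency_s <= 0:
        raise ValueError("dip_latency_s must be positive")

    def _bump(mode: float, k: float) -> np.ndarray:
        # gamma-shaped, unit maximum at t = mode; k controls width
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(t > 0, t / mode, 0.0)
            b = u ** (k - 1) * np.exp((k - 1) * (1.0 - u))
        return np.where(t > 0, b, 0.0)

    h = _bump(peak_latency_s, 6.0) - dip_ratio * _bump(dip_latency_s, 3.0)
    m = h.max()
    if m <= 0:
        return np.zeros_like(t)
    return h * (amplitude / m)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # child stream = hash of (master seed, subject index) via SeedSequence
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def simulate_subject(cfg: SimulationConfig, subject_index: int) -> tuple[Recording, GroundTruth]:
    """Simulate one subject; deterministic given ``(cfg.seed, subject_index)``."""
    cfg.validate()
    rng = _subject_rng(cfg.seed, subject_index)
    fs, n_ch = cfg.fs, cfg.n_channels
    n_samples = int(round(cfg.duration_s * fs))
    t = np.arange(n_samples) / fs
    npz = cfg.noise_params

    # subject-level random effect scales all activation amplitudes
    subject_gain = float(np.exp(rng.normal(0.0, cfg.subject_effect_sigma)))

    # Systemic coupling is global (all channels near gain 1); the activation
    # response is spatially localized to a responsive channel subset, as for
    # cortical pain processing under a whole-head probe.  The distinct spatial
    # patterns are what lets rest-referenced PCA delete systemic components
    # without deleting the task response.
    sys_gain = rng.normal(1.0, 0.2, size=n_ch)
    responsive = rng.random(n_ch) < 0.5
    if not responsive.any():
        responsive[rng.integers(n_ch)] = True
    hrf_gain = np.abs(
        np.where(responsive, rng.normal(1.2, 0.2, n_ch), rng.normal(0.15, 0.05, n_ch))
    )
    osc_gain = np.abs(
        np.where(responsive, rng.normal(1.2, 0.2, n_ch), rng.normal(0.15, 0.05, n_ch))
    )

    # shared systemic physiology
    systemic = np.zeros(n_samples)
    for f_hz, amp in (
        (npz.cardiac_freq_hz, npz.cardiac_amp),
        (npz.resp_freq_hz, npz.resp_amp),
        (npz.mayer_freq_hz, npz.mayer_amp),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        systemic += amp * np.sin(2 * np.pi * f_hz * t + phase)
    drift = npz.drift_slope * t

    hbo = sys_gain[:, None] * systemic[None, :] + drift[None, :] * rng.normal(
        1.0, 0.3, size=(n_ch, 1)
    )

    # randomised trial order, class-balanced
    labels = np.repeat([1, 2, 3, 4], cfg.n_trials_per_class)
    rng.shuffle(labels)
    epoch_n = int(round(cfg.epoch_len_s * fs))
    t_epoch = np.arange(epoch_n) / fs
    taper = tukey(epoch_n, alpha=0.2)  # soften oscillation onsets/offsets

    onsets, amplitudes = [], []
    for i, label in enumerate(labels):
        onset_s = cfg.rest_len_s + i * (cfg.epoch_len_s + cfg.inter_stimulus_rest_s)
        onsets.append(onset_s)
        start = int(round(onset_s * fs))
        cp = cfg.class_params[int(label)]

        amp = cp.hrf_amplitude * subject_gain * float(np.exp(rng.normal(0.0, 0.1)))
        amplitudes.append(amp)
        hrf = hrf_kernel(t_epoch, amp, cp.hrf_peak_latency_s)

        osc = np.zeros(epoch_n)
        for power, f_peak, lo, hi in (
            (cp.vlfo_power, cp.vlfo_peak_freq_hz, 0.01, 0.08),
            (cp.lfo_power, cp.lfo_peak_freq_hz, 0.08, 0.15),
        ):
            if power <= 0:
                continue
            f_hz = float(np.clip(f_peak * (1.0 + rng.normal(0.0, 0.05)), lo, hi))
            phase = rng.uniform(0, 2 * np.pi)
            osc += power * np.sin(2 * np.pi * f_hz * t_epoch + phase)
        osc *= taper

        seg = slice(start, start + epoch_n)
        hbo[:, seg] += hrf_gain[:, None] * hrf[None, :]
        hbo[:, seg] += osc_gain[:, None] * (subject_gain * osc)[None, :]

    # white noise
    if npz.white_sigma > 0:
        hbo += rng.normal(0.0, npz.white_sigma, size=hbo.shape)

    # motion artifacts: per channel, Poisson-placed spike + decaying step
    artifact_rows = []
    rate = npz.artifact_rate_per_min * cfg.duration_s / 60.0
    for ch in range(n_ch):
        n_art = rng.poisson(rate)
        for time_s in np.sort(rng.uniform(0, cfg.duration_s, size=n_art)):
            k0 = int(time_s * fs)
            sign = rng.choice([-1.0, 1.0])
            tail = np.arange(n_samples - k0) / fs
            hbo[ch, k0:] += sign * npz.artifact_amp * np.exp(-tail / 1.0)
            hbo[ch, k0:] += sign * 0.2 * npz.artifact_amp * np.exp(-tail / 20.0)
            artifact_rows.append({"channel": ch + 1, "time_s": float(time_s)})

    events = pd.DataFrame(
        [{"onset_s": 0.0, "label": 0, "kind": "rest"}]
        + [
            {"onset_s": float(o), "label": int(l), "kind": "stimulus"}
            for o, l in zip(onsets, labels)
        ]
    )
    rec = Recording(
        subject_id=f"S{subject_index + 1:02d}",
        hbo=hbo,
        fs=fs,
        events=events,
    )
    truth = GroundTruth(
        trials=pd.DataFrame(
            {
                "trial": np.arange(cfg.n_trials),
                "onset_s": onsets,
                "label": labels.astype(int),
                "amplitude": amplitudes,
            }
        ),
        artifacts=pd.DataFrame(artifact_rows, columns=["channel", "time_s"]),
    )
    return rec, truth


def simulate_dataset(cfg: SimulationConfig) -> list[tuple[Recording, GroundTruth]]:
    """Simulate ``cfg.n_subjects`` recordings with per-subject child seeds."""
    return [simulate_subject(cfg, i) for i in range(cfg.n_subjects)]
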