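"""Shared data model: recordings, stimulus events, epochs and feature tables.

A :class:`Recording` holds one subject's multi-channel oxyhaemoglobin (HbO)
series (channels x samples, arbitrary concentration units such as mM.mm)
sampled at ``fs`` Hz, together with a stimulus event table.  Epoching cuts a
fixed-length stimulus-locked window out of every channel for every stimulus
event.  Feature tables carry one row per (trial, channel) sample with a fixed,
versioned 69-column feature schema shared by the whole package.

Conventions used everywhere:

* onset-to-sample conversion is ``floor(onset_s * fs)``, 0-based;
* epoch windows are half-open ``[start, start + n)`` with
  ``n = round(epoch_len_s * fs)`` samples;
* epochs whose window runs past the end of the recording are zero-padded and
  flagged, never silently truncated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PainClass",
    "PAIN_CLASSES",
    "Recording",
    "Epoch",
    "extract_epochs",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
    "METADATA_COLUMNS",
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "WAVELET_FEATURES",
    "FEATURE_NAMES",
    "BIOMARKER_13",
]


# --------------------------------------------------------------------------
# Pain classes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PainClass:
    """One of the four thermal pain conditions (modality x intensity)."""

    code: int
    name: str

    def __post_init__(self) -> None:
        if self.code not in _CODE_TO_NAME:
            raise ValueError(f"pain class code must be 1..4, got {self.code}")
        if _CODE_TO_NAME[self.code] != self.name:
            raise ValueError(
                f"code {self.code} maps to {_CODE_TO_NAME[self.code]!r}, "
                f"not {self.name!r}"
            )

    @classmethod
    def from_code(cls, code: int) -> "PainClass":
        return cls(int(code), _CODE_TO_NAME[int(code)])

    @classmethod
    def from_name(cls, name: str) -> "PainClass":
        return cls(_NAME_TO_CODE[name], name)


_CODE_TO_NAME = {1: "LowCold", 2: "LowHeat", 3: "HighCold", 4: "HighHeat"}
_NAME_TO_CODE = {v: k for k, v in _CODE_TO_NAME.items()}

#: The four conditions in label-code order.
PAIN_CLASSES = tuple(PainClass.from_code(c) for c in (1, 2, 3, 4))


# --------------------------------------------------------------------------
# Canonical feature schema (69 names, fixed order)
# --------------------------------------------------------------------------

#: Sample metadata columns preceding the feature columns in every table.
METADATA_COLUMNS = ["subject", "trial", "channel", "label"]

#: 9 time-domain features, in canonical order.
TIME_FEATURES = [
    "mean", "var", "skew", "kurt", "peak", "slope", "auc", "rms", "timepeak",
]

#: 23 frequency-domain features: 15 Fourier magnitudes on the 1/90 Hz grid
#: (F1..F8 in the VLFO band, F9..F15 in the LFO band), then per-band summary
#: statistics (vl = VLFO 0.01-0.08 Hz, l = LFO 0.08-0.15 Hz).
FREQ_FEATURES = [f"F{j}" for j in range(1, 16)] + [
    "meanfvl", "meanfl",   # mean |F| per band
    "varvl", "varl",       # variance of |F| per band
    "maxevl", "maxel",     # maximum energy |F|^2 per band
    "fmaxvl", "fmaxl",     # frequency (Hz) of the maximum energy per band
]

#: 37 wavelet-domain features: 30 per-scale mean |CWT| coefficients on the
#: 10-voice geometric grid (W1..W9 LFO, W10..W30 VLFO), then per-band
#: summaries and the absolute mean ratio.
WAVELET_FEATURES = [f"W{k}" for k in range(1, 31)] + [
    "mwvl", "mwl",         # mean of per-scale means per band
    "vwvl", "vwl",         # variance of |coefficients| per band
    "wpsvl", "wpsl",       # wavelet power spectrum (sum |W|^2) per band
    "amr",                 # |mwvl - mwl|
]

#: Canonical 69-feature column order: 9 time + 23 frequency + 37 wavelet.
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES + WAVELET_FEATURES
assert len(FEATURE_NAMES) == 69

#: The 13-feature pain biomarker subset, in its JMI rank order.
BIOMARKER_13 = [
    "timepeak", "F5", "W5", "W29", "varvl", "vwvl", "mean",
    "W11", "F11", "vwl", "W25", "F7", "W21",
]


# --------------------------------------------------------------------------
# Recording
# --------------------------------------------------------------------------

_EVENT_COLUMNS = ["onset_s", "label", "kind"]


@dataclass
class Recording:
    """One subject's multi-channel HbO recording plus its event table.

    Parameters
    ----------
    subject_id : str
    hbo : ndarray, shape (n_channels, n_samples)
        Oxyhaemoglobin concentration series, arbitrary units.
    fs : float
        Sampling rate in Hz (10 Hz in the reference acquisition).
    events : DataFrame with columns ``onset_s``, ``label``, ``kind``
        ``kind`` is ``"stimulus"`` or ``"rest"``; stimulus rows carry a class
        label in 1..4, rest rows carry label 0.
    channel_names : list of str, optional
        Defaults to ``ch01..chNN``.
    """

    subject_id: str
    hbo: np.ndarray
    fs: float = 10.0
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_EVENT_COLUMNS))
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        if self.hbo.ndim != 2:
            raise ValueError("hbo must be a 2-D (channels x samples) array")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(1, self.n_channels + 1)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal the channel count")
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.hbo)):
            bad = np.argwhere(~np.isfinite(self.hbo))[0]
            raise ValueError(
                f"non-finite HbO value at channel {bad[0] + 1}, sample {bad[1]}"
            )
        ev = self.events
        missing = [c for c in _EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"event table lacks column(s): {missing}")
        onsets = ev["onset_s"].to_numpy(dtype=float)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            i = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise ValueError(f"event onsets not strictly increasing at row {i}")
        if np.any(onsets < 0) or np.any(onsets > self.duration_s):
            bad = onsets[(onsets < 0) | (onsets > self.duration_s)][0]
            raise ValueError(
                f"event onset {bad} s lies outside the recording "
                f"(duration {self.duration_s} s)"
            )
        stim = ev[ev["kind"] == "stimulus"]
        labels = stim["label"].to_numpy(dtype=int) if len(stim) else np.array([], int)
        if len(labels) and not np.all(np.isin(labels, [1, 2, 3, 4])):
            bad = labels[~np.isin(labels, [1, 2, 3, 4])][0]
            raise ValueError(f"stimulus label must be 1..4, got {bad}")

    def stimulus_events(self) -> pd.DataFrame:
        """Stimulus rows of the event table, in onset order."""
        return self.events[self.events["kind"] == "stimulus"].reset_index(drop=True)


# --------------------------------------------------------------------------
# Epochs
# --------------------------------------------------------------------------

@dataclass
class Epoch:
    """A fixed-length single-channel stimulus-locked segment."""

    subject_id: str
    trial_id: int
    channel: int          # 1-based channel index
    label: int            # pain class code 1..4
    x: np.ndarray
    fs: float
    padded: bool = False  # True when the source ran short and was zero-padded

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("epoch contains non-finite samples")


def extract_epochs(rec: Recording, epoch_len_s: float) -> list[Epoch]:
    """Cut one epoch per (stimulus event, channel) from a recording.

    The window spans ``[onset, onset + epoch_len_s)``; the start sample is
    ``floor(onset * fs)`` and the window holds ``round(epoch_len_s * fs)``
    samples.  Windows running past the end of the recording are zero-padded
    and flagged via ``Epoch.padded``.  A recording with no stimulus events
    yields an empty list.
    """
    if not epoch_len_s > 0:
        raise ValueError("epoch_len_s must be positive")
    n = int(round(epoch_len_s * rec.fs))
    epochs: list[Epoch] = []
    stim = rec.stimulus_events()
    for trial_id, row in enumerate(stim.itertuples(index=False)):
        start = math.floor(float(row.onset_s) * rec.fs)
        stop = start + n
        pad = stop > rec.n_samples
        for ch in range(rec.n_channels):
            seg = rec.hbo[ch, start:min(stop, rec.n_samples)]
            if pad:
                seg = np.concatenate([seg, np.zeros(stop - rec.n_samples)])
            epochs.append(
                Epoch(
                    subject_id=rec.subject_id,
                    trial_id=trial_id,
                    channel=ch + 1,
                    label=int(row.label),
                    x=seg,
                    fs=rec.fs,
                    padded=pad,
                )
            )
    return epochs


# --------------------------------------------------------------------------
# Recording bundle I/O
# --------------------------------------------------------------------------
# A bundle is three text files sharing a prefix: <name>_hbo.csv (header =
# channel names, rows = samples), <name>_events.csv (onset_s,label,kind) and
# <name>_meta.json ({"subject_id": ..., "fs": ...}).

def write_recording(rec: Recording, directory: str | Path, name: str | None = None) -> Path:
    """Write a recording bundle; returns the bundle prefix path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or rec.subject_id
    prefix = directory / name
    hbo = pd.DataFrame(rec.hbo.T, columns=rec.channel_names)
    hbo.to_csv(f"{prefix}_hbo.csv", index=False)
    ev = rec.events.copy()
    ev["label"] = ev["label"].astype(int)
    ev.to_csv(f"{prefix}_events.csv", index=False)
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump({"subject_id": rec.subject_id, "fs": rec.fs}, fh)
    return prefix


def read_recording(path: str | Path) -> Recording:
    """Read a recording bundle written by :func:`write_recording`.

    ``path`` is either the bundle prefix (``dir/name``) or a directory
    containing exactly one bundle.
    """
    path = Path(path)
    if path.is_dir():
        metas = sorted(path.glob("*_meta.json"))
        if len(metas) != 1:
            raise ValueError(
                f"{path} holds {len(metas)} recording bundles; pass the bundle prefix"
            )
        path = Path(str(metas[0])[: -len("_meta.json")])
    hbo_path = Path(f"{path}_hbo.csv")
    ev_path = Path(f"{path}_events.csv")
    meta_path = Path(f"{path}_meta.json")
    for p in (hbo_path, ev_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"missing bundle file {p}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    hbo = pd.read_csv(hbo_path, float_precision="round_trip")
    if hbo.isna().any().any():
        col = hbo.columns[hbo.isna().any()][0]
        row = int(hbo[hbo[col].isna()].index[0])
        raise ValueError(f"NaN in {hbo_path} at column {col!r}, row {row}")
    events = pd.read_csv(ev_path)
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"{ev_path}: malformed header, missing {missing}")
    return Recording(
        subject_id=str(meta["subject_id"]),
        hbo=hbo.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        events=events[_EVENT_COLUMNS],
        channel_names=list(hbo.columns),
    )


# --------------------------------------------------------------------------
# Feature table I/O
# --------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> None:
    """Raise a schema error unless ``table`` has the canonical columns."""
    expected = METADATA_COLUMNS + FEATURE_NAMES
    missing = [c for c in expected if c not in table.columns]
    extra = [c for c in table.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"feature table schema mismatch: missing={missing}, extra={extra}"
        )
    feat = table[FEATURE_NAMES].to_numpy(dtype=float)
    if not np.all(np.isfinite(feat)):
        r, c = np.argwhere(~np.isfinite(feat))[0]
        raise ValueError(
            f"non-finite feature value at row {r}, column {FEATURE_NAMES[c]!r}"
        )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV: metadata columns first, then the 69 features."""
    validate_feature_table(table)
    ordered = table[METADATA_COLUMNS + FEATURE_NAMES]
    ordered.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    validate_feature_table(table)
    return table[METADATA_COLUMNS + FEATURE_NAMES]
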