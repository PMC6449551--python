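import numpy as np
import pandas as pd
import pytest

from painfnirs import (
    FEATURE_NAMES,
    METADATA_COLUMNS,
    Recording,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_recording():
    """3-channel, 100-sample recording with one stimulus event."""
    rs = np.random.default_rng(7)
    events = pd.DataFrame(
        [
            {"onset_s": 0.0, "label": 0, "kind": "rest"},
            {"onset_s": 2.0, "label": 1, "kind": "stimulus"},
        ]
    )
    return Recording(
        subject_id="T01",
        hbo=rs.normal(size=(3, 100)),
        fs=10.0,
        events=events,
    )


@pytest.fixture
def small_sim_cfg():
    """A miniature simulation: quick, but structurally complete."""
    return SimulationConfig(
        n_subjects=2,
        n_trials_per_class=1,
        n_channels=3,
        seed=99,
    )


def random_feature_table(n_subjects=6, rows_per_subject=12, seed=0, planted=None):
    """A synthetic feature table with iid noise features.

    ``planted``: optional dict {feature_name: callable(labels, rng) -> values}
    to overwrite specific columns with label-dependent values.
    """
    rs = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        labels = np.tile([1, 2, 3, 4], rows_per_subject // 4 + 1)[:rows_per_subject]
        for i, lab in enumerate(labels):
            rows.append({"subject": f"S{s:02d}", "trial": i, "channel": 1, "label": int(lab)})
    meta = pd.DataFrame(rows)
    feat = pd.DataFrame(
        rs.normal(size=(len(meta), len(FEATURE_NAMES))), columns=FEATURE_NAMES
    )
    table = pd.concat([meta, feat], axis=1)
    if planted:
        for name, fn in planted.items():
            table[name] = fn(table["label"].to_numpy(), rs)
    return table
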