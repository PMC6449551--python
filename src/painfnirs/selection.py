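"""Filter-based feature ranking: information gain, JMI, and chi-squared.

All three criteria operate on discretized features (continuous values are
binned, equal-frequency by default) and score association with the class
label without reference to any classifier.  Mutual information is the
plug-in estimate in bits.  The JMI ranking is greedy-forward: the first
feature maximises I(f; Y); each subsequent pick maximises
J(f) = sum over already-selected s of I((f, s); Y), the mutual information
between the jointly discretized pair and the label.  Ties are broken by the
candidate's position in the input column order, making rankings fully
deterministic and row-permutation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES

__all__ = [
    "DiscretizationConfig",
    "RankingResult",
    "discretize",
    "mutual_information",
    "chi2_statistic",
    "rank_ig",
    "rank_chi2",
    "rank_jmi",
]


@dataclass
class DiscretizationConfig:
    n_bins: int = 10
    strategy: str = "equal-frequency"   # or "equal-width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy not in ("equal-frequency", "equal-width"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class RankingResult:
    """An ordered permutation of feature names with per-feature scores."""

    criterion: str                      # "IG" | "JMI" | "CHI2"
    names: list[str]
    scores: list[float]
    trace: list[dict] = field(default_factory=list)   # JMI greedy trace

    def top(self, m: int) -> list[str]:
        return self.names[:m]


def discretize(values: np.ndarray, cfg: DiscretizationConfig | None = None) -> np.ndarray:
    """Map continuous values to integer bins in ``[0, n_bins)``.

    Equal-frequency binning places edges at empirical quantiles (duplicate
    edges merged); a constant feature collapses to a single bin.  The
    mapping is monotone in the values.
    """
    cfg = cfg or DiscretizationConfig()
    v = np.asarray(values, dtype=float)
    if cfg.strategy == "equal-frequency":
        qs = np.linspace(0, 1, cfg.n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(v, qs))
    else:
        lo, hi = v.min(), v.max()
        edges = np.unique(np.linspace(lo, hi, cfg.n_bins + 1)[1:-1]) if hi > lo else np.array([])
    # side='left': a value equal to an inner edge falls in the lower bin,
    # so a constant feature collapses to bin 0
    return np.searchsorted(edges, v, side="left").astype(np.int64)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ai = np.unique(a, return_inverse=True)[1]
    bi = np.unique(b, return_inverse=True)[1]
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    return table


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information I(A; B) in bits; empty cells contribute 0."""
    table = _contingency(a, b)
    n = table.sum()
    pab = table / n
    pa = pab.sum(axis=1, keepdims=True)
    pb = pab.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pab * np.log2(pab / (pa * pb))
    return float(np.nansum(terms))


def chi2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson chi-squared of the A x B contingency table, no correction."""
    table = _contingency(a, b)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def _feature_matrix(
    features: pd.DataFrame, cfg: DiscretizationConfig
) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = [c for c in features.columns if c in FEATURE_NAMES] or [
        c for c in features.columns if c != "label"
    ]
    if "label" not in features.columns:
        raise ValueError("feature table lacks a 'label' column")
    y = features["label"].to_numpy()
    binned = np.stack([discretize(features[c].to_numpy(), cfg) for c in names])
    return names, binned, y


def _sorted_result(criterion: str, names: list[str], scores: np.ndarray) -> RankingResult:
    # stable sort on descending score; ties keep canonical (input) order
    order = np.argsort(-scores, kind="stable")
    return RankingResult(
        criterion=criterion,
        names=[names[i] for i in order],
        scores=[float(scores[i]) for i in order],
    )


def rank_ig(features: pd.DataFrame, cfg: DiscretizationConfig | None = None) -> RankingResult:
    """Rank by information gain: I(discretized feature; label), descending."""
    cfg = cfg or DiscretizationConfig()
    names, binned, y = _feature_matrix(features, cfg)
    scores = np.array([mutual_information(row, y) for row in binned])
    return _sorted_result("IG", names, scores)


def rank_chi2(features: pd.DataFrame, cfg: DiscretizationConfig | None = None) -> RankingResult:
    """Rank by the Pearson chi-squared statistic of bins x classes, descending."""
    cfg = cfg or DiscretizationConfig()
    names, binned, y = _feature_matrix(features, cfg)
    scores = np.array([chi2_statistic(row, y) for row in binned])
    return _sorted_result("CHI2", names, scores)


def rank_jmi(
    features: pd.DataFrame,
    cfg: DiscretizationConfig | None = None,
    exhaustive_oracle: bool = False,
) -> RankingResult:
    """Greedy-forward JMI ranking; returns the full permutation with a trace.

    ``exhaustive_oracle`` switches to a deliberately simple per-pair loop
    intended for cross-checking on small instances; it refuses more than
    25 features.
    """
    cfg = cfg or DiscretizationConfig()
    names, binned, y = _feature_matrix(features, cfg)
    n_feat = len(names)
    if exhaustive_oracle and n_feat > 25:
        raise ValueError("exhaustive oracle mode is limited to <= 25 features")

    mi_single = np.array([mutual_information(row, y) for row in binned])
    selected: list[int] = []
    objectives: list[float] = []
    remaining = list(range(n_feat))
    trace: list[dict] = []

    first = int(np.argmax(mi_single))   # argmax keeps lowest index on ties
    selected.append(first)
    objectives.append(float(mi_single[first]))
    remaining.remove(first)
    trace.append({"step": 1, "picked": names[first], "objective": float(mi_single[first])})

    n_bins_of = binned.max(axis=1) + 1
    while remaining:
        best_j, best_idx = -np.inf, None
        for idx in remaining:
            j = 0.0
            for s in selected:
                joint = binned[idx] * n_bins_of[s] + binned[s]
                j += mutual_information(joint, y)
            if j > best_j:
                best_j, best_idx = j, idx
        selected.append(best_idx)
        objectives.append(float(best_j))
        remaining.remove(best_idx)
        trace.append(
            {"step": len(selected), "picked": names[best_idx], "objective": float(best_j)}
        )

    return RankingResult(
        criterion="JMI",
        names=[names[i] for i in selected],
        scores=objectives,
        trace=trace,
    )
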