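"""Subject-level classification protocol.

Samples are (trial, channel) feature rows; all splitting is at the subject
level so channels of one subject never straddle a train/test boundary.  The
protocol is: a random 13/5 subject split, leave-one-subject-out CV over the
training subjects for hyperparameter selection, refit on all training rows,
and per-validation-subject accuracy (correct/total) averaged across the
held-out subjects.  Accuracy-vs-top-m curves re-run the whole selection for
every feature-subset size m.

Classifiers: LDA, K-NN (K = 1..20, Euclidean), and SVMs with linear, RBF
(C in {0.1, 1, 10, 100}, gamma in {0.001, 0.01, 0.1, 1}) and cubic
polynomial kernels, all multiclass one-vs-one.  Features are z-scored with
statistics fitted on the training side of each fold only.  Hyperparameter
ties go to the simplest model (smallest K, then C, then gamma).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import FEATURE_NAMES, TIME_FEATURES, FREQ_FEATURES, WAVELET_FEATURES
from .selection import RankingResult

__all__ = [
    "SplitPlan",
    "ModelSpec",
    "default_model_specs",
    "make_split",
    "losocv_select",
    "fit_predict",
    "accuracy_curve",
    "domain_baselines",
    "permutation_null",
    "plot_accuracy_curves",
]


@dataclass
class SplitPlan:
    train_subjects: list
    val_subjects: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.val_subjects):
            raise ValueError("train and validation subject sets overlap")


def make_split(subject_ids: list, n_train: int, n_val: int, seed: int) -> SplitPlan:
    """Uniformly random disjoint subject split; deterministic given seed."""
    subject_ids = list(subject_ids)
    if n_train + n_val != len(subject_ids):
        raise ValueError(
            f"n_train + n_val = {n_train + n_val} must equal the "
            f"{len(subject_ids)} available subjects"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    train = [subject_ids[i] for i in sorted(order[:n_train])]
    val = [subject_ids[i] for i in sorted(order[n_train:])]
    return SplitPlan(train_subjects=train, val_subjects=val, seed=seed)


# --------------------------------------------------------------------------
# Model specifications
# --------------------------------------------------------------------------

_SVM_C = (0.1, 1.0, 10.0, 100.0)
_SVM_GAMMA = (0.001, 0.01, 0.1, 1.0)


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    kind: str                              # LDA | KNN | SVM_LINEAR | SVM_RBF | SVM_POLY
    grid: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = {
            "LDA": {},
            "KNN": {"n_neighbors": tuple(range(1, 21))},
            "SVM_LINEAR": {"C": _SVM_C},
            "SVM_RBF": {"C": _SVM_C, "gamma": _SVM_GAMMA},
            "SVM_POLY": {"C": _SVM_C},
        }
        if self.kind not in defaults:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        merged = dict(defaults[self.kind])
        merged.update(self.grid)
        self.grid = merged
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grids must be non-empty")

    def combinations(self) -> list[dict]:
        """Grid points ordered simplest-first (ascending in every axis)."""
        if not self.grid:
            return [{}]
        keys = sorted(self.grid)              # C before gamma, deterministic
        values = [sorted(self.grid[k]) for k in keys]
        return [dict(zip(keys, combo)) for combo in itertools.product(*values)]

    def build(self, hp: dict):
        if self.kind == "LDA":
            return LinearDiscriminantAnalysis()
        if self.kind == "KNN":
            return KNeighborsClassifier(metric="euclidean", **hp)
        if self.kind == "SVM_LINEAR":
            return SVC(kernel="linear", **hp)
        if self.kind == "SVM_RBF":
            return SVC(kernel="rbf", **hp)
        if self.kind == "SVM_POLY":
            return SVC(kernel="poly", degree=3, gamma="scale", **hp)
        raise ValueError(self.kind)


def default_model_specs() -> list[ModelSpec]:
    return [
        ModelSpec("LDA"),
        ModelSpec("KNN"),
        ModelSpec("SVM_LINEAR"),
        ModelSpec("SVM_RBF"),
        ModelSpec("SVM_POLY"),
    ]


# --------------------------------------------------------------------------
# Fitting machinery
# --------------------------------------------------------------------------

def _xy(table: pd.DataFrame, feature_names: list[str]):
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    return X, y


def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def losocv_select(
    train_table: pd.DataFrame,
    spec: ModelSpec,
    feature_names: list[str],
) -> tuple[dict, float, pd.DataFrame]:
    """Leave-one-subject-out grid search over the training subjects.

    Returns ``(best_hp, best_cv_accuracy_pct, grid_table)``; ties are
    resolved toward the simplest hyperparameters.  Folds whose training side
    lacks one of the classes are skipped with a warning.
    """
    subjects = sorted(train_table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO CV needs at least 2 training subjects")
    all_classes = np.unique(train_table["label"].to_numpy())

    folds = []
    for held in subjects:
        tr = train_table[train_table["subject"] != held]
        te = train_table[train_table["subject"] == held]
        if len(np.unique(tr["label"])) < len(all_classes):
            warnings.warn(
                f"LOSO fold holding out {held!r}: training side lacks a class; skipped"
            )
            continue
        Xtr, ytr = _xy(tr, feature_names)
        Xte, yte = _xy(te, feature_names)
        mu, sd = _zscore_fit(Xtr)
        folds.append(((Xtr - mu) / sd, ytr, (Xte - mu) / sd, yte))

    min_fold_rows = min(len(f[1]) for f in folds) if folds else 0
    rows = []
    best_hp, best_acc = None, -np.inf
    for hp in spec.combinations():
        if hp.get("n_neighbors", 0) > min_fold_rows:
            continue   # K larger than the smallest fold is infeasible
        accs = []
        for Xtr, ytr, Xte, yte in folds:
            model = spec.build(hp).fit(Xtr, ytr)
            accs.append(float(np.mean(model.predict(Xte) == yte)))
        acc = 100.0 * float(np.mean(accs)) if accs else np.nan
        rows.append({**hp, "cv_accuracy_pct": acc})
        if acc > best_acc:                      # strict >: simplest-first wins ties
            best_acc, best_hp = acc, hp
    if best_hp is None:
        raise ValueError("no feasible hyperparameter combination for this grid")
    return best_hp, float(best_acc), pd.DataFrame(rows)


def fit_predict(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    spec: ModelSpec,
    hp: dict,
    feature_names: list[str],
) -> dict:
    """Refit on all training rows and score each test subject separately.

    Returns a dict with ``mean_accuracy_pct`` (mean of per-subject
    accuracies), ``per_subject`` and the raw predictions.
    """
    Xtr, ytr = _xy(train_table, feature_names)
    Xte, yte = _xy(test_table, feature_names)
    mu, sd = _zscore_fit(Xtr)
    model = spec.build(hp).fit((Xtr - mu) / sd, ytr)
    pred = model.predict((Xte - mu) / sd)

    per_subject = {}
    for subj in sorted(test_table["subject"].unique()):
        mask = (test_table["subject"] == subj).to_numpy()
        per_subject[subj] = 100.0 * float(np.mean(pred[mask] == yte[mask]))
    return {
        "mean_accuracy_pct": float(np.mean(list(per_subject.values()))),
        "per_subject": per_subject,
        "predictions": pred,
    }


def _split_tables(table: pd.DataFrame, split: SplitPlan):
    train = table[table["subject"].isin(split.train_subjects)]
    val = table[table["subject"].isin(split.val_subjects)]
    if not len(train) or not len(val):
        raise ValueError("split leaves an empty train or validation side")
    return train, val


def accuracy_curve(
    table: pd.DataFrame,
    split: SplitPlan,
    ranking: RankingResult,
    spec: ModelSpec,
    m_values: list[int] | None = None,
) -> pd.DataFrame:
    """Validation accuracy as a function of the top-m ranked features.

    For each m the full protocol is re-run: LOSO hyperparameter selection on
    the training subjects using only the top-m features, refit, and
    per-subject validation accuracy.  ``m_values`` defaults to 1..(all).
    """
    train, val = _split_tables(table, split)
    if m_values is None:
        m_values = list(range(1, len(ranking.names) + 1))
    rows = []
    for m in m_values:
        names = ranking.top(m)
        hp, cv_acc, _ = losocv_select(train, spec, names)
        res = fit_predict(train, val, spec, hp, names)
        rows.append(
            {
                "criterion": ranking.criterion,
                "classifier": spec.kind,
                "m": m,
                "accuracy_pct": res["mean_accuracy_pct"],
                "cv_accuracy_pct": cv_acc,
                "hyperparameters": hp,
                "per_subject": res["per_subject"],
            }
        )
    return pd.DataFrame(rows)


DOMAIN_GROUPS = {
    "time": TIME_FEATURES,
    "frequency": FREQ_FEATURES,
    "wavelet": WAVELET_FEATURES,
    "all": FEATURE_NAMES,
}


def domain_baselines(
    table: pd.DataFrame,
    split: SplitPlan,
    specs: list[ModelSpec],
) -> pd.DataFrame:
    """No-selection accuracies on the fixed time/frequency/wavelet/all groups."""
    train, val = _split_tables(table, split)
    rows = []
    for spec in specs:
        for domain, names in DOMAIN_GROUPS.items():
            hp, cv_acc, _ = losocv_select(train, spec, names)
            res = fit_predict(train, val, spec, hp, names)
            rows.append(
                {
                    "classifier": spec.kind,
                    "domain": domain,
                    "n_features": len(names),
                    "accuracy_pct": res["mean_accuracy_pct"],
                    "cv_accuracy_pct": cv_acc,
                    "hyperparameters": hp,
                }
            )
    return pd.DataFrame(rows)


def permutation_null(
    table: pd.DataFrame,
    split: SplitPlan,
    spec: ModelSpec,
    hp: dict,
    feature_names: list[str],
    n_permutations: int = 5,
    seed: int = 0,
) -> list[float]:
    """Chance-level control: accuracies after permuting all labels.

    Labels are permuted across the whole table (train and validation alike)
    before the standard fit/validate pass; with four balanced classes the
    expected accuracy is 25%.
    """
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_permutations):
        shuffled = table.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        train, val = _split_tables(shuffled, split)
        res = fit_predict(train, val, spec, hp, feature_names)
        accs.append(res["mean_accuracy_pct"])
    return accs


def plot_accuracy_curves(curves: pd.DataFrame, path) -> None:
    """Accuracy-vs-m line plot, one line per (criterion, classifier)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for (crit, clf), grp in curves.groupby(["criterion", "classifier"]):
        grp = grp.sort_values("m")
        ax.plot(grp["m"], grp["accuracy_pct"], marker="o", label=f"{crit} / {clf}")
    ax.set_xlabel("top-m ranked features")
    ax.set_ylabel("validation accuracy (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
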