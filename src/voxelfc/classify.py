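"""Repeated hold-out classification of the two cohorts.

The reference protocol is a soft-margin linear SVM (C=1) evaluated on many
random stratified 80/20 train/test splits; accuracy, sensitivity and
specificity are averaged over splits.  Feature sets or algorithms compared
against each other always share the exact same split sequence so the
comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import AlignmentError, ConfigurationError, ParameterError, SampleSizeError

__all__ = [
    "EvalProtocol",
    "ClassificationReport",
    "PairedComparison",
    "evaluate",
    "compare_feature_sets",
    "compare_classifiers",
    "ALGORITHMS",
]

_SEED_MOD = 2**31

METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated hold-out evaluation settings (defaults follow the reference
    protocol: 80/20 stratified splits ×1000, linear SVM with C=1)."""

    train_fraction: float = 0.8
    n_runs: int = 1000
    svm_c: float = 1.0
    kernel: str = "linear"  # linear | gaussian
    stratified: bool = True
    base_seed: int = 0
    positive_label: str | None = None  # cohort treated as "patient"
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        if self.svm_c <= 0:
            raise ParameterError("svm_c must be positive")
        if self.kernel not in ("linear", "gaussian"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")


@dataclass
class ClassificationReport:
    """Per-run and aggregate hold-out metrics for one feature set."""

    feature_label: str
    protocol: EvalProtocol
    per_run: pd.DataFrame  # accuracy, sensitivity, specificity, tp, tn, fp, fn
    summary: pd.DataFrame = field(init=False)  # mean/std per metric

    def __post_init__(self) -> None:
        agg = {}
        for m in METRICS:
            vals = self.per_run[m].to_numpy(dtype=float)
            agg[m] = {
                "mean": float(np.nanmean(vals)),
                "std": float(np.nanstd(vals)),
                "n_defined": int(np.sum(np.isfinite(vals))),
            }
        self.summary = pd.DataFrame(agg).T

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])


@dataclass
class PairedComparison:
    """Two reports evaluated on identical split sequences, plus the per-run
    paired metric differences (second minus first)."""

    report_a: ClassificationReport
    report_b: ClassificationReport
    differences: pd.DataFrame


def _build_estimator(name: str, protocol: EvalProtocol):
    c = protocol.svm_c
    factories = {
        "linear_svm": lambda: SVC(kernel="linear", C=c),
        "gaussian_svm": lambda: SVC(kernel="rbf", C=c, gamma="scale"),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=0),
        "linear_discriminant": lambda: LinearDiscriminantAnalysis(),
        "logistic_regression": lambda: LogisticRegression(max_iter=1000),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
    }
    if name not in factories:
        raise ConfigurationError(
            f"unknown algorithm {name!r}; choose from {sorted(factories)}"
        )
    return factories[name]()


ALGORITHMS = (
    "decision_tree",
    "linear_discriminant",
    "logistic_regression",
    "knn",
    "gaussian_svm",
    "linear_svm",
)


def make_splits(labels: np.ndarray, protocol: EvalProtocol) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic train/test index sequence; run r uses seed
    ``base_seed + r``.  Shared across feature sets for paired comparisons."""
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    strat = labels if protocol.stratified else None
    splits = []
    for r in range(protocol.n_runs):
        seed = (int(protocol.base_seed) + r) % _SEED_MOD
        train, test = train_test_split(
            idx,
            train_size=protocol.train_fraction,
            random_state=seed,
            stratify=strat,
        )
        splits.append((train, test))
    return splits


def _run_metrics(y_true, y_pred, positive) -> dict:
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    protocol: EvalProtocol,
    *,
    algorithm: str = "linear_svm",
    feature_label: str = "features",
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ClassificationReport:
    """Repeated hold-out evaluation of one feature matrix.

    Features are z-scored with training-split statistics before fitting
    (protocol.standardize).  Metrics undefined in a run (a class absent from
    the test split, only possible without stratification) are recorded as
    NaN and excluded from that metric's aggregate.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.size:
        raise AlignmentError("features and labels have mismatched rows")
    if features.shape[1] < 1:
        raise ParameterError("need at least one feature")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise SampleSizeError("need two classes with >=2 subjects each")
    positive = protocol.positive_label if protocol.positive_label is not None else classes[-1]
    if positive not in classes:
        raise ConfigurationError(f"positive_label {positive!r} not among {classes}")
    if splits is None:
        splits = make_splits(labels, protocol)
    rows = []
    for train, test in splits:
        x_train, x_test = features[train], features[test]
        if protocol.standardize:
            scaler = StandardScaler().fit(x_train)
            # guard constant features in the training split
            scaler.scale_[scaler.scale_ == 0] = 1.0
            x_train = scaler.transform(x_train)
            x_test = scaler.transform(x_test)
        est = _build_estimator(algorithm, protocol)
        est.fit(x_train, labels[train])
        rows.append(_run_metrics(labels[test], est.predict(x_test), positive))
    per_run = pd.DataFrame(rows)
    return ClassificationReport(feature_label=feature_label, protocol=protocol,
                                per_run=per_run)


def compare_feature_sets(
    features_a: np.ndarray,
    features_b: np.ndarray,
    labels: np.ndarray,
    protocol: EvalProtocol,
    *,
    labels_ab: tuple[str, str] = ("all_fc", "dfc"),
    algorithm: str = "linear_svm",
) -> PairedComparison:
    """Evaluate two feature sets for the same subjects on identical split
    sequences; differences are per-run (B − A)."""
    features_a = np.asarray(features_a, float)
    features_b = np.asarray(features_b, float)
    if features_a.shape[0] != features_b.shape[0]:
        raise AlignmentError("feature sets have different subject counts")
    splits = make_splits(np.asarray(labels), protocol)
    rep_a = evaluate(features_a, labels, protocol, algorithm=algorithm,
                     feature_label=labels_ab[0], splits=splits)
    rep_b = evaluate(features_b, labels, protocol, algorithm=algorithm,
                     feature_label=labels_ab[1], splits=splits)
    diffs = rep_b.per_run[list(METRICS)] - rep_a.per_run[list(METRICS)]
    return PairedComparison(report_a=rep_a, report_b=rep_b, differences=diffs)


def compare_classifiers(
    features: np.ndarray,
    labels: np.ndarray,
    protocol: EvalProtocol,
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> pd.DataFrame:
    """Mean/std metrics per algorithm, all on the same paired split
    sequence."""
    splits = make_splits(np.asarray(labels), protocol)
    rows = []
    for name in algorithms:
        rep = evaluate(features, labels, protocol, algorithm=name,
                       feature_label=name, splits=splits)
        row = {"algorithm": name}
        for m in METRICS:
            row[f"{m}_mean"] = rep.summary.loc[m, "mean"]
            row[f"{m}_std"] = rep.summary.loc[m, "std"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("algorithm")


def threshold_sweep(
    zmaps_list,
    subjects,
    theta_values,
    *,
    alpha: float = 0.05,
    protocol: EvalProtocol,
    mask,
) -> pd.DataFrame:
    """Re-run activity → connectivity → selection → paired evaluation for a
    grid of activation thresholds (per-subject decompositions are reused).

    ``zmaps_list`` and ``subjects`` are aligned lists over all subjects of
    both cohorts.  θ values that leave fewer than two joint common voxels or
    an empty selection produce a row flagged degenerate; the sweep continues.
    """
    from .activity import (  # local import to avoid a cycle at module load
        group_common_voxels,
        joint_common_voxels,
        subject_active_voxels,
    )
    from .connectivity import stack_group_fc
    from .diffstats import select_dfc
    from .errors import PipelineDegenerateError

    theta_values = list(theta_values)
    if any(t <= 0 for t in theta_values) or sorted(theta_values) != theta_values:
        raise ParameterError("theta values must be positive and ascending")
    labels = np.asarray([s.group_label for s in subjects])
    groups = sorted(set(labels))
    rows = []
    for theta in theta_values:
        row = {"theta": theta, "n1": 0, "n2": 0, "n12": 0, "n_edges": 0,
               "n_dfci": 0, "degenerate": False}
        for m in METRICS:
            row[f"{m}_all_fc"] = np.nan
            row[f"{m}_dfc"] = np.nan
        try:
            avls = {g: [] for g in groups}
            for zm, s in zip(zmaps_list, subjects):
                avls[s.group_label].append(subject_active_voxels(zm, theta, mask))
            cavl1 = group_common_voxels(avls[groups[0]])
            cavl2 = group_common_voxels(avls[groups[1]])
            row["n1"], row["n2"] = cavl1.n, cavl2.n
            cavl12 = joint_common_voxels(cavl1, cavl2)
            row["n12"] = cavl12.n
            fc1 = stack_group_fc([s for s in subjects if s.group_label == groups[0]], cavl12)
            fc2 = stack_group_fc([s for s in subjects if s.group_label == groups[1]], cavl12)
            row["n_edges"] = fc1.edge_count
            result = select_dfc(fc1, fc2, alpha=alpha)
            row["n_dfci"] = int(result.dfci.size)
            all_fc = np.vstack([fc1.matrix, fc2.matrix])
            subj_labels = np.concatenate(
                [np.repeat(groups[0], fc1.n_subjects),
                 np.repeat(groups[1], fc2.n_subjects)]
            )
            if result.is_empty:
                rep = evaluate(all_fc, subj_labels, protocol,
                               feature_label="all_fc")
                for m in METRICS:
                    row[f"{m}_all_fc"] = rep.mean(m)
                row["degenerate"] = True
            else:
                dfc = np.vstack([result.dfc1, result.dfc2])
                comp = compare_feature_sets(all_fc, dfc, subj_labels, protocol)
                for m in METRICS:
                    row[f"{m}_all_fc"] = comp.report_a.mean(m)
                    row[f"{m}_dfc"] = comp.report_b.mean(m)
        except PipelineDegenerateError:
            row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows)
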