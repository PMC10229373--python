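"""Train, select, persist, and apply the organellar-DNA classifier.

Model families: a linear classifier (logistic regression), random forest,
k-nearest neighbors, and AdaBoost. Selection is by stratified k-fold
cross-validation on the training split, scored with the pooled multiclass
Matthews correlation coefficient; the winning family is refit on the whole
training split. Class imbalance (organellar contigs are a tiny minority of
real assemblies) is handled by inverse-frequency sample weights by default.

Features are standardized per column with train-set statistics stored in the
model bundle; sequence length enters as log10(length_bp) since contig
lengths span several orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.class_weight import compute_sample_weight

from .errors import InputError, SchemaError
from .features import CLASSES, COLUMNS, LabeledTable

__all__ = [
    "FAMILIES",
    "MODEL_FORMAT",
    "CVReport",
    "ModelBundle",
    "Prediction",
    "stratified_split",
    "cross_validate",
    "train_best",
    "predict",
    "save_bundle",
    "load_bundle",
    "write_predictions",
    "read_predictions",
]

FAMILIES = ("linear", "random_forest", "knn", "adaboost")

# Tie-break precedence when CV scores are equal.
_PRECEDENCE = ("adaboost", "random_forest", "linear", "knn")

MODEL_FORMAT = "orgscreen-model-v1"

# Model feature columns; length_bp is log10-transformed before scaling.
_MODEL_COLUMNS = [c for c in COLUMNS if c != "seq_id"]

DEFAULT_TEST_FRACTION = 5 / 6  # train:test = 1:5


def _make_estimator(family: str, seed: int):
    if family == "linear":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    raise InputError(f"unknown model family {family!r}; expected one of {FAMILIES}")


def _design_matrix(frame: pd.DataFrame) -> np.ndarray:
    X = frame[_MODEL_COLUMNS].to_numpy(dtype=float).copy()
    li = _MODEL_COLUMNS.index("length_bp")
    X[:, li] = np.log10(X[:, li])
    return X


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0  # constant columns pass through unscaled
    return means, sds


def _sample_weights(y: np.ndarray, weighting: str) -> np.ndarray | None:
    if weighting == "none":
        return None
    if weighting == "balanced":
        return compute_sample_weight("balanced", y)
    raise InputError(f"unknown weighting mode {weighting!r}; expected 'balanced' or 'none'")


def _fit(family: str, seed: int, X: np.ndarray, y: np.ndarray, weighting: str):
    est = _make_estimator(family, seed)
    sw = _sample_weights(y, weighting)
    if sw is not None and family != "knn":  # k-NN has no sample_weight support
        est.fit(X, y, sample_weight=sw)
    else:
        est.fit(X, y)
    return est


def _ovr_mcc(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> float:
    return float(matthews_corrcoef(y_true == positive, y_pred == positive))


@dataclass
class CVReport:
    """Per-family cross-validation scores: pooled multiclass MCC per fold plus
    one-vs-rest MCC per organellar class, averaged over folds."""

    k: int
    seed: int
    fold_mcc: dict[str, list[float]] = field(default_factory=dict)
    mean_mcc: dict[str, float] = field(default_factory=dict)
    ovr_mean_mcc: dict[str, dict[str, float]] = field(default_factory=dict)

    def best_family(self) -> str:
        if not self.mean_mcc:
            raise InputError("empty CV report")
        return min(self.mean_mcc, key=lambda f: (-self.mean_mcc[f], _PRECEDENCE.index(f)))

    def to_text(self) -> str:
        lines = [f"cross-validation: {self.k} folds, seed {self.seed}"]
        for fam in sorted(self.mean_mcc, key=lambda f: -self.mean_mcc[f]):
            folds = " ".join(f"{v:.3f}" for v in self.fold_mcc[fam])
            ovr = " ".join(f"{cls}={v:.3f}" for cls, v in self.ovr_mean_mcc[fam].items())
            lines.append(f"{fam:<14} mean MCC {self.mean_mcc[fam]:.4f}  [{folds}]  ovr: {ovr}")
        lines.append(f"best family: {self.best_family()}")
        return "\n".join(lines)


@dataclass
class ModelBundle:
    """A fitted classifier plus the exact feature schema it expects."""

    model_family: str
    estimator: object
    feature_columns: list[str]
    scale_means: np.ndarray
    scale_sds: np.ndarray
    class_labels: tuple[str, ...]
    training_seed: int
    cv_report: CVReport | None = None


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    predicted_class: str
    class_scores: dict[str, float]


def _require_labels(table: LabeledTable, op: str) -> np.ndarray:
    if table.labels is None:
        raise InputError(f"{op} requires a labeled table")
    return table.label_array()


def stratified_split(
    table: LabeledTable, test_fraction: float = DEFAULT_TEST_FRACTION, seed: int = 0
) -> tuple[LabeledTable, LabeledTable]:
    """Disjoint, exhaustive, class-stratified train/test split (default train:test 1:5)."""
    y = _require_labels(table, "stratified_split")
    classes, counts = np.unique(y, return_counts=True)
    small = [f"{c} ({n})" for c, n in zip(classes, counts) if n < 2]
    if small:
        raise InputError(
            "every class needs >= 2 members to stratify; too small: "
            + ", ".join(small)
            + " — consider pooling assemblies or the class-weighting option"
        )
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(idx, test_size=test_fraction, random_state=seed, stratify=y)
    train_idx.sort()
    test_idx.sort()

    def subset(rows: np.ndarray) -> LabeledTable:
        frame = table.frame.iloc[rows].reset_index(drop=True)
        labels = {s: table.labels[s] for s in frame["seq_id"]}
        return LabeledTable(frame=frame, labels=labels, schema_version=table.schema_version)

    return subset(train_idx), subset(test_idx)


def cross_validate(
    train: LabeledTable,
    families: tuple[str, ...] = FAMILIES,
    k: int = 10,
    seed: int = 0,
    weighting: str = "balanced",
) -> CVReport:
    """Stratified k-fold CV of each model family on the training split.

    If the smallest class has fewer than k members, k is lowered to that
    count with a warning. Scores are the pooled multiclass MCC per fold and
    the fold-averaged one-vs-rest MCC for each organellar class.
    """
    if not families:
        raise InputError("no model families given")
    for fam in families:
        _make_estimator(fam, 0)  # validate names early
    y = _require_labels(train, "cross_validate")
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < 2:
        raise InputError("cross-validation needs >= 2 members in every class")
    if min_class < k:
        warnings.warn(f"minority class has {min_class} members; lowering k from {k} to {min_class}")
        k = min_class
    if k < 2:
        raise InputError("k must be >= 2")

    X = _design_matrix(train.frame)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = CVReport(k=k, seed=seed)
    organellar = [c for c in CLASSES if c != "nuclear" and c in set(y)]

    for fam in families:
        fold_scores: list[float] = []
        ovr_scores: dict[str, list[float]] = {c: [] for c in organellar}
        for tr, te in skf.split(X, y):
            means, sds = _fit_scaler(X[tr])
            Xtr = (X[tr] - means) / sds
            Xte = (X[te] - means) / sds
            est = _fit(fam, seed, Xtr, y[tr], weighting)
            pred = est.predict(Xte)
            fold_scores.append(float(matthews_corrcoef(y[te], pred)))
            for cls in organellar:
                ovr_scores[cls].append(_ovr_mcc(y[te], pred, cls))
        report.fold_mcc[fam] = fold_scores
        report.mean_mcc[fam] = float(np.mean(fold_scores))
        report.ovr_mean_mcc[fam] = {c: float(np.mean(v)) for c, v in ovr_scores.items()}
    return report


def train_best(
    train: LabeledTable, cv_report: CVReport, seed: int = 0, weighting: str = "balanced"
) -> ModelBundle:
    """Refit the family with the highest pooled CV MCC on all of the training split.

    Ties go to the fixed precedence order adaboost > random_forest > linear > knn.
    """
    family = cv_report.best_family()
    y = _require_labels(train, "train_best")
    X = _design_matrix(train.frame)
    means, sds = _fit_scaler(X)
    est = _fit(family, seed, (X - means) / sds, y, weighting)
    present = tuple(c for c in CLASSES if c in set(y))
    return ModelBundle(
        model_family=family,
        estimator=est,
        feature_columns=list(_MODEL_COLUMNS),
        scale_means=means,
        scale_sds=sds,
        class_labels=present,
        training_seed=seed,
        cv_report=cv_report,
    )


def predict(bundle: ModelBundle, table: LabeledTable) -> list[Prediction]:
    """Apply a trained bundle to a feature table; one Prediction per row."""
    missing = [c for c in bundle.feature_columns if c not in table.frame.columns]
    extra = [c for c in table.frame.columns if c not in bundle.feature_columns and c != "seq_id"]
    if missing or extra:
        raise SchemaError(f"feature schema mismatch; missing: {missing}, extra: {extra}")
    if len(table) == 0:
        return []
    X = (_design_matrix(table.frame) - bundle.scale_means) / bundle.scale_sds
    proba = bundle.estimator.predict_proba(X)
    est_classes = list(bundle.estimator.classes_)
    order = [est_classes.index(c) for c in bundle.class_labels]
    proba = proba[:, order]

    out: list[Prediction] = []
    for sid, row in zip(table.seq_ids, proba):
        total = row.sum()
        scores = row / total if total > 0 else np.full(len(row), 1.0 / len(row))
        # argmax over the fixed class order breaks ties toward the first class
        winner = bundle.class_labels[int(np.argmax(scores))]
        out.append(
            Prediction(
                seq_id=sid,
                predicted_class=winner,
                class_scores={c: float(s) for c, s in zip(bundle.class_labels, scores)},
            )
        )
    return out


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a bundle as a single archive (fitted params + schema + seed + CV report)."""
    joblib.dump({"format": MODEL_FORMAT, "bundle": bundle}, path)


def load_bundle(path) -> ModelBundle:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != MODEL_FORMAT:
        raise SchemaError(f"{path}: not a {MODEL_FORMAT} archive")
    return blob["bundle"]


def write_predictions(predictions: list[Prediction], path) -> None:
    """TSV: seq_id, predicted_class, then one score column per class (0 if absent)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tpredicted_class\t" + "\t".join(f"score_{c}" for c in CLASSES) + "\n")
        for p in predictions:
            scores = "\t".join("%.17g" % p.class_scores.get(c, 0.0) for c in CLASSES)
            fh.write(f"{p.seq_id}\t{p.predicted_class}\t{scores}\n")


def read_predictions(path) -> dict[str, str]:
    """Read back a predictions TSV as seq_id -> predicted class."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["seq_id", "predicted_class"]:
            raise SchemaError(f"{path}: not a predictions TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = parts[1]
    return out
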