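"""Stacked ensemble classification and cross-validated evaluation.

Three heterogeneous base classifiers — an RBF-kernel SVM, a 150-tree random
forest, and a 32-unit single-step LSTM — are trained on the fused feature
vectors.  A meta-learner is then trained on the base classifiers' scores
over a held-out quarter of the training data (classic stacking: the meta
model never sees rows the bases trained on, and meta-instances are the
3-vectors ``z = [p_svm, p_rf, p_lstm]``).

:func:`kfold_cv` runs the whole pipeline — CSP surrogate, denoising,
handcrafted + CNN feature fusion, oversampling, stacking — under
stratified k-fold cross-validation with every supervised component fitted
inside the training fold.  Each fold records exactly which row indices each
fitted component saw, and :func:`audit_leakage` asserts those sets are
disjoint from the test fold.  A ``balance_before_split`` switch instead balances and
fits before splitting (the order some published protocols use) and is
flagged as leaking by the audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from ._nn import LSTMClassifier
from . import cnn as cnn_mod
from .balance import OversampleSpec, oversample_to_parity
from .features import FusionScaler, feature_matrix
from .io import INTERICTAL, PREICTAL, Segment
from .preprocess import FilterSpec, denoise
from .spatial import apply_surrogate, fit_csp

__all__ = [
    "EnsembleConfig",
    "PipelineConfig",
    "BaseModelSet",
    "StackedEnsemble",
    "MetricsReport",
    "CVReport",
    "fit_base",
    "stack_fit",
    "stack_predict",
    "compute_metrics",
    "kfold_cv",
    "audit_leakage",
]


@dataclass
class EnsembleConfig:
    """Base-classifier and meta-learner settings."""

    svm_c: float = 1.0
    rf_trees: int = 150
    lstm_units: int = 32
    lstm_epochs: int = 80
    meta: str = "logistic"        # {"logistic", "lstm"}
    meta_split: float = 0.25      # fraction of training data held out as D_meta
    seed: int = 0


@dataclass
class BaseModelSet:
    """The three fitted base classifiers, each scoring in [0, 1]."""

    svm: CalibratedClassifierCV
    rf: RandomForestClassifier
    lstm: LSTMClassifier

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(n, 3) matrix of base scores [p_svm, p_rf, p_lstm]."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.column_stack(
            [
                self.svm.predict_proba(x)[:, 1],
                self.rf.predict_proba(x)[:, 1],
                self.lstm.predict_proba(x),
            ]
        )


@dataclass
class StackedEnsemble:
    base: BaseModelSet
    meta: object
    split_fraction: float
    train_indices: np.ndarray   # rows (within the fitting set) the bases saw
    meta_indices: np.ndarray    # rows the meta-learner saw


@dataclass
class MetricsReport:
    """Evaluation metrics at a fixed decision threshold plus ranking AUC."""

    accuracy: float              # %
    sensitivity: float           # %  TP / (TP + FN)
    specificity: float           # %  TN / (TN + FP)
    mcc: float
    auc_roc: float | None
    fp_rate: float               # FP / (FP + TN)
    confusion: dict[str, int]    # {"tp", "fp", "tn", "fn"}
    fp_per_hour: float | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "fp_rate": self.fp_rate,
            "fp_per_hour": self.fp_per_hour,
        }
        d.update(self.confusion)
        return d


@dataclass
class FoldRecord:
    """Provenance of one CV fold for the leakage audit."""

    fold: int
    test_indices: np.ndarray
    component_train_indices: dict[str, set[int]]
    metrics: MetricsReport


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    folds: list[FoldRecord]
    balance_before_split: bool = False

    def summary(self) -> dict[str, tuple[float, float]]:
        """metric -> (mean, std) across folds."""
        out = {}
        keys = ["accuracy", "sensitivity", "specificity", "mcc", "auc_roc", "fp_rate"]
        for k in keys:
            vals = [getattr(m, k) for m in self.per_fold]
            vals = [v for v in vals if v is not None]
            if vals:
                out[k] = (float(np.mean(vals)), float(np.std(vals)))
        return out


# ---------------------------------------------------------------------------
# base classifiers & stacking (Algorithm-1 style)
# ---------------------------------------------------------------------------

def fit_base(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: EnsembleConfig | None = None,
) -> BaseModelSet:
    """Fit SVM (RBF), random forest (150 trees) and single-step LSTM."""
    config = config or EnsembleConfig()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int).ravel()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class to fit the base models")
    # RBF-kernel SVM with Platt-calibrated probability scores; the internal
    # calibration CV cannot exceed the smallest class count
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", C=config.svm_c, random_state=config.seed),
        ensemble=False,
        cv=int(min(5, counts.min())),
    ).fit(x, y)
    rf = RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=config.seed
    ).fit(x, y)
    lstm = LSTMClassifier(
        n_units=config.lstm_units, epochs=config.lstm_epochs, seed=config.seed
    ).fit(x, y)
    return BaseModelSet(svm=svm, rf=rf, lstm=lstm)


def _make_meta(config: EnsembleConfig):
    if config.meta == "logistic":
        return LogisticRegression(random_state=config.seed)
    if config.meta == "lstm":
        return LSTMClassifier(n_units=8, epochs=200, seed=config.seed)
    raise ValueError(f"unknown meta-learner {config.meta!r}")


def stack_fit(
    features: np.ndarray,
    labels: np.ndarray,
    config: EnsembleConfig | None = None,
) -> StackedEnsemble:
    """Stacking: split D into D_train/D_meta, fit bases on D_train, fit the
    meta-learner on base scores over D_meta.

    The split is stratified so both partitions contain both classes.
    """
    config = config or EnsembleConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    idx = np.arange(len(y))
    train_idx, meta_idx = train_test_split(
        idx, test_size=config.meta_split, stratify=y, random_state=config.seed
    )
    base = fit_base(x[train_idx], y[train_idx], config)
    z = base.predict_proba(x[meta_idx])
    meta = _make_meta(config)
    meta.fit(z, y[meta_idx])
    return StackedEnsemble(
        base=base,
        meta=meta,
        split_fraction=config.meta_split,
        train_indices=np.sort(train_idx),
        meta_indices=np.sort(meta_idx),
    )


def _meta_scores(meta, z: np.ndarray) -> np.ndarray:
    if hasattr(meta, "predict_proba"):
        p = meta.predict_proba(z)
        return p[:, 1] if p.ndim == 2 else p
    return np.asarray(meta.predict(z), dtype=float)


def stack_predict(
    ensemble: StackedEnsemble, x: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) of the stacked ensemble; label = score >= threshold."""
    z = ensemble.base.predict_proba(np.atleast_2d(np.asarray(x, dtype=float)))
    scores = _meta_scores(ensemble.meta, z)
    return scores, (scores >= threshold).astype(int)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _auc_trapezoid(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by trapezoidal integration over all score thresholds."""
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) + 1
    cut = np.r_[distinct, y.size]
    tps = np.cumsum(y_sorted)[cut - 1]
    fps = np.cumsum(1 - y_sorted)[cut - 1]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    interictal_hours: float | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics (in %), MCC, trapezoidal AUC and FP rates.

    The preictal class is the positive one.  With a single-class ``y_true``
    the AUC is undefined and reported as ``None`` with a warning.
    ``fp_per_hour`` = false alarms per interictal hour, when hours are
    supplied.
    """
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size or y.size == 0:
        raise ValueError("y_true and scores must be equal-length, non-empty")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = 100.0 * (tp + tn) / y.size
    sensitivity = 100.0 * tp / n_pos if n_pos else float("nan")
    specificity = 100.0 * tn / n_neg if n_neg else float("nan")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class y_true: AUC undefined, reported as missing")
        auc = None
    else:
        auc = _auc_trapezoid(y, s)
    fp_rate = fp / n_neg if n_neg else float("nan")
    fp_per_hour = fp / interictal_hours if interictal_hours else None
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=float(mcc),
        auc_roc=auc,
        fp_rate=float(fp_rate),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        fp_per_hour=fp_per_hour,
    )


# ---------------------------------------------------------------------------
# full-pipeline cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the per-fold pipeline needs, driven by one seed."""

    surrogate_mode: str = "csp"           # {"csp", "average"}
    denoise: bool = True
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    cnn_filters: tuple[int, ...] = cnn_mod.REDUCED_FILTERS
    cnn_epochs: int = 10
    oversample: OversampleSpec = field(default_factory=OversampleSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    balance_before_split: bool = False
    seed: int = 0


def _labels_to_int(segments: list[Segment]) -> np.ndarray:
    y = np.empty(len(segments), dtype=int)
    for i, s in enumerate(segments):
        if s.label == PREICTAL:
            y[i] = 1
        elif s.label == INTERICTAL:
            y[i] = 0
        else:
            raise ValueError(f"segment {i} is unlabeled; label before CV")
    return y


def _fit_fold_features(
    x_raw: np.ndarray,
    y: np.ndarray,
    fit_rows: np.ndarray,
    config: PipelineConfig,
    fs: float,
):
    """Fit CSP + CNN + scaler on ``fit_rows`` and featurize every row."""
    if config.surrogate_mode == "csp":
        model = fit_csp(
            x_raw[fit_rows][y[fit_rows] == 1], x_raw[fit_rows][y[fit_rows] == 0]
        )
        surr = np.stack([apply_surrogate(model, x_raw[i])[0] for i in range(len(y))])
    elif config.surrogate_mode == "average":
        surr = x_raw.mean(axis=1)
    else:
        raise ValueError(f"unknown surrogate_mode {config.surrogate_mode!r}")

    hand = feature_matrix(list(surr), sampling_rate=fs)

    spec = cnn_mod.build_architecture(
        in_channels=1, input_length=surr.shape[1], filters=config.cnn_filters
    )
    net, _ = cnn_mod.train(
        spec,
        surr[fit_rows][:, None, :],
        y[fit_rows],
        cnn_mod.TrainConfig(epochs=config.cnn_epochs, seed=config.seed),
    )
    cnn_feats = net.features(surr[:, None, :])
    scaler = FusionScaler().fit(hand[fit_rows], cnn_feats[fit_rows])
    fused = scaler.transform(hand, cnn_feats)
    return fused


def kfold_cv(
    segments: list[Segment],
    config: PipelineConfig | None = None,
    k: int = 5,
    interictal_hours: float | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per training fold: CSP fit, CNN training, feature standardization,
    minority oversampling, base-classifier and meta-learner training; the
    test fold only ever passes through already-fitted transforms.  With
    ``balance_before_split`` the oversampler and all feature transforms are fit on
    the full dataset before splitting (logged as leaking).
    """
    config = config or PipelineConfig()
    y = _labels_to_int(segments)
    fs = segments[0].sampling_rate
    x_raw = np.stack([s.samples for s in segments])
    if config.denoise:
        x_raw = np.stack(
            [denoise(s, config.filter_spec).samples for s in segments]
        )

    min_class = min(np.bincount(y))
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} rows; reducing k to {min_class}")
        k = int(min_class)
    if k < 2:
        raise ValueError("need k >= 2 and at least 2 rows per class")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    all_rows = np.arange(len(y))

    if config.balance_before_split:
        warnings.warn(
            "balance_before_split: oversampling and feature fitting precede the "
            "train/test split; test-fold information leaks into fitted "
            "components"
        )
        fused_all = _fit_fold_features(x_raw, y, all_rows, config, fs)
        fused_all, y_all, _ = _oversample(fused_all, y, config, parents=all_rows)
    else:
        fused_all, y_all = None, None

    per_fold: list[MetricsReport] = []
    folds: list[FoldRecord] = []
    split_y = y_all if config.balance_before_split else y
    split_x = np.zeros(len(split_y))
    for fold_i, (train_rows, test_rows) in enumerate(skf.split(split_x, split_y)):
        if config.balance_before_split:
            fused, ys = fused_all, y_all
            comp_rows: set[int] = set(all_rows.tolist())
            x_tr, y_tr = fused[train_rows], ys[train_rows]
            x_te, y_te = fused[test_rows], ys[test_rows]
        else:
            fused = _fit_fold_features(x_raw, y, train_rows, config, fs)
            x_tr, y_tr, parent_rows = _oversample(
                fused[train_rows], y[train_rows], config, parents=train_rows
            )
            x_te, y_te = fused[test_rows], y[test_rows]
            comp_rows = set(train_rows.tolist()) | parent_rows

        ens_config = EnsembleConfig(**{**vars(config.ensemble), "seed": config.seed + fold_i})
        ensemble = stack_fit(x_tr, y_tr, ens_config)
        scores, _ = stack_predict(ensemble, x_te)
        m = compute_metrics(
            y_te, scores, interictal_hours=interictal_hours
        )
        per_fold.append(m)
        folds.append(
            FoldRecord(
                fold=fold_i,
                test_indices=np.sort(test_rows),
                component_train_indices={
                    "csp": comp_rows,
                    "cnn": comp_rows,
                    "scaler": comp_rows,
                    "oversampler": comp_rows,
                    "base": comp_rows,
                    "meta": comp_rows,
                },
                metrics=m,
            )
        )
    return CVReport(per_fold=per_fold, folds=folds, balance_before_split=config.balance_before_split)


def _oversample(x: np.ndarray, y: np.ndarray, config: PipelineConfig,
                parents: np.ndarray):
    """Balance classes by synthesizing minority rows; returns augmented set
    plus the set of parent row indices the oversampler consumed."""
    spec = OversampleSpec(**{**vars(config.oversample), "seed": config.seed})
    x_aug, y_aug = oversample_to_parity(x, y, spec)
    return x_aug, y_aug, set(parents.tolist())


def audit_leakage(report: CVReport) -> None:
    """Assert no fitted component's training rows intersect its test fold.

    Raises ``AssertionError`` naming the fold and component on violation.
    ``balance_before_split`` reports are expected to fail this audit.
    """
    for rec in report.folds:
        test = set(rec.test_indices.tolist())
        for name, rows in rec.component_train_indices.items():
            inter = rows & test
            assert not inter, (
                f"fold {rec.fold}: component {name!r} trained on "
                f"{len(inter)} test rows (e.g. {sorted(inter)[:5]})"
            )
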