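"""Decoder training, evaluation metrics, the 9-strategy grid and rm-ANOVA.

A decoder is CSP (fitted on training trials only — no leakage into the test
set) followed by one of three classifiers on the normalized log-variance
features: LDA (shared within-class covariance), a linear-kernel SVM with
cross-validated cost, or a one-hidden-layer backpropagation network (BPNN)
with a cross-validated hidden width. Hyperparameters are chosen by
stratified 10-fold cross-validation inside the training set and the final
model is refit on all training trials.

Evaluation reports the 2×2 confusion matrix plus, per class treated as
positive: precision = TP/(TP+FP), recall = TP/(TP+FN) and
F = 2·precision·recall/(precision+recall), all on the percent scale.

The strategy grid crosses the three classifiers with three train-test
ratios (50/50, 60/40, 80/20) across sessions; the two-way within-subjects
ANOVA uses the textbook repeated-measures sums-of-squares decomposition
with subject × factor interactions as error terms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .csp import CSPModel, features_from_epochs, fit_csp

CLASSIFIER_KINDS = ("LDA", "SVM", "BPNN")
#: complexity ranking used to break strategy-grid ties (smaller model wins)
_MODEL_RANK = {"LDA": 0, "SVM": 1, "BPNN": 2}
DEFAULT_SVM_COSTS = (0.1, 1.0, 10.0)
DEFAULT_BPNN_WIDTHS = (5, 10, 20)


@dataclass(frozen=True)
class SplitPlan:
    """Train-test ratio, CV folds and seed of one classification strategy."""

    train_fraction: float = 0.8
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0
    allowed_fractions: tuple[float, ...] = (0.5, 0.6, 0.8)

    def __post_init__(self) -> None:
        if self.train_fraction not in self.allowed_fractions:
            raise ValueError(
                f"train_fraction {self.train_fraction} not in {self.allowed_fractions}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def split(
    x: np.ndarray, y: np.ndarray, plan: SplitPlan
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified deterministic split: returns (x_train, y_train, x_test, y_test).

    Per class, ``floor(train_fraction * n_class)`` trials go to training
    (documented floor rounding on odd counts).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(plan.seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
        perm = rng.permutation(idx)
        n_train = int(np.floor(plan.train_fraction * len(idx)))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return x[tr], y[tr], x[te], y[te]


@dataclass
class MetricsReport:
    """Confusion matrix (rows = true, cols = predicted) with percent metrics."""

    confusion: np.ndarray
    classes: tuple[str, str]
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f_scores: dict[str, float]
    n_test: int
    degenerate_precision: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_scores": self.f_scores,
            "n_test": self.n_test,
            "degenerate_precision": self.degenerate_precision,
        }


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_confusion(confusion: np.ndarray, classes: tuple[str, str]) -> MetricsReport:
    """Accuracy / per-class precision, recall, F-score (percent) from counts."""
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2):
        raise ValueError("confusion matrix must be 2×2")
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * np.trace(cm) / total
    precision, recall, fs = {}, {}, {}
    degenerate = []
    for k, cls in enumerate(classes):
        tp = cm[k, k]
        fp = cm[1 - k, k]
        fn = cm[k, 1 - k]
        if tp + fp == 0:
            precision[cls] = 0.0  # 0/0 convention: no positive predictions
            degenerate.append(cls)
        else:
            precision[cls] = 100.0 * tp / (tp + fp)
        recall[cls] = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
        fs[cls] = f_score(precision[cls], recall[cls])
    return MetricsReport(
        confusion=cm.astype(int),
        classes=tuple(classes),
        accuracy=float(accuracy),
        precision=precision,
        recall=recall,
        f_scores=fs,
        n_test=int(total),
        degenerate_precision=degenerate,
    )


def _extract_params(kind: str, clf) -> dict:
    """Serialize the decision function to plain arrays (JSON-safe)."""
    if kind == "LDA":
        return {"w": clf.coef_.ravel().tolist(), "b": float(clf.intercept_[0])}
    if kind == "SVM":
        w = (clf.dual_coef_ @ clf.support_vectors_).ravel()
        return {"w": w.tolist(), "b": float(clf.intercept_[0])}
    if kind == "BPNN":
        return {
            "coefs": [c.tolist() for c in clf.coefs_],
            "intercepts": [c.tolist() for c in clf.intercepts_],
            "activation": clf.activation,
        }
    raise ValueError(f"unknown classifier kind {kind!r}")


def _decision_values(kind: str, params: dict, feats: np.ndarray) -> np.ndarray:
    """Decision function > 0 → second class (sklearn classes_[1] order)."""
    if kind in ("LDA", "SVM"):
        w = np.asarray(params["w"], dtype=float)
        return feats @ w + params["b"]
    h = feats
    coefs = [np.asarray(c, dtype=float) for c in params["coefs"]]
    intercepts = [np.asarray(c, dtype=float) for c in params["intercepts"]]
    for wmat, bvec in zip(coefs[:-1], intercepts[:-1]):
        h = h @ wmat + bvec
        if params["activation"] == "relu":
            h = np.maximum(h, 0.0)
        elif params["activation"] == "tanh":
            h = np.tanh(h)
        elif params["activation"] == "logistic":
            h = 1.0 / (1.0 + np.exp(-h))
        else:  # identity
            pass
    return (h @ coefs[-1] + intercepts[-1]).ravel()


@dataclass
class DecoderModel:
    """CSP projection + band/window + a trained binary classifier."""

    csp: CSPModel
    classifier_kind: str
    classifier_params: dict
    class_pair: tuple[str, str]
    cv_summary: dict = field(default_factory=dict)
    trained: bool = True
    seed: int = 0

    def predict_features(self, feats: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("decoder is not trained")
        dec = _decision_values(self.classifier_kind, self.classifier_params, feats)
        out = np.where(dec > 0, self.class_pair[1], self.class_pair[0])
        return out.astype(object)

    def predict(self, epochs, window_s=None) -> np.ndarray:
        feats = features_from_epochs(self.csp, epochs, window_s)
        return self.predict_features(feats)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "csp": json.loads(self.csp.to_json()),
            "classifier_kind": self.classifier_kind,
            "classifier_params": self.classifier_params,
            "class_pair": list(self.class_pair),
            "cv_summary": self.cv_summary,
            "trained": self.trained,
            "seed": self.seed,
        }
        text = json.dumps(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DecoderModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            csp=CSPModel.from_json(json.dumps(d["csp"])),
            classifier_kind=d["classifier_kind"],
            classifier_params=d["classifier_params"],
            class_pair=tuple(d["class_pair"]),
            cv_summary=d.get("cv_summary", {}),
            trained=d.get("trained", True),
            seed=d.get("seed", 0),
        )


def _make_classifier(kind: str, seed: int, **kw):
    if kind == "LDA":
        return LinearDiscriminantAnalysis()
    if kind == "SVM":
        return SVC(kernel="linear", C=kw.get("C", 1.0))
    if kind == "BPNN":
        return MLPClassifier(
            hidden_layer_sizes=(kw.get("width", 10),),
            solver="lbfgs",
            max_iter=1000,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def _cv_folds_for(y: np.ndarray, requested: int) -> int:
    """Shrink the fold count when a class is too small to stratify."""
    smallest = min(np.sum(y == c) for c in np.unique(y))
    folds = min(requested, int(smallest))
    if folds < 2:
        raise ValueError("too few trials per class for cross-validation")
    if folds < requested:
        warnings.warn(f"reducing CV folds from {requested} to {folds}")
    return folds


def train_decoder(
    train_data: np.ndarray,
    train_labels: np.ndarray,
    kind: str,
    plan: SplitPlan,
    class_pair: tuple[str, str] | None = None,
    m: int = 2,
    fs: float | None = None,
    covariance_mode: str = "segmented",
    channel_labels: tuple[str, ...] | None = None,
    band: tuple[float, float] | None = None,
    window_s: tuple[float, float] | None = None,
) -> DecoderModel:
    """Fit CSP + classifier on training trials only.

    ``train_data`` is trials × channels × samples already restricted to the
    analysis band and feature window. Hyperparameters (SVM cost, BPNN
    hidden width) are chosen by stratified k-fold CV on the training set;
    the winner is refit on all training trials.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"classifier kind must be one of {CLASSIFIER_KINDS}")
    train_labels = np.asarray(train_labels)
    if len(train_labels) < 20:
        warnings.warn("fewer than 20 training trials; estimates will be unstable")
    if class_pair is None:
        uniq = sorted(np.unique(train_labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly 2 classes, found {uniq}")
        class_pair = (uniq[0], uniq[1])

    csp = fit_csp(
        train_data,
        train_labels,
        class_pair,
        m=m,
        fs=fs,
        covariance_mode=covariance_mode,
        channel_labels=channel_labels,
        band=band,
        window_s=window_s,
    )
    feats = features_from_epochs(csp, train_data)
    y = (train_labels == class_pair[1]).astype(int)
    folds = _cv_folds_for(y, plan.cv_folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=plan.seed)

    cv_summary: dict = {"folds": folds}
    if kind == "LDA":
        clf = _make_classifier(kind, plan.seed)
        cv_summary["cv_accuracy"] = float(
            np.mean(cross_val_score(clf, feats, y, cv=cv))
        )
    elif kind == "SVM":
        scores = {
            c: float(np.mean(cross_val_score(_make_classifier(kind, plan.seed, C=c),
                                             feats, y, cv=cv)))
            for c in DEFAULT_SVM_COSTS
        }
        best = max(sorted(scores), key=lambda c: scores[c])
        clf = _make_classifier(kind, plan.seed, C=best)
        cv_summary.update({"cv_accuracy": scores[best], "C": best, "grid": scores})
    else:  # BPNN
        scores = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for w in DEFAULT_BPNN_WIDTHS:
                scores[w] = float(
                    np.mean(cross_val_score(_make_classifier(kind, plan.seed, width=w),
                                            feats, y, cv=cv))
                )
        best = max(sorted(scores), key=lambda w: scores[w])
        clf = _make_classifier(kind, plan.seed, width=best)
        cv_summary.update({"cv_accuracy": scores[best], "hidden_units": best,
                           "grid": {str(k): v for k, v in scores.items()}})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(feats, y)
    return DecoderModel(
        csp=csp,
        classifier_kind=kind,
        classifier_params=_extract_params(kind, clf),
        class_pair=class_pair,
        cv_summary=cv_summary,
        trained=True,
        seed=plan.seed,
    )


def evaluate(model: DecoderModel, test_data: np.ndarray, test_labels: np.ndarray) -> MetricsReport:
    """Confusion matrix and percent metrics of a trained decoder on test trials."""
    if not model.trained:
        raise RuntimeError("decoder is not trained")
    test_labels = np.asarray(test_labels)
    if len(test_labels) == 0:
        raise ValueError("empty test set")
    feats = features_from_epochs(model.csp, np.asarray(test_data, dtype=float))
    pred = model.predict_features(feats)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(test_labels, pred):
        cm[model.class_pair.index(t), model.class_pair.index(p)] += 1
    return metrics_from_confusion(cm, model.class_pair)


@dataclass
class StrategyGridResult:
    """Table-style accuracies of the classifier × ratio grid across sessions."""

    table: pd.DataFrame  # index S1..S9; columns: classifier, ratio, sessions..., Average
    best_strategy: str

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def cross_session_average(accuracies) -> float:
    """Cross-session average accuracy of one strategy row."""
    return float(np.mean(np.asarray(accuracies, dtype=float)))


def strategy_grid(
    sessions: dict[str, tuple[np.ndarray, np.ndarray]],
    class_pairs: dict[str, tuple[str, str]] | None = None,
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS,
    ratios: tuple[float, ...] = (0.5, 0.6, 0.8),
    seed: int = 0,
    m: int = 2,
    fs: float | None = None,
    cv_folds: int = 10,
) -> StrategyGridResult:
    """Evaluate every classifier × train-test-ratio strategy on every session.

    ``sessions`` maps a session name to its (band+window-restricted) trials
    and labels. Strategies are named S1..S9 row-wise (classifier-major, as
    in the standard grid layout). The best strategy maximizes the
    cross-session average; exact ties go to the simpler model class
    (LDA < SVM < BPNN), then to the larger training fraction.
    """
    rows = []
    names = []
    k = 0
    for kind in classifiers:
        for ratio in ratios:
            k += 1
            name = f"S{k}"
            plan = SplitPlan(train_fraction=ratio, cv_folds=cv_folds, seed=seed)
            accs = {}
            for sess, (x, y) in sessions.items():
                pair = class_pairs[sess] if class_pairs else None
                xtr, ytr, xte, yte = split(x, y, plan)
                model = train_decoder(
                    xtr, ytr, kind, plan, class_pair=pair, m=m, fs=fs
                )
                accs[sess] = evaluate(model, xte, yte).accuracy
            row = {"classifier": kind, "train_ratio": ratio, **accs}
            row["Average"] = cross_session_average(list(accs.values()))
            rows.append(row)
            names.append(name)
    table = pd.DataFrame(rows, index=names)
    best = min(
        table.index,
        key=lambda s: (
            -table.loc[s, "Average"],
            _MODEL_RANK[table.loc[s, "classifier"]],
            -table.loc[s, "train_ratio"],
        ),
    )
    return StrategyGridResult(table=table, best_strategy=best)


def rm_anova_2x2(table: np.ndarray) -> dict[str, float]:
    """Two-factor within-subjects ANOVA on a subjects × 2 × 2 accuracy table.

    Returns F and p for factor A (axis 1), factor B (axis 2) and their
    interaction. Error terms are the subject × effect interaction mean
    squares (the standard repeated-measures decomposition). A zero error
    variance with a non-zero effect yields ``F = inf, p = 0``; with a zero
    effect, ``F = 0, p = 1``.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2 or y.shape[2] != 2:
        raise ValueError("table must be subjects × 2 × 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cell in the ANOVA table")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    gm = y.mean()
    m_a = y.mean(axis=(0, 2))  # levels of A
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)  # subjects × A
    m_bs = y.mean(axis=1)

    ss_a = 2 * n * np.sum((m_a - gm) ** 2)
    ss_b = 2 * n * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = 2 * np.sum((m_as - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_abs = np.sum(resid**2)

    df_effect = 1
    df_err = n - 1

    def f_and_p(ss_eff: float, ss_err: float) -> tuple[float, float]:
        ms_eff = ss_eff / df_effect
        ms_err = ss_err / df_err
        scale = max(abs(gm) ** 2, 1.0)
        if ms_err <= 1e-14 * scale:
            return (0.0, 1.0) if ms_eff <= 1e-14 * scale else (float("inf"), 0.0)
        f = ms_eff / ms_err
        return float(f), float(stats.f.sf(f, df_effect, df_err))

    f_a, p_a = f_and_p(ss_a, ss_as)
    f_b, p_b = f_and_p(ss_b, ss_bs)
    f_ab, p_ab = f_and_p(ss_ab, ss_abs)
    return {"F_A": f_a, "p_A": p_a, "F_B": f_b, "p_B": p_b, "F_AB": f_ab, "p_AB": p_ab}
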