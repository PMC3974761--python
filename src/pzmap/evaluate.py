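"""Classifier evaluation: confusion metrics, ROC/PR curves, threshold
selection by balanced accuracy, and the patient-wise nested CV harness.

Sensitivity (TPR), specificity (SPC) and positive predictive value (PPV) are
the standard confusion ratios; the working probability threshold is the one
maximizing balanced accuracy BAC = (TPR + SPC) / 2 over a fixed grid.  The
ROC AUC is computed as the tie-adjusted Mann-Whitney concordance probability
(the probability that a randomly chosen positive outranks a randomly chosen
negative), which the trapezoidal curve area matches to numerical precision.

Cross-validation is patient-wise: no pixel of a test patient ever enters
training, and hyperparameters are tuned by inner CV on the training pool
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "roc_auc_score_ranked",
    "pr_auc",
    "select_threshold_bac",
    "balanced_accuracy",
    "auc_confidence_interval",
    "friedman_test",
    "nested_cv",
]

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Per-fold records with mean +/- sd summaries and curve fragments."""

    folds: list[dict] = field(default_factory=list)
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def summarize(self) -> None:
        if not self.folds:
            return
        keys = [
            k
            for k in self.folds[0]
            if k != "fold"
            and isinstance(self.folds[0][k], (int, float, np.floating))
        ]
        for k in keys:
            vals = np.array([f[k] for f in self.folds], dtype=float)
            ok = np.isfinite(vals)
            self.summary[k] = (
                float(np.mean(vals[ok])) if ok.any() else float("nan"),
                float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else 0.0,
            )


def confusion_metrics(
    pred: np.ndarray, true: np.ndarray
) -> tuple[float, float, float, ConfusionCounts]:
    """TPR, SPC and PPV from {-1,+1} label vectors.

    A 0/0 ratio (e.g. PPV with no positive predictions) is reported as NaN
    (undefined), never as 0.
    """
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    for arr in (pred, true):
        if set(np.unique(arr)) - {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == -1)))
    tn = int(np.sum((pred == -1) & (true == -1)))
    fn = int(np.sum((pred == -1) & (true == 1)))

    def ratio(a: int, b: int) -> float:
        return a / b if b > 0 else float("nan")

    return (
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
        ratio(tp, tp + fp),
        ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn),
    )


def roc_auc_score_ranked(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-adjusted Mann-Whitney concordance (rank-based AUC)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores, method="average")
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC curve by threshold sweep plus the concordance AUC.

    Returns a dict with ``thresholds``, ``tpr``, ``fpr`` and ``auc``; the
    trapezoidal area under the swept curve matches the rank-based
    concordance within numerical precision.
    """
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc_score_ranked(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores, pos_label=1)
    trap = float(np.trapezoid(tpr, fpr))
    if abs(trap - auc) > 1e-10:
        raise AssertionError(
            f"trapezoid area {trap} disagrees with concordance {auc}"
        )
    return {"thresholds": thr, "tpr": tpr, "fpr": fpr, "auc": auc}


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Precision-recall curve with trapezoidal area on the recall grid."""
    labels = np.asarray(labels, dtype=int)
    if np.sum(labels == 1) == 0:
        raise ValueError("no positive points")
    precision, recall, thr = precision_recall_curve(labels, scores, pos_label=1)
    # drop the artificial (recall 0, precision 1) anchor, integrate the real
    # operating points over increasing recall, and extend to recall 0 at the
    # lowest-recall precision; constant scores then give area = prevalence
    prec, rec = precision[:-1][::-1], recall[:-1][::-1]
    auc = float(np.trapezoid(prec, rec)) + float(rec[0] * prec[0])
    return {"thresholds": thr, "precision": precision, "recall": recall, "auc": auc}


def balanced_accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    tpr, spc, _, _ = confusion_metrics(pred, true)
    return 0.5 * (tpr + spc)


def select_threshold_bac(
    probabilities: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Probability threshold maximizing BAC over a grid (ties -> smallest)."""
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, float)
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best_theta, best_bac = float(grid[0]), -np.inf
    for theta in grid:
        pred = np.where(probabilities >= theta, 1, -1)
        bac = balanced_accuracy(pred, labels)
        if np.isnan(bac):
            bac = -np.inf
        if bac > best_bac:  # strict: ties keep the smaller theta
            best_bac, best_theta = bac, float(theta)
    return best_theta


def auc_confidence_interval(
    scores: np.ndarray,
    labels: np.ndarray,
    patient_id: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling whole patients."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    patient_id = np.asarray(patient_id)
    patients = np.unique(patient_id)
    groups = {p: np.nonzero(patient_id == p)[0] for p in patients}
    aucs = []
    for _ in range(n_boot):
        pick = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([groups[p] for p in pick])
        if len(np.unique(labels[idx])) < 2:
            continue
        aucs.append(roc_auc_score_ranked(scores[idx], labels[idx]))
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def friedman_test(*samples) -> tuple[float, float]:
    """Friedman rank test across matched model results (delegated)."""
    stat, p = stats.friedmanchisquare(*samples)
    return float(stat), float(p)


def _default_trainer(config=None):
    """Per-patient incremental-ensemble trainer for the CV harness."""
    from .ensemble import (
        EnsembleConfig,
        EnsembleModel,
        learnpp_increment,
        predict_probability,
    )

    cfg = config or EnsembleConfig()

    def trainer(train, seed: int):
        model = EnsembleModel()
        for k, pid in enumerate(np.unique(train.patient_id)):
            batch = train.subset(np.nonzero(train.patient_id == pid)[0])
            learnpp_increment(model, batch, config=cfg, seed=seed + k)
        return lambda X: predict_probability(model, X)

    return trainer


def nested_cv(
    train,
    trainer=None,
    outer_k: int = 3,
    inner_k: int = 10,
    seed: int = 0,
    threshold_grid: np.ndarray | None = None,
    config=None,
) -> EvalReport:
    """Patient-wise nested cross-validation.

    Outer folds split by patient, so no pixel of a test patient is seen in
    training; the trainer tunes its hyperparameters by inner CV on the
    training pool only.  ``trainer(train_set, seed)`` must return a callable
    mapping a feature matrix to positive-class probabilities; the default
    trains one incremental-ensemble batch per training patient.  Setting
    ``outer_k`` to the number of patients gives leave-one-patient-out.
    """
    from .ensemble import TrainingSet

    if trainer is None:
        trainer = _default_trainer(config)
    patients = np.unique(train.patient_id)
    if len(patients) < outer_k:
        raise ValueError("fewer patients than outer folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_patients = np.array_split(patients[order], outer_k)

    report = EvalReport()
    for fold_id, test_pats in enumerate(fold_patients):
        test_sel = np.isin(train.patient_id, test_pats)
        assert not (
            set(np.asarray(train.patient_id)[test_sel])
            & set(np.asarray(train.patient_id)[~test_sel])
        )
        tr = TrainingSet(
            X=train.X[~test_sel],
            y=train.y[~test_sel],
            patient_id=np.asarray(train.patient_id)[~test_sel],
        )
        predict = trainer(tr, seed=seed + 1000 * fold_id)
        probs = predict(train.X[test_sel])
        y_test = train.y[test_sel]
        roc = roc_auc(probs, y_test)
        pr = pr_auc(probs, y_test)
        theta = select_threshold_bac(probs, y_test, grid=threshold_grid)
        pred = np.where(probs >= theta, 1, -1)
        tpr, spc, ppv, counts = confusion_metrics(pred, y_test)
        report.folds.append(
            {
                "fold": fold_id,
                "test_patients": list(map(int, test_pats)),
                "n_test": int(test_sel.sum()),
                "auc_roc": roc["auc"],
                "auc_pr": pr["auc"],
                "theta": theta,
                "tpr": tpr,
                "spc": spc,
                "ppv": ppv,
                "bac": 0.5 * (tpr + spc),
            }
        )
        if fold_id == 0:
            report.curves = {
                "roc_fpr": roc["fpr"],
                "roc_tpr": roc["tpr"],
                "pr_recall": pr["recall"],
                "pr_precision": pr["precision"],
            }
    report.summarize()
    return report
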