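"""Incremental SVM ensemble with distribution-weighted resampling.

The training core is a boosting-style incremental ensemble: each data batch
(increment) contributes a sequence of weak hypotheses, each a soft-margin RBF
SVM trained on a resample drawn from a weight distribution that concentrates
on points the current ensemble finds hard.  A hypothesis is accepted only if
its weighted error on the whole batch is below 1/2; accepted hypotheses vote
with weight ``log(1/beta)`` where ``beta = eps / (1 - eps)`` is the
normalized error.  After each accepted iteration the composite (voted)
hypothesis is evaluated the same way and the point weights of correctly
classified points are shrunk by the composite normalized error, so the next
resample focuses on the remaining hard points.  New batches never require
access to earlier batches' data — earlier hypotheses simply keep voting —
which is what makes the scheme incremental (it learns from new data,
preserves prior knowledge, and avoids catastrophic unlearning).

Probability maps come from Platt calibration: a sigmoid
``P(y=+1 | f) = 1 / (1 + exp(A f + B))`` fitted to each hypothesis' decision
values, combined across the ensemble by a vote-weighted average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

from .evaluate import roc_auc_score_ranked

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "WeakHypothesis",
    "EnsembleModel",
    "PlattCalibration",
    "EnsembleConfig",
    "train_base_svm",
    "optimize_hyperparams",
    "remove_outliers_oneclass",
    "bootstrap_balance",
    "learnpp_increment",
    "random_subspace_increment",
    "vote",
    "fit_platt",
    "predict_probability",
    "split_batches",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrainingSet:
    """Labeled feature matrix with per-point weights and patient ids."""

    X: np.ndarray
    y: np.ndarray
    patient_id: np.ndarray | None = None
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be in {-1, +1}")
        if self.patient_id is None:
            self.patient_id = np.zeros(len(self.y), dtype=int)
        if self.w is not None and np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def distribution(self) -> np.ndarray:
        """Normalized weight distribution D = w / sum(w)."""
        w = np.ones(self.n) if self.w is None else self.w
        return w / w.sum()

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            X=self.X[idx],
            y=self.y[idx],
            patient_id=self.patient_id[idx],
            w=None if self.w is None else self.w[idx],
        )


@dataclass
class PlattCalibration:
    """Sigmoid posterior ``P(y=+1 | f) = 1 / (1 + exp(A f + B))``."""

    A: float
    B: float

    def predict(self, f: np.ndarray) -> np.ndarray:
        z = self.A * np.asarray(f, dtype=float) + self.B
        # numerically stable in both tails
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
        return out


@dataclass
class WeakHypothesis:
    """One accepted base classifier with its ensemble bookkeeping.

    ``epsilon`` is the weighted error on the full batch it was trained in;
    ``beta = epsilon / (1 - epsilon)`` its normalized error; the voting
    weight is ``log(1 / beta)``.  ``subspace`` lists the feature columns the
    model consumes.
    """

    model: SVC
    C: float
    gamma: float
    subspace: np.ndarray
    epsilon: float = np.nan
    beta: float = np.nan
    calibration: PlattCalibration | None = None
    # per-column standardization fitted on the training subset; the RBF
    # distance is meaningless across heterogeneous feature scales
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Xs = np.asarray(X, dtype=float)[:, self.subspace]
        if self.scale_mean is not None:
            Xs = (Xs - self.scale_mean) / self.scale_sd
        return Xs

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(self._transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)

    @property
    def vote_weight(self) -> float:
        # beta -> 0 for a perfect learner; floor it so the weight stays
        # finite (and dominant) instead of producing inf - inf margins
        return float(np.log(1.0 / max(self.beta, 1e-12)))


@dataclass
class EnsembleModel:
    """Accepted weak hypotheses grouped by data increment.

    ``history`` records, per accepted iteration, the weak error ``epsilon_t``,
    the composite error ``E_t`` and its normalization ``B_t``.
    """

    increments: list[list[WeakHypothesis]] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    calibration: PlattCalibration | None = None
    config: "EnsembleConfig | None" = None

    @property
    def hypotheses(self) -> list[WeakHypothesis]:
        return [h for inc in self.increments for h in inc]


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunables of the incremental training loop.

    ``T`` iterations per increment; rejected hypotheses (weighted error or
    composite error >= 1/2) are redrawn up to ``max_retries`` times;
    hyperparameters are searched once per increment by default
    (``optimize_every = "increment"``) or per iteration ("iteration"), with
    ``inner_cv_folds``-fold CV AUC as the objective.
    """

    T: int = 20
    max_retries: int = 10
    inner_cv_folds: int = 10
    optimize_every: str = "increment"  # "increment" | "iteration" | "never"
    fixed_C: float = 1.0
    fixed_gamma: float = 0.1
    min_base_train_acc: float = 0.5
    grid_log2C: tuple[int, int, int] = (-3, 10, 2)
    grid_log2gamma: tuple[int, int, int] = (-10, 3, 2)
    nm_maxiter: int = 25
    calibrate: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# base learner and hyperparameter search


def train_base_svm(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float,
    subspace: np.ndarray | None = None,
) -> WeakHypothesis:
    """Fit one soft-margin RBF SVM (kernel ``exp(-gamma ||x - x'||^2)``).

    Decision values are real-valued signed distances to the separating
    hyperplane in feature space.  Error bookkeeping fields are left unset.
    """
    y = np.asarray(y, dtype=int)
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if subspace is None:
        subspace = np.arange(np.asarray(X).shape[1])
    subspace = np.asarray(subspace, dtype=int)
    Xs = np.asarray(X, dtype=float)[:, subspace]
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns pass through centered
    model = SVC(C=C, gamma=gamma, kernel="rbf")
    model.fit((Xs - mu) / sd, y)
    return WeakHypothesis(
        model=model, C=C, gamma=gamma, subspace=subspace,
        scale_mean=mu, scale_sd=sd,
    )


def _cv_auc(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int
) -> float:
    """Stratified k-fold CV AUC of a single RBF SVM at (C, gamma)."""
    y = np.asarray(y)
    n_min = min(np.sum(y == 1), np.sum(y == -1))
    k = int(min(folds, n_min))
    if k < 2:
        raise ValueError("too few points per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        h = train_base_svm(X[tr], y[tr], C, gamma)
        scores[te] = h.decision(X[te])
    return roc_auc_score_ranked(scores, y)


def optimize_hyperparams(
    train: TrainingSet,
    config: EnsembleConfig = EnsembleConfig(),
    objective=None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing cross-validated AUC.

    A coarse log2 grid locates the starting point; a Nelder-Mead simplex
    search in (log2 C, log2 gamma) refines it.  ``objective`` may substitute
    any callable ``(C, gamma) -> score`` (used in tests with analytic
    surrogates).  Deterministic for a given seed.
    """
    seed = config.seed if seed is None else seed
    if objective is None:
        X, y = train.X, train.y

        def objective(C: float, gamma: float) -> float:
            return _cv_auc(X, y, C, gamma, config.inner_cv_folds, seed)

    lo_c, hi_c, st_c = config.grid_log2C
    lo_g, hi_g, st_g = config.grid_log2gamma
    center = ((lo_c + hi_c) / 2.0, (lo_g + hi_g) / 2.0)
    entries = []
    for lc in range(lo_c, hi_c + 1, st_c):
        for lg in range(lo_g, hi_g + 1, st_g):
            entries.append((objective(2.0**lc, 2.0**lg), lc, lg))
    best_val = max(v for v, _, _ in entries)
    # among (near-)tied grid points prefer the one closest to the grid
    # center: on a plateau extreme corners mean badly under/over-fit models
    ties = [(lc, lg) for v, lc, lg in entries if v >= best_val - 1e-12]
    best = min(
        ties, key=lambda p: (p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2
    )
    if np.ptp([v for v, _, _ in entries]) == 0:
        warnings.warn("flat hyperparameter objective; returning grid default")
        return 2.0 ** best[0], 2.0 ** best[1]

    res = minimize(
        lambda p: -objective(2.0 ** p[0], 2.0 ** p[1]),
        x0=np.array(best, dtype=float),
        method="Nelder-Mead",
        options={"maxiter": config.nm_maxiter, "xatol": 1e-3, "fatol": 1e-6},
    )
    lc, lg = res.x
    return float(2.0**lc), float(2.0**lg)


# ---------------------------------------------------------------------------
# data cleaning and balancing


def remove_outliers_oneclass(
    points: np.ndarray,
    nu: float = 0.05,
    gamma: float | str = "scale",
    min_size: int = 20,
) -> np.ndarray:
    """Indices of points kept by a one-class SVM boundary.

    Fits the one-class formulation to one class of one patient and drops
    points outside the learned support.  Below ``min_size`` points the call
    is a no-op (all indices kept) with a warning.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < min_size:
        warnings.warn("class too small for outlier removal; keeping all points")
        return np.arange(n)
    oc = OneClassSVM(nu=nu, gamma=gamma, kernel="rbf")
    flags = oc.fit_predict(points)
    return np.nonzero(flags == 1)[0]


def clean_training_set(
    train: TrainingSet, nu: float = 0.05, gamma: float | str = "scale"
) -> TrainingSet:
    """One-class outlier removal applied per class per patient."""
    keep = np.zeros(train.n, dtype=bool)
    for pid in np.unique(train.patient_id):
        for cls in (-1, 1):
            sel = np.nonzero((train.patient_id == pid) & (train.y == cls))[0]
            if sel.size == 0:
                continue
            kept = remove_outliers_oneclass(train.X[sel], nu=nu, gamma=gamma)
            keep[sel[kept]] = True
    return train.subset(np.nonzero(keep)[0])


def bootstrap_balance(train: TrainingSet, seed: int = 0) -> TrainingSet:
    """Balance class counts per patient by Monte-Carlo resampling.

    Per patient, the majority class is undersampled without replacement and
    the minority class oversampled with replacement until both sit at the
    geometric mean of the original class counts (rounded).  Already-balanced
    patients pass through unchanged.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for pid in np.unique(train.patient_id):
        psel = np.nonzero(train.patient_id == pid)[0]
        idx_pos = psel[train.y[psel] == 1]
        idx_neg = psel[train.y[psel] == -1]
        if idx_pos.size == 0 or idx_neg.size == 0:
            raise ValueError(f"patient {pid} lacks one of the classes")
        n_pos, n_neg = idx_pos.size, idx_neg.size
        if n_pos == n_neg:
            parts.append(psel)
            continue
        target = int(round(np.sqrt(n_pos * n_neg)))
        out = []
        for idx in (idx_neg, idx_pos):
            if idx.size >= target:
                out.append(rng.choice(idx, size=target, replace=False))
            else:
                out.append(rng.choice(idx, size=target, replace=True))
        parts.append(np.concatenate(out))
    all_idx = np.concatenate(parts)
    return TrainingSet(
        X=train.X[all_idx], y=train.y[all_idx], patient_id=train.patient_id[all_idx]
    )


# ---------------------------------------------------------------------------
# voting


def _vote_sums(
    hypotheses: list[WeakHypothesis], X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Summed log(1/beta) votes for +1 and -1 per row."""
    vp = np.zeros(len(X))
    vn = np.zeros(len(X))
    for h in hypotheses:
        pred = h.predict(X)
        w = h.vote_weight
        vp[pred == 1] += w
        vn[pred == -1] += w
    return vp, vn


def vote(
    model_or_hypotheses, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-majority vote over all hypotheses.

    Returns (labels, margins): the label is the class with the larger summed
    ``log(1/beta)`` vote (ties go to -1, the non-lesion class); the margin is
    the normalized vote difference in [-1, 1].
    """
    hyps = (
        model_or_hypotheses.hypotheses
        if isinstance(model_or_hypotheses, EnsembleModel)
        else list(model_or_hypotheses)
    )
    if not hyps:
        raise ValueError("model has no hypotheses")
    X = np.asarray(X, dtype=float)
    vp, vn = _vote_sums(hyps, X)
    labels = np.where(vp > vn, 1, -1)  # tie -> -1
    total = vp + vn
    with np.errstate(invalid="ignore", divide="ignore"):
        margin = np.where(total > 0, (vp - vn) / total, 0.0)
    return labels, margin


# ---------------------------------------------------------------------------
# incremental training


def _weighted_sample_without_replacement(
    rng: np.random.Generator, D: np.ndarray, size: int
) -> np.ndarray:
    return rng.choice(len(D), size=size, replace=False, p=D)


def learnpp_increment(
    model: EnsembleModel,
    S_k: TrainingSet,
    T: int | None = None,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int | None = None,
) -> EnsembleModel:
    """Train one data increment of the incremental ensemble.

    Runs up to ``T`` accepted iterations on batch ``S_k``: each iteration
    draws a training half TR_t by weighted sampling without replacement from
    the current distribution D_t, fits an RBF SVM, computes the weighted
    error ``epsilon_t`` on the entire batch (rejecting and redrawing when it
    reaches 1/2), votes all hypotheses so far into a composite hypothesis,
    computes the composite weighted error ``E_t`` (same rejection rule), and
    shrinks the weights of points the composite classifies correctly by
    ``B_t = E_t / (1 - E_t)``.  Earlier increments' data are never touched;
    their hypotheses only vote.  Modifies and returns ``model``.
    """
    T = config.T if T is None else T
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(np.unique(S_k.y)) < 2:
        raise ValueError("batch must contain both classes")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model.config = config

    m = S_k.n
    w = np.ones(m)  # uniform initial weights for this batch
    accepted: list[WeakHypothesis] = []
    C_opt: float | None = None
    gamma_opt: float | None = None
    if config.optimize_every == "never":
        C_opt, gamma_opt = config.fixed_C, config.fixed_gamma

    half = int(np.ceil(m / 2))
    t = 0
    while t < T:
        D = w / w.sum()
        assert abs(D.sum() - 1.0) < 1e-12
        hypothesis = None
        for attempt in range(config.max_retries):
            tr_idx = _weighted_sample_without_replacement(rng, D, half)
            tr = S_k.subset(tr_idx)
            if len(np.unique(tr.y)) < 2:
                continue
            if C_opt is None or config.optimize_every == "iteration":
                C_opt, gamma_opt = optimize_hyperparams(
                    tr, config=config, seed=int(rng.integers(2**31 - 1))
                )
            h = train_base_svm(tr.X, tr.y, C_opt, gamma_opt)
            if np.mean(h.predict(tr.X) == tr.y) < config.min_base_train_acc:
                continue
            pred = h.predict(S_k.X)
            eps = float(D[pred != S_k.y].sum())
            if eps >= 0.5:
                logger.info("rejected weak hypothesis with epsilon=%.3f", eps)
                continue
            h.epsilon = eps
            h.beta = eps / (1.0 - eps)
            comp_pred, _ = vote(model.hypotheses + accepted + [h], S_k.X)
            E = float(D[comp_pred != S_k.y].sum())
            if E >= 0.5:
                logger.info("rejected composite with E=%.3f", E)
                continue
            hypothesis = (h, eps, E, comp_pred)
            break
        if hypothesis is None:
            warnings.warn(
                f"retry budget exhausted at iteration {t}; "
                f"increment stops with {len(accepted)} hypotheses"
            )
            break
        h, eps, E, comp_pred = hypothesis
        B = E / (1.0 - E)
        if config.calibrate:
            h.calibration = fit_platt(h.decision(S_k.X), S_k.y)
        accepted.append(h)
        model.history.append(
            {
                "increment": len(model.increments),
                "iteration": t,
                "epsilon": eps,
                "beta": h.beta,
                "E": E,
                "B": B,
                "C": h.C,
                "gamma": h.gamma,
                "D_sum": float(D.sum()),
            }
        )
        # E = 0 means every point is correct: the uniform shrink cancels in
        # the normalization, so the distribution is simply left unchanged
        if B > 0:
            w = np.where(comp_pred == S_k.y, w * B, w)
        t += 1

    model.increments.append(accepted)
    if config.calibrate and model.hypotheses:
        _, margins = vote(model, S_k.X)
        model.calibration = fit_platt(margins, S_k.y)
    return model


def random_subspace_increment(
    model: EnsembleModel,
    S_k: TrainingSet,
    T: int | None = None,
    L: int = 5,
    r: int | None = None,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int | None = None,
) -> EnsembleModel:
    """Random-subspace variant of the incremental training loop.

    Per iteration, ``L`` feature subspaces of size ``r`` are drawn uniformly
    without replacement (within each subspace) and one base classifier is
    trained per subspace on the drawn TR_t.  The hypothesis error is the mean
    square error between the Platt-calibrated score and the {0,1}-encoded
    label, normalized to ``beta = mse / (1 - mse)``; all subspace hypotheses
    join the weighted-majority vote.
    """
    T = config.T if T is None else T
    f = S_k.X.shape[1]
    if r is None:
        r = max(1, int(round(0.5 * f)))
    if not (1 <= r <= f):
        raise ValueError("subspace size r must be in [1, n_features]")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model.config = config

    m = S_k.n
    w = np.ones(m)
    accepted: list[WeakHypothesis] = []
    C_opt = gamma_opt = None
    if config.optimize_every == "never":
        C_opt, gamma_opt = config.fixed_C, config.fixed_gamma
    half = int(np.ceil(m / 2))
    y01 = (S_k.y + 1) / 2.0

    t = 0
    while t < T:
        D = w / w.sum()
        batch = None
        for attempt in range(config.max_retries):
            tr_idx = _weighted_sample_without_replacement(rng, D, half)
            tr = S_k.subset(tr_idx)
            if len(np.unique(tr.y)) < 2:
                continue
            if C_opt is None:
                C_opt, gamma_opt = optimize_hyperparams(
                    tr, config=config, seed=int(rng.integers(2**31 - 1))
                )
            cands = []
            for _ in range(L):
                sub = np.sort(rng.choice(f, size=r, replace=False))
                h = train_base_svm(tr.X, tr.y, C_opt, gamma_opt, subspace=sub)
                h.calibration = fit_platt(h.decision(S_k.X), S_k.y)
                p = h.calibration.predict(h.decision(S_k.X))
                mse = float(np.mean((p - y01) ** 2))
                if mse >= 0.5:
                    continue
                h.epsilon = mse
                h.beta = mse / (1.0 - mse)
                cands.append(h)
            if not cands:
                continue
            comp_pred, _ = vote(model.hypotheses + accepted + cands, S_k.X)
            E = float(D[comp_pred != S_k.y].sum())
            if E >= 0.5:
                continue
            batch = (cands, E, comp_pred)
            break
        if batch is None:
            warnings.warn(
                f"retry budget exhausted at iteration {t}; "
                f"increment stops with {len(accepted)} hypotheses"
            )
            break
        cands, E, comp_pred = batch
        B = E / (1.0 - E)
        accepted.extend(cands)
        for h in cands:
            model.history.append(
                {
                    "increment": len(model.increments),
                    "iteration": t,
                    "epsilon": h.epsilon,
                    "beta": h.beta,
                    "E": E,
                    "B": B,
                    "C": h.C,
                    "gamma": h.gamma,
                }
            )
        if B > 0:
            w = np.where(comp_pred == S_k.y, w * B, w)
        t += 1

    model.increments.append(accepted)
    if config.calibrate and model.hypotheses:
        _, margins = vote(model, S_k.X)
        model.calibration = fit_platt(margins, S_k.y)
    return model


def split_batches(
    train: TrainingSet, K: int, seed: int = 0
) -> list[TrainingSet]:
    """Randomly permute and split a pooled set into K equal-sized batches."""
    if K < 1 or K > train.n:
        raise ValueError("K must be in [1, n]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train.n)
    return [train.subset(np.sort(part)) for part in np.array_split(perm, K)]


# ---------------------------------------------------------------------------
# Platt calibration and probability maps


def fit_platt(
    decision_values: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PlattCalibration:
    """Fit the sigmoid posterior to decision values by regularized MLE.

    Targets are the standard smoothed frequencies ``t+ = (N+ + 1)/(N+ + 2)``
    and ``t- = 1/(N- + 2)``; the negative log-likelihood is minimized by
    Newton iterations with backtracking line search.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))

    def nll(a: float, b: float) -> float:
        z = a * f + b
        # log(1 + e^z) - (1 - t) z   computed stably
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    fval = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        # gradient of nll wrt (A, B): sum (sigma(z) - (1 - t)) * (f, 1)
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        g = s - (1.0 - t)
        grad = np.array([np.sum(g * f), np.sum(g)])
        if np.all(np.abs(grad) < tol):
            break
        wgt = s * (1.0 - s) + 1e-12
        H = np.array(
            [
                [np.sum(wgt * f * f) + 1e-12, np.sum(wgt * f)],
                [np.sum(wgt * f), np.sum(wgt) + 1e-12],
            ]
        )
        step = np.linalg.solve(H, grad)
        # backtracking line search
        lam, improved = 1.0, False
        for _ in range(30):
            A_new, B_new = A - lam * step[0], B - lam * step[1]
            f_new = nll(A_new, B_new)
            if f_new < fval - 1e-12 * lam * grad @ step:
                A, B, fval, improved = A_new, B_new, f_new, True
                break
            lam *= 0.5
        if not improved:
            break
    else:
        raise RuntimeError("Platt calibration did not converge")
    return PlattCalibration(A=float(A), B=float(B))


def predict_probability(
    model: EnsembleModel, X: np.ndarray
) -> np.ndarray:
    """Ensemble posterior probability of the positive (lesion) class.

    The vote-weighted average of the per-hypothesis Platt probabilities:
    ``P = sum_t v_t P_t(+1 | x) / sum_t v_t`` with ``v_t = log(1/beta_t)``.
    """
    hyps = model.hypotheses
    if not hyps:
        raise ValueError("model has no hypotheses")
    if any(h.calibration is None for h in hyps):
        raise ValueError("hypotheses are not calibrated")
    X = np.asarray(X, dtype=float)
    num = np.zeros(len(X))
    den = 0.0
    for h in hyps:
        v = h.vote_weight
        num += v * h.calibration.predict(h.decision(X))
        den += v
    return num / den


def predict_probability_map(
    model: EnsembleModel, stack, shape: tuple[int, int, int]
) -> np.ndarray:
    """Probability map reshaped onto the mask geometry (0 outside the mask)."""
    probs = predict_probability(model, stack.X)
    out = np.zeros(shape, dtype=np.float32)
    idx = stack.pixel_index
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = probs
    return out
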