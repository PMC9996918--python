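"""PLS-DA with Mahalanobis-distance classification, BER-tuned components,
VIP-driven iterative variable selection, and confusion-matrix validation.

The PLS machinery is written from scratch: NIPALS PLS2 against a centered
two-column class-indicator response, variable importance in projection (VIP),
balanced error rate (BER) under repeated stratified k-fold cross-validation,
and a pruning loop that removes VIP < 1 variables until the cross-validated
BER stops improving.  Model validation aggregates out-of-fold predictions
over many CV repeats into class-wise confusion percentages, and a
label-permutation analogue checks that performance is not spurious (true
positives should sit at the 50% chance level for balanced classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import POSITIVE_CLASS, TransformedMatrix
from .errors import ConvergenceError, InputError

logger = logging.getLogger(__name__)

_RIDGE = 1e-8  # regularizer on the pooled score covariance
_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------
@dataclass
class PlsdaModel:
    """Fitted PLS-DA model.

    ``weights`` (p×A), ``x_loadings`` (p×A), ``x_scores`` (n×A) and
    ``y_loadings`` (2×A) follow the NIPALS convention with unit-norm weight
    vectors.  ``rotation`` = W(PᵀW)⁻¹ projects new centered data straight to
    scores.  Classification data: per-class centroids of training scores and
    their pooled within-class covariance (for Mahalanobis distances).
    """

    weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    rotation: np.ndarray
    n_components: int
    classes: tuple[str, ...]
    retained_ids: list[str]
    x_mean: np.ndarray
    class_centroids: dict[str, np.ndarray]
    score_covariance: np.ndarray
    vip: np.ndarray | None = None


@dataclass
class CvResult:
    """Mean balanced error rate per candidate component count."""

    ber_by_ncomp: np.ndarray
    chosen_ncomp: int
    folds: int
    repeats: int
    seed: int | None

    @property
    def best_ber(self) -> float:
        return float(self.ber_by_ncomp[self.chosen_ncomp - 1])


@dataclass
class ValidationReport:
    """Aggregated out-of-fold confusion table from repeated CV.

    ``confusion_percent`` rows are true classes and sum to 100; ``counts``
    holds the raw aggregated assignments.  Accuracy and precision treat the
    resilient class ("L") as positive.
    """

    counts: pd.DataFrame
    confusion_percent: pd.DataFrame
    accuracy: float
    precision: float
    folds: int
    repeats: int
    seed: int | None
    permuted: bool = False

    @property
    def tp_percent(self) -> float:
        """Percentage of positive-class samples assigned to the positive class."""
        return float(self.confusion_percent.loc[POSITIVE_CLASS, POSITIVE_CLASS])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, TransformedMatrix):
        return X.values.to_numpy(dtype=float), list(X.values.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"V{j + 1}" for j in range(arr.shape[1])]


def _check_classes(y: np.ndarray) -> tuple[str, ...]:
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) != 2:
        raise InputError(f"exactly two classes required, got {classes}")
    for c in classes:
        if (y == c).sum() < 2:
            raise InputError(f"class {c!r} has fewer than 2 samples")
    return classes


def _dummy_matrix(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    """Centered one-hot class-indicator matrix (n × 2)."""
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    return Y - Y.mean(axis=0)


def balanced_error_rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of per-class misclassification rates."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rates = []
    for c in pd.unique(y_true):
        sel = y_true == c
        rates.append(float(np.mean(y_pred[sel] != c)))
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------
def fit(X, y, n_components: int) -> PlsdaModel:
    """Fit a PLS-DA model by NIPALS PLS2.

    The class vector is encoded as a centered two-column indicator matrix;
    components are extracted one at a time (weight/score/loading iteration
    with X- and Y-deflation).  Fewer than ``n_components`` components are
    returned if the response is exhausted first (perfect fit).
    """
    Xmat, ids = _as_matrix(X)
    y = np.asarray(y)
    if Xmat.shape[0] != len(y):
        raise InputError(f"X has {Xmat.shape[0]} rows but y has {len(y)} labels")
    classes = _check_classes(y)
    n, p = Xmat.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise InputError(
            f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}], "
            f"got {n_components}"
        )

    x_mean = Xmat.mean(axis=0)
    Xc = Xmat - x_mean
    Y = _dummy_matrix(y, classes)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    a_done = 0
    for a in range(n_components):
        ynorms = np.linalg.norm(Y, axis=0)
        if ynorms.max() < 1e-12:  # response exhausted: perfect fit
            break
        u = Y[:, int(np.argmax(ynorms))]
        t_old = np.zeros(n)
        for it in range(_NIPALS_MAX_ITER):
            w = Xc.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                raise ConvergenceError(f"degenerate weight vector at component {a + 1}")
            w /= wn
            t = Xc @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if np.linalg.norm(t - t_old) <= _NIPALS_TOL * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS did not converge within {_NIPALS_MAX_ITER} iterations "
                f"at component {a + 1}"
            )
        pvec = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, pvec)
        Y = Y - np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, pvec, t, q
        a_done += 1

    if a_done == 0:
        raise InputError("no PLS component could be extracted (degenerate response)")
    W, P, T, Q = W[:, :a_done], P[:, :a_done], T[:, :a_done], Q[:, :a_done]
    rotation = W @ np.linalg.inv(P.T @ W)

    centroids = {c: T[y == c].mean(axis=0) for c in classes}
    pooled = np.zeros((a_done, a_done))
    for c in classes:
        D = T[y == c] - centroids[c]
        pooled += D.T @ D
    pooled /= max(n - len(classes), 1)
    pooled += _RIDGE * np.eye(a_done)

    model = PlsdaModel(
        weights=W, x_loadings=P, x_scores=T, y_loadings=Q, rotation=rotation,
        n_components=a_done, classes=classes, retained_ids=ids, x_mean=x_mean,
        class_centroids=centroids, score_covariance=pooled,
    )
    model.vip = vip_scores(model)
    return model


def transform(model: PlsdaModel, X, n_components: int | None = None) -> np.ndarray:
    """Project new samples into the model's score space."""
    Xmat, ids = _as_matrix(X)
    if Xmat.shape[1] != len(model.retained_ids):
        raise InputError(
            f"column mismatch: model has {len(model.retained_ids)} variables, "
            f"input has {Xmat.shape[1]}"
        )
    a = model.n_components if n_components is None else min(n_components, model.n_components)
    return (Xmat - model.x_mean) @ model.rotation[:, :a]


def predict(model: PlsdaModel, X, n_components: int | None = None) -> np.ndarray:
    """Assign each sample the class whose training-score centroid is nearest
    under Mahalanobis distance with the pooled within-class covariance."""
    T_new = transform(model, X, n_components)
    a = T_new.shape[1]
    cov_inv = np.linalg.inv(model.score_covariance[:a, :a])
    dists = np.empty((T_new.shape[0], len(model.classes)))
    for k, c in enumerate(model.classes):
        d = T_new - model.class_centroids[c][:a]
        dists[:, k] = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    return np.asarray(model.classes, dtype=object)[np.argmin(dists, axis=1)]


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ), where SS_a is the
    response variance captured by component a (‖q_a‖²·‖t_a‖²).  Mean squared
    VIP is 1 by construction.
    """
    W, T, Q = model.weights, model.x_scores, model.y_loadings
    p = W.shape[0]
    ss = np.sum(Q**2, axis=0) * np.sum(T**2, axis=0)
    total = ss.sum()
    if total <= 0:
        raise InputError("VIP undefined: model explains no response variance")
    wnorm2 = np.sum(W**2, axis=0)
    contrib = (W**2 / wnorm2) @ ss
    return np.sqrt(p * contrib / total)


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------
def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random stratified fold assignment: class proportions preserved."""
    assignments = [[] for _ in range(folds)]
    for c in pd.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for k, part in enumerate(np.array_split(idx, folds)):
            assignments[k].extend(part.tolist())
    return [np.array(sorted(a), dtype=int) for a in assignments]


def _cv_pass(
    Xmat: np.ndarray,
    y: np.ndarray,
    max_ncomp: int,
    folds: int,
    rng: np.random.Generator,
    counts: np.ndarray,
    classes: tuple[str, ...],
) -> None:
    """One round of stratified k-fold CV; accumulate per-component error
    counts into ``counts`` of shape (max_ncomp, n_classes, 2) = (errors, totals)."""
    for attempt in range(100):
        fold_idx = _stratified_folds(y, folds, rng)
        ok = all(
            len(np.unique(y[np.setdiff1d(np.arange(len(y)), te)])) == 2 for te in fold_idx
        )
        if ok:
            break
        logger.debug("redrawing folds: a training split lacked a class")
    else:
        raise InputError("could not draw folds with both classes in every training split")

    all_idx = np.arange(len(y))
    for te in fold_idx:
        if len(te) == 0:
            continue
        tr = np.setdiff1d(all_idx, te)
        model = fit(Xmat[tr], y[tr], min(max_ncomp, len(tr) - 1, Xmat.shape[1]))
        for a in range(1, max_ncomp + 1):
            pred = predict(model, Xmat[te], n_components=a)
            for k, c in enumerate(classes):
                sel = y[te] == c
                counts[a - 1, k, 0] += np.sum(pred[sel] != c)
                counts[a - 1, k, 1] += sel.sum()


def cross_validate(
    X,
    y,
    max_ncomp: int | None = None,
    folds: int = 4,
    repeats: int = 100,
    seed: int | None = None,
) -> CvResult:
    """Tune the component count by repeated stratified k-fold CV.

    For each candidate count 1..max_ncomp the mean balanced error rate over
    repeats is computed (per repeat, class-wise errors are pooled over the k
    folds); the chosen count attains the minimum, ties toward fewer
    components.  Deterministic given ``seed``.
    """
    Xmat, _ = _as_matrix(X)
    y = np.asarray(y)
    classes = _check_classes(y)
    n, p = Xmat.shape
    if max_ncomp is None:
        max_ncomp = max(1, min(10, n - 2, p))
    rng = np.random.default_rng(seed)

    bers = np.zeros((repeats, max_ncomp))
    for r in range(repeats):
        counts = np.zeros((max_ncomp, len(classes), 2))
        _cv_pass(Xmat, y, max_ncomp, folds, rng, counts, classes)
        with np.errstate(invalid="ignore"):
            class_rates = counts[:, :, 0] / counts[:, :, 1]
        bers[r] = np.nanmean(class_rates, axis=1)
    mean_ber = bers.mean(axis=0)
    chosen = int(np.argmin(mean_ber)) + 1  # argmin takes the first ⇒ fewer comps on ties
    return CvResult(
        ber_by_ncomp=mean_ber, chosen_ncomp=chosen, folds=folds, repeats=repeats, seed=seed
    )


# ---------------------------------------------------------------------------
# iterative VIP selection
# ---------------------------------------------------------------------------
def iterative_selection(
    X,
    y,
    seed: int | None = None,
    folds: int = 4,
    tune_repeats: int = 100,
    vip_threshold: float = 1.0,
    max_ncomp: int | None = None,
    max_iterations: int = 50,
) -> tuple[PlsdaModel, CvResult, list[dict]]:
    """Iteratively prune VIP < 1 variables, retuning and refitting each round.

    Each iteration tunes the component count by BER cross-validation, fits on
    all current variables, computes VIP from that full-data fit, and drops
    variables below ``vip_threshold``.  The loop stops when nothing is
    dropped, when fewer than 2 variables would remain, or when the
    cross-validated BER worsens relative to the best iteration so far.  The
    returned model/CV pair is the iteration with the minimum BER (ties toward
    fewer variables); the trace records every iteration.
    """
    if isinstance(X, TransformedMatrix):
        Xdf = X.values
    elif isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        arr = np.asarray(X, dtype=float)
        Xdf = pd.DataFrame(arr, columns=[f"V{j + 1}" for j in range(arr.shape[1])])
    y = np.asarray(y)
    if Xdf.shape[1] < 2:
        raise InputError("iterative selection needs at least 2 variables")

    base_seed = 0 if seed is None else int(seed)
    trace: list[dict] = []
    best: tuple[PlsdaModel, CvResult] | None = None
    current = Xdf
    for iteration in range(1, max_iterations + 1):
        cv = cross_validate(
            current, y, max_ncomp=max_ncomp, folds=folds,
            repeats=tune_repeats, seed=base_seed + iteration,
        )
        model = fit(current, y, cv.chosen_ncomp)
        trace.append(
            {
                "iteration": iteration,
                "n_variables": current.shape[1],
                "n_components": model.n_components,
                "ber": cv.best_ber,
                "variables": list(current.columns),
            }
        )
        if best is None or cv.best_ber < best[1].best_ber or (
            cv.best_ber == best[1].best_ber
            and current.shape[1] < len(best[0].retained_ids)
        ):
            best = (model, cv)
        elif cv.best_ber > best[1].best_ber:
            logger.info("iteration %d: BER worsened, stopping", iteration)
            break

        keep = model.vip >= vip_threshold
        if keep.all():
            logger.info("iteration %d: all VIP >= %.2f, stopping", iteration, vip_threshold)
            break
        if keep.sum() < 2:
            logger.info("iteration %d: fewer than 2 variables would remain, stopping", iteration)
            break
        current = current.loc[:, current.columns[keep]]

    assert best is not None
    return best[0], best[1], trace


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------
def _aggregate_report(
    counts: pd.DataFrame, folds: int, repeats: int, seed: int | None, permuted: bool
) -> ValidationReport:
    percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pos, neg = POSITIVE_CLASS, [c for c in counts.index if c != POSITIVE_CLASS][0]
    tp = counts.loc[pos, pos]
    fn = counts.loc[pos, neg]
    fp = counts.loc[neg, pos]
    tn = counts.loc[neg, neg]
    total = tp + fn + fp + tn
    accuracy = float((tp + tn) / total) if total else float("nan")
    precision = float(tp / (tp + fp)) if (tp + fp) else float("nan")
    return ValidationReport(
        counts=counts, confusion_percent=percent, accuracy=accuracy,
        precision=precision, folds=folds, repeats=repeats, seed=seed, permuted=permuted,
    )


def _subset_for_model(model: PlsdaModel, X) -> np.ndarray:
    if isinstance(X, TransformedMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        missing = set(model.retained_ids) - set(X.columns)
        if missing:
            raise InputError(f"model variables absent from X: {sorted(missing)[:5]}")
        return X[model.retained_ids].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] != len(model.retained_ids):
        raise InputError("X column count does not match model variables")
    return arr


def validate(
    model: PlsdaModel,
    X,
    y,
    folds: int = 4,
    repeats: int = 10_000,
    seed: int | None = None,
) -> ValidationReport:
    """Confusion matrix from repeated stratified k-fold CV on the model's
    retained variables, with accuracy and precision (resilient class "L"
    as the positive)."""
    Xmat = _subset_for_model(model, X)
    y = np.asarray(y)
    classes = _check_classes(y)
    rng = np.random.default_rng(seed)
    a = model.n_components
    agg = pd.DataFrame(0.0, index=list(classes), columns=list(classes))
    all_idx = np.arange(len(y))
    for _ in range(repeats):
        fold_idx = _stratified_folds(y, folds, rng)
        for te in fold_idx:
            if len(te) == 0:
                continue
            tr = np.setdiff1d(all_idx, te)
            m = fit(Xmat[tr], y[tr], min(a, len(tr) - 1, Xmat.shape[1]))
            pred = predict(m, Xmat[te])
            for yt, yp in zip(y[te], pred):
                agg.loc[yt, yp] += 1
    return _aggregate_report(agg, folds, repeats, seed, permuted=False)


def permuted_validate(
    model: PlsdaModel,
    X,
    y,
    folds: int = 4,
    repeats: int = 1_000,
    seed: int | None = None,
) -> ValidationReport:
    """Permutation analogue of :func:`validate`: per repeat the class labels
    are uniformly permuted (class counts preserved) before one round of
    k-fold CV.  For balanced classes the true-positive percentage should sit
    near the 50% chance level; a large gap to the unpermuted matrix indicates
    genuine signal."""
    Xmat = _subset_for_model(model, X)
    y = np.asarray(y)
    classes = _check_classes(y)
    rng = np.random.default_rng(seed)
    a = model.n_components
    agg = pd.DataFrame(0.0, index=list(classes), columns=list(classes))
    all_idx = np.arange(len(y))
    for _ in range(repeats):
        yp_labels = rng.permutation(y)
        fold_idx = _stratified_folds(yp_labels, folds, rng)
        for te in fold_idx:
            if len(te) == 0:
                continue
            tr = np.setdiff1d(all_idx, te)
            m = fit(Xmat[tr], yp_labels[tr], min(a, len(tr) - 1, Xmat.shape[1]))
            pred = predict(m, Xmat[te])
            for yt, yhat in zip(yp_labels[te], pred):
                agg.loc[yt, yhat] += 1
    return _aggregate_report(agg, folds, repeats, seed, permuted=True)
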