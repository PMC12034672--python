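"""Feature selection (mRMR) and the SVM classification protocol.

Feature selection is greedy max-relevance / min-redundancy on quantile-
discretized features: the first feature maximizes MI with the label; each
subsequent one maximizes ``relevance - mean redundancy`` (MID variant;
``relevance / mean redundancy`` = MIQ is available) against the already
selected set.  Ties break to the lowest column index, so the selection is a
deterministic function of the input alone.

Classification follows a repeated protocol: per repetition, features are
z-scored on training statistics, an SVM grid over kernel x C is scored by
stratified k-fold CV accuracy on the training set (repeat-specific fold
seed), the winner is refit on the whole training set, and test-class
probabilities are emitted.  Final probabilities are the mean over
repetitions; hard labels take the arg-max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SelectionResult",
    "ClassifierProtocolConfig",
    "PredictionResult",
    "mrmr_select",
    "fit_and_predict",
]

_DEFAULT_C_GRID = tuple(2.0 ** e for e in (-5, -3, -1, 1, 3, 5))


@dataclass(frozen=True)
class SelectionResult:
    """Ordered mRMR selection with per-step criterion values."""

    selected_indices: tuple[int, ...]
    scores: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.selected_indices)


@dataclass(frozen=True)
class ClassifierProtocolConfig:
    """Knobs of the repeated CV + grid-search SVM protocol."""

    c_grid: tuple[float, ...] = _DEFAULT_C_GRID
    kernel_set: tuple[str, ...] = ("linear", "rbf")
    n_folds: int = 5
    n_repeats: int = 100
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class PredictionResult:
    """Averaged test-set probabilities, hard labels, and protocol metadata."""

    probabilities: np.ndarray  # (n_test, n_classes), rows sum to 1
    labels: np.ndarray  # arg-max of the averaged probabilities
    classes: np.ndarray  # class values, column order of `probabilities`
    best_params: tuple[tuple[str, float], ...]  # per repeat (kernel, C)
    n_repeats: int


def _quantile_discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-column quantile binning into at most ``n_bins`` integer levels."""
    qs = np.quantile(X, np.linspace(0, 1, n_bins + 1)[1:-1], axis=0)
    # searchsorted per column against that column's inner quantiles
    out = np.zeros(X.shape, dtype=np.int8)
    for b in range(qs.shape[0]):
        out += (X > qs[b]).astype(np.int8)
    return out


def _discrete_mi(
    codes: np.ndarray, n_levels: int, target: np.ndarray, n_classes: int
) -> np.ndarray:
    """MI (nats) between every row of ``codes`` and the discrete ``target``."""
    n = target.size
    onehot_t = np.zeros((n_classes, n), dtype=np.float32)
    onehot_t[target, np.arange(n)] = 1.0
    onehot_f = np.zeros((codes.shape[0], n_levels, n), dtype=np.float32)
    rows = np.repeat(np.arange(codes.shape[0]), n)
    onehot_f[rows, codes.ravel(), np.tile(np.arange(n), codes.shape[0])] = 1.0
    joint = np.einsum("fbn,cn->fbc", onehot_f, onehot_t) / n
    pf = joint.sum(axis=2)  # (F, B)
    pt = joint.sum(axis=1)  # (F, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pf[:, :, None] * pt[:, None, :])
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    return terms.sum(axis=(1, 2))


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_bins: int = 3,
    variant: str = "MID",
    row_ids: Sequence[int] | None = None,
    access_log: "object | None" = None,
) -> SelectionResult:
    """Greedy mRMR feature selection on quantile-discretized features.

    Parameters
    ----------
    X, y
        Trials x features matrix and discrete labels (>= 2 classes).
    k
        Number of features to select (<= feature count).
    n_bins
        Quantile levels used to discretize features for the MI estimates.
    variant
        ``"MID"`` (relevance minus mean redundancy) or ``"MIQ"`` (quotient).
    row_ids, access_log
        Optional audit hooks: when given, the global row ids actually read by
        the selection are recorded on ``access_log`` under stage ``"mrmr"``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be trials x features")
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("labels are constant; mRMR needs >= 2 classes")
    n_feat = X.shape[1]
    if not 1 <= k <= n_feat:
        raise ValueError(f"k={k} outside [1, {n_feat}]")
    if variant not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR variant {variant!r}")
    if access_log is not None and row_ids is not None:
        access_log.record("mrmr", row_ids)

    codes = _quantile_discretize(X, n_bins).T  # (F, n)
    relevance = _discrete_mi(codes, n_bins, y_codes, classes.size)

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_feat)
    available = np.ones(n_feat, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            last = selected[-1]
            # MI of every feature with the last selected one
            redundancy_sum += _discrete_mi(
                codes, n_bins, codes[last].astype(np.int64), n_bins
            )
            mean_red = redundancy_sum / step
            if variant == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / (mean_red + 1e-12)
        crit = np.where(available, crit, -np.inf)
        best = int(np.argmax(crit))  # argmax ties -> lowest index
        selected.append(best)
        scores.append(float(crit[best]))
        available[best] = False
    return SelectionResult(tuple(selected), tuple(scores))


def _grid_search(
    X: np.ndarray, y: np.ndarray, cfg: ClassifierProtocolConfig, fold_seed: int
) -> tuple[str, float, dict[tuple[str, float], float]]:
    """Best (kernel, C) by stratified k-fold CV accuracy; first wins ties."""
    n_splits = min(cfg.n_folds, int(np.bincount(
        np.unique(y, return_inverse=True)[1]).min()))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=fold_seed)
    folds = list(skf.split(X, y))
    cv_scores: dict[tuple[str, float], float] = {}
    best_key, best_acc = None, -1.0
    for kernel in cfg.kernel_set:
        for c in cfg.c_grid:
            accs = []
            for tr_idx, va_idx in folds:
                clf = SVC(kernel=kernel, C=c, gamma="scale")
                clf.fit(X[tr_idx], y[tr_idx])
                accs.append(float(np.mean(clf.predict(X[va_idx]) == y[va_idx])))
            acc = float(np.mean(accs))
            cv_scores[(kernel, c)] = acc
            if acc > best_acc:
                best_key, best_acc = (kernel, c), acc
    return best_key[0], best_key[1], cv_scores


def fit_and_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: ClassifierProtocolConfig,
    train_row_ids: Sequence[int] | None = None,
    test_row_ids: Sequence[int] | None = None,
    access_log: "object | None" = None,
) -> PredictionResult:
    """Repeated grid-searched SVM: average test-class probabilities.

    Per repetition the training set alone drives standardization, grid
    search, and the final fit; the test set is only ever transformed and
    scored.  Probabilities are averaged over ``cfg.n_repeats`` repetitions
    (each with its own fold seed) and hard labels take the arg-max.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training set holds a single class")
    if access_log is not None and train_row_ids is not None:
        access_log.record("standardize", train_row_ids)
        access_log.record("grid_search", train_row_ids)
        access_log.record("fit", train_row_ids)
    if access_log is not None and test_row_ids is not None:
        access_log.record("predict", test_row_ids)

    if cfg.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)

    seeds = [int(s) for s in
             np.random.SeedSequence(cfg.seed).generate_state(cfg.n_repeats)
             & 0x7FFFFFFF]
    prob_sum = np.zeros((X_test.shape[0], classes.size))
    best_params: list[tuple[str, float]] = []
    for rep_seed in seeds:
        kernel, c, _ = _grid_search(X_train, y_train, cfg, rep_seed)
        clf = SVC(kernel=kernel, C=c, gamma="scale", probability=True,
                  random_state=rep_seed)
        with warnings.catch_warnings():
            # sklearn 1.9 deprecates SVC(probability=True); the Platt-scaled
            # probabilities are exactly what the averaging protocol needs.
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X_train, y_train)
        prob = clf.predict_proba(X_test)
        # align columns to the sorted class order (SVC sorts classes_ already)
        prob_sum += prob
        best_params.append((kernel, float(c)))
    probabilities = prob_sum / cfg.n_repeats
    labels = classes[np.argmax(probabilities, axis=1)]
    return PredictionResult(
        probabilities, labels, classes, tuple(best_params), cfg.n_repeats
    )
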