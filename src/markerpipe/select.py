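"""Penalized-regression variable selection with repeated cross-validation.

Elastic-net / LASSO logistic (or multinomial) regression is solved by
cyclic coordinate descent inside an IRLS loop, over a descending log-spaced
lambda grid with warm starts. The selection protocol mirrors the screening
design: the dataset is split 2:1 into train/test when the smallest group is
large enough, lambda is chosen at the cross-validation minimum, the run is
repeated with fresh fold/split seeds, and variables selected in at least
half the runs form the final penalized-selection set, intersected with the
differential-expression calls for the consensus table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_meta import SampleMetadata, ValidationError

#: minimum size of the smallest group for an automatic train/test split
SPLIT_MIN_GROUP = 15


# ---------------------------------------------------------------------------
# coordinate-descent elastic net
# ---------------------------------------------------------------------------

def _soft_threshold(z: np.ndarray, g: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - g, 0.0)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _wls_coordinate_descent(
    Xs: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    b0: float,
    lam: float,
    alpha: float,
    tol: float = 1e-7,
    max_pass: int = 1000,
    Xs2: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Penalized weighted least squares by coordinate descent with an active
    set; candidate features are added by a vectorized KKT check."""
    n, p = Xs.shape
    wn = w / n
    wsum = wn.sum()
    if Xs2 is None:
        Xs2 = Xs * Xs
    wx2 = wn @ Xs2                               # per-coordinate curvature
    r = z - b0 - Xs @ beta
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    soft = _soft_threshold
    dot = np.dot
    active = set(np.flatnonzero(beta).tolist())
    while True:
        # inner loop on the current active set
        cols = {j: wn * Xs[:, j] for j in active}
        for _ in range(max_pass):
            delta = 0.0
            b0_new = b0 + dot(wn, r) / wsum
            r += b0 - b0_new
            delta = max(delta, abs(b0_new - b0) ** 2 * wsum)
            b0 = b0_new
            for j in active:
                num = dot(cols[j], r) + wx2[j] * beta[j]
                den = wx2[j] + l2
                if den <= 0:
                    new = 0.0
                elif num > l1:
                    new = (num - l1) / den
                elif num < -l1:
                    new = (num + l1) / den
                else:
                    new = 0.0
                if new != beta[j]:
                    r += Xs[:, j] * (beta[j] - new)
                    delta = max(delta, wx2[j] * (new - beta[j]) ** 2)
                    beta[j] = new
            if delta < tol:
                break
        # KKT screen over all coordinates (single matmul)
        grad = (wn * r) @ Xs
        viol = np.flatnonzero((np.abs(grad) > l1 + 1e-12) & (beta == 0.0))
        new_members = [int(j) for j in viol if j not in active]
        if not new_members:
            return beta, b0
        active.update(new_members)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


@dataclass
class ENPath:
    """Solution path over a descending lambda grid."""

    lambdas: np.ndarray
    coefs: np.ndarray            # n_lambda x p (binomial/gaussian) or n_lambda x K x p
    intercepts: np.ndarray       # n_lambda or n_lambda x K
    family: str
    classes: np.ndarray | None = None


def lambda_grid(lambda_max: float, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    top = np.log10(max(lambda_max, 1e-12))
    return np.logspace(top, top - decades, n_lambda)


def enet_path(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "binomial",
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
) -> ENPath:
    """Fit the full elastic-net path; ``X`` is samples x features.

    Predictors are standardized internally; coefficients are returned on the
    original scale. ``family`` is gaussian, binomial (y in {0,1}) or
    multinomial (y integer class labels).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    Xs, mu, sd = _standardize(X)
    alpha_eff = max(alpha, 1e-3)   # keeps lambda_max finite for pure ridge

    if family == "multinomial":
        return _multinomial_path(Xs, mu, sd, y, alpha, alpha_eff, lambdas, n_lambda)

    if family == "binomial":
        yb = y.astype(float)
        if set(np.unique(yb)) - {0.0, 1.0}:
            raise ValidationError("binomial family needs labels in {0,1}")
        pbar = yb.mean()
        grad0 = Xs.T @ (yb - pbar) / n
    elif family == "gaussian":
        yb = y.astype(float)
        grad0 = Xs.T @ (yb - yb.mean()) / n
    else:
        raise ValidationError(f"unknown family {family!r}")

    if lambdas is None:
        lambdas = lambda_grid(float(np.abs(grad0).max()) / alpha_eff, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)

    beta = np.zeros(p)
    b0 = float(np.log(pbar / (1 - pbar))) if family == "binomial" and 0 < pbar < 1 else (
        float(yb.mean()) if family == "gaussian" else 0.0)
    coefs = np.zeros((lambdas.size, p))
    intercepts = np.zeros(lambdas.size)
    Xs2 = Xs * Xs
    for li, lam in enumerate(lambdas):
        if family == "gaussian":
            beta, b0 = _wls_coordinate_descent(
                Xs, yb, np.ones(n), beta, b0, lam, alpha, Xs2=Xs2)
        else:
            for _ in range(10):
                eta = b0 + Xs @ beta
                prob = _sigmoid(eta)
                w = np.maximum(prob * (1 - prob), 1e-5)
                z = eta + (yb - prob) / w
                old = beta.copy()
                old0 = b0
                beta, b0 = _wls_coordinate_descent(Xs, z, w, beta, b0, lam, alpha,
                                                   Xs2=Xs2)
                if max(np.abs(beta - old).max(initial=0.0), abs(b0 - old0)) < 1e-5:
                    break
        coefs[li] = beta / sd
        intercepts[li] = b0 - float((beta / sd) @ mu)
    return ENPath(lambdas, coefs, intercepts, family)


def _multinomial_path(Xs, mu, sd, y, alpha, alpha_eff, lambdas, n_lambda) -> ENPath:
    n, p = Xs.shape
    classes = np.unique(y)
    K = classes.size
    if K < 3:
        raise ValidationError("multinomial family expects >= 3 classes")
    Y = (y[:, None] == classes[None, :]).astype(float)
    pbar = Y.mean(axis=0)
    if lambdas is None:
        g = max(float(np.abs(Xs.T @ (Y[:, k] - pbar[k]) / n).max()) for k in range(K))
        lambdas = lambda_grid(g / alpha_eff, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    B = np.zeros((K, p))
    b0 = np.log(np.maximum(pbar, 1e-6))
    coefs = np.zeros((lambdas.size, K, p))
    intercepts = np.zeros((lambdas.size, K))
    Xs2 = Xs * Xs
    for li, lam in enumerate(lambdas):
        for _ in range(10):
            moved = 0.0
            eta = b0[None, :] + Xs @ B.T
            eta -= eta.max(axis=1, keepdims=True)
            P = np.exp(eta)
            P /= P.sum(axis=1, keepdims=True)
            for k in range(K):
                pk = np.clip(P[:, k], 1e-5, 1 - 1e-5)
                w = np.maximum(pk * (1 - pk), 1e-5)
                etak = b0[k] + Xs @ B[k]
                z = etak + (Y[:, k] - pk) / w
                old = B[k].copy()
                old0 = b0[k]
                B[k], b0[k] = _wls_coordinate_descent(Xs, z, w, B[k], b0[k], lam, alpha,
                                                      Xs2=Xs2)
                moved = max(moved, np.abs(B[k] - old).max(initial=0.0), abs(b0[k] - old0))
            if moved < 1e-6:
                break
        coefs[li] = B / sd[None, :]
        intercepts[li] = b0 - (B / sd[None, :]) @ mu
    return ENPath(lambdas, coefs, intercepts, "multinomial", classes)


def _deviance(path_coef, path_int, family, classes, X, y) -> float:
    """Mean deviance of one path point on held-out data."""
    if family == "binomial":
        prob = _sigmoid(path_int + X @ path_coef)
        prob = np.clip(prob, 1e-10, 1 - 1e-10)
        return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    if family == "multinomial":
        eta = path_int[None, :] + X @ path_coef.T
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        idx = np.searchsorted(classes, y)
        return float(-2.0 * np.mean(np.log(np.clip(P[np.arange(len(y)), idx], 1e-10, None))))
    resid = y - (path_int + X @ path_coef)
    return float(np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# protocol: split decision, folds, CV, repeated runs
# ---------------------------------------------------------------------------

def decide_split(meta_or_labels) -> str:
    """``split`` (2/3 train, stratified) when the smallest group has >= 15
    samples, else ``no_split``."""
    if isinstance(meta_or_labels, SampleMetadata):
        counts = meta_or_labels.groups.value_counts()
    else:
        counts = pd.Series(list(meta_or_labels)).value_counts()
    return "split" if int(counts.min()) >= SPLIT_MIN_GROUP else "no_split"


def stratified_split(labels: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-group shuffled 2:1 split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    train, test = [], []
    for lv in np.unique(labels):
        idx = np.flatnonzero(labels == lv)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per sample, class-balanced; errors if any training
    fold-complement would lose a class."""
    labels = np.asarray(labels)
    folds = np.empty(labels.size, dtype=int)
    for lv in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == lv))
        if idx.size < 2:
            raise ValidationError(
                f"class {lv!r} has fewer than 2 samples; stratified folding impossible"
            )
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class ENRun:
    """One repetition of the cross-validated elastic-net selection."""

    run_index: int
    seed: int
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    chosen_lambda: float
    selected: dict[str, float]          # variable id -> coefficient (max |coef| over classes)
    auc: float | None                   # None when no test split
    split: str = "no_split"

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "mean_deviance": self.cv_mean, "se": self.cv_se}
        )


def elastic_net_select(
    X: np.ndarray,
    variable_ids: list[str],
    labels: np.ndarray,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    split: str | None = None,
    rule: str = "min",
) -> ENRun:
    """One cross-validated selection run.

    ``X`` is variables x samples. With ``split == "split"`` the data are
    first divided 2:1 (stratified); the path and CV run on the training part
    and the AUC is evaluated on the held-out test scores. ``rule`` picks the
    CV-minimum lambda (default) or the 1-se lambda.
    """
    if folds < 3:
        raise ValidationError("need at least 3 CV folds")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("need >= 2 classes for selection")
    family = "binomial" if classes.size == 2 else "multinomial"
    y = (labels == classes[1]).astype(float) if family == "binomial" else \
        np.searchsorted(classes, labels)
    Xi = np.asarray(X, dtype=float).T          # samples x variables
    rng = np.random.default_rng(seed)
    if split is None:
        split = decide_split(labels)
    if split == "split":
        tr, te = stratified_split(labels, 2.0 / 3.0, rng)
    else:
        tr, te = np.arange(Xi.shape[0]), None

    Xtr, ytr = Xi[tr], y[tr]
    base = enet_path(Xtr, ytr, family=family, alpha=alpha)
    fold_id = stratified_folds(labels[tr], folds, rng)
    dev = np.zeros((folds, base.lambdas.size))
    for f in range(folds):
        hold = fold_id == f
        sub = enet_path(Xtr[~hold], ytr[~hold], family=family, alpha=alpha,
                        lambdas=base.lambdas)
        for li in range(base.lambdas.size):
            dev[f, li] = _deviance(sub.coefs[li], sub.intercepts[li], family,
                                   base.classes, Xtr[hold], ytr[hold])
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    imin = int(np.argmin(cv_mean))
    if rule == "1se":
        ok = np.flatnonzero(cv_mean <= cv_mean[imin] + cv_se[imin])
        imin = int(ok[0])
    chosen = float(base.lambdas[imin])

    coef = base.coefs[imin]
    if family == "multinomial":
        mags = np.abs(coef).max(axis=0)
        sel_idx = np.flatnonzero(mags != 0)
        selected = {variable_ids[j]: float(mags[j]) for j in sel_idx}
    else:
        sel_idx = np.flatnonzero(coef != 0)
        selected = {variable_ids[j]: float(coef[j]) for j in sel_idx}

    auc = None
    if te is not None:
        if family == "binomial":
            scores = base.intercepts[imin] + Xi[te] @ coef
            auc = roc_auc(scores, y[te])
        else:
            eta = base.intercepts[imin][None, :] + Xi[te] @ coef.T
            aucs = []
            for ki in range(classes.size):
                truth = (y[te] == ki).astype(int)
                if 0 < truth.sum() < truth.size:
                    aucs.append(roc_auc(eta[:, ki], truth))
            auc = float(np.mean(aucs)) if aucs else None
    return ENRun(0, seed, base.lambdas, cv_mean, cv_se, chosen, selected, auc, split)


def repeated_selection(
    X: np.ndarray,
    variable_ids: list[str],
    labels: np.ndarray,
    alpha: float = 0.5,
    runs: int = 10,
    base_seed: int = 0,
    folds: int = 10,
    split: str | None = None,
) -> tuple[list[ENRun], pd.DataFrame, set[str]]:
    """Repeat the selection ``runs`` times with seeds base_seed + r.

    Returns the runs, a per-variable selection-frequency table, and the
    penalized-selection set: variables chosen in at least half the runs.
    """
    if runs < 1:
        raise ValidationError("runs must be >= 1")
    results = []
    freq: dict[str, int] = {}
    for r in range(runs):
        run = elastic_net_select(
            X, variable_ids, labels, alpha=alpha, folds=folds,
            seed=base_seed + r, split=split)
        run.run_index = r
        results.append(run)
        for v in run.selected:
            freq[v] = freq.get(v, 0) + 1
    table = pd.DataFrame(
        sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["id", "n_selected"],
    )
    table["frequency"] = table["n_selected"] / runs
    en_set = {v for v, c in freq.items() if c >= runs / 2.0}
    return results, table, en_set


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ConsensusSet:
    """Overlap between differential-expression calls and penalized selection."""

    dea_ids: set[str]
    en_ids: set[str]
    intersection: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.intersection = self.dea_ids & self.en_ids

    def venn_counts(self) -> dict[str, int]:
        return {
            "dea_only": len(self.dea_ids - self.en_ids),
            "en_only": len(self.en_ids - self.dea_ids),
            "both": len(self.intersection),
        }


def consensus_overlap(dea_ids: set[str], en_ids: set[str]) -> ConsensusSet:
    return ConsensusSet(set(dea_ids), set(en_ids))
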