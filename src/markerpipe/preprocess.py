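"""Missing-value imputation, low-count filtering, and normalization.

Sequencing counts are filtered on counts-per-million, scaled between samples
by the weighted trimmed mean of M-values (TMM), and transformed to log2-CPM
with observation-level precision weights from the empirical mean-variance
trend (the voom construction). Continuous platforms (arrays, mass
spectrometry) are log/logit transformed and quantile normalized or centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_meta import ExpressionMatrix, SampleMetadata, ValidationError


@dataclass
class NormalizationReport:
    """Book-keeping for the preprocessing stage of one run."""

    library_sizes: np.ndarray | None = None
    tmm_factors: np.ndarray | None = None
    transformation: str = "none"
    centering: str = "none"
    n_filtered: int = 0
    n_imputed: int = 0
    removed_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(
    X: ExpressionMatrix, method: str = "lls", k: int = 10
) -> tuple[ExpressionMatrix, int]:
    """Fill missing entries by local least squares (default) or k-NN.

    LLS: for each incomplete variable the ``k`` complete variables most
    similar to it (absolute Pearson correlation over the shared observed
    samples) act as least-squares predictors; missing entries are predicted
    from that regression. KNN: a missing entry is the mean of the ``k``
    nearest variables' values at that sample (Euclidean distance over shared
    observed coordinates). Observed entries are never altered. Variables with
    fewer than ``k`` eligible neighbours fall back to their own observed mean
    (with a warning); a fully missing variable is an error.
    """
    if method not in ("lls", "knn"):
        raise ValueError("method must be 'lls' or 'knn'")
    if k < 1:
        raise ValueError("k must be a positive integer")
    V = X.values.copy()
    miss = ~np.isfinite(V)
    n_missing = int(miss.sum())
    if n_missing == 0:
        return X.copy_with(V), 0
    fully_missing = np.where(miss.all(axis=1))[0]
    if fully_missing.size:
        raise ValidationError(
            f"variable {X.variable_ids[fully_missing[0]]!r} has no observed values"
        )
    complete = ~miss.any(axis=1)
    incomplete_rows = np.where(miss.any(axis=1))[0]
    for i in incomplete_rows:
        if method == "lls":
            _impute_lls_row(V, miss, i, complete, k, X.variable_ids)
        else:
            _impute_knn_row(V, miss, i, k, X.variable_ids)
    assert np.isfinite(V).all()
    return X.copy_with(V), n_missing


def _impute_lls_row(V, miss, i, complete, k, ids) -> None:
    obs = ~miss[i]
    mis = miss[i]
    cand = np.where(complete)[0]
    cand = cand[cand != i]
    if cand.size >= k and obs.sum() >= 2:
        target = V[i, obs]
        block = V[np.ix_(cand, np.where(obs)[0])]
        sims = _abs_pearson(block, target)
        order = np.argsort(-sims, kind="stable")
        nbr = cand[order[:k]]
        A = np.column_stack([np.ones(obs.sum()), V[np.ix_(nbr, np.where(obs)[0])].T])
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        Apred = np.column_stack(
            [np.ones(mis.sum()), V[np.ix_(nbr, np.where(mis)[0])].T]
        )
        V[i, mis] = Apred @ coef
    else:
        warnings.warn(
            f"variable {ids[i]!r}: fewer than k eligible neighbours; "
            "falling back to variable-mean imputation"
        )
        V[i, mis] = V[i, obs].mean()


def _impute_knn_row(V, miss, i, k, ids) -> None:
    obs_i = ~miss[i]
    for j in np.where(miss[i])[0]:
        cand = np.where(~miss[:, j])[0]
        cand = cand[cand != i]
        dists = np.full(cand.size, np.inf)
        for c_idx, c in enumerate(cand):
            shared = obs_i & ~miss[c]
            if shared.any():
                d = V[i, shared] - V[c, shared]
                dists[c_idx] = float(np.sqrt(np.sum(d * d)))
        finite = np.isfinite(dists)
        if finite.sum() >= k:
            order = np.argsort(dists, kind="stable")[:k]
            V[i, j] = V[cand[order], j].mean()
        else:
            warnings.warn(
                f"variable {ids[i]!r}: fewer than k eligible neighbours; "
                "falling back to variable-mean imputation"
            )
            V[i, j] = V[i, obs_i].mean()


def _abs_pearson(block: np.ndarray, target: np.ndarray) -> np.ndarray:
    bc = block - block.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((bc * bc).sum(axis=1) * (tc * tc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ tc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


# ---------------------------------------------------------------------------
# count filtering and TMM
# ---------------------------------------------------------------------------

def cpm(counts: np.ndarray, lib_sizes: np.ndarray | None = None) -> np.ndarray:
    """Counts per million over raw library sizes."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts / lib_sizes * 1e6


def filter_low_counts(
    X: ExpressionMatrix, meta: SampleMetadata
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop variables without CPM > 1 in at least ``m`` samples.

    ``m`` is the size of the smallest group, so a variable expressed only in
    the smallest experimental group still survives.
    """
    if X.datatype != "seq":
        raise ValidationError("low-count filtering applies to seq data only")
    m = int(meta.groups.value_counts().min())
    keep = (cpm(X.values) > 1.0).sum(axis=1) >= m
    removed = [v for v, k in zip(X.variable_ids, keep) if not k]
    if not keep.any():
        raise ValidationError(
            "all variables removed by the low-count filter; review the threshold"
        )
    kept = [v for v, k in zip(X.variable_ids, keep) if k]
    return X.subset_variables(kept), removed


def tmm_factors(X: ExpressionMatrix) -> np.ndarray:
    """Weighted trimmed mean of M-values scale factors, one per sample.

    The reference sample is the column whose upper-quartile CPM is closest to
    the mean upper-quartile. M (log ratio) and A (average log abundance) are
    computed on the CPM scale over variables positive in both sample and
    reference; the 30% most extreme M and 5% most extreme A are trimmed
    (intersection kept) and the factor is 2**(weighted mean M) with inverse
    delta-method binomial variances as weights. Factors are rescaled to
    geometric mean 1.
    """
    counts = X.values
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    if np.any(counts < 0):
        raise ValidationError("TMM requires non-negative counts")
    lib = counts.sum(axis=0)
    C = cpm(counts, lib)
    uq = np.array([np.quantile(C[:, s][C[:, s] > 0], 0.75) if (C[:, s] > 0).any() else 0.0
                   for s in range(C.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        both = (counts[:, s] > 0) & (counts[:, ref] > 0)
        if not both.any():
            raise ValidationError(
                f"sample {X.sample_ids[s]!r} shares no positive variables with the reference"
            )
        cs, cr = C[both, s], C[both, ref]
        M = np.log2(cs / cr)
        A = 0.5 * (np.log2(cs) + np.log2(cr))
        # delta-method binomial variance of M, on the CPM scale (library 1e6)
        # so that rescaling a column leaves both M-values and weights unchanged
        w = 1.0 / ((1e6 - cs) / (1e6 * cs) + (1e6 - cr) / (1e6 * cr))
        keep = _double_trim_mask(M, A, 0.30, 0.05)
        if not keep.any():
            keep = np.ones_like(M, dtype=bool)
        log_factors[s] = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _double_trim_mask(M: np.ndarray, A: np.ndarray, m_frac: float, a_frac: float) -> np.ndarray:
    """Keep entries inside both central quantile bands (total trim fractions)."""
    n = M.size
    rm = np.argsort(np.argsort(M, kind="stable"), kind="stable") + 1
    ra = np.argsort(np.argsort(A, kind="stable"), kind="stable") + 1
    keep_m = (rm > n * m_frac / 2) & (rm <= n * (1 - m_frac / 2))
    keep_a = (ra > n * a_frac / 2) & (ra <= n * (1 - a_frac / 2))
    return keep_m & keep_a


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------

@dataclass
class VoomResult:
    """log2-CPM matrix with per-observation precision weights and the trend."""

    logcpm: np.ndarray
    weights: np.ndarray
    trend_x: np.ndarray   # mean log2-CPM (sorted ascending)
    trend_y: np.ndarray   # sqrt residual sd


def voom_transform(
    X: ExpressionMatrix, factors: np.ndarray, design: np.ndarray
) -> VoomResult:
    """Counts to log2-CPM plus precision weights from the mean-variance trend.

    logcpm = log2((count + 0.5) / (libsize*factor + 1) * 1e6). Per-variable
    OLS residual standard deviations under ``design`` are lowess-smoothed
    (span 0.5) against mean log2-CPM on the sqrt scale; each observation's
    weight is trend(fitted logcpm)**-4 with the sqrt-sd floored at 1e-4.
    """
    counts = X.values
    n_var, n_samp = counts.shape
    design = np.asarray(design, dtype=float)
    if design.shape[0] != n_samp:
        raise ValidationError("design rows must match sample count")
    rank = np.linalg.matrix_rank(design)
    if n_samp <= design.shape[1] or rank < design.shape[1]:
        raise ValidationError("fewer samples than design columns (or rank-deficient design)")

    eff_lib = counts.sum(axis=0) * np.asarray(factors, dtype=float)
    logcpm = np.log2((counts + 0.5) / (eff_lib + 1.0) * 1e6)

    pinv = np.linalg.pinv(design)
    beta = logcpm @ pinv.T                     # variables x coefficients
    fitted = beta @ design.T
    resid = logcpm - fitted
    df_resid = n_samp - rank
    s = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_s = np.maximum(np.sqrt(s), 1e-4)
    abar = logcpm.mean(axis=1)

    if np.ptp(abar) < 1e-12 or n_var < 2:
        trend_x = np.array([abar.mean() - 0.5, abar.mean() + 0.5])
        trend_y = np.full(2, max(float(sqrt_s.mean()), 1e-4))
    else:
        sm = lowess(sqrt_s, abar, frac=0.5, it=3, return_sorted=True)
        trend_x, trend_y = sm[:, 0], np.maximum(sm[:, 1], 1e-4)
        trend_x, uniq = np.unique(trend_x, return_index=True)
        trend_y = trend_y[uniq]
    w = np.interp(fitted, trend_x, trend_y) ** -4
    return VoomResult(logcpm=logcpm, weights=w, trend_x=trend_x, trend_y=trend_y)


# ---------------------------------------------------------------------------
# continuous normalization
# ---------------------------------------------------------------------------

def normalize_continuous(
    X: ExpressionMatrix,
    transform: str = "log2",
    center: str = "quantile",
    offset: bool = False,
) -> ExpressionMatrix:
    """Element-wise transform then column normalization for array/ms data.

    ``transform``: log2 | log10 | logit | none (``offset`` adds +1 before a
    log). ``center``: quantile (columns share the mean order-statistic
    distribution, ties averaged), mean, median, or none.
    """
    V = X.values.copy()
    if transform in ("log2", "log10"):
        if offset:
            V = V + 1.0
        if np.any(V <= 0):
            i, j = np.argwhere(V <= 0)[0]
            raise ValidationError(
                f"log transform needs positive values; cell at variable "
                f"{X.variable_ids[i]!r}, sample {X.sample_ids[j]!r} (use the +1 offset flag)"
            )
        V = np.log2(V) if transform == "log2" else np.log10(V)
    elif transform == "logit":
        if np.any((V <= 0) | (V >= 1)):
            i, j = np.argwhere((V <= 0) | (V >= 1))[0]
            raise ValidationError(
                f"logit requires values strictly in (0,1); cell at variable "
                f"{X.variable_ids[i]!r}, sample {X.sample_ids[j]!r}"
            )
        V = np.log(V / (1 - V))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    if center == "quantile":
        V = quantile_normalize(V)
    elif center in ("mean", "median"):
        stat = np.mean if center == "mean" else np.median
        V = V - stat(V, axis=0, keepdims=True)
    elif center != "none":
        raise ValueError(f"unknown centering {center!r}")
    return X.copy_with(V)


def quantile_normalize(V: np.ndarray) -> np.ndarray:
    """Each column's sorted values become the across-column mean order statistics.

    A tied block within a column receives the mean of the reference values its
    ranks span, keeping the output deterministic.
    """
    n, m = V.shape
    order = np.argsort(V, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(V, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(V)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            assigned[i:k + 1] = reference[i:k + 1].mean()
            i = k + 1
        out[order[:, j], j] = assigned
    return out
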