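"""Weighted co-expression network analysis and paired correlation screening.

An unsigned adjacency |cor|^beta is raised to a soft power chosen for
approximate scale-free topology, converted to the topological overlap matrix
(TOM), clustered by average linkage on TOM dissimilarity, cut into modules,
and modules with sufficiently correlated eigengenes (first principal
components) are merged. Intramodular connectivity ranks hub variables.
A separate screen computes per-variable Spearman correlation between two
paired matrices (e.g. interstitial fluid vs serum abundances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .dea import bh_adjust
from .io_meta import ValidationError


@dataclass
class ModuleSet:
    """Variable -> module assignment (0 = unassigned) with eigengenes."""

    labels: np.ndarray                   # per-variable module id
    variable_ids: list[str]
    beta: int | None = None
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)
    k_within: np.ndarray | None = None
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in set(self.labels.tolist()) - {0})

    def members(self, module: int) -> list[str]:
        return [v for v, l in zip(self.variable_ids, self.labels) if l == module]


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

def adjacency_matrix(X: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned adjacency |pearson|^beta with zero diagonal; X is variables x samples."""
    if not np.all(np.isfinite(X)):
        raise ValidationError("expression values must be finite (impute first)")
    sd = X.std(axis=1)
    if np.any(sd < 1e-12):
        bad = int(np.argmin(sd))
        raise ValidationError(f"variable index {bad} is constant; correlation undefined")
    C = np.corrcoef(X)
    A = np.abs(np.clip(C, -1, 1)) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 freq(k) on log10 mean(k) over connectivity bins.

    Positive when the slope is negative (the scale-free direction); degenerate
    connectivity spreads return -inf so callers fall through to the max-R^2
    branch.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) < 1e-12:
        return -np.inf
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return -np.inf
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(
    X: np.ndarray,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``target_r2``; otherwise
    the power of maximal fit, with a warning."""
    if X.shape[0] < 20:
        warnings.warn("fewer than 20 variables; soft-threshold fit is unreliable")
    rows = []
    for b in powers:
        A = adjacency_matrix(X, b)
        k = A.sum(axis=1)
        rows.append({"power": b, "sft_r2": scale_free_fit(k), "mean_k": float(k.mean())})
    fit = pd.DataFrame(rows)
    ok = fit[fit["sft_r2"] >= target_r2]
    if len(ok):
        return int(ok.iloc[0]["power"]), fit
    warnings.warn(
        f"no candidate power reached scale-free R^2 {target_r2}; "
        "using the power with maximal fit"
    )
    if np.all(~np.isfinite(fit["sft_r2"])):
        return int(fit.iloc[0]["power"]), fit
    return int(fit.loc[fit["sft_r2"].idxmax(), "power"]), fit


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def tom_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Topological overlap w_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij).

    l_ij counts shared-neighbour adjacency mass; the diagonal is 1 and the
    dissimilarity used downstream is 1 - w.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.any((A < 0) | (A > 1)):
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if np.any(np.abs(np.diag(A)) > 1e-12):
        raise ValidationError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        W = (L + A) / denom
    W[~np.isfinite(W)] = 0.0
    np.fill_diagonal(W, 1.0)
    return W


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def module_eigengene(X_mod: np.ndarray) -> np.ndarray:
    """First principal component of the standardized module block
    (variables x samples), unit norm, sign anchored to positive mean loading."""
    Z = X_mod - X_mod.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    Z = Z / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    loadings = Z @ e
    if loadings.mean() < 0:
        e = -e
    return e / np.linalg.norm(e)


def detect_and_merge_modules(
    diss_tom: np.ndarray,
    X: np.ndarray,
    variable_ids: list[str],
    min_size: int = 20,
    merge_cut: float = 0.25,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Average-linkage tree on TOM dissimilarity, static cut, eigengene merge.

    Branches below ``cut_height`` form initial modules; those smaller than
    ``min_size`` go to label 0. Pairs of modules whose eigengene
    dissimilarity (1 - pearson) is below ``merge_cut`` are merged iteratively
    (closest pair first), recomputing eigengenes after each merge.
    """
    if not 0.0 <= merge_cut < 1.0:
        raise ValidationError("merge_cut must lie in [0, 1)")
    if min_size < 3:
        raise ValidationError("min module size must be >= 3")
    n = diss_tom.shape[0]
    D = np.array(diss_tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    tree = average(squareform(D, checks=False))
    raw = fcluster(tree, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    next_id = 1
    for cl in np.unique(raw):
        idx = np.flatnonzero(raw == cl)
        if idx.size >= min_size:
            labels[idx] = next_id
            next_id += 1
    ms = ModuleSet(labels, list(variable_ids))
    if not ms.module_ids:
        warnings.warn("no branch reached the minimum module size; all variables unassigned")
        return ms

    eig = {m: module_eigengene(X[labels == m]) for m in ms.module_ids}
    while merge_cut > 0 and len(eig) > 1:
        mids = sorted(eig)
        best = None
        for i, a in enumerate(mids):
            for b in mids[i + 1:]:
                d = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if d < merge_cut and (best is None or d < best[2]):
                    best = (a, b, d)
        if best is None:
            break
        a, b, d = best
        labels[labels == b] = a
        ms.merge_history.append((a, b, d))
        eig.pop(b)
        eig[a] = module_eigengene(X[labels == a])
    # relabel 1..M by size, deterministically
    sizes = {m: int((labels == m).sum()) for m in eig}
    remap = {m: i + 1 for i, m in enumerate(sorted(sizes, key=lambda m: (-sizes[m], m)))}
    new_labels = np.array([remap.get(l, 0) for l in labels])
    ms.labels = new_labels
    ms.eigengenes = {remap[m]: e for m, e in eig.items()}
    return ms


def intramodular_connectivity(
    A: np.ndarray, modules: ModuleSet, top_frac: float = 0.25
) -> tuple[np.ndarray, dict[int, pd.DataFrame]]:
    """kWithin_i = sum of adjacency to same-module members; per-module top list.

    Each module reports its ceil(top_frac * size) most connected variables.
    """
    if not 0.0 < top_frac <= 1.0:
        raise ValidationError("top_frac must be in (0, 1]")
    labels = modules.labels
    k_within = np.zeros(labels.size)
    tops: dict[int, pd.DataFrame] = {}
    for m in modules.module_ids:
        idx = np.flatnonzero(labels == m)
        block = A[np.ix_(idx, idx)]
        kw = block.sum(axis=1)
        k_within[idx] = kw
        n_top = int(np.ceil(top_frac * idx.size))
        order = np.argsort(-kw, kind="stable")[:n_top]
        tops[m] = pd.DataFrame(
            {
                "id": [modules.variable_ids[idx[o]] for o in order],
                "kWithin": kw[order],
            }
        )
    modules.k_within = k_within
    return k_within, tops


def wgcna_modules(
    X: np.ndarray,
    variable_ids: list[str],
    min_size: int = 20,
    merge_cut: float = 0.25,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
    max_block: int = 5000,
    top_frac: float = 0.25,
    seed: int = 0,
) -> tuple[ModuleSet, pd.DataFrame, dict[int, pd.DataFrame]]:
    """End-to-end module detection; large inputs are processed block-wise.

    Above ``max_block`` variables, variables are pre-clustered (k-means on
    standardized profiles) into blocks of at most ``max_block``, modules are
    detected per block, and modules from different blocks whose eigengenes
    are closer than ``merge_cut`` are merged, mirroring block-wise network
    construction on large matrices.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    beta, fit = pick_soft_threshold(X, powers, target_r2)
    if p <= max_block:
        A = adjacency_matrix(X, beta)
        modules = detect_and_merge_modules(
            1.0 - tom_from_adjacency(A), X, variable_ids, min_size, merge_cut)
    else:
        modules = _blockwise_detect(X, variable_ids, beta, min_size, merge_cut,
                                    max_block, seed)
        A = adjacency_matrix(X, beta)
    modules.beta = beta
    _, tops = intramodular_connectivity(A, modules, top_frac)
    return modules, fit, tops


def _blockwise_detect(X, variable_ids, beta, min_size, merge_cut, max_block, seed):
    from .cluster import kmeans_partition

    p = X.shape[0]
    n_blocks = int(np.ceil(p / max_block))
    Z = (X - X.mean(axis=1, keepdims=True))
    sd = Z.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    part = kmeans_partition(Z / sd, n_blocks, restarts=5, seed=seed)
    labels = np.zeros(p, dtype=int)
    eig: dict[int, np.ndarray] = {}
    next_id = 1
    for b in range(1, n_blocks + 1):
        idx = np.flatnonzero(part.assignments == b)
        if idx.size < min_size:
            continue
        A = adjacency_matrix(X[idx], beta)
        sub = detect_and_merge_modules(
            1.0 - tom_from_adjacency(A), X[idx],
            [variable_ids[i] for i in idx], min_size, merge_cut)
        for m in sub.module_ids:
            labels[idx[sub.labels == m]] = next_id
            eig[next_id] = sub.eigengenes[m]
            next_id += 1
    ms = ModuleSet(labels, list(variable_ids))
    # cross-block eigengene merge
    while merge_cut > 0 and len(eig) > 1:
        mids = sorted(eig)
        best = None
        for i, a in enumerate(mids):
            for b2 in mids[i + 1:]:
                d = 1.0 - float(np.corrcoef(eig[a], eig[b2])[0, 1])
                if d < merge_cut and (best is None or d < best[2]):
                    best = (a, b2, d)
        if best is None:
            break
        a, b2, d = best
        labels[labels == b2] = a
        ms.merge_history.append((a, b2, d))
        eig.pop(b2)
        eig[a] = module_eigengene(X[labels == a])
    sizes = {m: int((labels == m).sum()) for m in eig}
    remap = {m: i + 1 for i, m in enumerate(sorted(sizes, key=lambda m: (-sizes[m], m)))}
    ms.labels = np.array([remap.get(l, 0) for l in labels])
    ms.eigengenes = {remap[m]: e for m, e in eig.items()}
    return ms


# ---------------------------------------------------------------------------
# paired correlation screen
# ---------------------------------------------------------------------------

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation as Pearson on midranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 or sy < 1e-12:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def paired_spearman_screen(
    X1: np.ndarray,
    X2: np.ndarray,
    variable_ids: list[str],
    rho_cut: float = 0.5,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-variable Spearman correlation between two paired matrices.

    p-values use the t approximation on n-2 df; FDR across variables; the
    significance gate is one-sided positive: rho > rho_cut and FDR < fdr_cut.
    Variables with < 4 complete pairs are flagged untestable (NaN rho).
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape != X2.shape:
        raise ValidationError("paired matrices must share the same shape")
    rows = []
    for i, vid in enumerate(variable_ids):
        ok = np.isfinite(X1[i]) & np.isfinite(X2[i])
        n = int(ok.sum())
        if n < 4:
            rows.append({"id": vid, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho = spearman_rho(X1[i, ok], X2[i, ok])
        if not np.isfinite(rho) or abs(rho) >= 1.0:
            p = 0.0 if np.isfinite(rho) else np.nan
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append({"id": vid, "rho": rho, "p": p, "n": n})
    table = pd.DataFrame(rows)
    testable = table["p"].notna()
    fdr = np.full(len(table), np.nan)
    if testable.any():
        fdr[testable.to_numpy()] = bh_adjust(table.loc[testable, "p"].to_numpy())
    table["FDR"] = fdr
    sig = table[(table["rho"] > rho_cut) & (table["FDR"] < fdr_cut)]["id"].tolist()
    return table, sig
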