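"""Sample clustering: k-means over a range of k, BIC model selection, and
classical multidimensional scaling coordinates for plotting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_meta import ExpressionMatrix, ValidationError


@dataclass
class KMeansFit:
    assignments: np.ndarray      # 1-based cluster labels
    centroids: np.ndarray
    wcss: float


@dataclass
class ClusteringResult:
    per_k: dict[int, KMeansFit]
    bic: dict[int, float]
    selected_k: int
    mds: np.ndarray | None = None
    mds_eigenvalue_share: np.ndarray | None = None

    def bic_table(self) -> pd.DataFrame:
        ks = sorted(self.bic)
        return pd.DataFrame({"k": ks, "bic": [self.bic[k] for k in ks],
                             "wcss": [self.per_k[k].wcss for k in ks]})


def kmeans_partition(
    S: np.ndarray, k: int, restarts: int = 25, seed: int = 0
) -> KMeansFit:
    """Lloyd iteration, best of ``restarts`` seeded initializations by WCSS.

    Empty clusters are re-seeded at the point farthest from its centroid.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k > n:
        raise ValidationError("k cannot exceed the number of samples")
    if not np.all(np.isfinite(S)):
        raise ValidationError("features must be finite")
    rng = np.random.default_rng(seed)
    best: KMeansFit | None = None
    for _ in range(max(restarts, 1)):
        centroids = S[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(300):
            d2 = ((S[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            for c in range(k):
                if not np.any(new_labels == c):
                    # re-seed an empty cluster at the farthest point
                    far = int(d2[np.arange(n), new_labels].argmax())
                    centroids[c] = S[far]
                    new_labels[far] = c
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for c in range(k):
                centroids[c] = S[labels == c].mean(axis=0)
        wcss = float(((S - centroids[labels]) ** 2).sum())
        if best is None or wcss < best.wcss:
            best = KMeansFit(labels + 1, centroids.copy(), wcss)
    return best


def _bic_spherical(S: np.ndarray, fit: KMeansFit) -> float:
    """BIC of a spherical equal-variance Gaussian mixture evaluated at the
    k-means partition: 2*loglik - p*ln(n), p = k*d + k - 1 + 1."""
    n, d = S.shape
    k = fit.centroids.shape[0]
    labels = fit.assignments - 1
    sigma2 = fit.wcss / (n * d)
    if sigma2 <= 0:
        raise ValidationError("zero-variance fit; BIC undefined")
    ll = 0.0
    for c in range(k):
        nc = int((labels == c).sum())
        if nc == 0:
            continue
        ll += nc * np.log(nc / n)
    ll += -0.5 * n * d * np.log(2 * np.pi * sigma2) - 0.5 * fit.wcss / sigma2
    p = k * d + k - 1 + 1
    return float(2.0 * ll - p * np.log(n))


def select_k_bic(
    S: np.ndarray,
    k_range: tuple[int, ...] | None = None,
    seed: int = 0,
    restarts: int = 25,
) -> ClusteringResult:
    """Run k-means for each k and select the BIC maximizer (ties -> smallest k).

    Default k range is 2..min(10, n//3).
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k_range is None:
        k_range = tuple(range(2, max(min(10, n // 3), 2) + 1))
    per_k: dict[int, KMeansFit] = {}
    bic: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValidationError(f"k={k} outside the valid range [2, n-1]")
        fit = kmeans_partition(S, k, restarts=restarts, seed=seed + k)
        try:
            bic[k] = _bic_spherical(S, fit)
        except ValidationError:
            warnings.warn(f"degenerate zero-variance fit at k={k}; skipped")
            continue
        per_k[k] = fit
    if not bic:
        raise ValidationError("no k produced a valid fit")
    best_bic = max(bic.values())
    selected = min(k for k, b in bic.items() if b == best_bic)
    return ClusteringResult(per_k, bic, selected)


def classical_mds(X: ExpressionMatrix, top_n: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Two-dimensional classical (Torgerson) MDS over the top-N most variable
    variables; returns (coordinates n_samples x 2, eigenvalue shares)."""
    V = X.values
    if V.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 samples")
    variances = V.var(axis=1)
    top = np.argsort(-variances, kind="stable")[: min(top_n, V.shape[0])]
    S = V[top].T                              # samples x features
    sq = (S ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * S @ S.T
    np.clip(D2, 0.0, None, out=D2)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(float(evals[0]), 1.0)
    if evals[0] <= tol:
        raise ValidationError("no positive eigenvalues; degenerate geometry")
    # exactly collinear samples have a single positive eigenvalue; the second
    # axis is then identically zero rather than an error
    top2 = np.maximum(evals[:2], 0.0)
    coords = evecs[:, :2] * np.sqrt(top2)
    share = top2 / evals[evals > 0].sum()
    return coords, share
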