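"""Cox proportional-hazards screening for prognostic variables.

Each candidate variable is fit in its own Cox model alongside adjustment
covariates (age, immune scores, ...). The partial likelihood uses Efron tie
handling and is maximized by Newton-Raphson. Before screening, two model
assumptions are checked on the adjustment covariates: proportional hazards
(scaled Schoenfeld residuals against Kaplan-Meier-transformed event times)
and linearity of continuous covariates with the log hazard (likelihood-ratio
test against a natural cubic spline); a covariate failing linearity enters
through the spline basis instead. P-values across variables are BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dea import bh_adjust
from .io_meta import SampleMetadata, ValidationError


@dataclass
class CoxFit:
    beta: np.ndarray
    cov: np.ndarray                  # inverse observed information
    loglik: float
    loglik_null: float
    score_norm: float
    converged: bool
    estimable: bool
    n_events: int


def _event_blocks(time: np.ndarray, event: np.ndarray):
    """Samples sorted by time; yields (risk-set start index, tied event rows)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    blocks = []
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        deaths = [k for k in range(i, j + 1) if e[k]]
        if deaths:
            blocks.append((i, np.array(deaths)))
        i = j + 1
    return order, blocks


def _cox_quantities(Z: np.ndarray, order, blocks, beta: np.ndarray):
    """Efron partial log-likelihood, score and information."""
    Zs = Z[order]
    eta = Zs @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    n, p = Zs.shape
    # suffix sums over the risk set
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Zs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * Zs[:, :, None] * Zs[:, None, :])[::-1], axis=0)[::-1]
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for start, deaths in blocks:
        d = deaths.size
        wd = w[deaths]
        s0r, s1r, s2r = S0[start], S1[start], S2[start]
        s0d = wd.sum()
        s1d = (wd[:, None] * Zs[deaths]).sum(axis=0)
        s2d = (wd[:, None, None] * Zs[deaths][:, :, None] * Zs[deaths][:, None, :]).sum(axis=0)
        ll += eta[deaths].sum()
        U += Zs[deaths].sum(axis=0)
        for l in range(d):
            f = l / d
            phi0 = s0r - f * s0d
            phi1 = s1r - f * s1d
            phi2 = s2r - f * s2d
            ll -= np.log(phi0)
            U -= phi1 / phi0
            I += phi2 / phi0 - np.outer(phi1, phi1) / phi0 ** 2
    return ll, U, I


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Newton-Raphson maximization of the Efron partial likelihood.

    Converges on the score norm; diverging estimates (|beta| > 15, monotone
    likelihood / separation) are flagged non-estimable rather than raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != time.size:
        Z = Z.T
    if np.any(time <= 0):
        raise ValidationError("follow-up times must be positive")
    if set(np.unique(event)) - {0.0, 1.0}:
        raise ValidationError("event indicator must be 0/1")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValidationError("need at least 2 events")
    sds = Z.std(axis=0)
    if np.any(sds < 1e-12):
        raise ValidationError(f"constant covariate at column {int(np.argmin(sds))}")

    order, blocks = _event_blocks(time, event)
    p = Z.shape[1]
    beta = np.zeros(p)
    ll, U, I = _cox_quantities(Z, order, blocks, beta)
    ll_null = ll
    converged = False
    estimable = True
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            estimable = False
            break
        new_beta = beta + step
        new_ll, new_U, new_I = _cox_quantities(Z, order, blocks, new_beta)
        halves = 0
        while new_ll < ll - 1e-12 and halves < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_U, new_I = _cox_quantities(Z, order, blocks, new_beta)
            halves += 1
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
        if np.any(np.abs(beta) > 15):
            estimable = False
            warnings.warn("diverging Cox estimate (|beta| > 15); flagged non-estimable")
            break
        if np.linalg.norm(U) < tol:
            converged = True
            break
    if estimable and not converged and np.linalg.norm(U) > 1e-4:
        raise ValidationError("Cox Newton-Raphson failed to converge")
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        estimable = False
    return CoxFit(beta, cov, float(ll), float(ll_null), float(np.linalg.norm(U)),
                  converged, estimable, n_events)


# ---------------------------------------------------------------------------
# residuals and assumption checks
# ---------------------------------------------------------------------------

def schoenfeld_residuals(time, event, Z, fit: CoxFit):
    """Per-event covariate residuals z_k - E[z | risk set] and event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != time.size:
        Z = Z.T
    order, blocks = _event_blocks(time, event)
    Zs = Z[order]
    ts = time[order]
    eta = np.clip(Zs @ fit.beta, -200, 200)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Zs)[::-1], axis=0)[::-1]
    resid, times = [], []
    for start, deaths in blocks:
        zbar = S1[start] / S0[start]
        for k in deaths:
            resid.append(Zs[k] - zbar)
            times.append(ts[k])
    return np.array(resid), np.array(times)


def km_transform(time: np.ndarray, event: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    """1 - left-continuous Kaplan-Meier estimate evaluated at the event times."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv = 1.0
    km_at: dict[float, float] = {}
    for ut in uniq:
        km_at[ut] = surv                    # left-continuous: value just before ut
        at_risk = (t >= ut).sum()
        d = ((t == ut) & (e == 1)).sum()
        surv *= 1.0 - d / at_risk
    return np.array([1.0 - km_at[et] for et in event_times])


def ph_test(time, event, Z, fit: CoxFit) -> np.ndarray:
    """Proportional-hazards p-value per covariate.

    Correlation-style score test of the scaled Schoenfeld residuals against
    the Kaplan-Meier transform of event time; chi-square with 1 df.
    """
    resid, ev_times = schoenfeld_residuals(time, event, Z, fit)
    d = resid.shape[0]
    g = km_transform(np.asarray(time, float), np.asarray(event, float), ev_times)
    gc = g - g.mean()
    scaled = d * resid @ fit.cov + fit.beta[None, :]
    pvals = np.empty(Z.shape[1] if Z.ndim == 2 else 1)
    denom_g = float((gc ** 2).sum())
    for j in range(pvals.size):
        num = float(gc @ scaled[:, j]) ** 2
        den = d * fit.cov[j, j] * denom_g
        chi = num / den if den > 0 else 0.0
        pvals[j] = float(stats.chi2.sf(chi, 1))
    return pvals


def natural_spline_basis(x: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """3-column natural cubic spline basis.

    Knots default to (min, q25, q75, max); the basis is linear beyond the
    boundary knots (the standard truncated-power natural-spline construction).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = np.quantile(x, [0.0, 0.25, 0.75, 1.0])
    knots = np.unique(np.asarray(knots, dtype=float))
    if knots.size < 3:
        raise ValidationError("need >= 3 distinct knots for a natural spline")
    K = knots.size

    def d(k_idx):
        num = (np.maximum(x - knots[k_idx], 0) ** 3
               - np.maximum(x - knots[-1], 0) ** 3)
        return num / (knots[-1] - knots[k_idx])

    cols = [x]
    dlast = d(K - 2)
    for k_idx in range(K - 2):
        cols.append(d(k_idx) - dlast)
    return np.column_stack(cols)


def linearity_test(time, event, Z, col: int) -> float:
    """LRT p-value: linear entry of covariate ``col`` vs its natural-spline entry."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != np.asarray(time).size:
        Z = Z.T
    lin = cox_fit(time, event, Z)
    spline = natural_spline_basis(Z[:, col])
    Z_ext = np.column_stack([spline, np.delete(Z, col, axis=1)])
    ext = cox_fit(time, event, Z_ext)
    df = Z_ext.shape[1] - Z.shape[1]
    lrt = 2.0 * (ext.loglik - lin.loglik)
    return float(stats.chi2.sf(max(lrt, 0.0), df))


def assumption_checks(
    time, event, Z, fit: CoxFit, continuous: list[bool] | None = None
) -> pd.DataFrame:
    """Per-covariate PH and (continuous only) linearity check p-values."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != np.asarray(time).size:
        Z = Z.T
    if int(np.asarray(event).sum()) < 3:
        warnings.warn("fewer than 3 events; assumption checks skipped")
        return pd.DataFrame({"ph_p": [np.nan] * Z.shape[1],
                             "linearity_p": [np.nan] * Z.shape[1]})
    if continuous is None:
        continuous = [np.unique(Z[:, j]).size > 5 for j in range(Z.shape[1])]
    ph_p = ph_test(time, event, Z, fit)
    lin_p = []
    for j in range(Z.shape[1]):
        if continuous[j]:
            try:
                lin_p.append(linearity_test(time, event, Z, j))
            except ValidationError:
                lin_p.append(np.nan)
        else:
            lin_p.append(np.nan)   # not applicable to categorical covariates
    return pd.DataFrame({"ph_p": ph_p, "linearity_p": lin_p})


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def survival_records(meta: SampleMetadata) -> pd.DataFrame:
    if not meta.has_survival:
        raise ValidationError("metadata lacks the survival triplet (age, outcome.time, outcome)")
    return pd.DataFrame(
        {
            "time": meta.table["outcome.time"].astype(float),
            "event": meta.table["outcome"].astype(float),
            "age": meta.table["age"].astype(float),
        },
        index=meta.table.index,
    )


def survival_screen(
    X: np.ndarray,
    variable_ids: list[str],
    time: np.ndarray,
    event: np.ndarray,
    adjust: np.ndarray | None = None,
    adjust_names: list[str] | None = None,
    fdr_cut: float = 0.05,
    check_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One Cox model per variable with shared adjustment covariates.

    Adjustment covariates failing the linearity check (at ``check_alpha``)
    enter through a natural cubic spline. Returns the per-variable table
    (logHR, se, CI, p, FDR) and the per-covariate check table with the
    spline flags. Non-estimable variables carry NaN and are excluded from
    the FDR computation.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)

    checks = pd.DataFrame(columns=["covariate", "ph_p", "linearity_p", "spline"])
    adj_design = None
    if adjust is not None and np.size(adjust):
        adjust = np.atleast_2d(np.asarray(adjust, dtype=float))
        if adjust.shape[0] != time.size:
            adjust = adjust.T
        names = adjust_names or [f"cov{j}" for j in range(adjust.shape[1])]
        base = cox_fit(time, event, adjust)
        chk = assumption_checks(time, event, adjust, base)
        spline_flags = (chk["linearity_p"] < check_alpha).fillna(False)
        checks = pd.DataFrame(
            {
                "covariate": names,
                "ph_p": chk["ph_p"],
                "linearity_p": chk["linearity_p"],
                "spline": spline_flags,
            }
        )
        pieces = []
        for j in range(adjust.shape[1]):
            if spline_flags.iloc[j]:
                pieces.append(natural_spline_basis(adjust[:, j]))
            else:
                pieces.append(adjust[:, [j]])
        adj_design = np.column_stack(pieces)

    rows = []
    for i, vid in enumerate(variable_ids):
        Z = X[[i]].T if adj_design is None else np.column_stack([X[i], adj_design])
        try:
            fit = cox_fit(time, event, Z)
        except ValidationError:
            fit = None
        if fit is None or not fit.estimable:
            rows.append({"id": vid, "logHR": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
            continue
        b = float(fit.beta[0])
        se = float(np.sqrt(fit.cov[0, 0]))
        z = b / se
        rows.append(
            {
                "id": vid,
                "logHR": b,
                "se": se,
                "ci_low": b - 1.959963984540054 * se,
                "ci_high": b + 1.959963984540054 * se,
                "p": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    testable = table["p"].notna().to_numpy()
    fdr = np.full(len(table), np.nan)
    if testable.any():
        fdr[testable] = bh_adjust(table.loc[testable, "p"].to_numpy())
    table["FDR"] = fdr
    table["log2HR"] = table["logHR"] / np.log(2.0)   # forest plots use the log2 scale
    return table, checks
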