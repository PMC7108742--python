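"""Distributional diagnostics on randomly selected variables.

For each inspected variable: sample skewness/kurtosis, a bootstrap
skewness-kurtosis cloud (the Cullen-Frey display), maximum-likelihood fits
of candidate distributions, and QQ/PP coordinates for the best candidate.
Kurtosis is reported raw (normal reference 3), matching Cullen-Frey axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_meta import ValidationError

CANDIDATES = ("normal", "lognormal", "weibull", "gamma", "poisson", "binomial")


@dataclass
class DistFit:
    name: str
    params: dict[str, float]
    loglik: float


@dataclass
class DistFitReport:
    variable_id: str
    skewness: float
    kurtosis: float                     # raw, normal = 3
    fits: list[DistFit] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    bootstrap: np.ndarray | None = None  # replicates x 2 (skewness, kurtosis)
    qq: pd.DataFrame | None = None
    pp: pd.DataFrame | None = None

    @property
    def best_fit(self) -> DistFit | None:
        return max(self.fits, key=lambda f: f.loglik) if self.fits else None


def sample_moments(x: np.ndarray) -> tuple[float, float]:
    """Sample skewness m3/m2^1.5 and raw kurtosis m4/m2^2 (n denominators)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("need n >= 4 for moment estimates")
    m = x.mean()
    c = x - m
    m2 = float((c ** 2).mean())
    if m2 <= 0:
        raise ValidationError("constant vector: moments undefined")
    m3 = float((c ** 3).mean())
    m4 = float((c ** 4).mean())
    return m3 / m2 ** 1.5, m4 / m2 ** 2


def fit_candidate_distributions(
    x: np.ndarray, candidates: tuple[str, ...] = CANDIDATES
) -> tuple[list[DistFit], dict[str, str]]:
    """Maximum-likelihood fits; support violations skip the candidate.

    Closed forms: normal (mean, sd with n denominator), lognormal (moments of
    log x), poisson (mean), binomial success probability with size fixed at
    max(x). Gamma and weibull are fit numerically with location pinned at 0.
    """
    x = np.asarray(x, dtype=float)
    fits: list[DistFit] = []
    skipped: dict[str, str] = {}
    is_count = np.all(x >= 0) and np.all(x == np.round(x))
    for name in candidates:
        if name == "normal":
            mu, sd = x.mean(), x.std()
            if sd <= 0:
                skipped[name] = "zero variance"
                continue
            ll = float(stats.norm.logpdf(x, mu, sd).sum())
            fits.append(DistFit(name, {"mean": mu, "sd": sd}, ll))
        elif name == "lognormal":
            if np.any(x <= 0):
                skipped[name] = "requires x > 0"
                continue
            lx = np.log(x)
            mu, sd = lx.mean(), lx.std()
            if sd <= 0:
                skipped[name] = "zero variance on log scale"
                continue
            ll = float(stats.lognorm.logpdf(x, sd, scale=np.exp(mu)).sum())
            fits.append(DistFit(name, {"meanlog": mu, "sdlog": sd}, ll))
        elif name == "weibull":
            if np.any(x <= 0):
                skipped[name] = "requires x > 0"
                continue
            shape, _, scale = stats.weibull_min.fit(x, floc=0)
            ll = float(stats.weibull_min.logpdf(x, shape, scale=scale).sum())
            fits.append(DistFit(name, {"shape": shape, "scale": scale}, ll))
        elif name == "gamma":
            if np.any(x <= 0):
                skipped[name] = "requires x > 0"
                continue
            shape, _, scale = stats.gamma.fit(x, floc=0)
            ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
            fits.append(DistFit(name, {"shape": shape, "scale": scale}, ll))
        elif name == "poisson":
            if not is_count:
                skipped[name] = "requires non-negative integers"
                continue
            lam = x.mean()
            ll = float(stats.poisson.logpmf(x.astype(int), lam).sum())
            fits.append(DistFit(name, {"lambda": lam}, ll))
        elif name == "binomial":
            if not is_count:
                skipped[name] = "requires non-negative integers"
                continue
            size = int(x.max())
            if size == 0:
                skipped[name] = "all zero"
                continue
            prob = float(x.mean() / size)  # MLE of p at fixed size
            ll = float(stats.binom.logpmf(x.astype(int), size, prob).sum())
            fits.append(DistFit(name, {"size": size, "prob": prob}, ll))
        else:
            skipped[name] = "unknown candidate"
    return fits, skipped


def bootstrap_cullen_frey(
    x: np.ndarray, replicates: int = 500, seed: int = 0
) -> np.ndarray:
    """Bootstrap (skewness, kurtosis) pairs; constant resamples are redrawn
    (up to 100 retries each)."""
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValidationError("need n >= 10 for the bootstrap cloud")
    rng = np.random.default_rng(seed)
    pairs = np.empty((replicates, 2))
    for r in range(replicates):
        for attempt in range(100):
            resample = rng.choice(x, size=x.size, replace=True)
            if np.ptp(resample) > 0:
                pairs[r] = sample_moments(resample)
                break
        else:
            raise ValidationError("bootstrap kept producing constant resamples")
    return pairs


def _qq_pp(x: np.ndarray, fit: DistFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = x.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    xs = np.sort(x)
    dist = {
        "normal": lambda: stats.norm(fit.params["mean"], fit.params["sd"]),
        "lognormal": lambda: stats.lognorm(fit.params["sdlog"],
                                           scale=np.exp(fit.params["meanlog"])),
        "weibull": lambda: stats.weibull_min(fit.params["shape"],
                                             scale=fit.params["scale"]),
        "gamma": lambda: stats.gamma(fit.params["shape"], scale=fit.params["scale"]),
        "poisson": lambda: stats.poisson(fit.params["lambda"]),
        "binomial": lambda: stats.binom(int(fit.params["size"]), fit.params["prob"]),
    }[fit.name]()
    qq = pd.DataFrame({"theoretical": dist.ppf(probs), "empirical": xs})
    pp = pd.DataFrame({"theoretical": probs, "empirical": dist.cdf(xs)})
    return qq, pp


def distcheck_report(
    x: np.ndarray,
    variable_id: str,
    candidates: tuple[str, ...] = CANDIDATES,
    replicates: int = 500,
    seed: int = 0,
) -> DistFitReport:
    """Full diagnostic bundle for one variable."""
    skew, kurt = sample_moments(x)
    fits, skipped = fit_candidate_distributions(x, candidates)
    boot = bootstrap_cullen_frey(x, replicates, seed) if replicates > 0 else np.empty((0, 2))
    report = DistFitReport(variable_id, skew, kurt, fits, skipped, boot)
    if report.best_fit is not None:
        report.qq, report.pp = _qq_pp(np.asarray(x, dtype=float), report.best_fit)
    return report


def distcheck_random_variables(
    X: np.ndarray,
    variable_ids: list[str],
    n_variables: int = 10,
    replicates: int = 500,
    seed: int = 0,
) -> list[DistFitReport]:
    """Diagnostics for ``n_variables`` randomly selected rows (seeded)."""
    rng = np.random.default_rng(seed)
    n = min(n_variables, len(variable_ids))
    chosen = rng.choice(len(variable_ids), size=n, replace=False)
    reports = []
    for i in chosen:
        try:
            reports.append(
                distcheck_report(X[i], variable_ids[i], replicates=replicates,
                                 seed=seed + int(i))
            )
        except ValidationError as exc:
            warnings.warn(f"variable {variable_ids[i]!r} skipped: {exc}")
    return reports
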