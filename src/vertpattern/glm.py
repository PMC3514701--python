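"""Severity-association inference: logit-link binomial GLMs and friends.

The workhorse is a hand-written iteratively reweighted least squares (IRLS)
fit of a Bernoulli GLM with logit link.  Severity enters as a single
numeric covariate over the scale values {0, 1, 3, 4, 6, 7, 8, 9}; sex and
gestational-age bands may be added as factors.  On top of the fits sit an
overdispersion check (Pearson χ²/df), Wald comparisons of slopes between
outcome groups via a joint interaction model, likelihood-ratio tests of
severity × factor interactions, frequency-trend correlations and pattern ×
covariate χ² tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

MAX_ITER = 100
DEV_TOL = 1e-8
#: coefficient magnitude beyond which we declare (quasi-)separation
SEPARATION_BOUND = 30.0


class GLMError(ValueError):
    pass


@dataclass
class GLMFit:
    """Converged (or flagged) logit-link Bernoulli GLM."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    deviance: float
    pearson_chi2: float
    n: int
    df_resid: int
    converged: bool
    iterations: int
    separation: bool = False
    cov: np.ndarray = field(default=None, repr=False)

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def coef_of(self, term: str) -> float:
        return float(self.coef[self.term_index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.term_index(term)])

    def p_of(self, term: str) -> float:
        return float(self.p[self.term_index(term)])

    @property
    def dispersion_ratio(self) -> float:
        if self.df_resid <= 0:
            raise GLMError("no residual degrees of freedom")
        return self.pearson_chi2 / self.df_resid


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def irls_logit(X: np.ndarray, y: np.ndarray, terms: list[str] | None = None) -> GLMFit:
    """Fit a Bernoulli GLM with logit link by IRLS.

    Iterates weighted least squares on the working response
    ``z = eta + (y - mu) / w`` with weights ``w = mu (1 - mu)`` until the
    relative deviance change drops below 1e-8 (max 100 iterations).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise GLMError("design/response shape mismatch")
    n, p = X.shape
    if y.sum() == 0 or y.sum() == n:
        raise GLMError("outcome has no events or no non-events")
    terms = terms or [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    dev = _bernoulli_deviance(y, np.full(n, y.mean()))
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise GLMError(f"singular information matrix: {err}") from err
        new_dev = _bernoulli_deviance(y, expit(X @ beta))
        if abs(dev - new_dev) / (abs(new_dev) + 0.1) < DEV_TOL:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    pearson = float(np.sum((y - mu) ** 2 / w))
    # a perfect fit (deviance ~ 0) is the signature of complete separation
    separation = (
        bool(np.any(np.abs(beta) > SEPARATION_BOUND)) or not converged or dev < 1e-6
    )
    if separation:
        warnings.warn(
            "possible separation or non-convergence; coefficients unreliable",
            stacklevel=2,
        )
    return GLMFit(
        terms=list(terms),
        coef=beta,
        se=se,
        z=zstat,
        p=pvals,
        deviance=dev,
        pearson_chi2=pearson,
        n=n,
        df_resid=n - p,
        converged=converged,
        iterations=it,
        separation=separation,
        cov=cov,
    )


def _factor_dummies(values: np.ndarray, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values).tolist())
    cols = [(np.asarray(values) == lvl).astype(float) for lvl in levels[1:]]
    names = [f"{prefix}[{lvl}]" for lvl in levels[1:]]
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def fit_severity_glm(
    outcome: np.ndarray,
    severity: np.ndarray,
    sex: np.ndarray | None = None,
    age_band: np.ndarray | None = None,
) -> GLMFit:
    """Per-outcome severity association: logit(P) = a + b·severity (+ factors).

    ``outcome`` may contain NaN for subjects whose status is non-available;
    those are excluded from this outcome's denominator only.
    """
    outcome = np.asarray(outcome, dtype=float)
    severity = np.asarray(severity, dtype=float)
    keep = ~np.isnan(outcome)
    outcome, severity = outcome[keep], severity[keep]
    parts = [np.ones_like(severity), severity]
    names = ["intercept", "severity"]
    for values, prefix in ((sex, "sex"), (age_band, "age")):
        if values is not None:
            dummies, dnames = _factor_dummies(np.asarray(values)[keep], prefix)
            if dummies.shape[1]:
                parts.append(dummies)
                names.extend(dnames)
    X = np.column_stack(parts)
    if np.allclose(severity.std(), 0):
        raise GLMError("no severity variance in this cohort")
    return irls_logit(X, outcome, names)


@dataclass
class OverdispersionCheck:
    ratio: float
    df: int
    overdispersed: bool
    threshold: float


def overdispersion_check(fit: GLMFit, threshold: float = 1.5) -> OverdispersionCheck:
    """Pearson χ² per residual degree of freedom, with a verdict."""
    ratio = fit.dispersion_ratio  # raises on df = 0
    return OverdispersionCheck(
        ratio=ratio, df=fit.df_resid, overdispersed=ratio > threshold, threshold=threshold
    )


@dataclass
class SlopeComparison:
    group_a: str
    group_b: str
    slope_a: float
    slope_b: float
    difference: float
    se_difference: float
    statistic: float
    p: float


def compare_slopes(
    outcome_a: np.ndarray,
    outcome_b: np.ndarray,
    severity: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
) -> SlopeComparison:
    """Wald test of equal severity slopes for two outcome groups.

    The two outcome vectors (over the same subjects and severity values)
    are stacked into a joint model with a group main effect and a
    group × severity interaction; the Wald statistic on the interaction
    contrast tests slope equality.
    """
    ya = np.asarray(outcome_a, dtype=float)
    yb = np.asarray(outcome_b, dtype=float)
    sev = np.asarray(severity, dtype=float)
    keep_a, keep_b = ~np.isnan(ya), ~np.isnan(yb)
    y = np.concatenate([ya[keep_a], yb[keep_b]])
    s = np.concatenate([sev[keep_a], sev[keep_b]])
    g = np.concatenate([np.zeros(keep_a.sum()), np.ones(keep_b.sum())])
    X = np.column_stack([np.ones_like(s), s, g, g * s])
    fit = irls_logit(X, y, ["intercept", "severity", "group", "group:severity"])
    diff = fit.coef_of("group:severity")
    se = fit.se_of("group:severity")
    slope_a = fit.coef_of("severity")
    return SlopeComparison(
        group_a=labels[0],
        group_b=labels[1],
        slope_a=slope_a,
        slope_b=slope_a + diff,
        difference=diff,
        se_difference=se,
        statistic=diff / se,
        p=fit.p_of("group:severity"),
    )


@dataclass
class InteractionLRT:
    chi2: float
    df: int
    p: float
    levels: list[str]


def interaction_lrt(
    outcomes_by_level: dict[str, np.ndarray], severity: np.ndarray
) -> InteractionLRT:
    """Likelihood-ratio test of a common severity slope across factor levels.

    Each level contributes one stacked binary outcome vector over the same
    subjects.  The full model has severity × level interactions; the null
    model a single slope.  df = levels − 1.
    """
    sev = np.asarray(severity, dtype=float)
    levels, ys, ss = [], [], []
    for lvl, y in outcomes_by_level.items():
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        if keep.sum() == 0 or np.nansum(y) == 0:
            warnings.warn(f"dropping empty factor level {lvl!r}", stacklevel=2)
            continue
        levels.append(lvl)
        ys.append(y[keep])
        ss.append(sev[keep])
    if len(levels) < 2:
        raise GLMError("need at least two non-empty factor levels")
    y = np.concatenate(ys)
    s = np.concatenate(ss)
    lvl_idx = np.concatenate([np.full(len(v), i) for i, v in enumerate(ys)])

    dummies, dnames = _factor_dummies(lvl_idx, "level")
    X0 = np.column_stack([np.ones_like(s), s, dummies])
    X1 = np.column_stack([X0, dummies * s[:, None]])
    fit0 = irls_logit(X0, y, ["intercept", "severity", *dnames])
    fit1 = irls_logit(X1, y, ["intercept", "severity", *dnames,
                              *[f"{d}:severity" for d in dnames]])
    chi2 = max(fit0.deviance - fit1.deviance, 0.0)
    df = len(levels) - 1
    return InteractionLRT(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), levels=levels)


@dataclass
class TrendResult:
    r: float
    p: float
    n_points: int


def freq_trend(frequencies: np.ndarray, band_index: np.ndarray | None = None) -> TrendResult:
    """Pearson correlation of a frequency against an ordered band index."""
    freqs = np.asarray(frequencies, dtype=float)
    idx = np.arange(len(freqs), dtype=float) if band_index is None else np.asarray(band_index, dtype=float)
    if len(freqs) < 3:
        raise GLMError("need at least 3 points for a trend")
    if np.allclose(freqs.std(), 0) or np.allclose(idx.std(), 0):
        raise GLMError("zero variance: trend correlation undefined")
    r, p = stats.pearsonr(freqs, idx)
    return TrendResult(r=float(r), p=float(p), n_points=len(freqs))


@dataclass
class ChisqResult:
    chi2: float
    df: int
    p: float
    warning: str | None = None
    simulated_p: float | None = None


def pattern_covariate_chisq(
    patterns: np.ndarray,
    covariate: np.ndarray,
    rng: np.random.Generator | None = None,
    n_sim: int = 2000,
) -> ChisqResult:
    """Pearson χ² of the pattern distribution across covariate bands.

    When expected counts are small (< 5) a warning is attached and, if an
    ``rng`` is supplied, a Monte-Carlo permutation p-value is added.
    """
    table = pd.crosstab(pd.Series(patterns), pd.Series(covariate))
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    chi2, p, df, expected = stats.chi2_contingency(table)
    warning = None
    simulated = None
    if (expected < 5).any():
        warning = "expected counts < 5; asymptotic p may be unreliable"
        if rng is not None:
            obs = np.asarray(table)
            flat_p = stats.contingency.expected_freq(obs) / obs.sum()
            count = 0
            with np.errstate(divide="ignore", invalid="ignore"):
                for _ in range(n_sim):
                    sim = rng.multinomial(obs.sum(), flat_p.ravel()).reshape(obs.shape)
                    exp_sim = stats.contingency.expected_freq(sim)
                    sim_chi2 = np.nansum((sim - exp_sim) ** 2 / exp_sim)
                    count += sim_chi2 >= chi2
            simulated = (count + 1) / (n_sim + 1)
    return ChisqResult(chi2=float(chi2), df=int(df), p=float(p),
                       warning=warning, simulated_p=simulated)
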