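"""Pearson and partial correlations with Fisher-z confidence intervals.

The partial correlation of x and y given covariates is the correlation of
the OLS residuals of x and y on the covariates; its two-tailed p comes
from the t distribution with n - 2 - k degrees of freedom, and the CI from
the Fisher z transform with an effective sample size reduced by k:
tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3 - k)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "fisher_ci", "pearson_fisher", "partial_corr"]


@dataclass
class CorrelationResult:
    r: float
    n: int
    k: int
    df: int
    p: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __str__(self) -> str:  # compact report, Table-style
        tag = f"pcc (k={self.k})" if self.k else "r"
        return (f"{tag} = {self.r:.3f} (p = {self.p:.4g}) "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}]")


def fisher_ci(r: float, n: int, k: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a (partial) correlation."""
    if abs(r) >= 1.0:
        raise ValueError("|r| = 1: Fisher interval degenerate")
    if n - 3 - k <= 0:
        raise ValueError("sample too small for a Fisher interval")
    z = np.arctanh(r)
    half = stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3 - k)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _corr_p(r: float, df: int) -> float:
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson_fisher(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Zero-order Pearson correlation with t-based p and Fisher-z CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1 exactly: degenerate")
    df = n - 2
    lo, hi = fisher_ci(r, n, 0, alpha)
    return CorrelationResult(r=r, n=n, k=0, df=df, p=_corr_p(r, df),
                             ci_low=lo, ci_high=hi, alpha=alpha)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_corr(x, y, covariates=None, alpha: float = 0.05) -> CorrelationResult:
    """Partial Pearson correlation adjusting for ``covariates`` (n x k).

    With no covariates this reduces exactly to :func:`pearson_fisher`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None:
        return pearson_fisher(x, y, alpha)
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[1] == 0:
        return pearson_fisher(x, y, alpha)
    n, k = C.shape
    if x.size != n or y.size != n:
        raise ValueError("covariate rows must match x and y")
    if n < k + 4:
        raise ValueError("too few observations for the requested adjustment")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance after adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        raise ValueError("|r| = 1 exactly: degenerate")
    df = n - 2 - k
    lo, hi = fisher_ci(r, n, k, alpha)
    return CorrelationResult(r=r, n=n, k=k, df=df, p=_corr_p(r, df),
                             ci_low=lo, ci_high=hi, alpha=alpha)
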