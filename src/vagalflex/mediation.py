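"""Single-mediator path analysis with a Monte Carlo indirect-effect test.

The product-of-coefficients approach fits three ordinary-least-squares
models (all with intercept and optional covariates):

* Model 1:  y ~ x            -> total effect, path c
* Model 2:  m ~ x            -> path a
* Model 3:  y ~ x + m        -> direct effect c' and path b

The indirect (mediational) effect is a*b.  Its sampling distribution is
approximated by drawing a* ~ N(a_hat, se_a^2) and b* ~ N(b_hat, se_b^2)
independently (they come from different fitted models) and forming a*b*;
the percentile interval of the draws is the confidence interval and the
two-tailed p is 2*min(P(product <= 0), P(product >= 0)).

Classification follows the total/direct-effect logic: *full* mediation
when c and the indirect effect are significant but c' is not; *partial*
when all three are; *none* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MediationModel", "MediationResults", "fit_path_models", "mc_indirect"]


def fit_path_models(data: pd.DataFrame, x: str, mediator: str, y: str,
                    covariates=()):
    """Fit the three path OLS models; returns (model1, model2, model3) results."""
    cols = [x, mediator, y, *covariates]
    d = data[cols].dropna()
    n = len(d)
    if n <= len(covariates) + 3:
        raise ValueError("too few complete cases for the path models")

    def _ols(dv, predictors):
        X = sm.add_constant(d[predictors], has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("rank-deficient design in path model")
        return sm.OLS(d[dv], X).fit()

    m1 = _ols(y, [x, *covariates])            # path c
    m2 = _ols(mediator, [x, *covariates])     # path a
    m3 = _ols(y, [x, mediator, *covariates])  # paths c', b
    return m1, m2, m3


def mc_indirect(a: float, se_a: float, b: float, se_b: float,
                n_sims: int = 10_000, seed=None, alpha: float = 0.05,
                return_draws: bool = False):
    """Monte Carlo percentile CI and two-tailed p for the indirect effect a*b."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(a, se_a, n_sims) * rng.normal(b, se_b, n_sims)
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    p_le = np.mean(draws <= 0.0)
    p_ge = np.mean(draws >= 0.0)
    p = float(min(1.0, 2.0 * min(p_le, p_ge)))
    if return_draws:
        return (float(lo), float(hi)), p, draws
    return (float(lo), float(hi)), p


@dataclass
class MediationResults:
    """Estimates, uncertainties and the Monte Carlo test for one mediation."""

    x: str
    mediator: str
    y: str
    covariates: tuple
    n: int
    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    c: float
    se_c: float
    p_c: float
    c_prime: float
    se_c_prime: float
    p_c_prime: float
    indirect_point: float
    mc_ci_low: float
    mc_ci_high: float
    mc_p: float
    n_sims: int
    seed: object
    alpha: float
    classification: str
    model1: object = field(repr=False, default=None)
    model2: object = field(repr=False, default=None)
    model3: object = field(repr=False, default=None)
    indirect_draws: np.ndarray = field(repr=False, default=None)

    @property
    def indirect_significant(self) -> bool:
        return self.mc_p < self.alpha

    def to_dict(self) -> dict:
        keys = ["x", "mediator", "y", "n", "a", "se_a", "p_a", "b", "se_b",
                "p_b", "c", "se_c", "p_c", "c_prime", "se_c_prime",
                "p_c_prime", "indirect_point", "mc_ci_low", "mc_ci_high",
                "mc_p", "n_sims", "alpha", "classification"]
        out = {k: getattr(self, k) for k in keys}
        out["covariates"] = list(self.covariates)
        out["seed"] = None if self.seed is None else int(self.seed)
        return out

    def summary(self) -> str:
        lines = [
            f"Mediation: {self.x} -> {self.mediator} -> {self.y}",
            f"n = {self.n}, covariates: {', '.join(self.covariates) or 'none'}",
            "-" * 64,
            f"{'path':<10}{'coef':>10}{'SE':>10}{'p':>10}",
            f"{'a':<10}{self.a:>10.4f}{self.se_a:>10.4f}{self.p_a:>10.4f}",
            f"{'b':<10}{self.b:>10.4f}{self.se_b:>10.4f}{self.p_b:>10.4f}",
            f"{'c':<10}{self.c:>10.4f}{self.se_c:>10.4f}{self.p_c:>10.4f}",
            f"{'c_prime':<10}{self.c_prime:>10.4f}{self.se_c_prime:>10.4f}"
            f"{self.p_c_prime:>10.4f}",
            "-" * 64,
            f"indirect (a*b) = {self.indirect_point:.4f}, "
            f"{100 * (1 - self.alpha):.0f}% MC CI "
            f"[{self.mc_ci_low:.4f}, {self.mc_ci_high:.4f}], "
            f"p = {self.mc_p:.4f} ({self.n_sims} simulations)",
            f"classification: {self.classification} mediation"
            if self.classification != "none" else "classification: no mediation",
        ]
        return "\n".join(lines)

    def plot_indirect(self, ax=None):
        """Histogram of the Monte Carlo indirect-effect draws with CI bounds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.indirect_draws, bins=60, color="#4878a8", alpha=0.8)
        for v, style in ((self.indirect_point, "-"),
                         (self.mc_ci_low, "--"), (self.mc_ci_high, "--")):
            ax.axvline(v, color="k", linestyle=style, linewidth=1)
        ax.axvline(0.0, color="r", linewidth=1)
        ax.set_xlabel(f"indirect effect of {self.x} on {self.y}")
        ax.set_ylabel("Monte Carlo draws")
        return ax


class MediationModel:
    """Product-of-coefficients mediation model on a profiles DataFrame.

    Parameters
    ----------
    data : DataFrame with one row per subject.
    x, mediator, y : column names of predictor, mediator and outcome.
    covariates : columns entered in all three models.
    standardize : z-score all variables before fitting (for recovery of
        standardized path coefficients from simulations).
    """

    def __init__(self, data: pd.DataFrame, x: str, mediator: str, y: str,
                 covariates=(), standardize: bool = False):
        self.x, self.mediator, self.y = x, mediator, y
        self.covariates = tuple(covariates)
        cols = [x, mediator, y, *self.covariates]
        d = data[cols].dropna().reset_index(drop=True).astype(float)
        if standardize:
            d = (d - d.mean()) / d.std(ddof=1)
        self.data = d

    @classmethod
    def from_dataframe(cls, data, x, mediator, y, covariates=(), **kw):
        return cls(data, x, mediator, y, covariates, **kw)

    def fit(self, n_sims: int = 10_000, seed=None, alpha: float = 0.05) -> MediationResults:
        m1, m2, m3 = fit_path_models(self.data, self.x, self.mediator,
                                     self.y, self.covariates)
        a, se_a, p_a = m2.params[self.x], m2.bse[self.x], m2.pvalues[self.x]
        b, se_b, p_b = (m3.params[self.mediator], m3.bse[self.mediator],
                        m3.pvalues[self.mediator])
        c, se_c, p_c = m1.params[self.x], m1.bse[self.x], m1.pvalues[self.x]
        cp, se_cp, p_cp = m3.params[self.x], m3.bse[self.x], m3.pvalues[self.x]
        (lo, hi), p_mc, draws = mc_indirect(a, se_a, b, se_b, n_sims=n_sims,
                                            seed=seed, alpha=alpha,
                                            return_draws=True)
        indirect_sig = p_mc < alpha
        if p_c < alpha and indirect_sig and p_cp >= alpha:
            cls_ = "full"
        elif p_c < alpha and indirect_sig and p_cp < alpha:
            cls_ = "partial"
        else:
            cls_ = "none"
        return MediationResults(
            x=self.x, mediator=self.mediator, y=self.y,
            covariates=self.covariates, n=int(m1.nobs),
            a=float(a), se_a=float(se_a), p_a=float(p_a),
            b=float(b), se_b=float(se_b), p_b=float(p_b),
            c=float(c), se_c=float(se_c), p_c=float(p_c),
            c_prime=float(cp), se_c_prime=float(se_cp), p_c_prime=float(p_cp),
            indirect_point=float(a * b), mc_ci_low=lo, mc_ci_high=hi,
            mc_p=p_mc, n_sims=n_sims, seed=seed, alpha=alpha,
            classification=cls_, model1=m1, model2=m2, model3=m3,
            indirect_draws=draws,
        )
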