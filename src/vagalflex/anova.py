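"""Mixed-design ANOVA with generalized eta squared, plus simple effects.

The design is the classic psychophysiology layout: every subject provides
a complete set of within-subject cells (all combinations of 2-level
within factors, e.g. congruency x emotion x social), and subjects belong
to one between-subjects group (vagal-flexibility tertile).  The univariate
decomposition is computed stratum by stratum:

* between-subjects stratum — subject means; the group term is tested
  against subjects-within-groups error;
* one stratum per within effect — each subject's contrast score for that
  effect; the effect and its interaction with the group term are tested
  against the effect x subjects-within-groups error.

The group term enters either as a single-df linear trend across ordered
tertiles (``flex_coding="linear"``, the default) or as a categorical
factor (``"categorical"``).  Generalized eta squared for an effect is
SS_effect / (SS_effect + sum of every error SS in the model), the measure
appropriate for mixed designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedAnovaModel",
    "MixedAnovaResults",
    "anova_f",
    "generalized_eta_squared",
    "paired_contrast",
]

_TERTILE_ORDER = ("low", "medium", "high")


def anova_f(ss_num: float, df_num: int, ss_den: float, df_den: int) -> float:
    """F ratio from numerator/denominator sums of squares and dfs."""
    if min(ss_num, ss_den) < 0 or df_num < 1 or df_den < 1:
        raise ValueError("invalid sums of squares or degrees of freedom")
    return (ss_num / df_num) / (ss_den / df_den)


def generalized_eta_squared(ss_effect: float, error_ss) -> float:
    """ges = SS_effect / (SS_effect + sum over all error strata)."""
    total_err = float(np.sum(np.asarray(list(error_ss), dtype=float)))
    if ss_effect < 0 or total_err < 0:
        raise ValueError("sums of squares must be nonnegative")
    return ss_effect / (ss_effect + total_err)


def _rss(y: np.ndarray, X: np.ndarray | None) -> float:
    if X is None or X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _group_order(levels) -> list:
    lv = list(levels)
    if set(lv) <= set(_TERTILE_ORDER):
        return [g for g in _TERTILE_ORDER if g in lv]
    return sorted(lv)


@dataclass
class MixedAnovaResults:
    """Per-effect decomposition of a mixed design.

    ``table`` has one row per effect with SS_num, SS_den, df_num, df_den,
    F, p and ges; ``error_ss`` maps each error stratum to its SS.
    """

    table: pd.DataFrame
    error_ss: dict
    dv: str
    within: tuple
    between: str | None
    flex_coding: str
    n_subjects: int
    _cells: object = field(repr=False, default=None)
    _cell_matrix: np.ndarray = field(repr=False, default=None)
    _groups: np.ndarray = field(repr=False, default=None)
    _group_df: int = field(repr=False, default=0)

    def summary(self) -> str:
        hdr = (f"Mixed ANOVA on {self.dv}: within {' x '.join(self.within)}"
               + (f", between {self.between} ({self.flex_coding})"
                  if self.between else "")
               + f", n = {self.n_subjects}")
        body = self.table.to_string(
            float_format=lambda v: f"{v:0.4g}", index=True)
        return hdr + "\n" + body

    def simple_interaction(self, group_level, factors) -> tuple[float, int, int, float]:
        """Simple two-way interaction within one between-subjects group.

        The contrast collapses across the remaining within factors; the F
        ratio uses the omnibus model's pooled error stratum for that
        within effect (paper-style df_den = error df of the full model).
        Returns (F, df_num, df_den, p).
        """
        factors = tuple(factors)
        if any(f not in self.within for f in factors):
            raise KeyError(f"unknown within factors {factors}")
        mask = self._groups == group_level
        if mask.sum() < 2:
            raise ValueError("group slice needs at least 2 subjects")
        w = self._contrast(factors)
        s = self._cell_matrix[mask] @ w
        m = w.size
        ss = s.sum() ** 2 / (mask.sum() * m)
        name = " x ".join(factors)
        ss_err = self.error_ss[name]
        df_err = self.n_subjects - 1 - self._group_df
        f = anova_f(ss, 1, ss_err, df_err)
        return float(f), 1, int(df_err), float(stats.f.sf(f, 1, df_err))

    def _contrast(self, factors) -> np.ndarray:
        w = np.ones(len(self._cells))
        for f in factors:
            pos = self.within.index(f)
            levels = sorted({c[pos] for c in self._cells})
            signs = {levels[0]: 1.0, levels[1]: -1.0}
            w *= np.array([signs[c[pos]] for c in self._cells])
        return w


class MixedAnovaModel:
    """Mixed ANOVA on a long table of (possibly trial-level) observations.

    Parameters
    ----------
    data : long DataFrame; rows are aggregated to subject x cell means.
    dv : dependent-variable column.
    subject : subject identifier column.
    within : within-subject factor columns (each with exactly 2 levels).
    between : optional between-subjects group column.
    flex_coding : "linear" (single-df ordered trend, default) or
        "categorical" for the between term.
    """

    def __init__(self, data: pd.DataFrame, dv: str, subject: str,
                 within, between: str | None = None,
                 flex_coding: str = "linear"):
        if flex_coding not in ("linear", "categorical"):
            raise ValueError("flex_coding must be 'linear' or 'categorical'")
        self.dv, self.subject = dv, subject
        self.within = tuple(within)
        self.between = between
        self.flex_coding = flex_coding

        pivot = data.pivot_table(index=subject, columns=list(self.within),
                                 values=dv, aggfunc="mean")
        if pivot.isna().any().any():
            raise ValueError("unbalanced within-subject cells (missing cell means)")
        for f in self.within:
            if data[f].nunique() != 2:
                raise ValueError(f"within factor {f!r} must have exactly 2 levels")
        self._pivot = pivot
        self._cells = ([(c,) for c in pivot.columns]
                       if len(self.within) == 1 else list(pivot.columns))
        if between is not None:
            g = data.groupby(subject)[between].agg(
                lambda s: s.iloc[0] if s.nunique() == 1 else np.nan)
            g = g.reindex(pivot.index)
            if g.isna().any():
                raise ValueError("between-group label missing or inconsistent")
            counts = g.value_counts()
            if (counts < 2).any():
                raise ValueError("singleton between-subjects group")
            self._groups = g.to_numpy()
        else:
            self._groups = None

    # -- between-design columns ------------------------------------------
    def _between_design(self) -> tuple[np.ndarray, int]:
        n = len(self._pivot)
        if self._groups is None:
            return np.empty((n, 0)), 0
        order = _group_order(pd.unique(self._groups))
        if self.flex_coding == "linear":
            score = np.array([order.index(g) + 1.0 for g in self._groups])
            Z = (score - score.mean())[:, None]
            return Z, 1
        # sum-to-zero coding: q = g-1 columns
        gidx = np.array([order.index(g) for g in self._groups])
        q = len(order) - 1
        Z = np.zeros((n, q))
        for j in range(q):
            Z[gidx == j, j] = 1.0
        Z[gidx == q, :] = -1.0
        return Z, q

    def fit(self) -> MixedAnovaResults:
        Y = self._pivot.to_numpy(dtype=float)
        n, m = Y.shape
        Z, q = self._between_design()
        if n - 1 - q < 1:
            raise ValueError("not enough subjects for the error stratum")
        ones = np.ones((n, 1))
        X_full = np.hstack([ones, Z])

        rows = []
        error_ss: dict[str, float] = {}

        # between-subjects stratum (subject means, scaled projection)
        u = Y.sum(axis=1) / np.sqrt(m)
        rss_full = _rss(u, X_full)
        df_err_b = n - 1 - q
        if self.between is not None:
            ss_b = _rss(u, ones) - rss_full
            rows.append(dict(effect=self.between, SS_num=ss_b, df_num=q,
                             SS_den=rss_full, df_den=df_err_b))
        error_ss["between"] = rss_full

        # one stratum per within effect
        res = MixedAnovaResults(
            table=None, error_ss=error_ss, dv=self.dv, within=self.within,
            between=self.between, flex_coding=self.flex_coding,
            n_subjects=n, _cells=self._cells, _cell_matrix=Y,
            _groups=self._groups, _group_df=q)
        for k in range(1, len(self.within) + 1):
            for combo in itertools.combinations(self.within, k):
                w = res._contrast(combo)
                s = Y @ w
                rss_full_s = _rss(s, X_full)
                ss_err = rss_full_s / m
                name = " x ".join(combo)
                error_ss[name] = ss_err
                ss_eff = (_rss(s, Z) - rss_full_s) / m
                rows.append(dict(effect=name, SS_num=ss_eff, df_num=1,
                                 SS_den=ss_err, df_den=df_err_b))
                if self.between is not None:
                    ss_int = (_rss(s, ones) - rss_full_s) / m
                    rows.append(dict(
                        effect=f"{self.between} x {name}", SS_num=ss_int,
                        df_num=q, SS_den=ss_err, df_den=df_err_b))

        all_err = list(error_ss.values())
        for r in rows:
            r["SS_num"] = max(r["SS_num"], 0.0)  # clip tiny negative rounding
            r["F"] = anova_f(r["SS_num"], r["df_num"], r["SS_den"], r["df_den"])
            r["p"] = float(stats.f.sf(r["F"], r["df_num"], r["df_den"]))
            r["ges"] = generalized_eta_squared(r["SS_num"], all_err)
        table = pd.DataFrame(rows).set_index("effect")
        res.table = table
        return res


def paired_contrast(data: pd.DataFrame, dv: str, subject: str, factor: str,
                    where: dict | None = None) -> tuple[float, int, float]:
    """Paired t contrast between the two levels of ``factor``.

    Rows are first restricted by the ``where`` slice (column -> value),
    then averaged per subject x level; the t statistic is paired over
    subjects, first level minus second (sorted order).  Returns
    (t, df, p two-tailed).
    """
    d = data
    if where:
        for k, v in where.items():
            d = d[d[k] == v]
    if not len(d):
        raise ValueError("empty slice")
    cell = d.pivot_table(index=subject, columns=factor, values=dv, aggfunc="mean")
    cell = cell.dropna()
    if cell.shape[1] != 2:
        raise ValueError("contrast factor must have exactly 2 levels in the slice")
    if len(cell) < 2:
        raise ValueError("paired contrast needs at least 2 subjects")
    levels = sorted(cell.columns)
    t, p = stats.ttest_rel(cell[levels[0]], cell[levels[1]])
    return float(t), len(cell) - 1, float(p)
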