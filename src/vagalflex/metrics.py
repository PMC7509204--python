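"""Per-condition performance/reactivity scores and per-subject IIV profiles.

These are the study-level measured quantities: Stroop RT interference
(incongruent minus congruent mean RT) and its accuracy analogue per
condition, vagal reactivity (task minus preceding baseline) per condition,
and the across-condition mean and standard deviation that define the
intraindividual-variability (IIV) profile — Reactivity_MEAN/SD (vagal
flexibility) and Interference_MEAN/SD (performance stability).  Also the
cohort-level hygiene steps: >3 SD outlier exclusion and the tertile split
of vagal flexibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rt_interference",
    "accuracy_interference",
    "reactivity_score",
    "iiv_summary",
    "exclude_outliers",
    "tertile_split",
]


def _split_cells(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cong = trials[trials["congruency"] == "congruent"]
    incong = trials[trials["congruency"] == "incongruent"]
    return cong, incong


def rt_interference(trials: pd.DataFrame, correct_only: bool = False) -> float:
    """Mean incongruent RT minus mean congruent RT (ms) for one condition.

    Censored trials (missing RT) are excluded; incorrect trials are kept
    unless ``correct_only`` is set.
    """
    t = trials
    if correct_only:
        t = t[t["correct"]]
    cong, incong = _split_cells(t.dropna(subset=["rt_ms"]))
    if not len(cong) or not len(incong):
        raise ValueError("empty congruency cell: interference undefined")
    return float(incong["rt_ms"].mean() - cong["rt_ms"].mean())


def accuracy_interference(trials: pd.DataFrame) -> float:
    """Proportion correct, incongruent minus congruent, in [-1, 1]."""
    cong, incong = _split_cells(trials)
    if not len(cong) or not len(incong):
        raise ValueError("empty congruency cell: accuracy interference undefined")
    return float(incong["correct"].mean() - cong["correct"].mean())


def reactivity_score(task_value: float, baseline_value: float) -> float:
    """Task minus preceding baseline; positive = increase during task.

    Applies identically to RMSSD (ms) and HF-peak (Hz) reactivity.
    """
    if task_value is None or baseline_value is None or \
            np.isnan(task_value) or np.isnan(baseline_value):
        raise ValueError("missing segment value for reactivity score")
    return float(task_value - baseline_value)


def iiv_summary(condition_scores, ddof: int = 1) -> tuple[float, float]:
    """Arithmetic mean and SD across exactly four condition scores.

    The sample SD (denominator n-1) is the default, matching behavioural
    convention; ``ddof=0`` gives the population SD for sensitivity checks.
    """
    x = np.asarray(condition_scores, dtype=float)
    if x.size != 4:
        raise ValueError("IIV summary requires exactly 4 condition scores")
    if np.any(np.isnan(x)):
        raise ValueError("missing condition score")
    return float(x.mean()), float(x.std(ddof=ddof))


def exclude_outliers(
    profiles: pd.DataFrame,
    variables,
    k_sd: float = 3.0,
    subject_col: str = "subject",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects beyond ``k_sd`` SDs on any listed variable (single pass).

    Means and SDs are computed once on the full sample; a subject is
    removed when |value - mean| is strictly greater than k_sd * SD.
    Returns the filtered profiles and an exclusion log with one row per
    (subject, variable) trigger, recording the z-score.
    """
    if len(profiles) < 5:
        raise ValueError("need at least 5 profiles for outlier screening")
    log_rows = []
    drop: set = set()
    for var in variables:
        if var not in profiles.columns:
            raise KeyError(f"variable {var!r} not in profiles")
        vals = profiles[var].to_numpy(dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        z = (vals - mu) / sd
        for idx in np.flatnonzero(np.abs(z) > k_sd):
            subj = profiles.iloc[idx][subject_col]
            drop.add(subj)
            log_rows.append(dict(subject=subj, variable=var,
                                 value=vals[idx], z=z[idx]))
    log = pd.DataFrame(log_rows, columns=["subject", "variable", "value", "z"])
    kept = profiles[~profiles[subject_col].isin(drop)].reset_index(drop=True)
    return kept, log


def tertile_split(values) -> np.ndarray:
    """Rank-based split into low / medium / high groups.

    Cutpoints at the rounded n/3 and 2n/3 ranks, ties broken by stable
    rank order, so group sizes differ by at most one (47 -> 16/15/16).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("tertile split needs at least 3 subjects")
    if np.unique(v).size < 3:
        raise ValueError("tertile split needs at least 3 distinct values")
    order = np.argsort(v, kind="stable")
    cut1 = round(n / 3)
    cut2 = round(2 * n / 3)
    labels = np.empty(n, dtype=object)
    labels[order[:cut1]] = "low"
    labels[order[cut1:cut2]] = "medium"
    labels[order[cut2:]] = "high"
    return labels
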