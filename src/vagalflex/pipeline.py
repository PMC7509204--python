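"""End-to-end orchestration: sessions -> HRV metrics -> profiles -> inference.

`build_profiles` turns labeled interbeat-interval segments and trial
tables into one row per subject of derived scalars: resting (ln)RMSSD,
per-condition vagal reactivity and its across-condition mean/SD (vagal
flexibility), Stroop interference and its mean/SD (performance
stability), and the HF-peak respiration covariates.  `screen_profiles`
applies the >3 SD outlier exclusion and the vagal-flexibility tertile
split.  Convenience constructors wire the profiles into the correlation
table, the four mediation models and the mixed ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .anova import MixedAnovaModel
from .cohort import CONDITIONS, HIGH_EMOTION, HIGH_SOCIAL
from .correlations import partial_corr, pearson_fisher
from .hrv import hrv_summary, ln_skew_transform
from .mediation import MediationModel

__all__ = [
    "build_profiles",
    "screen_profiles",
    "transform_decisions",
    "make_rt_long",
    "correlation_table",
    "mediation_models",
    "estimate_paths",
    "CohortAnalysis",
    "analyze_cohort",
]

#: confound set entered in every mediation path model
MEDIATION_COVARIATES = ("age", "bmi", "sex", "resting_hf_peak")

#: HF-peak (respiration) analog used as the fourth covariate for each
#: HRV metric in the partial correlations
HF_PEAK_ANALOG = {
    "ln_reactivity_sd": "hf_peak_sd",
    "reactivity_sd": "hf_peak_sd",
    "reactivity_mean": "hf_peak_mean",
    "resting_ln_rmssd": "resting_hf_peak",
    "resting_rmssd": "resting_hf_peak",
}


def build_profiles(
    sessions,
    correct: bool = True,
    threshold_ms: float = 250.0,
    sd_ddof: int = 1,
    correct_only: bool = False,
    ln_sd_floor_ms: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-subject profiles and the per-condition score table.

    Returns ``(profiles, condition_scores)``; ``condition_scores`` has one
    row per subject x condition with the reactivity and interference
    scores that the IIV summaries aggregate.
    """
    prof_rows, cond_rows = [], []
    for s in sessions:
        seg_summ = {name: hrv_summary(series, correct=correct,
                                      threshold_ms=threshold_ms)
                    for name, series in s.segments.items()}
        rest = seg_summ["rest_baseline"]
        reacts, hf_reacts, interfs, acc_interfs = [], [], [], []
        for c in CONDITIONS:
            base, task = seg_summ[f"{c}_baseline"], seg_summ[f"{c}_task"]
            react = metrics.reactivity_score(task.rmssd, base.rmssd)
            hf_react = metrics.reactivity_score(task.hf_peak, base.hf_peak)
            ctr = s.trials[s.trials["condition"] == c]
            interf = metrics.rt_interference(ctr, correct_only=correct_only)
            acc = metrics.accuracy_interference(ctr)
            reacts.append(react)
            hf_reacts.append(hf_react)
            interfs.append(interf)
            acc_interfs.append(acc)
            cond_rows.append(dict(
                subject=s.subject, condition=c,
                rmssd_baseline=base.rmssd, rmssd_task=task.rmssd,
                rmssd_reactivity=react, hf_peak_reactivity=hf_react,
                rt_interference=interf, accuracy_interference=acc,
            ))
        r_mean, r_sd = metrics.iiv_summary(reacts, ddof=sd_ddof)
        i_mean, i_sd = metrics.iiv_summary(interfs, ddof=sd_ddof)
        h_mean, h_sd = metrics.iiv_summary(hf_reacts, ddof=sd_ddof)
        if r_sd < ln_sd_floor_ms:
            warnings.warn(
                f"{s.subject}: Reactivity_SD below {ln_sd_floor_ms} ms floored "
                "before log", stacklevel=2)
        prof_rows.append(dict(
            subject=s.subject, age=s.age, sex=s.sex, bmi=s.bmi,
            resting_rmssd=rest.rmssd,
            resting_ln_rmssd=rest.ln_rmssd,
            resting_hf_peak=rest.hf_peak,
            resting_hf_power=rest.hf_power,
            reactivity_mean=r_mean, reactivity_sd=r_sd,
            ln_reactivity_sd=float(np.log(max(r_sd, ln_sd_floor_ms))),
            interference_mean=i_mean, interference_sd=i_sd,
            accuracy_interference_mean=float(np.mean(acc_interfs)),
            hf_peak_mean=h_mean, hf_peak_sd=h_sd,
            n_corrected=int(sum(v.n_corrected for v in seg_summ.values())),
        ))
    return pd.DataFrame(prof_rows), pd.DataFrame(cond_rows)


def transform_decisions(profiles: pd.DataFrame,
                        variables=("resting_rmssd", "reactivity_sd"),
                        alpha: float = 0.05) -> dict[str, bool]:
    """Shapiro-Wilk-gated log-transform decisions for skewed metrics."""
    return {v: ln_skew_transform(profiles[v].to_numpy(), alpha=alpha)[1]
            for v in variables}


def screen_profiles(
    profiles: pd.DataFrame,
    outlier_variables=("interference_sd", "ln_reactivity_sd"),
    k_sd: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outlier exclusion (>k SD, single pass) then flexibility tertiles."""
    kept, log = metrics.exclude_outliers(profiles, outlier_variables, k_sd=k_sd)
    kept = kept.copy()
    kept["flexibility_tertile"] = metrics.tertile_split(
        kept["reactivity_sd"].to_numpy())
    return kept, log


def make_rt_long(sessions, profiles: pd.DataFrame) -> pd.DataFrame:
    """Long cell-mean RT table for the mixed ANOVA.

    One row per subject x condition x congruency with the mean RT over
    valid trials, the emotion/social condition factors, and the subject's
    flexibility tertile from ``profiles``.
    """
    if "flexibility_tertile" not in profiles.columns:
        raise KeyError("profiles must carry flexibility_tertile (screen first)")
    tert = profiles.set_index("subject")["flexibility_tertile"]
    rows = []
    for s in sessions:
        if s.subject not in tert.index:
            continue  # excluded subject
        t = s.trials.dropna(subset=["rt_ms"])
        cell = t.groupby(["condition", "congruency"])["rt_ms"].mean()
        for (c, cong), rt in cell.items():
            rows.append(dict(
                subject=s.subject, condition=c, congruency=cong,
                emotion="high" if c in HIGH_EMOTION else "low",
                social="high" if c in HIGH_SOCIAL else "low",
                flexibility=tert[s.subject], rt_ms=float(rt),
            ))
    return pd.DataFrame(rows)


def correlation_table(profiles: pd.DataFrame,
                      hrv_vars=("ln_reactivity_sd", "reactivity_mean",
                                "resting_ln_rmssd"),
                      perf_vars=("interference_mean", "interference_sd"),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Zero-order and partial correlations between HRV and performance.

    Partial correlations adjust for sex, age, BMI and the HF-peak
    (respiration) analog of the HRV metric.
    """
    rows = []
    for hv in hrv_vars:
        for pv in perf_vars:
            x = profiles[hv].to_numpy()
            y = profiles[pv].to_numpy()
            zero = pearson_fisher(x, y, alpha=alpha)
            cov_cols = ["sex", "age", "bmi", HF_PEAK_ANALOG[hv]]
            pcc = partial_corr(x, y, profiles[cov_cols].to_numpy(), alpha=alpha)
            for kind, res in (("r", zero), ("pcc", pcc)):
                rows.append(dict(
                    hrv_metric=hv, performance_metric=pv, kind=kind,
                    r=res.r, n=res.n, k=res.k, df=res.df, p=res.p,
                    ci_low=res.ci_low, ci_high=res.ci_high,
                ))
    return pd.DataFrame(rows)


def mediation_models(profiles: pd.DataFrame,
                     x: str = "resting_ln_rmssd") -> dict[str, MediationModel]:
    """The four mediation models of the design (mediator x outcome)."""
    out = {}
    for mediator in ("ln_reactivity_sd", "reactivity_mean"):
        for y in ("interference_sd", "interference_mean"):
            out[f"{mediator}->{y}"] = MediationModel(
                profiles, x=x, mediator=mediator, y=y,
                covariates=MEDIATION_COVARIATES)
    return out


def estimate_paths(profiles: pd.DataFrame, seed=None, n_sims: int = 10_000,
                   standardize: bool = True):
    """Fit the focal mediation (flexibility -> stability) on z-scored data.

    Standardizing puts the estimated paths on the latent scale of the
    synthetic generator, for parameter-recovery checks.
    """
    model = MediationModel(
        profiles, x="resting_ln_rmssd", mediator="ln_reactivity_sd",
        y="interference_sd", covariates=MEDIATION_COVARIATES,
        standardize=standardize)
    return model.fit(n_sims=n_sims, seed=seed)


@dataclass
class CohortAnalysis:
    profiles: pd.DataFrame
    condition_scores: pd.DataFrame
    exclusions: pd.DataFrame
    transforms: dict
    correlations: pd.DataFrame
    mediations: dict
    rt_anova: object


def analyze_cohort(sessions, seed=None, n_sims: int = 10_000,
                   **profile_kwargs) -> CohortAnalysis:
    """The full analysis chain on a list of sessions."""
    profiles, cond = build_profiles(sessions, **profile_kwargs)
    transforms = transform_decisions(profiles)
    kept, excl = screen_profiles(profiles)
    corr = correlation_table(kept)
    meds = {}
    for i, (name, model) in enumerate(mediation_models(kept).items()):
        med_seed = None if seed is None else int(seed) + i
        meds[name] = model.fit(n_sims=n_sims, seed=med_seed)
    long = make_rt_long(sessions, kept)
    anova_res = MixedAnovaModel(
        long, dv="rt_ms", subject="subject",
        within=("congruency", "emotion", "social"),
        between="flexibility", flex_coding="linear").fit()
    return CohortAnalysis(
        profiles=kept, condition_scores=cond, exclusions=excl,
        transforms=transforms, correlations=corr, mediations=meds,
        rt_anova=anova_res)
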