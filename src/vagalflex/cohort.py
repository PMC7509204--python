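"""Synthetic cohorts with a known latent mediation structure.

A generated cohort emulates a psychophysiological session: a 5-min resting
baseline, then four Stroop-with-auditory-distractor conditions (crossing
low/high emotional and social content: LELS, HELS, LEHS, HEHS), each
preceded by its own 2-min baseline.  Per subject the generator realizes

* nine interbeat-interval segments whose short-term variability (RMSSD)
  and respiratory-frequency oscillation (RSA) are controlled by a latent
  vagal tone,
* 64 Stroop trials per condition (32 congruent / 32 incongruent) with
  ex-Gaussian response times, a congruency interference effect, and an
  emotion-distraction effect that shrinks as latent flexibility rises,
* covariates (age, sex, BMI) and a per-subject respiratory frequency.

The latent chain is the point: a standard-normal resting-vagal trait T
drives latent flexibility F = a*T + e_m, which drives a latent
performance-variability axis S = b*F + c'*T + e_y (negative S = more
stable interference).  T maps to the resting vagal tone (hence resting
RMSSD), F to the spread of per-condition vagal reactivity shifts, and S
to the spread of per-condition interference effects, so the full
measurement pipeline can be validated against known ground truth: with
the default b = -0.40, higher flexibility yields a tighter interference
spread, and the pipeline's measured path b recovers -0.40.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.special import expit

from .hrv import IBISeries

__all__ = [
    "CONDITIONS",
    "CohortSpec",
    "GroundTruth",
    "SubjectSession",
    "generate_condition_order",
    "valid_condition_orders",
    "generate_ibi_series",
    "generate_trials",
    "generate_cohort",
    "rsa_amplitude",
    "expected_rmssd",
]

#: Canonical condition labels: low/high Emotion x low/high Social distractors.
CONDITIONS = ("LELS", "HELS", "LEHS", "HEHS")

HIGH_EMOTION = frozenset({"HELS", "HEHS"})
HIGH_SOCIAL = frozenset({"LEHS", "HEHS"})

#: Fixed across-condition shape of vagal reactivity shifts (unit sample SD,
#: zero mean), taken from the characteristic condition-level means of the
#: paradigm: a positive shift for LELS/HELS/LEHS and a negative one for HEHS.
_REACTIVITY_PATTERN_MS = (1.66, 1.95, 3.39, -2.14)

#: Fixed across-condition shape of Stroop interference (unit sample SD):
#: interference is largest under high-emotion/high-social distraction.
_INTERFERENCE_PATTERN_MS = (113.09, 133.87, 127.15, 147.27)


def _standardized_pattern(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)


@dataclass
class CohortSpec:
    """Parameters of the simulated cohort.

    Path coefficients are on the standardized latent scale.  The default
    residual SDs keep the latent variables standardized for the default
    paths (a = 0.65, b = -0.40, c' = 0): e_m = sqrt(1 - a^2),
    e_y = sqrt(1 - b^2 - c'^2 - 2*a*b*c').
    """

    n_subjects: int = 47
    path_a: float = 0.65
    path_b: float = -0.40
    path_c_prime: float = 0.0
    noise_sd_m: float | None = None
    noise_sd_y: float | None = None
    mean_ibi_ms: float = 850.0
    rsa_freq_hz: float = 0.232
    rsa_amp_range_ms: tuple[float, float] = (0.0, 90.0)
    base_rt_ms: float = 920.0
    interference_ms: float = 120.0
    emotion_distraction_ms: float = 60.0
    accuracy_base: float = 0.985
    seed: int = 0

    # --- latent-to-observable mapping constants (documented, configurable) ---
    #: slope of ln(vagal tone) on the latent trait T
    tone_lnsd: float = 0.9
    #: marginal SD of the AR(1) IBI noise per unit of vagal tone (ms);
    #: linear in tone, so resting RMSSD inherits the positive skew of the
    #: log-normal tone distribution (the RSA amplitude alone saturates)
    noise_per_tone_ms: float = 14.0
    #: physiological ceiling on the AR(1) noise SD (caps the extreme tail
    #: of the tone distribution; binds for roughly the top 3% of subjects)
    noise_sd_cap_ms: float = 70.0
    #: lag-1 autocorrelation of the IBI noise
    ar_phi: float = 0.4
    #: median across-condition SD of reactivity shifts (ms) at F = 0
    reactivity_sd_base_ms: float = 12.0
    #: slope of ln(reactivity spread) on latent flexibility F
    flex_lnsd_slope: float = 0.85
    #: across-condition SD of interference (ms) at S = 0
    interference_sd_base_ms: float = 90.0
    #: linear growth of the interference spread per unit of the latent
    #: variability axis S (sets the across-subject CV of Interference_SD
    #: near the ~0.5 seen in comparable cohorts)
    stability_slope: float = 0.55
    interference_sd_floor_ms: float = 10.0
    #: idiosyncratic per-condition noise, as a fraction of the subject spread
    condition_noise_frac: float = 0.2
    #: ex-Gaussian RT parameters (sigma of the Gaussian part, tau of the tail)
    rt_sigma_ms: float = 70.0
    rt_tau_ms: float = 150.0
    rt_deadline_ms: float = 5000.0
    #: how steeply flexibility suppresses emotional distraction (0 = not at all)
    flex_attenuation: float = 1.0
    accuracy_incongruent_drop: float = 0.012
    n_trials_per_condition: int = 64
    #: segment durations (s)
    rest_duration_s: float = 300.0
    baseline_duration_s: float = 120.0
    task_duration_s: float = 180.0
    #: between-subject SD of the respiratory (RSA) frequency (Hz)
    resp_freq_sd_hz: float = 0.04
    #: respiration speeds up slightly during task segments (Hz)
    task_resp_shift_hz: float = 0.03

    def resolved_noise_sds(self) -> tuple[float, float]:
        """Residual SDs of the latent equations (defaults standardize F, S)."""
        a, b, c = self.path_a, self.path_b, self.path_c_prime
        sd_m = self.noise_sd_m
        if sd_m is None:
            v = 1.0 - a * a
            if v <= 0:
                raise ValueError("path_a too large to standardize the mediator")
            sd_m = float(np.sqrt(v))
        sd_y = self.noise_sd_y
        if sd_y is None:
            v = 1.0 - b * b - c * c - 2.0 * a * b * c
            if v <= 0:
                raise ValueError("paths too large to standardize the outcome")
            sd_y = float(np.sqrt(v))
        return sd_m, sd_y

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if not (0.15 <= self.rsa_freq_hz <= 0.4):
            raise ValueError("rsa_freq_hz must lie in the 0.15-0.4 Hz HF band")
        if not (300.0 < self.mean_ibi_ms < 2000.0):
            raise ValueError("mean_ibi_ms outside physiological range")
        if not (0.0 <= self.accuracy_base <= 1.0):
            raise ValueError("accuracy_base must be a probability")
        for name in ("noise_per_tone_ms", "rt_sigma_ms", "rt_tau_ms",
                     "reactivity_sd_base_ms", "interference_sd_base_ms",
                     "resp_freq_sd_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_sd_m is not None and self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be nonnegative")
        if self.noise_sd_y is not None and self.noise_sd_y < 0:
            raise ValueError("noise_sd_y must be nonnegative")
        self.resolved_noise_sds()


@dataclass
class SubjectSession:
    """One subject's labeled recording segments, trial table and covariates."""

    subject: str
    age: float
    sex: int
    bmi: float
    segments: dict[str, IBISeries]
    trials: pd.DataFrame
    condition_order: tuple[str, ...]


@dataclass
class GroundTruth:
    """Latent variables and true per-condition effects behind a cohort."""

    latents: pd.DataFrame          # subject, T, F, S, tone, resp_freq_hz
    reactivity_shifts: pd.DataFrame  # subject, condition, shift_ms
    interference_true: pd.DataFrame  # subject, condition, interference_ms
    condition_orders: dict[str, tuple[str, ...]]
    spec: CohortSpec


def valid_condition_orders() -> list[tuple[str, ...]]:
    """All orders of the four conditions satisfying the adjacency constraint.

    A high-emotion condition must not directly follow the other high-emotion
    condition, and a high-social condition must not follow the other
    high-social condition.
    """
    out = []
    for perm in itertools.permutations(CONDITIONS):
        ok = True
        for u, v in zip(perm, perm[1:]):
            if {u, v} <= HIGH_EMOTION or {u, v} <= HIGH_SOCIAL:
                ok = False
                break
        if ok:
            out.append(perm)
    return out


_VALID_ORDERS = valid_condition_orders()


def generate_condition_order(seed=None) -> tuple[str, ...]:
    """Draw a condition order uniformly from the valid counterbalancing set.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _VALID_ORDERS[int(rng.integers(len(_VALID_ORDERS)))]


def rsa_amplitude(vagal_tone: float, rsa_amp_range_ms=(0.0, 90.0)) -> float:
    """RSA sinusoid amplitude (ms): saturating, strictly increasing in tone."""
    lo, hi = rsa_amp_range_ms
    tone = float(vagal_tone)
    if tone < 0:
        raise ValueError("vagal_tone must be nonnegative")
    return lo + (hi - lo) * tone / (1.0 + tone)


def expected_rmssd(
    vagal_tone: float,
    rsa_freq_hz: float,
    mean_ibi_ms: float,
    rsa_amp_range_ms=(0.0, 90.0),
    noise_per_tone_ms: float = 14.0,
    ar_phi: float = 0.4,
    noise_sd_cap_ms: float = 70.0,
) -> float:
    """Analytic RMSSD implied by the generator's signal model.

    The RSA sinusoid of amplitude A sampled every ``mean_ibi_ms`` contributes
    sqrt(2)*A*|sin(pi*f*dt)| to the successive-difference RMS; the AR(1)
    noise of marginal SD s contributes s*sqrt(2*(1-phi)).
    """
    amp = rsa_amplitude(vagal_tone, rsa_amp_range_ms)
    dt = mean_ibi_ms / 1000.0
    rsa = np.sqrt(2.0) * amp * abs(np.sin(np.pi * rsa_freq_hz * dt))
    sd = min(noise_per_tone_ms * vagal_tone, noise_sd_cap_ms)
    noise = sd * np.sqrt(2.0 * (1.0 - ar_phi))
    return float(np.hypot(rsa, noise))


def _tone_for_rmssd(target_ms: float, rsa_freq_hz: float, mean_ibi_ms: float,
                    spec: CohortSpec) -> float:
    """Invert the analytic tone -> RMSSD map (monotone) for a target RMSSD."""
    kwargs = dict(
        rsa_freq_hz=rsa_freq_hz,
        mean_ibi_ms=mean_ibi_ms,
        rsa_amp_range_ms=spec.rsa_amp_range_ms,
        noise_per_tone_ms=spec.noise_per_tone_ms,
        ar_phi=spec.ar_phi,
        noise_sd_cap_ms=spec.noise_sd_cap_ms,
    )
    lo_val = expected_rmssd(0.0, **kwargs)
    if target_ms <= lo_val:
        return 0.0
    hi = 1.0
    while expected_rmssd(hi, **kwargs) < target_ms:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target RMSSD unattainable under the signal model")
    return float(optimize.brentq(
        lambda tone: expected_rmssd(tone, **kwargs) - target_ms, 0.0, hi))


def generate_ibi_series(
    duration_s: float,
    mean_ibi_ms: float = 850.0,
    vagal_tone: float = 1.0,
    rsa_freq_hz: float = 0.25,
    shift_ms: float = 0.0,
    seed=None,
    rsa_amp_range_ms=(0.0, 90.0),
    noise_per_tone_ms: float = 14.0,
    ar_phi: float = 0.4,
    noise_sd_cap_ms: float = 70.0,
    label: str = "",
    subject: str = "",
) -> IBISeries:
    """Simulate an interbeat-interval segment.

    IBI_k = mean + shift + A(tone) * sin(2*pi*f*t_k) + AR(1) noise, where
    t_k is cumulative time and both the RSA amplitude A and the noise SD
    increase with ``vagal_tone`` (RMSSD is therefore monotone in tone, and
    a zero-tone series is exactly constant).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (300.0 < mean_ibi_ms < 2000.0):
        raise ValueError("mean_ibi_ms outside physiological range (300, 2000)")
    if vagal_tone < 0:
        raise ValueError("vagal_tone must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = mean_ibi_ms + shift_ms
    if base <= 0:
        raise ValueError("shift_ms drives the mean interval nonpositive")
    n = int(np.ceil(duration_s * 1000.0 / base * 1.25)) + 20
    sd = min(noise_per_tone_ms * vagal_tone, noise_sd_cap_ms)
    if sd > 0:
        white = rng.standard_normal(n) * sd * np.sqrt(1.0 - ar_phi**2)
        noise = signal.lfilter([1.0], [1.0, -ar_phi], white)
    else:
        rng.standard_normal(n)  # keep the stream position tone-independent
        noise = np.zeros(n)
    core = base + noise
    t = np.cumsum(core) / 1000.0
    amp = rsa_amplitude(vagal_tone, rsa_amp_range_ms)
    ibi = core + amp * np.sin(2.0 * np.pi * rsa_freq_hz * t)
    ibi = np.clip(ibi, 1.0, None)
    cum = np.cumsum(ibi)
    keep = int(np.searchsorted(cum, duration_s * 1000.0, side="right"))
    keep = max(keep, 2)
    return IBISeries(ibi[:keep], label=label, subject=subject)


def _distraction_factor(flexibility_level: float, flex_attenuation: float) -> float:
    """Multiplier on the emotion-distraction effect; 1 at F=0, falls as F rises."""
    if flex_attenuation == 0:
        return 1.0
    return float(np.clip(2.0 * expit(-flex_attenuation * flexibility_level), 0.0, 2.0))


def generate_trials(
    condition: str,
    flexibility_level: float,
    spec: CohortSpec | None = None,
    seed=None,
    interference_override_ms: float | None = None,
    n_trials: int | None = None,
    subject: str = "",
) -> pd.DataFrame:
    """Simulate one condition's Stroop trial table.

    Response times are ex-Gaussian; incongruent trials are slower by the
    condition's true interference.  In high-emotion conditions the
    interference is inflated by an emotion-distraction effect that is
    scaled down as ``flexibility_level`` rises.  Responses slower than the
    5-s deadline are censored: missing RT, scored incorrect.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition label {condition!r}")
    spec = spec if spec is not None else CohortSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_trials_per_condition if n_trials is None else int(n_trials)
    if n % 2:
        raise ValueError("trial count must split evenly between congruencies")
    if interference_override_ms is not None:
        interference = float(interference_override_ms)
    else:
        interference = spec.interference_ms
        if condition in HIGH_EMOTION:
            interference += spec.emotion_distraction_ms * _distraction_factor(
                flexibility_level, spec.flex_attenuation)
    half = n // 2
    congruency = np.array(["congruent"] * half + ["incongruent"] * half)
    rng.shuffle(congruency)
    incong = congruency == "incongruent"
    target_mean = np.where(incong, spec.base_rt_ms + interference, spec.base_rt_ms)
    mu = target_mean - spec.rt_tau_ms  # ex-Gaussian mean = mu + tau
    rt = rng.normal(mu, spec.rt_sigma_ms) + rng.exponential(spec.rt_tau_ms, size=n)
    rt = np.maximum(rt, 150.0)
    p_correct = np.where(
        incong,
        np.clip(spec.accuracy_base - spec.accuracy_incongruent_drop, 0.0, 1.0),
        spec.accuracy_base,
    )
    correct = rng.random(n) < p_correct
    censored = rt > spec.rt_deadline_ms
    rt = np.where(censored, np.nan, rt)
    correct = np.where(censored, False, correct)
    return pd.DataFrame({
        "subject": subject,
        "condition": condition,
        "trial_index": np.arange(n),
        "congruency": congruency,
        "rt_ms": rt,
        "correct": correct.astype(bool),
    })


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectSession], GroundTruth]:
    """Generate a full cohort and its ground truth; reproducible from the seed."""
    spec.validate()
    sd_m, sd_y = spec.resolved_noise_sds()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    T = rng.standard_normal(n)
    F = spec.path_a * T + sd_m * rng.standard_normal(n)
    S = spec.path_b * F + spec.path_c_prime * T + sd_y * rng.standard_normal(n)

    age = np.round(np.clip(rng.normal(19.5, 1.45, n), 18.0, 26.0), 1)
    sex = (rng.random(n) < 0.66).astype(int)  # 1 = female
    bmi = np.round(np.clip(rng.normal(24.1, 4.16, n), 16.0, 40.0), 1)
    resp = np.clip(rng.normal(0.232, spec.resp_freq_sd_hz, n), 0.16, 0.39)

    q_pattern = dict(zip(CONDITIONS, _standardized_pattern(_REACTIVITY_PATTERN_MS)))
    p_pattern = dict(zip(CONDITIONS, _standardized_pattern(_INTERFERENCE_PATTERN_MS)))

    sessions: list[SubjectSession] = []
    lat_rows, shift_rows, interf_rows = [], [], []
    orders: dict[str, tuple[str, ...]] = {}
    width = max(3, len(str(n)))
    for i in range(n):
        subj = f"S{i + 1:0{width}d}"
        tone = float(np.exp(spec.tone_lnsd * T[i]))
        order = generate_condition_order(rng)
        orders[subj] = order

        segments: dict[str, IBISeries] = {}
        segments["rest_baseline"] = generate_ibi_series(
            spec.rest_duration_s, spec.mean_ibi_ms, tone, resp[i],
            seed=rng, rsa_amp_range_ms=spec.rsa_amp_range_ms,
            noise_per_tone_ms=spec.noise_per_tone_ms, ar_phi=spec.ar_phi,
                noise_sd_cap_ms=spec.noise_sd_cap_ms,
            label="rest_baseline", subject=subj,
        )

        sigma_f = spec.reactivity_sd_base_ms * float(np.exp(spec.flex_lnsd_slope * F[i]))
        eta = rng.standard_normal(4)
        shifts = {
            c: sigma_f * (q_pattern[c] + spec.condition_noise_frac * eta[j])
            for j, c in enumerate(CONDITIONS)
        }

        sigma_s = max(
            spec.interference_sd_floor_ms,
            spec.interference_sd_base_ms * (1.0 + spec.stability_slope * S[i]),
        )
        # The high-emotion loading of the condition pattern, scaled by
        # sigma_s, is the sole flexibility-linked route to interference:
        # stable subjects (low S via high F) shrink the emotion-distraction
        # effect along with the rest of the spread, so the latent chain is
        # the only F -> interference pathway (clean path-b recovery).
        eps = rng.standard_normal(4)
        true_interf = {}
        for j, c in enumerate(CONDITIONS):
            true_interf[c] = spec.interference_ms + sigma_s * (
                p_pattern[c] + spec.condition_noise_frac * eps[j])

        base_expected = expected_rmssd(
            tone, resp[i], spec.mean_ibi_ms, spec.rsa_amp_range_ms,
            spec.noise_per_tone_ms, spec.ar_phi, spec.noise_sd_cap_ms)
        trial_frames = []
        for c in order:
            segments[f"{c}_baseline"] = generate_ibi_series(
                spec.baseline_duration_s, spec.mean_ibi_ms, tone, resp[i],
                seed=rng, rsa_amp_range_ms=spec.rsa_amp_range_ms,
                noise_per_tone_ms=spec.noise_per_tone_ms, ar_phi=spec.ar_phi,
                noise_sd_cap_ms=spec.noise_sd_cap_ms,
                label=f"{c}_baseline", subject=subj,
            )
            task_resp = min(resp[i] + spec.task_resp_shift_hz, 0.395)
            # the saturating signal model bounds attainable RMSSD; clamp
            # extreme positive shifts just below that ceiling
            ceiling = expected_rmssd(
                1e9, task_resp, spec.mean_ibi_ms, spec.rsa_amp_range_ms,
                spec.noise_per_tone_ms, spec.ar_phi, spec.noise_sd_cap_ms)
            target = float(np.clip(base_expected + shifts[c], 3.0, ceiling - 0.5))
            task_tone = _tone_for_rmssd(target, task_resp, spec.mean_ibi_ms, spec)
            segments[f"{c}_task"] = generate_ibi_series(
                spec.task_duration_s, spec.mean_ibi_ms, task_tone, task_resp,
                seed=rng, rsa_amp_range_ms=spec.rsa_amp_range_ms,
                noise_per_tone_ms=spec.noise_per_tone_ms, ar_phi=spec.ar_phi,
                noise_sd_cap_ms=spec.noise_sd_cap_ms,
                label=f"{c}_task", subject=subj,
            )
            trial_frames.append(generate_trials(
                c, F[i], spec, seed=rng,
                interference_override_ms=true_interf[c], subject=subj,
            ))
        trials = pd.concat(trial_frames, ignore_index=True)
        sessions.append(SubjectSession(
            subject=subj, age=float(age[i]), sex=int(sex[i]), bmi=float(bmi[i]),
            segments=segments, trials=trials, condition_order=order,
        ))
        lat_rows.append(dict(subject=subj, T=T[i], F=F[i], S=S[i],
                             tone=tone, resp_freq_hz=resp[i]))
        for c in CONDITIONS:
            shift_rows.append(dict(subject=subj, condition=c, shift_ms=shifts[c]))
            interf_rows.append(dict(subject=subj, condition=c,
                                    interference_ms=true_interf[c]))

    truth = GroundTruth(
        latents=pd.DataFrame(lat_rows),
        reactivity_shifts=pd.DataFrame(shift_rows),
        interference_true=pd.DataFrame(interf_rows),
        condition_orders=orders,
        spec=spec,
    )
    return sessions, truth
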