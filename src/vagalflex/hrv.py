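"""Heart-rate-variability metrics from interbeat-interval (IBI/RR) series.

The substrate of every metric here is an ordered series of interbeat
intervals in milliseconds (one recording segment).  The module provides

* Kubios-style artifact correction (running-median detection, cubic-spline
  replacement),
* RMSSD, the root mean square of successive IBI differences — the
  time-domain index of cardiac vagal activity,
* an autoregressive (Burg) spectral estimate of the evenly resampled IBI
  tachogram, from which high-frequency (0.15-0.4 Hz) power and the HF peak
  frequency (a proxy for respiration rate) are extracted,
* a Shapiro-Wilk-gated natural-log transform for positively skewed
  per-subject metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, signal, stats
from statsmodels.regression.linear_model import burg

__all__ = [
    "IBISeries",
    "SpectralEstimate",
    "HRVSummary",
    "correct_artifacts",
    "compute_rmssd",
    "compute_ar_spectrum",
    "hrv_summary",
    "ln_skew_transform",
    "HF_BAND",
]

#: High-frequency (respiratory) band in Hz.
HF_BAND = (0.15, 0.40)


@dataclass
class IBISeries:
    """Ordered interbeat intervals (ms) for one recording segment."""

    intervals: np.ndarray
    label: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all interbeat intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration_s(self) -> float:
        """Total segment duration implied by the intervals, in seconds."""
        return float(self.intervals.sum()) / 1000.0

    @property
    def times_s(self) -> np.ndarray:
        """Cumulative beat times (s), one per interval (end of interval)."""
        return np.cumsum(self.intervals) / 1000.0


@dataclass
class SpectralEstimate:
    """Parametric (AR) spectral density of an IBI series.

    Power density is one-sided, in ms^2/Hz; ``hf_power`` integrates it over
    the 0.15-0.4 Hz respiratory band and ``hf_peak`` is the band argmax.
    """

    frequencies: np.ndarray
    density: np.ndarray
    order: int
    resample_hz: float
    hf_power: float
    hf_peak: float


@dataclass
class HRVSummary:
    rmssd: float
    ln_rmssd: float
    hf_power: float
    hf_peak: float
    n_corrected: int = 0


def compute_rmssd(series: IBISeries | np.ndarray) -> float:
    """Root mean square of successive differences, in ms.

    Shift-invariant (a constant added to every interval cancels in the
    differences) and scale-equivariant.
    """
    x = series.intervals if isinstance(series, IBISeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def correct_artifacts(
    series: IBISeries,
    threshold_ms: float = 250.0,
    window: int = 11,
) -> tuple[IBISeries, int]:
    """Replace artifactual intervals by cubic-spline interpolation.

    An interval is flagged when it deviates from a centered running-median
    baseline (``window`` beats) by more than ``threshold_ms`` — the same
    logic as threshold-based RR correction in standard HRV packages.
    Flagged beats are replaced with a cubic spline fitted through the
    surrounding clean beats (on the beat index axis).

    Returns the corrected series and the number of replaced intervals.
    Raises if the series is too short (< 5 beats) or if so much of the
    segment is flagged that no baseline remains (unusable segment).
    """
    x = np.asarray(series.intervals, dtype=float)
    if x.size < 5:
        raise ValueError("artifact correction needs at least 5 intervals")
    if threshold_ms <= 0:
        raise ValueError("threshold_ms must be positive")
    med = ndimage.median_filter(x, size=window, mode="nearest")
    bad = np.abs(x - med) > threshold_ms
    n_bad = int(bad.sum())
    if n_bad == 0:
        return IBISeries(x, series.label, series.subject), 0
    good = ~bad
    if good.sum() < 4 or 2 * n_bad >= x.size:
        raise ValueError("segment unusable: most intervals flagged as artifacts")
    idx = np.arange(x.size)
    spl = interpolate.CubicSpline(idx[good], x[good])
    fixed = x.copy()
    fixed[bad] = spl(idx[bad])
    if np.any(fixed <= 0):  # spline overshoot on pathological input
        fixed[bad] = np.interp(idx[bad], idx[good], x[good])
    return IBISeries(fixed, series.label, series.subject), n_bad


def _ar_density(rho: np.ndarray, sigma2: float, freqs: np.ndarray, dt: float) -> np.ndarray:
    """One-sided AR spectral density on ``freqs`` (Hz) for sampling step dt (s)."""
    k = np.arange(1, rho.size + 1)
    # transfer denominator A(f) = 1 - sum rho_k exp(-2*pi*i*f*k*dt)
    phase = np.exp(-2j * np.pi * dt * np.outer(freqs, k))
    denom = np.abs(1.0 - phase @ rho) ** 2
    return 2.0 * sigma2 * dt / denom


def compute_ar_spectrum(
    series: IBISeries,
    resample_hz: float = 4.0,
    order: int = 16,
    grid_step_hz: float = 0.001,
) -> SpectralEstimate:
    """Autoregressive (Burg) spectral estimate of an IBI series.

    The unevenly spaced tachogram is cubic-interpolated to an even grid at
    ``resample_hz``, linearly detrended, fit with an AR model of the given
    order by Burg recursion, and the parametric one-sided density evaluated
    from 0 to Nyquist on a grid no coarser than ``grid_step_hz``.
    ``hf_power`` is the trapezoidal integral over 0.15-0.4 Hz; ``hf_peak``
    the in-band argmax.
    """
    if not isinstance(series, IBISeries):
        series = IBISeries(np.asarray(series, float))
    if series.duration_s < 60.0:
        raise ValueError("AR spectrum needs at least 60 s of intervals")
    t = series.times_s
    x = series.intervals
    if np.ptp(x) == 0:
        raise ValueError("constant IBI series has no variance to analyse")
    dt = 1.0 / resample_hz
    grid = np.arange(t[0], t[-1], dt)
    even = interpolate.CubicSpline(t, x)(grid)
    even = signal.detrend(even, type="linear")
    if np.allclose(even, 0):
        raise ValueError("detrended series is degenerate")
    order = int(order)
    if order < 1 or order >= even.size // 2:
        raise ValueError("invalid AR order for segment length")
    rho, sigma2 = burg(even, order=order, demean=True)
    # Stability: Burg-estimated models are minimum-phase by construction,
    # but guard against numerically marginal poles.
    poles = np.roots(np.r_[1.0, -rho])
    if np.any(np.abs(poles) >= 1.0 - 1e-10):
        raise ValueError("unstable AR fit: degenerate or near-deterministic input")
    nyq = resample_hz / 2.0
    n_grid = max(int(np.ceil(nyq / grid_step_hz)) + 1, 64)
    freqs = np.linspace(0.0, nyq, n_grid)
    dens = _ar_density(rho, float(sigma2), freqs, dt)
    lo, hi = HF_BAND
    band = (freqs >= lo) & (freqs <= hi)
    hf_power = float(np.trapezoid(dens[band], freqs[band]))
    hf_peak = float(freqs[band][np.argmax(dens[band])])
    return SpectralEstimate(
        frequencies=freqs,
        density=dens,
        order=order,
        resample_hz=resample_hz,
        hf_power=hf_power,
        hf_peak=hf_peak,
    )


def hrv_summary(
    series: IBISeries,
    correct: bool = True,
    threshold_ms: float = 250.0,
    resample_hz: float = 4.0,
    order: int = 16,
) -> HRVSummary:
    """Artifact-correct a segment and summarise RMSSD and HF spectral metrics."""
    n_corrected = 0
    if correct:
        series, n_corrected = correct_artifacts(series, threshold_ms=threshold_ms)
    rmssd = compute_rmssd(series)
    spec = compute_ar_spectrum(series, resample_hz=resample_hz, order=order)
    ln_rmssd = float(np.log(rmssd)) if rmssd > 0 else float("nan")
    return HRVSummary(
        rmssd=rmssd,
        ln_rmssd=ln_rmssd,
        hf_power=spec.hf_power,
        hf_peak=spec.hf_peak,
        n_corrected=n_corrected,
    )


def ln_skew_transform(
    values: np.ndarray,
    alpha: float = 0.05,
    force: bool = False,
) -> tuple[np.ndarray, bool]:
    """Natural-log transform a positively skewed, non-normal sample.

    The transform is applied iff a Shapiro-Wilk test rejects normality at
    ``alpha`` AND the sample skewness is positive (or when ``force`` is
    set).  Returns the (possibly transformed) values and the decision flag.
    """
    x = np.asarray(values, dtype=float)
    if force:
        apply = True
    else:
        if x.size < 3:
            raise ValueError("need at least 3 values for the normality gate")
        p = stats.shapiro(x).pvalue
        apply = bool(p < alpha and stats.skew(x) > 0)
    if not apply:
        return x, False
    if np.any(x <= 0):
        raise ValueError("log transform requires strictly positive values")
    return np.log(x), True
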