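"""The ten movement quantity and quality variables for one wear period.

Quantity (from activity counts):

* total activity counts, counts per minute, counts per day — 15 s epochs;
* median / SD of acceleration over *moving* seconds (vector-magnitude
  counts > 0) and peak acceleration over all seconds — 1 s epochs.

Quality (computed per calendar day, then averaged across days):

* sample entropy of the 1 Hz vector-magnitude series during the hour of
  highest activity (regularity; higher = more random);
* jerk: mean absolute first difference of the band-passed acceleration
  magnitude times the sampling rate, in g/s (smoothness; higher = less
  smooth);
* mean and SD of frequency: power-weighted first and second moments of the
  band-passed magnitude's spectral density (order of movement).

Undefined values (no moving seconds, no qualifying day, zero spectral
power) propagate as NaN and are excluded from downstream statistics —
never imputed as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import fft as _sfft
from scipy import signal as _signal

from .counts import DEFAULT_CONFIG, PipelineConfig, bandpass_magnitude, to_counts
from .io import EpochSeries, RawTrace

__all__ = [
    "MetricSet",
    "METRIC_COLUMNS",
    "quantity_metrics",
    "highest_activity_hour",
    "sample_entropy",
    "entropy_metric",
    "jerk_metric",
    "frequency_metrics",
    "metrics_for_wear",
]

#: Metric-table column names, in report order.
METRIC_COLUMNS = [
    "total_counts",
    "counts_per_minute",
    "counts_per_day",
    "median_accel",
    "sd_accel",
    "peak_accel",
    "entropy",
    "jerk",
    "mean_freq",
    "sd_freq",
]


@dataclass
class MetricSet:
    """The ten movement variables for one wear period (NaN = undefined)."""

    total_counts: float = math.nan
    counts_per_minute: float = math.nan
    counts_per_day: float = math.nan
    median_accel: float = math.nan
    sd_accel: float = math.nan
    peak_accel: float = math.nan
    entropy: float = math.nan
    jerk: float = math.nan
    mean_freq: float = math.nan
    sd_freq: float = math.nan
    wear_minutes: float = math.nan
    n_days: int = 0

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# ---------------------------------------------------------------------------
# quantity


def quantity_metrics(
    vm_1s: EpochSeries, vm_15s: EpochSeries, wear_minutes: float, n_days: int
) -> MetricSet:
    """Movement-quantity variables from the two epoch-count series.

    Totals come from the 15 s series; the acceleration distribution
    statistics come from the 1 s series, with median and SD restricted to
    moving seconds (vm > 0) and the peak taken over all seconds.
    """
    if len(vm_15s) == 0 or len(vm_1s) == 0:
        raise ValueError("epoch series must be non-empty")
    if wear_minutes <= 0:
        raise ValueError("wear_minutes must be positive")
    out = MetricSet(wear_minutes=wear_minutes, n_days=n_days)
    total = float(vm_15s.vm_counts.sum())
    out.total_counts = total
    out.counts_per_minute = total / wear_minutes
    out.counts_per_day = total / max(n_days, 1)
    vm1 = vm_1s.vm_counts
    moving = vm1[vm1 > 0]
    out.peak_accel = float(vm1.max())
    if moving.size:
        out.median_accel = float(np.median(moving))
        out.sd_accel = float(np.std(moving, ddof=1)) if moving.size > 1 else 0.0
    return out


def highest_activity_hour(vm_1s: EpochSeries) -> tuple[int, int]:
    """Index and length of the 3600 s window maximizing summed VM counts.

    Ties are broken toward the earliest start.  A series shorter than one
    hour is returned whole (callers treat that day as non-qualifying).
    """
    if vm_1s.epoch_length != 1:
        raise ValueError("highest_activity_hour requires the 1 s epoch series")
    n = len(vm_1s)
    if n < 3600:
        return 0, n
    c = np.concatenate([[0.0], np.cumsum(vm_1s.vm_counts)])
    sums = np.round(c[3600:] - c[:-3600], 6)  # rounding stabilizes exact ties
    return int(np.argmax(sums)), 3600


# ---------------------------------------------------------------------------
# sample entropy


def _template_match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered template-match pair counts (B at length m, A at length m+1).

    A pair of templates matches when every coordinate agrees within
    tolerance ``r`` (Chebyshev).  Both counts run over the same N−m
    template set and exclude self-matches.  Works off a single pairwise
    point-match matrix, so the comparisons are bitwise identical to direct
    pair-by-pair counting.
    """
    n = x.size
    nt = n - m
    close = np.abs(x[:, None] - x[None, :]) <= r
    match = close[:nt, :nt]
    for k in range(1, m):
        match = match & close[k : k + nt, k : k + nt]
    b = int(match.sum()) - nt
    match = match & close[m : m + nt, m : m + nt]
    a = int(match.sum()) - nt
    return b, a


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B) of a 1-D series.

    ``A`` counts pairs of (m+1)-length templates and ``B`` pairs of m-length
    templates agreeing to within Chebyshev tolerance ``r`` (self-matches
    excluded; both counts over the same N−m template set).  ``r`` defaults to
    0.2 × SD of the series.  A constant series yields 0; if no template
    pairs match at length m (B = 0) or m+1 (A = 0) the value is undefined
    and NaN is returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    b, a = _template_match_counts(x, m, r)
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# daily segmentation helpers


def _day_slices(
    start_time: pd.Timestamp, n: int, step_s: float
) -> list[tuple[int, int]]:
    """(start, stop) index ranges of each calendar day of the device clock."""
    sec0 = (start_time - start_time.normalize()).total_seconds()
    bounds = [0]
    k = int(sec0 // 86400) + 1
    while True:
        i = int(math.ceil((k * 86400 - sec0) / step_s))
        if i >= n:
            break
        bounds.append(i)
        k += 1
    bounds.append(n)
    return [(bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# quality metrics (daily, then averaged)


def entropy_metric(
    vm_1s: EpochSeries, config: PipelineConfig = DEFAULT_CONFIG
) -> float:
    """Across-day average of daily sample entropy in the busiest hour.

    Per qualifying calendar day (≥ ``min_day_seconds`` of data): locate the
    hour of highest activity, then compute sample entropy of that hour's
    1 Hz VM series with tolerance ``entropy_r_factor`` × that hour's SD.
    """
    daily: list[float] = []
    for lo, hi in _day_slices(vm_1s.start_time, len(vm_1s), vm_1s.epoch_length):
        if hi - lo < config.min_day_seconds:
            continue
        day = EpochSeries(
            epoch_length=1,
            axis_counts=vm_1s.axis_counts[lo:hi],
            vm_counts=vm_1s.vm_counts[lo:hi],
            start_time=vm_1s.start_time + pd.Timedelta(seconds=lo),
        )
        w0, wlen = highest_activity_hour(day)
        hour = day.vm_counts[w0 : w0 + wlen]
        sd = float(np.std(hour))
        if sd == 0.0:
            daily.append(0.0)
            continue
        val = sample_entropy(hour, m=config.entropy_m, r=config.entropy_r_factor * sd)
        if not math.isnan(val):
            daily.append(val)
    return float(np.mean(daily)) if daily else math.nan


def jerk_metric(
    bp_magnitude: np.ndarray,
    sampling_rate: float,
    start_time: pd.Timestamp,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """Across-day average jerk (g/s) of the band-passed magnitude.

    Daily jerk is the mean absolute first difference of sequential samples
    multiplied by the sampling rate; days contributing under a minute of
    data are skipped.
    """
    step = 1.0 / sampling_rate
    min_n = int(60.0 * sampling_rate)
    daily = []
    for lo, hi in _day_slices(start_time, len(bp_magnitude), step):
        if hi - lo < max(min_n, 2):
            continue
        daily.append(float(np.mean(np.abs(np.diff(bp_magnitude[lo:hi]))) * sampling_rate))
    return float(np.mean(daily)) if daily else math.nan


def _spectral_moments(
    x: np.ndarray, fs: float, kernel_span: int
) -> tuple[float, float]:
    """Power-weighted mean and SD frequency of a smoothed periodogram."""
    nfft = _sfft.next_fast_len(len(x))  # day-length records hit slow FFT sizes
    f, pxx = _signal.periodogram(x, fs=fs, detrend="constant", nfft=nfft)
    f, pxx = f[1:], pxx[1:]  # exclude the 0 Hz ordinate
    if kernel_span > 1:
        k = np.ones(kernel_span) / kernel_span
        pxx = np.convolve(pxx, k, mode="same")
    total = pxx.sum()
    if total <= 0:
        return math.nan, math.nan
    mean = float((f * pxx).sum() / total)
    var = float((pxx * (f - mean) ** 2).sum() / total)
    return mean, math.sqrt(max(var, 0.0))


def frequency_metrics(
    bp_magnitude: np.ndarray,
    sampling_rate: float,
    start_time: pd.Timestamp,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Across-day average (mean_frequency, sd_frequency) in Hz.

    Per qualifying day the spectral density of the band-passed magnitude is
    estimated by a moving-average-smoothed periodogram and its power-weighted
    mean and SD are taken.
    """
    step = 1.0 / sampling_rate
    min_n = int(60.0 * sampling_rate)
    means, sds = [], []
    for lo, hi in _day_slices(start_time, len(bp_magnitude), step):
        if hi - lo < min_n:
            continue
        mu, sd = _spectral_moments(
            bp_magnitude[lo:hi], sampling_rate, config.spectrum_kernel_span
        )
        if not math.isnan(mu):
            means.append(mu)
            sds.append(sd)
    if not means:
        return math.nan, math.nan
    return float(np.mean(means)), float(np.mean(sds))


# ---------------------------------------------------------------------------
# orchestration


def metrics_for_wear(
    trace: RawTrace, config: PipelineConfig = DEFAULT_CONFIG
) -> MetricSet:
    """Compute the full ten-variable MetricSet for one wear period.

    Counts flow from the raw trace through the count-conversion filter onto
    1 s and 15 s epoch grids (each computed independently from 30 Hz data);
    jerk and the frequency moments are computed on the 0.2–12 Hz band-passed
    magnitude; entropy on the 1 Hz VM series.  Undefined metrics stay NaN.
    """
    if trace.duration_s < 3600:
        raise ValueError("wear period must be at least one hour")
    vm_1s = to_counts(trace, 1, config)
    vm_15s = to_counts(trace, 15, config)
    wear_minutes = len(vm_1s) / 60.0
    n_days = max(1, int(round(wear_minutes / 1440.0)))
    out = quantity_metrics(vm_1s, vm_15s, wear_minutes, n_days)

    mag = bandpass_magnitude(trace, config.movement_band_hz, config.movement_band_order)
    trim = int(round(config.edge_trim_s * trace.sampling_rate))
    mag = mag[trim : len(mag) - trim]
    t0 = trace.start_time + pd.Timedelta(seconds=config.edge_trim_s)

    out.entropy = entropy_metric(vm_1s, config)
    out.jerk = jerk_metric(mag, trace.sampling_rate, t0, config)
    out.mean_freq, out.sd_freq = frequency_metrics(mag, trace.sampling_rate, t0, config)
    return out
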