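"""Atrial activation-frequency analysis of simulated activation-time series.

Tissue-level fibrillation simulations are post-processed from per-point
activation times t_{c,i} (the upstroke instants of successive action
potentials).  Each point's instantaneous frequency series fcs(m) is the
reciprocal cycle length resampled to 10 Hz; points whose spectrum is not
sufficiently peaked are discarded (peak-conditioned selection); the
remaining series are averaged into fs(m).  Summary statistics mirror the
ECG side: Ffs is the median over time of fs(m), and dFfs quantifies the
modulation linearly related to a 0.14 Hz respiratory-type sinusoid via the
same orthogonal-subspace-projection machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .modulation import build_delay_matrix, delta_ff, project
from .synthetic import ActivationSet

__all__ = [
    "SimFrequencyTrend",
    "instantaneous_frequency",
    "peak_conditioned_selection",
    "mean_trend_and_summary",
    "delta_ffs",
    "analyze_activation_set",
]

FS_SIM = 10.0  # Hz, resampling rate of the instantaneous-frequency series
PEAK_THRESHOLD = 0.25  # minimum spectral concentration around the peak
PEAK_HALFWIDTH = 0.05  # Hz
SIM_RESP_RATE = 0.14  # Hz, respiratory-type reference sinusoid


@dataclass
class SimFrequencyTrend:
    """Per-point and averaged activation-frequency trends with summaries."""

    grid: np.ndarray  # common 10 Hz time grid, s
    fcs: dict[str, np.ndarray]  # per-point series on `grid` (NaN outside span)
    retained: dict[str, bool]
    fs_mean: np.ndarray  # mean over retained points (NaN where none contribute)
    ffs: float  # Hz, median over time of fs_mean
    delta_ffs: float | None = None  # Hz


def instantaneous_frequency(times: np.ndarray, fs_out: float = FS_SIM,
                            ) -> tuple[np.ndarray, np.ndarray] | None:
    """Instantaneous activation frequency of one point, resampled to 10 Hz.

    The rate 1/(t_{i+1} - t_i) is attributed to the interval midpoint and
    linearly interpolated onto a uniform grid spanning the activation span.
    Returns ``(grid_times, values)`` or None (with a warning) for points
    with fewer than three activations.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        warnings.warn("point dropped: fewer than 3 activations")
        return None
    d = np.diff(times)
    rates = 1.0 / d
    mids = times[:-1] + d / 2.0
    t0 = np.ceil(mids[0] * fs_out) / fs_out
    t1 = np.floor(mids[-1] * fs_out) / fs_out
    if t1 <= t0:
        warnings.warn("point dropped: activation span shorter than one grid step")
        return None
    grid = np.arange(t0, t1 + 0.5 / fs_out, 1.0 / fs_out)
    return grid, np.interp(grid, mids, rates)


def _spectral_concentration(x: np.ndarray, fs: float = FS_SIM,
                            halfwidth: float = PEAK_HALFWIDTH) -> float:
    """Fraction of detrended Welch power within +/- halfwidth of the peak."""
    x = sps.detrend(np.asarray(x, dtype=float), type="linear")
    nperseg = min(x.size, 512)
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    # ignore the residual-drift bins below the resolvable band
    sel = f >= 0.05
    f, pxx = f[sel], pxx[sel]
    total = pxx.sum()
    if total <= 0:
        return 0.0
    fpk = f[np.argmax(pxx)]
    return float(pxx[np.abs(f - fpk) <= halfwidth].sum() / total)


def peak_conditioned_selection(fcs: dict[str, np.ndarray],
                               threshold: float = PEAK_THRESHOLD,
                               halfwidth: float = PEAK_HALFWIDTH,
                               ) -> dict[str, bool]:
    """Retain points whose frequency-series spectrum is sufficiently peaked.

    A point passes when the fraction of its detrended Welch-spectrum power
    within +/- ``halfwidth`` Hz of the spectral peak reaches ``threshold``.
    """
    if not fcs:
        raise ValueError("no fcs series supplied")
    retained = {}
    for pid, series in fcs.items():
        v = series[~np.isnan(series)]
        retained[pid] = bool(
            v.size >= 32 and _spectral_concentration(v, halfwidth=halfwidth) >= threshold
        )
    if not any(retained.values()):
        raise ValueError("no peaked series: every point failed peak-conditioned selection")
    return retained


def mean_trend_and_summary(grid: np.ndarray, fcs: dict[str, np.ndarray],
                           retained: dict[str, bool],
                           ) -> tuple[np.ndarray, float]:
    """Average retained per-point series into fs(m); Ffs is its time median.

    Points not covering a grid sample are excluded at that sample; samples
    with no contributing point are NaN.
    """
    kept = [fcs[p] for p in fcs if retained.get(p, False)]
    if not kept:
        raise ValueError("no retained points")
    stack = np.vstack(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        fs_mean = np.nanmean(stack, axis=0)
    if np.all(np.isnan(fs_mean)):
        raise ValueError("fs(m) undefined everywhere")
    ffs = float(np.nanmedian(fs_mean))
    return fs_mean, ffs


def delta_ffs(fs_series: np.ndarray, fs: float = FS_SIM,
              resp_rate: float = SIM_RESP_RATE, q: int | None = None,
              min_duration_s: float = 60.0) -> float:
    """dFfs: OSP modulation of fs(m) against a reference sinusoid.

    The respiration signal is sin(2 pi resp_rate t) on the 10 Hz grid — the
    simulation side has no measured respiration, so the known modulation
    frequency serves as the reference.
    """
    x = np.asarray(fs_series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size / fs < min_duration_s:
        raise ValueError(f"fs(m) must cover at least {min_duration_s} s")
    m = x.size
    t = np.arange(m) / fs
    r = np.sin(2 * np.pi * resp_rate * t)
    if q is None:
        q = max(int(round(fs / (4.0 * resp_rate))), 1)
    f_tilde = (x - x.mean())[:m - q]
    V = build_delay_matrix(r, q)
    fr = project(f_tilde, V)
    return delta_ff(fr)


def analyze_activation_set(aset: ActivationSet,
                           window: tuple[float, float] | None = None,
                           threshold: float = PEAK_THRESHOLD,
                           resp_rate: float = SIM_RESP_RATE,
                           min_duration_s: float = 60.0) -> SimFrequencyTrend:
    """Full activation-side analysis of one simulation's activation times."""
    aset.validate()
    per_point = {}
    for pid, times in aset.times.items():
        t = np.asarray(times, dtype=float)
        if window is not None:
            t = t[(t >= window[0]) & (t < window[1])]
        out = instantaneous_frequency(t)
        if out is not None:
            per_point[pid] = out
    if not per_point:
        raise ValueError("no usable points in activation set")
    t_lo = min(g[0] for g, _ in per_point.values())
    t_hi = max(g[-1] for g, _ in per_point.values())
    grid = np.arange(t_lo, t_hi + 0.5 / FS_SIM, 1.0 / FS_SIM)
    fcs = {}
    for pid, (g, v) in per_point.items():
        series = np.full(grid.size, np.nan)
        i0 = int(round((g[0] - t_lo) * FS_SIM))
        series[i0:i0 + v.size] = v
        fcs[pid] = series
    retained = peak_conditioned_selection(fcs, threshold=threshold)
    fs_mean, ffs = mean_trend_and_summary(grid, fcs, retained)
    try:
        dffs = delta_ffs(fs_mean, resp_rate=resp_rate, min_duration_s=min_duration_s)
    except ValueError as exc:
        warnings.warn(f"dFfs unavailable: {exc}")
        dffs = None
    return SimFrequencyTrend(grid=grid, fcs=fcs, retained=retained,
                             fs_mean=fs_mean, ffs=ffs, delta_ffs=dffs)
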