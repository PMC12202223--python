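"""ECG-derived respiration: per-lead QRS slope-range series and a joint-lead
respiration signal via periodic component analysis (piCA).

Respiration modulates QRS morphology; the slope range (difference between
the maximum and minimum derivative inside the QRS interval) tracks that
modulation beat by beat.  The per-lead beat series are spline-interpolated
to a uniform 50 Hz grid, band-passed to the respiratory band, and combined
into a single maximally periodic signal r(m): for each candidate period tau
the lead combination w minimising

    eps(tau) = w' A_tau w / w' C w,

with C the lead covariance and A_tau the covariance of the tau-lagged
difference, is the smallest generalized eigenvector; the tau minimising
eps gives the respiration-rate estimate FRR = fs / tau*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, linalg
from scipy import signal as sps

from .preprocess import BeatSet, ECGRecord

__all__ = [
    "LeadRespSeries",
    "RespirationEstimate",
    "slope_range_series",
    "interpolate_resp",
    "joint_respiration",
    "respiration_from_record",
]

FS = 50.0
RESP_BAND = (0.08, 0.5)  # Hz, scanned respiration band
QRS_HALF_WINDOW = 0.050  # s around R for the derivative


@dataclass
class LeadRespSeries:
    """Per-beat slope-range values and their uniform 50 Hz interpolation."""

    beat_times: np.ndarray  # s, non-ectopic beats
    values: np.ndarray  # mV/s, max-min derivative in the QRS interval
    lead: str
    series: np.ndarray | None = None  # 50 Hz band-passed series
    t0: float = 0.0  # time of series[0]


@dataclass
class RespirationEstimate:
    """Joint-lead respiration signal with rate estimate."""

    r: np.ndarray  # unit-variance series at 50 Hz
    frr: float  # Hz
    weights: np.ndarray  # per-lead combination vector
    epsilon: float  # periodicity score at tau* (smaller = more periodic)
    fs: float = FS
    t0: float = 0.0


def slope_range_series(record: ECGRecord, beats: BeatSet, lead: str) -> LeadRespSeries:
    """Per-beat QRS slope range on one lead (ectopic beats skipped).

    The derivative is the first difference of the waveform over R +/- 50 ms,
    scaled to mV/s; the value is its max minus min.
    """
    fs = record.fs
    # low-pass before differencing: the derivative amplifies broadband noise
    # far above the QRS slope scale; 35 Hz keeps the QRS slopes intact
    sos = sps.butter(4, min(35.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, record.lead(lead))
    half = int(round(QRS_HALF_WINDOW * fs))
    times, values = [], []
    for r, ect in zip(beats.r_peaks, beats.ectopic):
        if ect:
            continue
        lo, hi = r - half, r + half + 1
        if lo < 0 or hi > x.size:
            continue
        d = np.diff(x[lo:hi]) * fs
        values.append(float(d.max() - d.min()))
        times.append(r / fs)
    if not values:
        raise ValueError(f"no usable beats for slope-range series on lead {lead}")
    return LeadRespSeries(beat_times=np.asarray(times), values=np.asarray(values),
                          lead=lead)


def interpolate_resp(series: LeadRespSeries, fs: float = FS,
                     band: tuple[float, float] = RESP_BAND) -> LeadRespSeries:
    """Cubic-spline interpolate the beat series to 50 Hz and band-pass it.

    The output is zero-mean (linear detrend followed by a zero-phase
    band-pass over the respiratory band).
    """
    bt, v = series.beat_times, series.values
    if bt.size < 10:
        raise ValueError("need at least 10 beats to interpolate respiration")
    if bt[-1] - bt[0] < 30.0:
        raise ValueError("beats span less than 30 s; respiration not resolvable")
    t0 = np.ceil(bt[0] * fs) / fs
    t1 = np.floor(bt[-1] * fs) / fs
    grid = np.arange(t0, t1 + 0.5 / fs, 1.0 / fs)
    spline = interpolate.CubicSpline(bt, v)
    y = spline(grid)
    y = sps.detrend(y, type="linear")
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, y)
    return LeadRespSeries(beat_times=bt, values=v, lead=series.lead,
                          series=y - y.mean(), t0=float(t0))


def joint_respiration(lead_series: list[LeadRespSeries], fs: float = FS,
                      band: tuple[float, float] = RESP_BAND,
                      freq_step: float = 0.01) -> RespirationEstimate:
    """Combine interpolated lead series into one maximally periodic signal.

    Scans candidate respiration frequencies over ``band`` on a 0.01 Hz grid
    (as integer lags tau = round(fs/f)), solving the generalized eigenvalue
    problem for each; the global minimiser gives r(m) and FRR.
    """
    if len(lead_series) < 2:
        raise ValueError("need at least two lead series for joint respiration")
    if any(s.series is None for s in lead_series):
        raise ValueError("lead series must be interpolated first")
    t0 = max(s.t0 for s in lead_series)
    t1 = min(s.t0 + s.series.size / fs for s in lead_series)
    if t1 - t0 < 30.0:
        raise ValueError("common lead-series support is shorter than 30 s")
    Z = np.vstack([
        s.series[int(round((t0 - s.t0) * fs)): int(round((t0 - s.t0) * fs))
                 + int(round((t1 - t0) * fs))]
        for s in lead_series
    ])
    Z = Z - Z.mean(axis=1, keepdims=True)
    L, M = Z.shape
    C = (Z @ Z.T) / M
    # whiten against the principal subspace of C: directions with negligible
    # lead-series energy (e.g. duplicated leads) are excluded rather than
    # ridge-inflated, so degenerate lead sets stay well posed
    evals, evecs = linalg.eigh(C)
    keep = evals > max(1e-10 * evals[-1], 0.0)
    if not keep.all():
        warnings.warn("rank-deficient lead covariance; restricting to its "
                      "principal subspace")
    W = evecs[:, keep] / np.sqrt(evals[keep])  # L x k whitening map
    Y = W.T @ Z  # whitened series, covariance ~ identity

    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    taus = np.unique(np.round(fs / freqs).astype(int))
    taus = taus[(taus >= 2) & (taus < M // 2)]
    cand = []
    for tau in taus:
        D = Y[:, tau:] - Y[:, :-tau]
        A = (D @ D.T) / (M - tau)
        vals, vecs = linalg.eigh(A)
        cand.append((float(vals[0]), int(tau), W @ vecs[:, 0]))
    eps_min = min(c[0] for c in cand)
    # a signal periodic at tau is also periodic at its multiples; among
    # essentially tied minima prefer the smallest lag (highest frequency) so
    # a subharmonic never wins a tie
    eps, tau_star, w = min((c for c in cand if c[0] <= eps_min * 1.05 + 1e-12),
                           key=lambda c: c[1])
    # deterministic sign: dominant weight positive
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    r = w @ Z
    sd = r.std()
    if sd == 0:
        raise ValueError("degenerate respiration signal (zero variance)")
    r = r / sd
    return RespirationEstimate(r=r, frr=float(fs / tau_star), weights=w,
                               epsilon=eps, t0=t0)


def respiration_from_record(record: ECGRecord, beats: BeatSet,
                            window: tuple[float, float] | None = None,
                            band: tuple[float, float] = RESP_BAND,
                            ) -> RespirationEstimate:
    """Slope-range + piCA respiration estimate, optionally restricted to a
    phase window (the per-phase analysis path)."""
    series = []
    for ln in record.lead_names:
        s = slope_range_series(record, beats, ln)
        if window is not None:
            t0, t1 = window
            sel = (s.beat_times >= t0) & (s.beat_times < t1)
            if sel.sum() < 10:
                continue
            s = LeadRespSeries(beat_times=s.beat_times[sel], values=s.values[sel],
                               lead=ln)
        try:
            series.append(interpolate_resp(s, band=band))
        except ValueError:
            continue
    if len(series) < 2:
        raise ValueError("fewer than two usable lead series for respiration")
    return joint_respiration(series, band=band)
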