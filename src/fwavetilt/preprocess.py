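"""ECG preprocessing: beat detection, ectopic classification, QRST
cancellation and resampling of the atrial residual to the 50 Hz f-wave rate.

Ventricular activity dominates the surface ECG; to analyse the atrial
fibrillatory waves the QRST complexes are removed by average-beat
subtraction: a normal-beat template (median beat) is amplitude-scaled to and
subtracted from every non-ectopic beat, while ectopic-beat windows — whose
morphology the template does not represent — are bridged by interpolation.
The residual on lead V1 is then low-pass filtered and resampled to 50 Hz,
which comfortably covers the 4–12 Hz fibrillatory band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGRecord",
    "BeatSet",
    "FWaveSignal",
    "detect_beats",
    "classify_ectopic",
    "cancel_qrst",
    "resample_to_50hz",
    "mean_heart_rate",
]

#: template window around the R peak covering the QRST complex, in seconds.
#: In AF there is no P wave, so the window starts just before QRS onset;
#: keeping it inside one RR interval at fibrillatory rates avoids template
#: overlap between adjacent beats.
BEAT_WINDOW = (-0.100, 0.430)


@dataclass
class ECGRecord:
    """Multi-lead sampled ECG with a tilt-phase timeline.

    ``samples`` is (n_leads, n_samples) in mV; ``timeline`` holds
    (phase_name, start_s, end_s) tuples, non-overlapping and ordered.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str]
    timeline: list[tuple[str, float, float]]

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError("lead_names length must match samples rows")
        ends = 0.0
        for name, t0, t1 in self.timeline:
            if t0 < ends or t1 <= t0:
                raise ValueError("timeline phases must be ordered and non-overlapping")
            ends = t1

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name!r} not in record ({self.lead_names})") from None


@dataclass
class BeatSet:
    """Detected beats with ectopic flags and per-lead normal-beat templates."""

    r_peaks: np.ndarray  # sample indices, strictly increasing
    ectopic: np.ndarray  # bool per beat
    templates: dict[str, np.ndarray]  # lead -> median normal beat
    correlation: np.ndarray  # per-beat correlation with the template
    fs: float
    window: tuple[float, float] = BEAT_WINDOW

    @property
    def r_times(self) -> np.ndarray:
        return self.r_peaks / self.fs

    def window_samples(self) -> tuple[int, int]:
        return int(round(self.window[0] * self.fs)), int(round(self.window[1] * self.fs))


@dataclass
class FWaveSignal:
    """Atrial residual on the analysis lead, resampled to exactly 50 Hz."""

    x: np.ndarray
    fs: float = 50.0
    source_lead: str = "V1"

    def __post_init__(self):
        if self.fs != 50.0:
            raise ValueError("FWaveSignal is defined at 50 Hz")

    @property
    def duration(self) -> float:
        return self.x.size / self.fs


# --------------------------------------------------------------------------


def _detection_lead(record: ECGRecord) -> int:
    """Index of the lead with the largest QRS-band (10–30 Hz) energy."""
    sos = sps.butter(2, [5.0, min(30.0, 0.45 * record.fs)], btype="bandpass",
                     fs=record.fs, output="sos")
    energies = [np.sum(sps.sosfiltfilt(sos, x) ** 2) for x in record.samples]
    return int(np.argmax(energies))


def detect_beats(record: ECGRecord, lead: str | None = None) -> np.ndarray:
    """Detect R peaks on a designated lead.

    An energy-envelope detector: QRS-band (10–30 Hz) zero-phase filtering,
    squaring, 120 ms moving-average smoothing, then peak picking with a
    200 ms refractory period and refinement to the local filtered-signal
    extremum.  Returns R-peak sample indices.
    """
    if record.duration < 10.0:
        raise ValueError("need at least 10 s of signal for beat detection")
    idx = record.lead_names.index(lead) if lead is not None else _detection_lead(record)
    x = record.samples[idx]
    if np.ptp(x) < 1e-6 or np.std(x) < 1e-8:
        raise ValueError("no beats detected: flat or near-constant signal")
    fs = record.fs
    sos = sps.butter(2, [5.0, min(30.0, 0.45 * fs)], btype="bandpass", fs=fs,
                     output="sos")
    xf = sps.sosfiltfilt(sos, x)
    env = sps.convolve(xf ** 2, np.ones(int(round(0.120 * fs))) / (0.120 * fs),
                       mode="same")
    # threshold relative to the envelope's upper quantile; the band reaches
    # down to 5 Hz so wide (ectopic) complexes keep detectable energy
    height = 0.10 * np.quantile(env, 0.99)
    if height <= 0:
        raise ValueError("no beats detected: flat or near-constant signal")
    peaks, _ = sps.find_peaks(env, height=height, distance=int(round(0.200 * fs)))
    if peaks.size == 0:
        raise ValueError("no beats detected")
    # refine to the extremum of |filtered signal| within +/- 60 ms
    half = int(round(0.060 * fs))
    refined = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined[i] = lo + int(np.argmax(np.abs(xf[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [0]
    for i in range(1, refined.size):
        if refined[i] - refined[keep[-1]] >= int(round(0.200 * fs)):
            keep.append(i)
    return refined[keep]


def _beat_matrix(x: np.ndarray, r_peaks: np.ndarray, w0: int, w1: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack beat windows into a matrix; beats truncated at record edges are
    excluded from the matrix (mask returned)."""
    ok = (r_peaks + w0 >= 0) & (r_peaks + w1 <= x.size)
    idx = r_peaks[ok][:, None] + np.arange(w0, w1)[None, :]
    return x[idx], ok


def classify_ectopic(record: ECGRecord, r_peaks: np.ndarray,
                     lead: str | None = None, corr_threshold: float = 0.9,
                     rr_threshold: float = 0.5) -> BeatSet:
    """Flag ectopic beats against an iteratively built normal template.

    A beat is ectopic if its correlation with the median-beat template falls
    below ``corr_threshold`` or its preceding RR interval deviates from the
    local median RR by more than ``rr_threshold`` (fractional).  The template
    is recomputed from non-flagged beats in a second pass.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 10:
        raise ValueError("insufficient beats (need >= 10) for ectopic classification")
    idx = record.lead_names.index(lead) if lead is not None else _detection_lead(record)
    x = record.samples[idx]
    fs = record.fs
    w0, w1 = int(round(BEAT_WINDOW[0] * fs)), int(round(BEAT_WINDOW[1] * fs))
    # morphology is judged on the QRS sub-window (R +/- 100 ms), where the
    # template dominates the fibrillatory waves and noise
    q0, q1 = int(round(-0.100 * fs)), int(round(0.100 * fs))
    beats, ok = _beat_matrix(x, r_peaks, q0, q1)

    def correlations(template: np.ndarray) -> np.ndarray:
        b = beats - beats.mean(axis=1, keepdims=True)
        t = template - template.mean()
        denom = np.linalg.norm(b, axis=1) * np.linalg.norm(t)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (b @ t) / denom
        c = np.where(denom > 0, c, 1.0)
        return c

    corr_ok = np.ones(beats.shape[0])
    morph_flags = np.zeros(beats.shape[0], dtype=bool)
    for _ in range(2):  # two template passes
        sel = ~morph_flags
        if not np.any(sel):
            sel = np.ones(beats.shape[0], dtype=bool)
        template = np.median(beats[sel], axis=0)
        corr_ok = correlations(template)
        morph_flags = corr_ok < corr_threshold

    # RR-interval rule on the full beat sequence; intervals touching a
    # morphology-flagged beat are excluded (a mislocated ectopic R peak must
    # not flag its normal neighbours)
    morph_full = np.zeros(r_peaks.size, dtype=bool)
    morph_full[ok] = morph_flags
    rr = np.diff(r_peaks) / fs
    rr_flags = np.zeros(r_peaks.size, dtype=bool)
    if rr.size >= 3:
        k = 5
        med = np.array([np.median(rr[max(0, i - k):i + k + 1]) for i in range(rr.size)])
        dev = np.abs(rr - med) / med
        clean_interval = ~(morph_full[:-1] | morph_full[1:])
        rr_flags[1:] = (dev > rr_threshold) & clean_interval

    ectopic = np.zeros(r_peaks.size, dtype=bool)
    ectopic[ok] = morph_flags
    ectopic |= rr_flags

    corr_full = np.ones(r_peaks.size)
    corr_full[ok] = corr_ok

    templates = {}
    sel = ~ectopic
    for li, ln in enumerate(record.lead_names):
        b, okl = _beat_matrix(record.samples[li], r_peaks, w0, w1)
        use = sel[okl]
        templates[ln] = np.median(b[use], axis=0) if np.any(use) else np.median(b, axis=0)

    return BeatSet(r_peaks=r_peaks, ectopic=ectopic, templates=templates,
                   correlation=corr_full, fs=fs)


def cancel_qrst(record: ECGRecord, beats: BeatSet, lead: str = "V1",
                return_replaced: bool = False):
    """Remove ventricular activity from one lead by average-beat subtraction.

    For each non-ectopic beat the per-lead template is amplitude-scaled by
    least squares and subtracted over its window; ectopic-beat windows are
    replaced by linear interpolation between the surrounding residual
    samples.  Samples outside beat windows are untouched.  Returns the
    residual at the source sampling rate; with ``return_replaced`` also a
    boolean mask of the interpolation-replaced samples (these carry no
    atrial information and should be excluded downstream).
    """
    x = record.lead(lead).copy()
    replaced = np.zeros(x.size, dtype=bool)
    if beats is None or beats.r_peaks.size == 0:
        return (x, replaced) if return_replaced else x
    template = beats.templates[lead]
    w0, w1 = beats.window_samples()
    n = x.size
    fs = record.fs
    # per-beat alignment: residual jitter in R-peak refinement leaves large
    # derivative-level residue, so each beat is shifted (up to +/- 10 ms) to
    # maximize QRS-window correlation with the template
    max_shift = int(round(0.010 * fs))
    q0, q1 = int(round(-0.100 * fs)) - w0, int(round(0.100 * fs)) - w0
    tq = template[q0:q1] - template[q0:q1].mean()
    aligned = np.empty(beats.r_peaks.size, dtype=int)
    frac_shift = np.zeros(beats.r_peaks.size)
    for i, r in enumerate(beats.r_peaks):
        best, best_c = 0, -np.inf
        scores = {}
        for sh in range(-max_shift, max_shift + 1):
            lo = r + sh + w0 + q0
            hi = r + sh + w0 + q1
            if lo < 0 or hi > n:
                continue
            seg = x[lo:hi]
            c = float((seg - seg.mean()) @ tq)
            nrm = np.linalg.norm(seg - seg.mean())
            if nrm > 0:
                c /= nrm
            scores[sh] = c
            if c > best_c:
                best_c, best = c, sh
        aligned[i] = r + best
        # sub-sample refinement: parabola through the three scores around the
        # integer optimum (jitter of even one sample leaves QRS-derivative
        # scale residue, far above the f-wave amplitude)
        if best - 1 in scores and best + 1 in scores:
            cm, c0, cp = scores[best - 1], scores[best], scores[best + 1]
            denom = cm - 2 * c0 + cp
            if denom < 0:
                frac_shift[i] = np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5)
    tmpl_idx = np.arange(template.size)
    for r, ect, df in zip(aligned, beats.ectopic, frac_shift):
        lo, hi = r + w0, r + w1
        clo, chi = max(lo, 0), min(hi, n)
        if chi <= clo:
            continue
        tmpl = (template if df == 0.0
                else np.interp(tmpl_idx + df, tmpl_idx, template))
        seg = tmpl[clo - lo:chi - lo]
        if ect:
            continue  # handled in the interpolation pass below
        w = x[clo:chi]
        # segment-wise least-squares scaling: the QRS and the T wave get
        # independent gains (respiration modulates them differently), plus a
        # constant column absorbing local baseline
        t_rel = (np.arange(clo, chi) - r) / record.fs
        qrs_mask = np.abs(t_rel) <= 0.120
        A = np.column_stack([seg * qrs_mask, seg * ~qrs_mask, np.ones(seg.size)])
        gram = A.T @ A
        if np.linalg.cond(gram) < 1e10:
            coef = np.linalg.solve(gram, A.T @ w)
        else:
            coef, *_ = np.linalg.lstsq(A, w, rcond=None)
        coef[2] = 0.0  # fit the baseline, but do not subtract it from the residual
        x[clo:chi] = w - A @ coef
    for r, ect in zip(aligned, beats.ectopic):
        if not ect:
            continue
        lo, hi = max(r + w0, 0), min(r + w1, n)
        if hi <= lo:
            continue
        left = x[lo - 1] if lo > 0 else x[hi] if hi < n else 0.0
        right = x[hi] if hi < n else left
        x[lo:hi] = np.linspace(left, right, hi - lo + 2)[1:-1]
        replaced[lo:hi] = True
    return (x, replaced) if return_replaced else x


def resample_to_50hz(residual: np.ndarray, source_fs: float,
                     source_lead: str = "V1") -> FWaveSignal:
    """Anti-alias filter (zero-phase low-pass, 23 Hz corner) and rationally
    resample the atrial residual to 50 Hz.

    Output length is ``floor(duration * 50)``, the f-wave signal contract.
    """
    if source_fs < 100:
        raise ValueError("source_fs must be >= 100 Hz")
    x = np.asarray(residual, dtype=float)
    if source_fs == 50.0:
        return FWaveSignal(x=x.copy(), source_lead=source_lead)
    sos = sps.butter(10, 23.0, btype="lowpass", fs=source_fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    from fractions import Fraction

    frac = Fraction(50, int(round(source_fs))) if float(source_fs).is_integer() else \
        Fraction(50.0 / source_fs).limit_denominator(1000)
    y = sps.resample_poly(xf, frac.numerator, frac.denominator)
    n_out = int(np.floor(x.size * 50.0 / source_fs))
    return FWaveSignal(x=y[:n_out], source_lead=source_lead)


def mean_heart_rate(beats: BeatSet, window: tuple[float, float]) -> float:
    """Average heart rate (bpm) in a phase window, ectopic beats disregarded.

    Only RR intervals between consecutive beats fully inside the window are
    used, and any interval adjacent to an ectopic beat is dropped.  Returns
    NaN (with a warning) when fewer than two usable beats remain.
    """
    t0, t1 = window
    times = beats.r_times
    inside = (times >= t0) & (times < t1)
    usable_rr = []
    for i in range(times.size - 1):
        if not (inside[i] and inside[i + 1]):
            continue
        if beats.ectopic[i] or beats.ectopic[i + 1]:
            continue
        usable_rr.append(times[i + 1] - times[i])
    if len(usable_rr) < 1 or inside.sum() < 2:
        warnings.warn(f"fewer than 2 usable beats in window [{t0}, {t1}); FHR missing")
        return float("nan")
    return 60.0 / float(np.mean(usable_rr))
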