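"""Respiratory f-wave frequency modulation via orthogonal subspace projection.

The detrended frequency trend f~ is projected onto the subspace spanned by
delayed copies of the respiration signal r(m),

    V = [r_0, r_1, ..., r_q],    r_d = [r(1+d), ..., r(M-q+d)]',
    f_r = V (V'V)^{-1} V' f~,

so f_r captures the part of the frequency variation linearly related to
respiration (at any phase shift up to q samples).  Two summary statistics
follow: the average peak amplitude

    dFf = sqrt(2 f_r' f_r / (M - q)),

which equals the amplitude of a sinusoid with the same mean power, and the
relative power Pr(%) = 100 f_r' f_r / f~' f~.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .freq import FrequencyTrend
from .respiration import RespirationEstimate

__all__ = [
    "OSPResult",
    "build_delay_matrix",
    "project",
    "delta_ff",
    "relative_power",
    "phase_modulation",
    "default_q",
]

FS = 50.0
MAX_GAP_S = 5.0
MIN_RUN_S = 60.0


@dataclass
class OSPResult:
    """Per-phase orthogonal-subspace-projection outcome."""

    fr: np.ndarray  # projected series, length M - q
    delta_ff: float  # Hz
    pr: float  # percent
    q: int
    m: int  # window length in samples
    frac_interpolated: float = 0.0


def build_delay_matrix(r: np.ndarray, q: int) -> np.ndarray:
    """Delay-embedding matrix V of shape (M-q, q+1); column d holds
    r[d : M-q+d]."""
    r = np.asarray(r, dtype=float)
    M = r.size
    if q >= M / 2:
        raise ValueError(f"q={q} must be < M/2 = {M / 2}")
    if q < 0:
        raise ValueError("q must be >= 0")
    cols = [r[d:M - q + d] for d in range(q + 1)]
    return np.column_stack(cols)


#: relative singular-value cutoff of the rank-revealing solve.  The delay
#: matrix of a narrowband respiration signal is numerically full rank only
#: through its noise: directions below this fraction of the dominant
#: singular value are treated as rank-deficient and excluded, which keeps
#: the projection from soaking up broadband trend noise.  Well-conditioned
#: delay matrices (smallest singular value a sizeable fraction of the
#: largest) are unaffected.
RCOND = 0.05


def project(f_tilde: np.ndarray, V: np.ndarray, rcond: float = RCOND) -> np.ndarray:
    """Least-squares projection of the detrended trend onto span(V).

    Uses a rank-revealing solve (SVD-based lstsq with relative cutoff
    ``rcond``), so a rank-deficient V — e.g. a constant or narrowband
    respiration signal — degrades gracefully to the pseudo-inverse
    projection onto the significant directions.
    """
    f_tilde = np.asarray(f_tilde, dtype=float)
    if f_tilde.size != V.shape[0]:
        raise ValueError(f"length mismatch: f~ has {f_tilde.size}, V has {V.shape[0]} rows")
    coef, *_ = np.linalg.lstsq(V, f_tilde, rcond=rcond)
    return V @ coef


def delta_ff(fr: np.ndarray) -> float:
    """Average peak amplitude of the projected series:
    sqrt(2 fr'fr / len(fr))."""
    fr = np.asarray(fr, dtype=float)
    if fr.size == 0:
        raise ValueError("empty projected series")
    return float(np.sqrt(2.0 * (fr @ fr) / fr.size))


def relative_power(fr: np.ndarray, f_tilde: np.ndarray) -> float:
    """Pr(%) = 100 fr'fr / f~'f~; NaN with a warning for a zero-energy f~."""
    fr = np.asarray(fr, dtype=float)
    f_tilde = np.asarray(f_tilde, dtype=float)
    if fr.size != f_tilde.size:
        raise ValueError("fr and f~ must have equal length")
    denom = float(f_tilde @ f_tilde)
    if denom <= 1e-18:  # exactly/numerically zero after mean subtraction
        warnings.warn("zero-energy detrended trend; Pr undefined")
        return float("nan")
    return float(100.0 * (fr @ fr) / denom)


def default_q(frr: float, fs: float = FS) -> int:
    """Default delay count: a quarter respiratory period in samples, spanning
    a 90-degree phase shift of the narrowband respiratory component."""
    if not frr > 0:
        raise ValueError("frr must be positive")
    return max(int(round(fs / (4.0 * frr))), 1)


def _bridge_gaps(f: np.ndarray, valid: np.ndarray, fs: float,
                 max_gap_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate invalid gaps up to ``max_gap_s``; return the
    bridged series, a usability mask and the bridged-sample mask."""
    usable = valid.copy()
    bridged = np.zeros_like(valid)
    out = f.copy()
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out, usable, bridged
    max_gap = int(round(max_gap_s * fs))
    starts = []
    i = 0
    inval = ~valid
    n = valid.size
    while i < n:
        if inval[i]:
            j = i
            while j < n and inval[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                out[i:j] = np.interp(np.arange(i, j), [i - 1, j], [f[i - 1], f[j]])
                usable[i:j] = True
                bridged[i:j] = True
            i = j
        else:
            i += 1
    return out, usable, bridged


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, stop) of the longest contiguous True run."""
    best = (0, 0)
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def phase_modulation(trend: FrequencyTrend, resp: RespirationEstimate,
                     window: tuple[float, float], q: int | None = None,
                     max_gap_s: float = MAX_GAP_S,
                     min_run_s: float = MIN_RUN_S) -> OSPResult | None:
    """OSP quantification of respiratory modulation within one phase window.

    Invalid trend samples are bridged by linear interpolation when the gap
    is at most ``max_gap_s``; otherwise the longest contiguous usable run is
    analysed.  Returns None (with a warning) when that run is shorter than
    ``min_run_s``.
    """
    t0, t1 = window
    fs = trend.fs
    i0 = max(int(round(t0 * fs)), 0)
    i1 = min(int(round(t1 * fs)), trend.f.size)
    f = trend.f[i0:i1]
    valid = trend.valid[i0:i1]

    f_b, usable, bridged = _bridge_gaps(np.nan_to_num(f), valid, fs, max_gap_s)
    s, e = _longest_run(usable)
    if (e - s) / fs < min_run_s:
        warnings.warn(f"phase window [{t0}, {t1}): longest usable run "
                      f"{(e - s) / fs:.1f} s < {min_run_s} s; modulation missing")
        return None

    # align respiration over the same absolute samples
    r0 = int(round(resp.t0 * fs))
    a = i0 + s - r0
    b = i0 + e - r0
    if a < 0 or b > resp.r.size:
        a_clip, b_clip = max(a, 0), min(b, resp.r.size)
        if (b_clip - a_clip) / fs < min_run_s:
            warnings.warn("respiration does not cover the usable trend run; "
                          "modulation missing")
            return None
        s += a_clip - a
        e -= b - b_clip
        a, b = a_clip, b_clip

    fw = f_b[s:e]
    r = resp.r[a:b]
    M = fw.size
    if q is None:
        q = default_q(resp.frr, fs)
    if q >= M / 2:
        q = max(int(M / 2) - 1, 1)
    f_tilde = (fw - fw.mean())[:M - q]
    V = build_delay_matrix(r, q)
    fr = project(f_tilde, V)
    return OSPResult(
        fr=fr,
        delta_ff=delta_ff(fr),
        pr=relative_power(fr, f_tilde),
        q=q, m=M,
        frac_interpolated=float(bridged[s:e].mean()),
    )
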