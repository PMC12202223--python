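"""Synthetic tilt-test ECG and activation-time generator with known ground truth.

The clinical recordings this package is designed for (persistent AF patients
undergoing baseline / head-down / head-up tilt) are not publicly available,
so validation rests on a generator that emulates their statistical structure:

* an atrial fibrillatory (f-wave) signal modelled as a fundamental plus a
  second harmonic whose instantaneous frequency carries a slow sinusoidal
  respiratory modulation on top of an Ornstein--Uhlenbeck drift,
* an irregular ventricular response (log-normal RR intervals, no serial
  correlation — the classic approximation for AF), rendered as
  sum-of-Gaussians QRST complexes whose QRS slopes are modulated by
  respiration, with a small fraction of morphologically deviant ectopic
  beats,
* additive broadband noise, and
* activation-time series mimicking the per-point output of tissue-level
  fibrillation simulations (instantaneous activation rate with sinusoidal
  respiratory-type modulation, plus "unpeaked" broadband-rate points).

Every generated object is accompanied by a :class:`GroundTruth` record so
that downstream estimators can be scored against known values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FWaveGenParams",
    "VentricularGenParams",
    "PhaseSpec",
    "TiltScenario",
    "GroundTruth",
    "ActivationSet",
    "generate_fwave",
    "generate_ventricular",
    "generate_tilt_recording",
    "generate_activation_series",
    "table2_scenario",
    "PHASE_NAMES",
    "DEFAULT_PHASE_DURATIONS",
]

#: Protocol order of the six tilt-test sub-phases: first 2 min / last 3 min of
#: baseline supine rest, head-down tilt and head-up tilt.
PHASE_NAMES = ("B1", "B2", "HDT1", "HDT2", "HUT1", "HUT2")

#: Default sub-phase durations in seconds (2 + 3 minutes per tilt phase).
DEFAULT_PHASE_DURATIONS = (120.0, 180.0, 120.0, 180.0, 120.0, 180.0)


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class FWaveGenParams:
    """Parameters of the synthetic f-wave signal for one phase.

    ``ff_mean`` is the phase-mean fundamental frequency (the quantity the
    pipeline estimates as Ff); ``mod_amplitude`` is the peak amplitude of the
    sinusoidal respiratory frequency modulation (ground truth for dFf);
    ``resp_rate`` the respiration rate (ground truth for FRR).  Amplitudes
    are in mV on the analysis lead V1.
    """

    ff_mean: float = 6.7  # Hz
    mod_amplitude: float = 0.077  # Hz, peak amplitude of respiratory modulation
    resp_rate: float = 0.14  # Hz
    a1: float = 0.10  # mV, fundamental amplitude
    a2: float = 0.035  # mV, second-harmonic amplitude
    drift_sd: float = 0.02  # Hz, stationary SD of the slow OU drift
    noise_sd: float = 0.08  # mV, additive white noise at the record rate
    # (puts the 5-s block quality index S around 0.5-0.7, so the S>0.3 gate
    # is exercised but rarely triggered on clean records)

    def validate(self) -> None:
        if not 4.0 <= self.ff_mean <= 12.0:
            raise ValueError(f"ff_mean must be in [4, 12] Hz, got {self.ff_mean}")
        if self.mod_amplitude < 0:
            raise ValueError("mod_amplitude must be >= 0")
        if not 0.05 < self.resp_rate < 0.6:
            raise ValueError(f"resp_rate must be in (0.05, 0.6) Hz, got {self.resp_rate}")
        if self.a1 <= 0 or self.a2 < 0:
            raise ValueError("require a1 > 0 and a2 >= 0")
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError("drift_sd and noise_sd must be >= 0")


@dataclass
class VentricularGenParams:
    """Parameters of the synthetic ventricular (QRST) activity for one phase."""

    mean_hr: float = 93.5  # bpm, phase-mean heart rate (FHR ground truth)
    rr_cv: float = 0.15  # coefficient of variation of RR intervals (AF irregularity,
    # moderate: most such cohorts are rate-controlled under beta-blockade)
    resp_morph_gain: float = 0.15  # fractional QRS amplitude/slope modulation
    ectopic_rate: float = 0.0107  # fraction of beats replaced by ectopics
    qrs_width: float = 90.0  # ms
    qrs_amp: float = 1.0  # mV, R-wave amplitude on the reference lead
    t_wave_amp: float = 0.3  # mV

    def validate(self) -> None:
        if not 40.0 <= self.mean_hr <= 180.0:
            raise ValueError(f"mean_hr must be in [40, 180] bpm, got {self.mean_hr}")
        if not 0.0 <= self.ectopic_rate <= 0.2:
            raise ValueError(f"ectopic_rate must be in [0, 0.2], got {self.ectopic_rate}")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")


@dataclass
class PhaseSpec:
    """One tilt sub-phase: name, duration and its generator parameters."""

    name: str
    duration: float  # s
    fwave: FWaveGenParams = field(default_factory=FWaveGenParams)
    ventricular: VentricularGenParams = field(default_factory=VentricularGenParams)


@dataclass
class TiltScenario:
    """Ordered six-phase tilt-test scenario driving the recording generator."""

    phases: list[PhaseSpec]
    rng_seed: int = 0
    fs: float = 500.0  # Hz, record sampling rate
    lead_names: tuple[str, ...] = ("V1", "II", "V5")

    def validate(self) -> None:
        names = [p.name for p in self.phases]
        if names != list(PHASE_NAMES):
            raise ValueError(
                f"phases must be exactly {PHASE_NAMES} in protocol order, got {names}"
            )
        for p in self.phases:
            if p.duration <= 0:
                raise ValueError(f"phase {p.name} has non-positive duration")
            p.fwave.validate()
            p.ventricular.validate()
        if "V1" not in self.lead_names:
            raise ValueError("lead V1 is required")
        if len(self.lead_names) < 2:
            raise ValueError("at least two leads are required")
        if self.fs < 250:
            raise ValueError("fs must be >= 250 Hz for QRS work")

    @property
    def timeline(self) -> list[tuple[str, float, float]]:
        """(name, start_s, end_s) per phase."""
        out, t = [], 0.0
        for p in self.phases:
            out.append((p.name, t, t + p.duration))
            t += p.duration
        return out


@dataclass
class GroundTruth:
    """Known truth accompanying a generated recording."""

    fs_truth: float  # sampling rate of f_true (50 Hz)
    f_true: np.ndarray  # instantaneous fundamental frequency, Hz
    beat_times: np.ndarray  # s
    ectopic: np.ndarray  # bool per beat
    timeline: list[tuple[str, float, float]]
    per_phase: dict[str, dict[str, float]]  # ff, delta_ff, frr, fhr per phase

    def to_dict(self) -> dict:
        return {
            "fs_truth": self.fs_truth,
            "f_true": self.f_true.tolist(),
            "beat_times": self.beat_times.tolist(),
            "ectopic": self.ectopic.astype(int).tolist(),
            "timeline": [list(t) for t in self.timeline],
            "per_phase": self.per_phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            fs_truth=float(d["fs_truth"]),
            f_true=np.asarray(d["f_true"], dtype=float),
            beat_times=np.asarray(d["beat_times"], dtype=float),
            ectopic=np.asarray(d["ectopic"], dtype=bool),
            timeline=[tuple(t) for t in d["timeline"]],
            per_phase=d["per_phase"],
        )


@dataclass
class ActivationSet:
    """Per-point activation times emulating tissue-simulation output.

    ``times[c]`` holds the strictly increasing activation instants of point
    ``c`` (seconds); ``truth`` records generator parameters when available.
    """

    times: dict[str, np.ndarray]
    duration: float
    truth: dict | None = None

    def validate(self, refractory_floor: float = 0.030) -> None:
        for pid, t in self.times.items():
            t = np.asarray(t, dtype=float)
            if t.size < 2:
                raise ValueError(f"point {pid}: need >= 2 activations")
            d = np.diff(t)
            if np.any(d <= 0):
                raise ValueError(f"point {pid}: activation times not strictly increasing")
            if np.any(d <= refractory_floor):
                raise ValueError(
                    f"point {pid}: inter-activation interval below the "
                    f"{refractory_floor*1e3:.0f} ms refractoriness floor"
                )


# --------------------------------------------------------------------------
# low-level builders


def _ou_drift(n: int, fs: float, sd: float, tau: float, rng: np.random.Generator,
              clip: float = 0.5) -> np.ndarray:
    """Ornstein--Uhlenbeck random walk with stationary SD `sd`, clipped so the
    composite frequency stays inside the constrained search interval."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau * fs))
    innov_sd = sd * np.sqrt(1.0 - a * a)
    e = rng.standard_normal(n) * innov_sd
    e[0] = rng.standard_normal() * sd  # stationary start
    x = lfilter([1.0], [1.0, -a], e)  # AR(1) recursion x[i] = a x[i-1] + e[i]
    return np.clip(x, -clip, clip)


def _fwave_from_ftrue(f_true: np.ndarray, fs: float, a1, a2, phi1: float,
                      phi2: float) -> np.ndarray:
    """Render a real two-harmonic f-wave from an instantaneous-frequency series.

    The phase is the integral of f_true so the analytic equivalent of the
    output matches the harmonic model the estimator fits.  ``a1``/``a2`` may
    be scalars or per-sample arrays (piecewise-constant across phases).
    """
    phase = 2.0 * np.pi * np.cumsum(f_true) / fs
    return a1 * np.cos(phase + phi1) + a2 * np.cos(2.0 * phase + phi2)


def _qrst_template(fs: float, qrs_width_ms: float, qrs_amp: float, t_amp: float,
                   ectopic: bool = False) -> tuple[np.ndarray, np.ndarray, int]:
    """Sum-of-Gaussians QRST template on a -250..+450 ms window around R.

    Returns (qrs_part, t_part, r_index); the QRS part is the portion scaled by
    the respiratory morphology gain.  Ectopic templates are widened and
    polarity-inverted, mimicking a ventricular-origin beat.
    """
    t = np.arange(int(round(-0.25 * fs)), int(round(0.45 * fs))) / fs
    w = qrs_width_ms / 90.0
    if ectopic:
        w *= 1.9
        sign = -0.9
    else:
        sign = 1.0
    t_shift = 0.0  # main deflection centred on the nominal R time
    # Q, R, S deflections
    qrs = (
        -0.12 * qrs_amp * np.exp(-0.5 * ((t - t_shift + 0.028 * w) / (0.010 * w)) ** 2)
        + qrs_amp * np.exp(-0.5 * ((t - t_shift) / (0.016 * w)) ** 2)
        - 0.25 * qrs_amp * np.exp(-0.5 * ((t - t_shift - 0.030 * w) / (0.012 * w)) ** 2)
    ) * sign
    t_wave = t_amp * np.exp(-0.5 * ((t - 0.26) / (0.055 if not ectopic else 0.09)) ** 2)
    if ectopic:
        t_wave = -t_wave
    r_index = int(round(0.25 * fs))
    return qrs, t_wave, r_index


# --------------------------------------------------------------------------
# public generators


def generate_fwave(params: FWaveGenParams, duration: float, fs: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phase of synthetic f-wave signal.

    Returns ``(signal, f_true)`` where ``f_true`` is the instantaneous
    fundamental frequency sampled at ``fs``:
    ``f_true(t) = ff_mean + mod_amplitude * sin(2*pi*resp_rate*t) + drift(t)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    params.validate()
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    drift = _ou_drift(n, fs, params.drift_sd, tau=30.0, rng=rng)
    f_true = params.ff_mean + params.mod_amplitude * np.sin(2 * np.pi * params.resp_rate * t) + drift
    phi1, phi2 = rng.uniform(-np.pi, np.pi, size=2)
    x = _fwave_from_ftrue(f_true, fs, params.a1, params.a2, phi1, phi2)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=n)
    return x, f_true


def generate_ventricular(params: VentricularGenParams, duration: float, fs: float,
                         resp_rate: float, rng: np.random.Generator,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one phase of ventricular activity.

    Returns ``(signal, beat_times, ectopic)``.  RR intervals are i.i.d.
    log-normal with mean ``60/mean_hr`` s and coefficient of variation
    ``rr_cv``; QRS amplitude is scaled by
    ``1 + resp_morph_gain * sin(2*pi*resp_rate*t_beat)``; ectopic beats use a
    widened inverted-polarity template.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if duration <= 0:
        raise ValueError("duration must be positive")
    params.validate()
    beat_times, ectopic = _draw_beats(params, duration, rng)
    resp_phase = 2 * np.pi * resp_rate * beat_times
    signal = _render_beats(params, beat_times, ectopic, resp_phase, duration, fs)
    return signal, beat_times, ectopic


def _draw_beats(params: VentricularGenParams, duration: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mean_rr = 60.0 / params.mean_hr
    if params.rr_cv == 0:
        n_max = int(np.ceil(duration / mean_rr)) + 2
        rr = np.full(n_max, mean_rr)
    else:
        sigma2 = np.log(1.0 + params.rr_cv ** 2)
        mu = np.log(mean_rr) - sigma2 / 2.0
        n_max = int(np.ceil(duration / mean_rr * (1 + 4 * params.rr_cv))) + 10
        rr = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_max)
        rr = np.maximum(rr, 0.25)  # physiological floor
    beat_times = 0.4 + np.cumsum(rr)
    beat_times = beat_times[beat_times < duration - 0.05]
    ectopic = rng.random(beat_times.size) < params.ectopic_rate
    return beat_times, ectopic


def _render_beats(params: VentricularGenParams, beat_times: np.ndarray,
                  ectopic: np.ndarray, resp_phase: np.ndarray, duration: float,
                  fs: float, gain: float = 1.0) -> np.ndarray:
    n = int(round(duration * fs))
    signal = np.zeros(n)
    qrs_n, t_n, r_idx = _qrst_template(fs, params.qrs_width, params.qrs_amp,
                                       params.t_wave_amp, ectopic=False)
    qrs_e, t_e, _ = _qrst_template(fs, params.qrs_width, params.qrs_amp,
                                   params.t_wave_amp, ectopic=True)
    tmpl_len = qrs_n.size
    for bt, ect, ph in zip(beat_times, ectopic, resp_phase):
        morph = 1.0 + params.resp_morph_gain * np.sin(ph)
        qrs, tw = (qrs_e, t_e) if ect else (qrs_n, t_n)
        beat = morph * qrs + tw
        start = int(round(bt * fs)) - r_idx
        lo, hi = max(start, 0), min(start + tmpl_len, n)
        signal[lo:hi] += gain * beat[lo - start:hi - start]
    return signal


def generate_tilt_recording(scenario: TiltScenario):
    """Generate a full six-phase multi-lead tilt-test record with ground truth.

    The f-wave phase and the respiratory phase are integrated continuously
    across phase boundaries, so the record behaves like one recording whose
    parameters change at the tilt transitions, not like six concatenated
    independent signals.  Lead V1 carries a 3x larger f-wave projection than
    the other leads, reflecting its role as the atrial analysis lead.

    Returns ``(record, truth)`` where ``record`` is a
    :class:`fwavetilt.preprocess.ECGRecord`.
    """
    scenario.validate()
    return _generate_from_phases(scenario.phases,
                                 np.random.default_rng(scenario.rng_seed),
                                 scenario.fs, scenario.lead_names)


def generate_phase_recording(phase: PhaseSpec, seed: int = 0, fs: float = 500.0,
                             lead_names: tuple[str, ...] = ("V1", "II", "V5")):
    """Generate a single-phase record (for controlled one-condition studies)."""
    phase.fwave.validate()
    phase.ventricular.validate()
    if phase.duration <= 0:
        raise ValueError("phase duration must be positive")
    return _generate_from_phases([phase], np.random.default_rng(seed), fs,
                                 lead_names)


def _generate_from_phases(phases: list[PhaseSpec], rng: np.random.Generator,
                          fs: float, lead_names: tuple[str, ...]):
    from .preprocess import ECGRecord  # local import to avoid a cycle

    timeline = []
    t_acc = 0.0
    for p in phases:
        timeline.append((p.name, t_acc, t_acc + p.duration))
        t_acc += p.duration
    total = timeline[-1][2]
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # piecewise-constant parameter series at the record rate
    ff_mean = np.empty(n)
    mod_amp = np.empty(n)
    resp_rate = np.empty(n)
    a1 = np.empty(n)
    a2 = np.empty(n)
    noise_sd = np.empty(n)
    for (name, t0, t1), ph in zip(timeline, phases):
        sl = slice(int(round(t0 * fs)), int(round(t1 * fs)))
        ff_mean[sl] = ph.fwave.ff_mean
        mod_amp[sl] = ph.fwave.mod_amplitude
        resp_rate[sl] = ph.fwave.resp_rate
        a1[sl] = ph.fwave.a1
        a2[sl] = ph.fwave.a2
        noise_sd[sl] = ph.fwave.noise_sd

    # continuous respiratory phase and f-wave frequency
    resp_phase = 2 * np.pi * np.cumsum(resp_rate) / fs
    drift = _ou_drift(n, fs, phases[0].fwave.drift_sd, tau=30.0, rng=rng)
    f_true = ff_mean + mod_amp * np.sin(resp_phase) + drift
    phi1, phi2 = rng.uniform(-np.pi, np.pi, size=2)
    fwave = _fwave_from_ftrue(f_true, fs, a1, a2, phi1, phi2)

    # sequential beat train with phase-dependent RR statistics
    beat_times_l: list[float] = []
    ectopic_l: list[bool] = []
    t_cur = 0.4
    for (name, t0, t1), ph in zip(timeline, phases):
        v = ph.ventricular
        mean_rr = 60.0 / v.mean_hr
        sigma2 = np.log(1.0 + v.rr_cv ** 2) if v.rr_cv > 0 else 0.0
        mu = np.log(mean_rr) - sigma2 / 2.0
        while t_cur < t1 - 0.05:
            if t_cur >= t0:
                beat_times_l.append(t_cur)
                ectopic_l.append(bool(rng.random() < v.ectopic_rate))
            rr = np.exp(mu + np.sqrt(sigma2) * rng.standard_normal()) if sigma2 > 0 else mean_rr
            t_cur += max(rr, 0.25)
    beat_times = np.asarray(beat_times_l)
    ectopic = np.asarray(ectopic_l, dtype=bool)

    # render ventricular activity once per lead gain
    beat_resp_phase = np.interp(beat_times, t, resp_phase)
    v0 = phases[0].ventricular
    # morphology parameters assumed phase-invariant apart from the gain series
    vent = _render_beats(v0, beat_times, ectopic, beat_resp_phase, total, fs)

    fwave_gain = {ln: (1.0 if ln == "V1" else 1.0 / 3.0) for ln in lead_names}
    vent_gain = {"V1": 0.8, "II": 1.0, "V5": 0.9}
    samples = np.empty((len(lead_names), n))
    for i, ln in enumerate(lead_names):
        noise = rng.normal(0.0, 1.0, size=n) * noise_sd
        samples[i] = vent_gain.get(ln, 1.0) * vent + fwave_gain[ln] * fwave + noise

    record = ECGRecord(samples=samples, fs=fs, lead_names=list(lead_names),
                       timeline=timeline)

    # ground truth, f_true stored at the 50 Hz analysis rate
    step = max(int(round(fs / 50.0)), 1)
    f_true_50 = f_true[::step]
    per_phase: dict[str, dict[str, float]] = {}
    for (name, t0, t1), ph in zip(timeline, phases):
        in_ph = (t >= t0) & (t < t1)
        # true FHR: mean RR over consecutive normal beats inside the phase,
        # intervals adjacent to an ectopic excluded (the FHR definition)
        inb = (beat_times >= t0) & (beat_times < t1)
        rr = [beat_times[i + 1] - beat_times[i]
              for i in range(beat_times.size - 1)
              if inb[i] and inb[i + 1] and not ectopic[i] and not ectopic[i + 1]]
        fhr = 60.0 / float(np.mean(rr)) if rr else float("nan")
        per_phase[name] = {
            "ff": float(np.median(f_true[in_ph])),
            "delta_ff": float(ph.fwave.mod_amplitude),
            "frr": float(ph.fwave.resp_rate),
            "fhr": float(fhr),
        }
    truth = GroundTruth(fs_truth=fs / step, f_true=f_true_50, beat_times=beat_times,
                        ectopic=ectopic, timeline=timeline, per_phase=per_phase)
    return record, truth


def generate_activation_series(n_points: int, duration: float, base_freq: float,
                               mod_amplitude: float, resp_rate: float,
                               jitter_sd: float, frac_unpeaked: float,
                               rng: np.random.Generator) -> ActivationSet:
    """Generate per-point activation-time series with a known rate profile.

    Each regular point fires at instantaneous rate
    ``base_freq + mod_amplitude * sin(2*pi*resp_rate*t)`` with Gaussian timing
    jitter of SD ``jitter_sd`` seconds; a fraction ``frac_unpeaked`` of points
    instead get broadband random rates, to exercise downstream
    peak-conditioned rejection.
    """
    if base_freq <= 0:
        raise ValueError("base_freq must be positive")
    if not 0 <= frac_unpeaked < 1:
        raise ValueError("frac_unpeaked must be in [0, 1)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_unpeaked = int(round(frac_unpeaked * n_points))
    unpeaked = np.zeros(n_points, dtype=bool)
    unpeaked[rng.choice(n_points, size=n_unpeaked, replace=False)] = True

    times: dict[str, np.ndarray] = {}
    for c in range(n_points):
        pid = f"p{c:03d}"
        tt: list[float] = []
        t_cur = float(rng.uniform(0, 1.0 / base_freq))
        while t_cur < duration:
            tt.append(t_cur)
            if unpeaked[c]:
                rate = base_freq + rng.normal(0.0, 0.6)
                rate = max(rate, 1.0)
                dt = 1.0 / rate
            else:
                # implicit midpoint: dt = 1 / rate(t + dt/2), two fixed-point sweeps
                dt = 1.0 / base_freq
                for _ in range(2):
                    rate = base_freq + mod_amplitude * np.sin(
                        2 * np.pi * resp_rate * (t_cur + dt / 2.0))
                    dt = 1.0 / rate
            if jitter_sd > 0:
                dt = max(dt + rng.normal(0.0, jitter_sd), 0.035)
            t_cur += dt
        times[pid] = np.asarray(tt)
    truth = {
        "base_freq": base_freq,
        "mod_amplitude": mod_amplitude,
        "resp_rate": resp_rate,
        "jitter_sd": jitter_sd,
        "unpeaked": {f"p{c:03d}": bool(unpeaked[c]) for c in range(n_points)},
    }
    return ActivationSet(times=times, duration=duration, truth=truth)


# --------------------------------------------------------------------------
# calibrated default scenario


#: Per-phase calibration: phase-mean fundamental frequency (Hz), respiratory
#: modulation amplitude (Hz), respiration rate (Hz) and mean heart rate (bpm)
#: matching the reported clinical medians for the six tilt sub-phases.
TABLE2_CALIBRATION = {
    "B1":   {"ff_mean": 6.74, "mod_amplitude": 0.077, "resp_rate": 0.13, "mean_hr": 93.5},
    "B2":   {"ff_mean": 6.69, "mod_amplitude": 0.070, "resp_rate": 0.13, "mean_hr": 89.75},
    "HDT1": {"ff_mean": 6.49, "mod_amplitude": 0.090, "resp_rate": 0.15, "mean_hr": 90.25},
    "HDT2": {"ff_mean": 6.55, "mod_amplitude": 0.063, "resp_rate": 0.16, "mean_hr": 93.5},
    "HUT1": {"ff_mean": 6.77, "mod_amplitude": 0.081, "resp_rate": 0.12, "mean_hr": 98.5},
    "HUT2": {"ff_mean": 6.72, "mod_amplitude": 0.079, "resp_rate": 0.15, "mean_hr": 96.0},
}


def table2_scenario(seed: int = 0, fs: float = 500.0, *, noise_sd: float | None = None,
                    drift_sd: float | None = None,
                    durations: tuple[float, ...] = DEFAULT_PHASE_DURATIONS,
                    ) -> TiltScenario:
    """Six-phase scenario calibrated to the reported clinical phase medians."""
    phases = []
    for name, dur in zip(PHASE_NAMES, durations):
        cal = TABLE2_CALIBRATION[name]
        fw = FWaveGenParams(ff_mean=cal["ff_mean"], mod_amplitude=cal["mod_amplitude"],
                            resp_rate=cal["resp_rate"])
        if noise_sd is not None:
            fw.noise_sd = noise_sd
        if drift_sd is not None:
            fw.drift_sd = drift_sd
        vp = VentricularGenParams(mean_hr=cal["mean_hr"])
        phases.append(PhaseSpec(name=name, duration=dur, fwave=fw, ventricular=vp))
    return TiltScenario(phases=phases, rng_seed=seed, fs=fs)


def scenario_to_dict(scenario: TiltScenario) -> dict:
    """Serializable form of a scenario (round-trips through YAML/JSON)."""
    return {
        "rng_seed": scenario.rng_seed,
        "fs": scenario.fs,
        "lead_names": list(scenario.lead_names),
        "phases": [
            {
                "name": p.name,
                "duration": p.duration,
                "fwave": dataclasses.asdict(p.fwave),
                "ventricular": dataclasses.asdict(p.ventricular),
            }
            for p in scenario.phases
        ],
    }


def scenario_from_dict(d: dict) -> TiltScenario:
    phases = [
        PhaseSpec(
            name=p["name"],
            duration=float(p["duration"]),
            fwave=FWaveGenParams(**p.get("fwave", {})),
            ventricular=VentricularGenParams(**p.get("ventricular", {})),
        )
        for p in d["phases"]
    ]
    return TiltScenario(
        phases=phases,
        rng_seed=int(d.get("rng_seed", 0)),
        fs=float(d.get("fs", 500.0)),
        lead_names=tuple(d.get("lead_names", ("V1", "II", "V5"))),
    )
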