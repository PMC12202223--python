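"""End-to-end pipelines: ECG record -> per-phase metrics; activation files ->
per-simulation summaries.

Every exclusion (bad quality block, gated recording, unpeaked point,
insufficient phase coverage) is logged with the rule that triggered it —
nothing is dropped silently.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import freq, io, modulation, preprocess, respiration
from .activation import analyze_activation_set
from .config import AnalysisConfig
from .preprocess import ECGRecord

__all__ = ["run_ecg_pipeline", "run_activation_pipeline"]

logger = logging.getLogger("fwavetilt")


def run_ecg_pipeline(record: ECGRecord, config: AnalysisConfig | None = None,
                     record_id: str = "record") -> pd.DataFrame:
    """Analyze one tilt-test ECG record into per-phase metrics.

    Returns a long-form table with one row per phase: ``patient``, ``phase``,
    ``ff`` (Hz), ``fhr`` (bpm), ``frr`` (Hz), ``delta_ff`` (Hz), ``pr`` (%),
    plus provenance columns (``usable``, ``valid_fraction``,
    ``frac_interpolated``).  A recording failing the quality gate is
    returned with ``usable=False`` and all metrics missing.
    """
    config = config or AnalysisConfig()

    r_peaks = preprocess.detect_beats(record)
    beats = preprocess.classify_ectopic(
        record, r_peaks,
        corr_threshold=config.ectopic_corr_threshold,
        rr_threshold=config.ectopic_rr_threshold,
    )
    logger.info("%s: %d beats, %.2f%% ectopic", record_id, r_peaks.size,
                100 * beats.ectopic.mean())

    residual, replaced = preprocess.cancel_qrst(record, beats, lead="V1",
                                                return_replaced=True)
    fsig = preprocess.resample_to_50hz(residual, record.fs)
    mask50 = np.zeros(fsig.x.size, dtype=bool)
    idx = np.unique((np.flatnonzero(replaced) * 50.0 / record.fs).astype(int))
    mask50[idx[idx < mask50.size]] = True

    f0 = freq.welch_anchor(fsig, band=config.f_band,
                           segment_s=config.welch_segment_s)
    xa = freq.analytic_signal(fsig)
    trend, recon = freq.frequency_trend(xa, f0, half_range=config.f_half_range)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s_blocks, q_valid = freq.quality_index(xa, recon,
                                               s_threshold=config.s_threshold)
    trend.valid &= q_valid
    half = freq.WINDOW_N // 2
    dil = np.convolve(mask50.astype(float), np.ones(2 * half + 1), mode="same") > 0
    trend.valid &= ~dil
    trend.s_blocks = s_blocks

    usable = freq.recording_gate(s_blocks, s_threshold=config.s_threshold,
                                 max_bad_fraction=config.max_bad_block_fraction)
    rows = []
    if not usable:
        bad = float(np.mean(np.isnan(s_blocks) | (s_blocks <= config.s_threshold)))
        logger.warning("%s EXCLUDED: %.0f%% of 5-s blocks below the S>%.1f "
                       "quality gate (limit %.0f%%)", record_id, 100 * bad,
                       config.s_threshold, 100 * config.max_bad_block_fraction)
        for name, t0, t1 in record.timeline:
            rows.append({"patient": record_id, "phase": name, "usable": False,
                         "ff": np.nan, "fhr": np.nan, "frr": np.nan,
                         "delta_ff": np.nan, "pr": np.nan,
                         "valid_fraction": np.nan, "frac_interpolated": np.nan})
        return pd.DataFrame(rows)

    for name, t0, t1 in record.timeline:
        window = (t0, t1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ff = freq.phase_median_frequency(trend, window,
                                             min_valid_fraction=config.min_valid_fraction)
            fhr = preprocess.mean_heart_rate(beats, window)
        if np.isnan(ff):
            logger.warning("%s %s: Ff missing (<%.0f%% valid trend samples)",
                           record_id, name, 100 * config.min_valid_fraction)
        try:
            resp = respiration.respiration_from_record(record, beats, window=window,
                                                       band=config.pica_band)
            frr = resp.frr
        except ValueError as exc:
            logger.warning("%s %s: respiration unavailable (%s)", record_id, name, exc)
            resp, frr = None, np.nan
        dff, pr, frac_interp = np.nan, np.nan, np.nan
        if resp is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                osp = modulation.phase_modulation(
                    trend, resp, window, q=config.q_delays,
                    max_gap_s=config.max_gap_s, min_run_s=config.min_run_s)
            if osp is None:
                logger.warning("%s %s: modulation missing (usable run < %.0f s)",
                               record_id, name, config.min_run_s)
            else:
                dff, pr, frac_interp = osp.delta_ff, osp.pr, osp.frac_interpolated
        i0, i1 = int(t0 * 50), int(t1 * 50)
        rows.append({
            "patient": record_id, "phase": name, "usable": True,
            "ff": ff, "fhr": fhr, "frr": frr, "delta_ff": dff, "pr": pr,
            "valid_fraction": float(trend.valid[i0:i1].mean()),
            "frac_interpolated": frac_interp,
        })
    return pd.DataFrame(rows)


def run_activation_pipeline(paths, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyze a batch of activation-time files into Ffs / dFfs summaries.

    Malformed files are reported per file and the batch continues.
    """
    config = config or AnalysisConfig()
    window = None
    rows = []
    for p in map(Path, paths):
        try:
            aset = io.read_activation_set(p)
            if config.activation_window_s is not None:
                end = aset.duration
                window = (end - config.activation_window_s, end + 1e-9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = analyze_activation_set(
                    aset, window=window, threshold=config.peak_threshold,
                    resp_rate=config.sim_resp_rate,
                    min_duration_s=config.activation_min_duration_s)
            n_ret = sum(res.retained.values())
            rows.append({
                "file": str(p), "ok": True,
                "n_points": len(res.fcs), "n_retained": n_ret,
                "retained_fraction": n_ret / len(res.fcs),
                "ffs": res.ffs, "delta_ffs": res.delta_ffs,
                "error": "",
            })
        except (ValueError, OSError, KeyError) as exc:
            logger.error("%s: %s", p, exc)
            rows.append({"file": str(p), "ok": False, "n_points": 0,
                         "n_retained": 0, "retained_fraction": np.nan,
                         "ffs": np.nan, "delta_ffs": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
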