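"""Per-recording analysis pipeline.

Chains the conditioning, wave-intensity and PU-loop steps into one
call and flattens the outcome into a JSON-serializable result dict /
a one-row marker record for cohort tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .waveio import (WaveformRecording, EnsembleBeat, correct_velocity_delay,
                     detect_beats, ensemble_average, lowpass_filter)
from . import wia
from . import loop as pu_loop

MARKER_COLUMNS = ["id", "group", "pws", "s1", "s2", "s1_plus_s2", "s2_s1_ratio",
                  "pct_td", "rel_bcw", "rel_mfcw", "rel_mfdw", "rel_lfdw",
                  "dpb1", "dpf1", "dpb2", "dpf2"]


def analyze_beat(beat: EnsembleBeat, config: AnalysisConfig | None = None) -> dict:
    """Full wave-intensity + loop-marker analysis of one ensemble beat."""
    config = config or AnalysisConfig()
    rho = config.rho_blood_kg_m3
    fs = beat.sampling_rate
    net = wia.compute_net_wi(beat.dpdt_pa, beat.dudt)
    lm = wia.detect_landmarks(net, beat)
    pws, diag = wia.estimate_pws(beat, rho, config=config, landmarks=lm)
    sep = wia.separate_components(beat, pws, rho, config=config)
    segments = wia.segment_waves(sep, lm, config=config)
    segments, ref = wia.quantify_waves(segments, net, lm, fs, sep=sep)
    timing = wia.compute_td(segments, lm, fs)
    deltas = wia.phase_pressure_deltas(sep, lm)

    pu = pu_loop.build_loop(beat, lm)
    warnings = list(lm.warnings)
    s1_onset = diag["backward_onset_idx"]
    if s1_onset is not None and s1_onset - lm.a_idx + 1 < config.s1_min_samples:
        # backward wave hard against A: extend to the minimum fit length
        s1_onset = lm.a_idx + config.s1_min_samples - 1
        warnings.append("backward-wave onset within the minimum S1 window; window extended")
    s1, s1_window, s1_raw = pu_loop.fit_s1(pu, s1_onset, rho, config=config)
    s2, s2_r2, s2_raw = pu_loop.fit_s2(pu, lm, rho, config=config)
    s1_plus_s2, s2_s1 = pu_loop.composite_markers(s1, s2)
    # bending is judged against the extrapolated water-hammer line: slope
    # rho * PWS (stable against window noise), anchored on the clean
    # initial window (greedy window capped at the backward-wave onset)
    g0, g1 = diag["greedy_window"]
    bend_end = min(g1, s1_window[1])
    if bend_end - g0 + 1 >= config.s1_min_samples:
        bending = pu_loop.detect_ab_bending(pu, (g0, bend_end), rho * pws, config=config)
    else:
        bending = "none"

    waves = {}
    for seg in segments:
        waves[seg.wave_type] = {
            "present": seg.present,
            "peak_wi_1e4": seg.peak_wi / 1e4,
            "cumulative_wi_1e2": seg.cumulative_wi / 1e2,
            "relative_magnitude": seg.relative_magnitude,
            "onset_s": seg.onset_idx / fs if seg.present else None,
            "end_s": seg.end_idx / fs if seg.present else None,
        }
    result = {
        "pws": pws,
        "s1": s1, "s2": s2, "s1_plus_s2": s1_plus_s2, "s2_s1_ratio": s2_s1,
        "s2_fit_r2": s2_r2, "ab_bending": bending,
        "landmarks": {"a_s": lm.a_idx / fs, "b_s": lm.b_idx / fs,
                      "c_s": lm.c_idx / fs, "d_s": lm.d_idx / fs, "act_s": lm.act},
        "td_s": timing.td, "pct_td": timing.pct_td, "bcw_absent": timing.absent,
        "waves": waves,
        "int_initial_net_wi_1e2": ref / 1e2,
        "phase_deltas": {"dpb1": deltas.dpb_phase1, "dpf1": deltas.dpf_phase1,
                         "dpb2": deltas.dpb_phase2, "dpf2": deltas.dpf_phase2},
        "pws_diagnostics": {"n_iter": diag["n_iter"], "converged": diag["converged"],
                            "fit_r2": diag["fit_r2"],
                            "greedy_window": list(diag["greedy_window"]),
                            "s1_window": list(s1_window)},
        "qc_warnings": warnings,
        "n_beats_averaged": beat.n_beats_averaged,
    }
    return result


def analyze_recording(rec: WaveformRecording, config: AnalysisConfig | None = None,
                      n_beats: int | None = None) -> dict:
    """Condition a raw recording and analyze its ensemble beat."""
    config = config or AnalysisConfig()
    if rec.velocity_delay == 0.0 and config.velocity_delay_s > 0:
        rec = WaveformRecording(rec.time, rec.pressure, rec.velocity,
                                rec.sampling_rate, config.velocity_delay_s, dict(rec.meta))
    if config.filter_before_ensemble:
        rec = lowpass_filter(rec, config=config)
    if rec.velocity_delay > 0:
        rec = correct_velocity_delay(rec)
    beats = detect_beats(rec, config=config)
    beat = ensemble_average(rec, beats, n_beats=n_beats, config=config)
    if not config.filter_before_ensemble:
        # filter the single averaged beat instead of the raw record
        from .waveio import differentiate
        tmp = WaveformRecording(beat.time, beat.pressure, beat.velocity, beat.sampling_rate)
        tmp = lowpass_filter(tmp, config=config)
        beat.pressure, beat.velocity = tmp.pressure, tmp.velocity
        beat.dpdt = differentiate(beat.pressure, beat.sampling_rate, config.derivative_step_s)
        beat.dudt = differentiate(beat.velocity, beat.sampling_rate, config.derivative_step_s)
    result = analyze_beat(beat, config=config)
    result["n_beats_detected"] = int(beats.foot_indices.size)
    result["meta"] = {k: v for k, v in rec.meta.items()
                      if isinstance(v, (str, int, float, bool))}
    return result


def marker_row(result: dict, subject_id: str = "", group: str = "") -> dict:
    """Flatten an analysis result into one cohort-table row."""
    w = result["waves"]
    return {
        "id": subject_id, "group": group,
        "pws": result["pws"], "s1": result["s1"], "s2": result["s2"],
        "s1_plus_s2": result["s1_plus_s2"], "s2_s1_ratio": result["s2_s1_ratio"],
        "pct_td": result["pct_td"],
        "rel_bcw": w["BCW"]["relative_magnitude"],
        "rel_mfcw": w["m_FCW"]["relative_magnitude"],
        "rel_mfdw": w["m_FDW"]["relative_magnitude"],
        "rel_lfdw": w["l_FDW"]["relative_magnitude"],
        "dpb1": result["phase_deltas"]["dpb1"], "dpf1": result["phase_deltas"]["dpf1"],
        "dpb2": result["phase_deltas"]["dpb2"], "dpf2": result["phase_deltas"]["dpf2"],
    }


def analyze_cohort(records: list, config: AnalysisConfig | None = None,
                   groups: dict | None = None) -> pd.DataFrame:
    """Analyze (id, recording, truth) triples into a marker table."""
    rows = []
    for sid, rec, truth in records:
        res = analyze_recording(rec, config=config)
        rows.append(marker_row(res, sid, getattr(truth, "group_label", None) or
                               (groups or {}).get(sid, "")))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def write_result_json(result: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=1, default=_json_default, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
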