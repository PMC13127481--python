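"""Analysis configuration.

All tunables of the waveform pipeline live in :class:`AnalysisConfig`;
every numeric default is documented there and can be overridden from a
YAML file (see :func:`load_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Conversion factor between mmHg and Pa.
MMHG_TO_PA = 133.322


@dataclass
class AnalysisConfig:
    """Tunable parameters of the P/U waveform analysis pipeline.

    Parameters
    ----------
    rho_blood_kg_m3 :
        Blood density used in the water-hammer relation and in the
        forward/backward separation. 1060 kg/m^3 is the usual value for
        whole blood.
    mmhg_to_pa :
        Pressure unit conversion; fixed physical constant, exposed for
        completeness.
    lowpass_cutoff_hz :
        Zero-phase low-pass cutoff applied to both channels before
        differentiation. 62.5 Hz removes electrical interference while
        leaving arterial waveform content (< ~30 Hz) untouched.
    derivative_step_s :
        Time step of the dP/dt and dU/dt central differences (2 ms).
    ensemble_beats :
        Number of beats averaged into the analysis beat.
    beat_rr_tolerance :
        Relative deviation of a beat's cycle length from the median
        cycle length beyond which the beat is excluded (ectopy/pause
        guard).
    velocity_delay_s :
        Hardware lag of the velocity channel relative to pressure;
        corrected by advancing the velocity series.
    filter_before_ensemble :
        Whether the low-pass filter is applied to the raw multi-beat
        record (default) or to the ensemble beat.
    bcw_detect_frac :
        BCW detection threshold as a fraction of peak forward wave
        intensity; a backward run must exceed it for
        ``bcw_min_samples`` consecutive samples to count as a wave.
    bcw_onset_floor_frac :
        Fraction of the detection threshold down to which samples are
        collected for the onset back-projection fit.
    bcw_min_samples :
        Sustained-crossing requirement for BCW detection.
    s1_r2_threshold :
        Goodness-of-fit bound for the greedy linear window used in
        pulse-wave-speed estimation.
    s1_min_samples :
        Minimum number of samples in any slope-fit window.
    s1_noise_floor_mmhg :
        Residual RMS below which the greedy window keeps growing even
        if R^2 dips (guards against noise on a short, shallow window).
    pws_rel_tol :
        Convergence tolerance of the PWS fixed-point iteration.
    pws_max_iter :
        Iteration cap of the same.
    bending_tol_mmhg :
        Mean signed residual from the extrapolated S1 line beyond which
        the A-B limb is called upward/downward bent.
    s2_two_point :
        Use a two-point B→C secant instead of least squares for S2
        (sensitivity-analysis alternative).
    """

    rho_blood_kg_m3: float = 1060.0
    mmhg_to_pa: float = MMHG_TO_PA
    lowpass_cutoff_hz: float = 62.5
    derivative_step_s: float = 0.002
    ensemble_beats: int = 5
    beat_rr_tolerance: float = 0.15
    velocity_delay_s: float = 0.0
    filter_before_ensemble: bool = True
    bcw_detect_frac: float = 0.005
    bcw_onset_floor_frac: float = 0.05
    bcw_min_samples: int = 3
    s1_r2_threshold: float = 0.995
    s1_min_samples: int = 5
    s1_noise_floor_mmhg: float = 0.5
    pws_rel_tol: float = 0.005
    pws_max_iter: int = 10
    bending_tol_mmhg: float = 1.0
    s2_two_point: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file and/or keyword overrides.

    Unknown keys in the file raise ``ValueError`` so typos do not pass
    silently.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**values)
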