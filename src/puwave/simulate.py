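"""Synthetic central-aortic P/U generator with analytic ground truth.

The generator inverts the linear wave-superposition model used by the
analysis: each injected wavelet contributes a raised-cosine-squared
lobe to dPf/dt (forward) or dPb/dt (backward), a single reflection site
returns the initial forward wavelet as a scaled, delayed backward copy
(reflection coefficient R, round-trip delay tau), pressure components
follow by integration, and velocity follows from the water-hammer
relation U = (Pf − Pb)/(rho·c). Measured P is p_diastolic + Pf + Pb;
each cycle closes with a linear end-diastolic relaxation of both
components back to zero, followed by a short quiet gap so the next
upstroke rises from a true zero of net wave intensity. Additive
Gaussian sensor noise and a velocity-channel hardware delay are applied
last.

Because the model is analytic, every scenario carries its ground truth:
the true pulse wave speed, the noise-free component pressures, the
injected wave catalog with closed-form cumulative intensities
(a lobe of increment dp and duration d has
cumulative WI = 1.5 dp^2 / (d · rho · c)), and the expected relative
BCW onset time and magnitude (R^2 for the delayed-copy reflection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MMHG_TO_PA
from .errors import ParameterError
from .waveio import WaveformRecording, write_waveform_csv

WAVELET_KINDS = ("forward_compression", "forward_decompression",
                 "backward_compression", "backward_decompression")

#: quiet diastolic gap before each upstroke (s); guarantees a net-WI
#: zero exists immediately before point A
QUIET_GAP_S = 0.020


@dataclass
class Wavelet:
    """One injected wave: a raised-cosine-squared lobe in dPf/dt or dPb/dt."""

    kind: str
    onset: float                  # s from cycle start
    duration: float               # s
    pressure_increment: float     # mmHg, signed change of Pf or Pb

    def __post_init__(self):
        if self.kind not in WAVELET_KINDS:
            raise ParameterError(f"unknown wavelet kind {self.kind!r}")
        if self.duration <= 0:
            raise ParameterError("wavelet duration must be positive")
        sign = -1.0 if "decompression" in self.kind else 1.0
        if sign * self.pressure_increment <= 0:
            raise ParameterError(
                f"{self.kind} wavelet must have pressure increment of sign {sign:+.0f}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def forward(self) -> bool:
        return self.kind.startswith("forward")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic recording."""

    pws: float                                  # m/s
    forward_wavelets: list[Wavelet]
    reflection_coefficient: float = 0.0         # in [0, 1)
    reflection_delay: float = 0.0               # s, round-trip to the reflection site
    extra_backward_wavelets: list[Wavelet] = field(default_factory=list)
    rho: float = 1060.0                         # kg/m^3
    p_diastolic: float = 67.0                   # mmHg
    heart_rate: float = 75.0                    # bpm
    sampling_rate: float = 500.0                # Hz
    n_beats: int = 8
    noise_sd_p: float = 0.0                     # mmHg
    noise_sd_u: float = 0.0                     # m/s
    velocity_delay: float = 0.0                 # s, hardware lag of U channel
    lead_in_s: float = 0.3                      # baseline before the first beat
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if self.pws <= 0:
            raise ParameterError("pws must be positive")
        if self.sampling_rate < 250:
            raise ParameterError("sampling_rate must be >= 250 Hz")
        if not (0 <= self.reflection_coefficient < 1):
            raise ParameterError("reflection coefficient must be in [0, 1)")
        if not self.forward_wavelets:
            raise ParameterError("at least one forward wavelet required")
        if any(not w.forward for w in self.forward_wavelets):
            raise ParameterError("forward_wavelets must contain forward kinds only")
        if any(w.forward for w in self.extra_backward_wavelets):
            raise ParameterError("extra_backward_wavelets must contain backward kinds only")
        T = self.cycle_s
        ends = [w.end for w in self.forward_wavelets + self.extra_backward_wavelets]
        if self.reflection_coefficient > 0:
            w0 = self.initial_wavelet
            ends.append(w0.end + self.reflection_delay)
        if min(w.onset for w in self.forward_wavelets + self.extra_backward_wavelets) < 0:
            raise ParameterError("wavelet onset before cycle start")
        if max(ends) > T - QUIET_GAP_S - 2.0 / self.sampling_rate:
            raise ParameterError("wavelets (or the reflection) extend past the cardiac cycle")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def initial_wavelet(self) -> Wavelet:
        return min(self.forward_wavelets, key=lambda w: w.onset)


@dataclass
class GroundTruth:
    """Analytic expectations for one synthetic scenario."""

    pws: float
    rho: float
    pf_true: np.ndarray            # mmHg, one noise-free cycle
    pb_true: np.ndarray            # mmHg, one noise-free cycle
    lead_in_samples: int
    cycle_samples: int
    wave_catalog: list             # dicts: kind/onset/duration/increment/cumulative_wi
    expected_act: float            # s, onset of initial wave -> peak noise-free U
    expected_pct_td: float | None  # reflection_delay / expected_act
    expected_rel_bcw: float | None  # R^2 for the delayed-copy reflection
    group_label: str | None = None

    def to_json(self) -> dict:
        d = asdict(self)
        d["pf_true"] = self.pf_true.tolist()
        d["pb_true"] = self.pb_true.tolist()
        return d


def _frac(x: np.ndarray) -> np.ndarray:
    """Fraction of a lobe's pressure increment delivered at phase x.

    The lobe 2/d · sin^2(pi s/d) integrates to x − sin(2 pi x)/(2 pi)
    for x in [0, 1]; clipped outside.
    """
    x = np.clip(x, 0.0, 1.0)
    return x - np.sin(2 * np.pi * x) / (2 * np.pi)


def _component_pressure(t: np.ndarray, wavelets: list[tuple[float, float, float]]) -> np.ndarray:
    """Analytic component pressure from (onset, duration, increment) lobes."""
    p = np.zeros_like(t)
    for onset, dur, inc in wavelets:
        p += inc * _frac((t - onset) / dur)
    return p


def _lobe_cumulative_wi(inc_mmhg: float, dur: float, rho: float, pws: float) -> float:
    """Closed-form time integral of a lobe's wave intensity (signed, SI)."""
    inc_pa = inc_mmhg * MMHG_TO_PA
    return 1.5 * inc_pa ** 2 / (dur * rho * pws)


def synthesize_beat(scn: SyntheticScenario) -> tuple[WaveformRecording, GroundTruth]:
    """Generate a multi-beat recording and its ground truth.

    Deterministic for a fixed scenario (the seed drives the noise);
    identical scenarios yield bit-identical output.
    """
    fs = scn.sampling_rate
    T = scn.cycle_s
    n_cycle = int(round(T * fs))
    t = np.arange(n_cycle) / fs

    fwd = [(w.onset, w.duration, w.pressure_increment) for w in scn.forward_wavelets]
    bwd = [(w.onset, w.duration, w.pressure_increment) for w in scn.extra_backward_wavelets]
    if scn.reflection_coefficient > 0:
        w0 = scn.initial_wavelet
        bwd.append((w0.onset + scn.reflection_delay, w0.duration,
                    scn.reflection_coefficient * w0.pressure_increment))
    pf = _component_pressure(t, fwd)
    pb = _component_pressure(t, bwd) if bwd else np.zeros_like(t)

    # linear end-diastolic relaxation of both components back to zero
    ends = [w.end for w in scn.forward_wavelets + scn.extra_backward_wavelets]
    if scn.reflection_coefficient > 0:
        ends.append(scn.initial_wavelet.end + scn.reflection_delay)
    t_relax = max(ends)
    t_quiet = T - QUIET_GAP_S
    ramp = np.clip((t_quiet - t) / (t_quiet - t_relax), 0.0, 1.0)
    pf_end = float(sum(inc for _, _, inc in fwd))
    pb_end = float(sum(inc for _, _, inc in bwd))
    pf = np.where(t >= t_relax, pf_end * ramp, pf)
    pb = np.where(t >= t_relax, pb_end * ramp, pb)

    u_cycle = (pf - pb) * MMHG_TO_PA / (scn.rho * scn.pws)
    p_cycle = scn.p_diastolic + pf + pb

    lead = int(round(scn.lead_in_s * fs))
    n_total = lead + scn.n_beats * n_cycle
    p = np.concatenate([np.full(lead, scn.p_diastolic), np.tile(p_cycle, scn.n_beats)])
    u = np.concatenate([np.zeros(lead), np.tile(u_cycle, scn.n_beats)])

    rng = np.random.default_rng(scn.seed)
    if scn.noise_sd_p > 0:
        p = p + rng.normal(0.0, scn.noise_sd_p, n_total)
    if scn.noise_sd_u > 0:
        u = u + rng.normal(0.0, scn.noise_sd_u, n_total)
    if scn.velocity_delay > 0:
        shift = int(round(scn.velocity_delay * fs))
        if shift > 0:
            u = np.concatenate([np.zeros(shift), u[:-shift]])

    rec = WaveformRecording(
        time=np.arange(n_total) / fs, pressure=p, velocity=u, sampling_rate=fs,
        velocity_delay=scn.velocity_delay,
        meta={"scenario": scn.name, "seed": scn.seed},
    )

    w0 = scn.initial_wavelet
    u_free = (pf - pb) * MMHG_TO_PA / (scn.rho * scn.pws)
    # acceleration time ends at the *first* velocity peak (end of the
    # initial positive net-WI), not a possible midsystolic re-peak
    du = np.diff(u_free)
    rising = np.flatnonzero(du > 0)
    b_true = int(np.argmax(u_free))
    if rising.size:
        fall = np.flatnonzero(du[rising[0]:] <= 0)
        if fall.size:
            b_true = int(rising[0] + fall[0])
    act = b_true / fs - w0.onset
    catalog = []
    for w in scn.forward_wavelets + scn.extra_backward_wavelets:
        catalog.append({
            "kind": w.kind, "onset": w.onset, "duration": w.duration,
            "pressure_increment": w.pressure_increment,
            "cumulative_wi": (1 if w.forward else -1)
            * _lobe_cumulative_wi(w.pressure_increment, w.duration, scn.rho, scn.pws),
        })
    if scn.reflection_coefficient > 0:
        catalog.append({
            "kind": "backward_compression", "onset": w0.onset + scn.reflection_delay,
            "duration": w0.duration,
            "pressure_increment": scn.reflection_coefficient * w0.pressure_increment,
            "cumulative_wi": -_lobe_cumulative_wi(
                scn.reflection_coefficient * w0.pressure_increment, w0.duration,
                scn.rho, scn.pws),
        })
    truth = GroundTruth(
        pws=scn.pws, rho=scn.rho, pf_true=pf, pb_true=pb,
        lead_in_samples=lead, cycle_samples=n_cycle,
        wave_catalog=catalog,
        expected_act=act,
        expected_pct_td=(scn.reflection_delay / act
                         if scn.reflection_coefficient > 0 else None),
        expected_rel_bcw=(scn.reflection_coefficient ** 2
                          if scn.reflection_coefficient > 0 else None),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# presets


def _closed_scenario(*, pws: float, fcw_inc: float, fcw_dur: float,
                     reflection_coefficient: float, reflection_delay: float,
                     mid_wavelets: list[Wavelet] | None = None,
                     extra_backward: list[Wavelet] | None = None,
                     lfdw_onset: float = 0.150, lfdw_dur: float = 0.150,
                     **kwargs) -> SyntheticScenario:
    """Build a scenario whose late forward decompression wave closes the
    cycle with U -> 0 at end-systole (Pf_end = Pb_end)."""
    mid = list(mid_wavelets or [])
    bwd = list(extra_backward or [])
    fwd = [Wavelet("forward_compression", 0.0, fcw_dur, fcw_inc)] + mid
    pb_end = reflection_coefficient * fcw_inc + sum(w.pressure_increment for w in bwd)
    pf_end = sum(w.pressure_increment for w in fwd)
    lfdw_inc = -(pf_end - pb_end)
    if lfdw_inc >= 0:
        raise ParameterError("closure requires net forward pressure above the backward level")
    fwd = fwd + [Wavelet("forward_decompression", lfdw_onset, lfdw_dur, lfdw_inc)]
    return SyntheticScenario(
        pws=pws, forward_wavelets=fwd,
        reflection_coefficient=reflection_coefficient,
        reflection_delay=reflection_delay,
        extra_backward_wavelets=bwd, **kwargs)


def preset_scenario(name: str, seed: int = 0, **overrides) -> SyntheticScenario:
    """Named waveform archetypes.

    ``non_cad``
        Compliant aorta: low pulse wave speed (6 m/s), large initial
        forward compression (55 mmHg), late moderate reflection
        (R = 0.25 arriving at ~90 % of the acceleration time), a
        midsystolic forward *decompression* wave (inertial midsystole),
        and a small early backward decompression wave.
    ``cad_ht``
        Stiff, hypertensive phenotype: high pulse wave speed
        (9.5 m/s), smaller initial wave (45 mmHg), early reflection
        (R = 0.3 at ~70 % of the acceleration time) and a midsystolic
        forward *compression* wave sized so its cumulative intensity is
        ~7 % of the initial positive net-WI.
    ``occlusion_before`` / ``occlusion_after``
        Identical base with the reflection switched from late/small to
        early/large, emulating proximal-aortic occlusion.
    """
    noise = dict(noise_sd_p=0.5, noise_sd_u=0.005)
    if name == "non_cad":
        scn = _closed_scenario(
            pws=6.0, fcw_inc=55.0, fcw_dur=0.100,
            reflection_coefficient=0.25, reflection_delay=0.090,
            mid_wavelets=[Wavelet("forward_decompression", 0.105, 0.060, -6.0)],
            extra_backward=[Wavelet("backward_decompression", 0.030, 0.040, -1.0)],
            lfdw_onset=0.170, lfdw_dur=0.150,
            seed=seed, name=name, **{**noise, **overrides})
    elif name == "cad_ht":
        # a small, sharp proximal reflection rides on top of the main
        # distal one so the backward pressure already rises ~2.4 mmHg by
        # peak velocity, as stiff hypertensive aortas show
        scn = _closed_scenario(
            pws=9.5, fcw_inc=45.0, fcw_dur=0.100,
            reflection_coefficient=0.30, reflection_delay=0.060,
            mid_wavelets=[Wavelet("forward_compression", 0.100, 0.045, 8.0)],
            extra_backward=[Wavelet("backward_compression", 0.060, 0.060, 3.0)],
            lfdw_onset=0.150, lfdw_dur=0.150,
            seed=seed, name=name, **{**noise, **overrides})
    elif name == "occlusion_before":
        scn = _closed_scenario(
            pws=7.0, fcw_inc=50.0, fcw_dur=0.100,
            reflection_coefficient=0.20, reflection_delay=0.085,
            lfdw_onset=0.160, lfdw_dur=0.150,
            seed=seed, name=name, **{**noise, **overrides})
    elif name == "occlusion_after":
        scn = _closed_scenario(
            pws=7.0, fcw_inc=50.0, fcw_dur=0.100,
            reflection_coefficient=0.45, reflection_delay=0.045,
            lfdw_onset=0.160, lfdw_dur=0.150,
            seed=seed, name=name, **{**noise, **overrides})
    else:
        raise ParameterError(
            f"unknown preset {name!r}; available: non_cad, cad_ht, "
            "occlusion_before, occlusion_after")
    return scn


DEFAULT_DISPERSION = {
    "pws": 0.20,
    "amplitude": 0.20,
    "reflection_coefficient": 0.20,
    "reflection_delay": 0.10,
    "heart_rate": 0.08,
}


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor with median 1 and coefficient of variation cv."""
    if cv < 0:
        raise ParameterError("dispersion CV must be >= 0")
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return float(np.exp(sigma * rng.standard_normal()))


def synthesize_cohort(n_cad: int = 21, n_noncad: int = 10,
                      dispersion: dict | None = None, seed: int = 0
                      ) -> tuple[list[tuple[str, WaveformRecording, GroundTruth]], pd.DataFrame]:
    """Draw a two-group cohort around the ``cad_ht`` and ``non_cad`` presets.

    Per-subject parameters are drawn log-normally around the preset
    values with the given coefficients of variation (median-preserving),
    fully determined by ``seed``. Returns the per-subject recordings
    with ground truth and a labels table.
    """
    if n_cad < 2 or n_noncad < 2:
        raise ParameterError("need at least 2 subjects per group")
    cv = dict(DEFAULT_DISPERSION)
    if dispersion:
        unknown = set(dispersion) - set(cv)
        if unknown:
            raise ParameterError(f"unknown dispersion keys: {sorted(unknown)}")
        cv.update(dispersion)
    if any(v < 0 for v in cv.values()):
        raise ParameterError("dispersion CV must be >= 0")

    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for group, preset, count in (("CAD", "cad_ht", n_cad), ("non-CAD", "non_cad", n_noncad)):
        base = preset_scenario(preset)
        for i in range(count):
            sid = f"{'cad' if group == 'CAD' else 'noncad'}_{i + 1:02d}"
            f_pws = _lognormal_factor(rng, cv["pws"])
            f_amp = _lognormal_factor(rng, cv["amplitude"])
            f_r = _lognormal_factor(rng, cv["reflection_coefficient"])
            f_tau = _lognormal_factor(rng, cv["reflection_delay"])
            f_hr = _lognormal_factor(rng, cv["heart_rate"])
            subj_seed = int(rng.integers(0, 2 ** 31 - 1))
            # _closed_scenario orders wavelets [initial FCW, *mid, closing l-FDW]
            base_fcw = base.forward_wavelets[0]
            mids = base.forward_wavelets[1:-1]

            def mid_factor(w: Wavelet) -> float:
                # the midsystolic forward compression wave compensates the
                # backward load, so its size tracks the reflection strength;
                # decompression (inertial) mid waves do not
                return f_amp * f_r if w.kind == "forward_compression" else f_amp
            scn = _closed_scenario(
                pws=base.pws * f_pws,
                fcw_inc=base_fcw.pressure_increment * f_amp,
                fcw_dur=base_fcw.duration,
                reflection_coefficient=min(0.95, base.reflection_coefficient * f_r),
                reflection_delay=float(np.clip(base.reflection_delay * f_tau, 0.020, 0.140)),
                mid_wavelets=[replace(w, pressure_increment=w.pressure_increment * mid_factor(w))
                              for w in mids],
                extra_backward=[replace(w, pressure_increment=w.pressure_increment * f_amp * f_r)
                                for w in base.extra_backward_wavelets
                                if w.kind == "backward_compression"] +
                               [replace(w, pressure_increment=w.pressure_increment * f_amp)
                                for w in base.extra_backward_wavelets
                                if w.kind == "backward_decompression"],
                lfdw_onset=0.170 if preset == "non_cad" else 0.150,
                lfdw_dur=0.150,
                heart_rate=base.heart_rate * f_hr,
                noise_sd_p=base.noise_sd_p, noise_sd_u=base.noise_sd_u,
                seed=subj_seed, name=f"{preset}:{sid}",
            )
            rec, truth = synthesize_beat(scn)
            truth.group_label = group
            records.append((sid, rec, truth))
            rows.append({"id": sid, "group": group, "true_pws": scn.pws,
                         "true_r": scn.reflection_coefficient,
                         "true_delay": scn.reflection_delay, "seed": subj_seed})
    return records, pd.DataFrame(rows)


def write_scenario(rec: WaveformRecording, truth: GroundTruth,
                   out_dir: str | Path, stem: str = "scenario") -> tuple[Path, Path]:
    """Write the waveform CSV and the ground-truth JSON; round-trip safe."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}_truth.json"
    write_waveform_csv(rec, csv_path)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return csv_path, json_path
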