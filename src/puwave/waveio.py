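"""Waveform I/O and signal conditioning.

Reads/writes the package's CSV dialect for simultaneous aortic pressure
and flow-velocity recordings and implements the conditioning chain that
precedes wave-intensity analysis: zero-phase low-pass filtering,
velocity-channel delay correction, pressure-foot beat detection,
ensemble averaging, and fixed-step time derivatives.

CSV dialect: UTF-8, comma-separated, header ``time_s,pressure_mmHg,
velocity_m_s``, uniform time grid; extra columns are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig, MMHG_TO_PA
from .errors import DataError, DetectionError, FormatError, ParameterError

CSV_COLUMNS = {"time": "time_s", "pressure": "pressure_mmHg", "velocity": "velocity_m_s"}

#: Baseline retained ahead of each detected pressure foot so that the
#: true wave onset (which a tangent-foot estimate can trail by a quarter
#: of the upstroke) is always inside the ensemble window.
PRE_FOOT_WINDOW_S = 0.10


@dataclass
class WaveformRecording:
    """Raw multi-beat pressure/velocity record on a uniform time grid."""

    time: np.ndarray          # s
    pressure: np.ndarray      # mmHg
    velocity: np.ndarray      # m/s
    sampling_rate: float      # Hz
    velocity_delay: float = 0.0   # s, hardware lag of the velocity channel
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.time.size
        if self.pressure.size != n or self.velocity.size != n:
            raise DataError("time, pressure and velocity must have equal length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise DataError("time must be strictly increasing")
            if np.max(np.abs(steps - 1.0 / self.sampling_rate)) > 1e-9:
                raise DataError("time grid is not uniform at 1/sampling_rate")
        for name, arr in (("pressure", self.pressure), ("velocity", self.velocity)):
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise DataError(f"non-finite {name} value at row {row}")
        if self.velocity_delay < 0:
            raise ParameterError("velocity_delay must be >= 0")

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0]

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class BeatIndex:
    """Pressure-upstroke feet and per-beat inclusion flags."""

    foot_indices: np.ndarray          # sample positions
    included: np.ndarray              # bool per beat
    exclusion_reasons: dict = field(default_factory=dict)  # beat index -> reason

    def __post_init__(self):
        self.foot_indices = np.asarray(self.foot_indices, dtype=int)
        self.included = np.asarray(self.included, dtype=bool)
        if np.any(np.diff(self.foot_indices) <= 0):
            raise DataError("foot indices must be strictly increasing")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass
class EnsembleBeat:
    """One averaged beat with its fixed-step time derivatives.

    ``dpdt`` is in mmHg/s (use :attr:`dpdt_pa` for Pa/s); the derivative
    step is ``round(derivative_step_s * sampling_rate)`` samples with
    central differences at interior points and one-sided stencils at the
    ends, so derivative series have the same length as the primaries.
    """

    time: np.ndarray          # s from window start
    pressure: np.ndarray      # mmHg
    velocity: np.ndarray      # m/s
    dpdt: np.ndarray          # mmHg/s
    dudt: np.ndarray          # m/s^2
    sampling_rate: float
    n_beats_averaged: int
    foot_offset: int = 0      # samples of pre-foot baseline in the window
    mmhg_to_pa: float = MMHG_TO_PA

    @property
    def dpdt_pa(self) -> np.ndarray:
        """dP/dt in Pa/s."""
        return self.dpdt * self.mmhg_to_pa

    @property
    def n_samples(self) -> int:
        return self.time.size


def read_waveform_csv(path: str | Path, column_map: dict | None = None) -> WaveformRecording:
    """Read a recording from the declared CSV dialect.

    ``column_map`` may rename the logical channels, e.g.
    ``{"pressure": "AOP_mmHg"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cols = dict(CSV_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path} (found {list(df.columns)})")
    if len(df) < 100:
        raise DataError(f"recording too short: {len(df)} samples (need >= 100)")
    t = df[cols["time"]].to_numpy(dtype=float)
    p = df[cols["pressure"]].to_numpy(dtype=float)
    u = df[cols["velocity"]].to_numpy(dtype=float)
    for name, arr in (("pressure", p), ("velocity", u)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise DataError(f"NaN/inf {name} at data row {int(bad[0])}")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise DataError("time column is not strictly increasing")
    med = float(np.median(steps))
    if np.max(np.abs(steps - med)) > 1e-9 + 1e-6 * med:
        raise DataError("non-uniform time grid")
    fs = 1.0 / med
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    # rebuild the grid from fs so the type invariant holds exactly
    t = t[0] + np.arange(t.size) / fs
    return WaveformRecording(t, p, u, sampling_rate=fs, meta={"source": str(path)})


def write_waveform_csv(rec: WaveformRecording, path: str | Path) -> None:
    """Write a recording in the declared dialect with round-trip precision."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(CSV_COLUMNS[k] for k in ("time", "pressure", "velocity")) + "\n")
        for t, p, u in zip(rec.time, rec.pressure, rec.velocity):
            fh.write(f"{float(t)!r},{float(p)!r},{float(u)!r}\n")


def lowpass_filter(rec: WaveformRecording, cutoff: float | None = None,
                   config: AnalysisConfig | None = None) -> WaveformRecording:
    """Zero-phase low-pass filter applied identically to both channels.

    A 4th-order Butterworth run forward and backward (``filtfilt``), so
    no relative time shift is introduced between P and U and wave
    landmarks keep their timing.
    """
    config = config or AnalysisConfig()
    cutoff = config.lowpass_cutoff_hz if cutoff is None else cutoff
    nyq = rec.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, cutoff, btype="low", fs=rec.sampling_rate, output="sos")
    p = signal.sosfiltfilt(sos, rec.pressure)
    u = signal.sosfiltfilt(sos, rec.velocity)
    meta = dict(rec.meta, lowpass_cutoff_hz=cutoff)
    return replace(rec, pressure=p, velocity=u, meta=meta)


def correct_velocity_delay(rec: WaveformRecording) -> WaveformRecording:
    """Advance the velocity channel by its calibrated hardware delay.

    The shift is rounded to the nearest sample; the sub-sample residual
    is recorded in ``meta['velocity_delay_residual_s']`` rather than
    silently dropped.
    """
    delay = rec.velocity_delay
    if delay < 0 or delay >= 0.050:
        raise ParameterError(f"velocity delay {delay} s outside [0, 50 ms) sanity bound")
    shift = int(round(delay * rec.sampling_rate))
    residual = delay - shift / rec.sampling_rate
    if shift == 0:
        u = rec.velocity.copy()
    else:
        u = np.concatenate([rec.velocity[shift:], np.full(shift, rec.velocity[-1])])
    meta = dict(rec.meta, velocity_delay_residual_s=residual,
                velocity_delay_corrected_s=shift / rec.sampling_rate)
    return replace(rec, velocity=u, velocity_delay=0.0, meta=meta)


def differentiate(series: np.ndarray, sampling_rate: float,
                  step_s: float = 0.002) -> np.ndarray:
    """Fixed-step time derivative of a sampled series.

    Central differences over ``k = round(step_s * sampling_rate) >= 1``
    samples at interior points, one-sided differences of the same span
    at the ends; the output has the length of the input.
    """
    x = np.asarray(series, dtype=float)
    k = max(1, int(round(step_s * sampling_rate)))
    if x.size < 2 * k + 1 or x.size < 3:
        raise DataError(f"series of {x.size} samples too short for {k}-sample derivative step")
    dt = k / sampling_rate
    d = np.empty_like(x)
    d[k:-k] = (x[2 * k:] - x[:-2 * k]) / (2.0 * dt)
    d[:k] = (x[k:2 * k] - x[:k]) / dt
    d[-k:] = (x[-k:] - x[-2 * k:-k]) / dt
    return d


def detect_beats(rec: WaveformRecording, config: AnalysisConfig | None = None) -> BeatIndex:
    """Locate pressure-upstroke feet and flag irregular beats.

    Candidate upstrokes are threshold crossings of dP/dt at 20 % of its
    global maximum; each foot is then refined by the intersecting-tangent
    method (tangent at the local dP/dt maximum intersected with the
    preceding diastolic baseline). Beats whose cycle length deviates
    more than ``beat_rr_tolerance`` from the median are excluded.
    """
    config = config or AnalysisConfig()
    if rec.duration < 2.0:
        raise DataError(f"recording of {rec.duration:.2f} s too short for beat detection (need >= 2 s)")
    fs = rec.sampling_rate
    dpdt = differentiate(rec.pressure, fs, config.derivative_step_s)
    peak = float(np.max(dpdt))
    if peak <= 0:
        raise DetectionError("no positive pressure upstroke found")
    thr = 0.2 * peak
    above = dpdt >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    feet = []
    search = int(0.15 * fs)
    base_win = int(0.20 * fs)
    refractory = int(0.25 * fs)
    for c in crossings:
        hi = min(int(c) + search, rec.n_samples)
        imax = int(c) + int(np.argmax(dpdt[c:hi]))
        slope = dpdt[imax]
        # amplitude validation: a genuine systolic upstroke reaches a
        # dP/dt peak comparable to the global one; filtered-noise spikes
        # that merely graze the threshold do not
        if slope < 0.5 * peak:
            continue
        lo = max(0, imax - base_win)
        baseline = float(np.min(rec.pressure[lo:imax + 1]))
        dt_back = (rec.pressure[imax] - baseline) / slope if slope > 0 else 0.0
        feet.append(max(0, int(round(imax - dt_back * fs))))
    # crossings on the same upstroke refine to (nearly) the same foot;
    # collapse anything within the refractory period
    deduped: list[int] = []
    for f_ in sorted(set(feet)):
        if not deduped or f_ - deduped[-1] > refractory:
            deduped.append(f_)
    feet_arr = np.asarray(deduped, dtype=int)
    if feet_arr.size < 2:
        raise DetectionError(f"found {feet_arr.size} upstroke(s); need >= 2 beats")
    if feet_arr.size < 2:
        raise DetectionError("fewer than 2 distinct feet after refinement")

    rr = np.diff(feet_arr).astype(float)
    med_rr = float(np.median(rr))
    included = np.ones(feet_arr.size, dtype=bool)
    reasons: dict[int, str] = {}
    for i, r in enumerate(rr):
        if abs(r - med_rr) > config.beat_rr_tolerance * med_rr:
            included[i] = False
            reasons[i] = f"cycle length {r / fs:.3f} s deviates > {config.beat_rr_tolerance:.0%} from median"
    # last beat: keep only if a full median cycle of samples remains
    if rec.n_samples - feet_arr[-1] < med_rr * (1.0 - config.beat_rr_tolerance):
        included[-1] = False
        reasons[feet_arr.size - 1] = "incomplete final cycle"
    return BeatIndex(feet_arr, included, reasons)


def ensemble_average(rec: WaveformRecording, beats: BeatIndex,
                     n_beats: int | None = None,
                     config: AnalysisConfig | None = None) -> EnsembleBeat:
    """Sample-wise mean of aligned beats with derivatives attached.

    Windows start :data:`PRE_FOOT_WINDOW_S` ahead of each foot and are
    truncated to the shortest included cycle; the first ``n_beats``
    usable beats enter the mean.
    """
    config = config or AnalysisConfig()
    n_beats = config.ensemble_beats if n_beats is None else n_beats
    fs = rec.sampling_rate
    pre = int(round(PRE_FOOT_WINDOW_S * fs))
    rr = np.diff(beats.foot_indices).astype(float)
    med_rr = int(round(float(np.median(rr))))

    usable = []
    for i, foot in enumerate(beats.foot_indices):
        if not beats.included[i]:
            continue
        if foot - pre < 0 or foot - pre + med_rr + pre > rec.n_samples:
            continue
        usable.append(int(foot))
    if len(usable) < n_beats:
        raise DataError(f"only {len(usable)} usable beats; {n_beats} required for the ensemble")
    chosen = usable[:n_beats]
    length = pre + med_rr
    p = np.mean([rec.pressure[f - pre:f - pre + length] for f in chosen], axis=0)
    u = np.mean([rec.velocity[f - pre:f - pre + length] for f in chosen], axis=0)
    return EnsembleBeat(
        time=np.arange(length) / fs,
        pressure=p,
        velocity=u,
        dpdt=differentiate(p, fs, config.derivative_step_s),
        dudt=differentiate(u, fs, config.derivative_step_s),
        sampling_rate=fs,
        n_beats_averaged=n_beats,
        foot_offset=pre,
        mmhg_to_pa=config.mmhg_to_pa,
    )
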