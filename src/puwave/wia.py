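"""Wave-intensity analysis of a central-aortic ensemble beat.

Implements net wave intensity (dP/dt · dU/dt), water-hammer estimation
of local pulse wave speed from the initial linear portion of the PU
relation, linear forward/backward separation

    Pf = (P + rho·c·U) / 2,      Pb = (P − rho·c·U) / 2,
    WIf = (dPf/dt)^2 / (rho·c),  WIb = −(dPb/dt)^2 / (rho·c),

systolic landmark detection (A: onset of the initial positive net-WI;
B: peak flow velocity; C: peak pressure; D: end of the second positive
net-WI), segmentation of the six wave types (initial FCW, BCW, e-BDW,
m-FCW, m-FDW, l-FDW), their cumulative-intensity quantification
relative to the initial positive net-WI, the relative backward-wave
onset time %Td = Td/AcT, and the phasic changes of Pf and Pb.

Sign conventions: forward waves carry WIf >= 0 and positive cumulative
intensity, backward waves WIb <= 0 and negative cumulative intensity;
compression waves raise the pressure component they travel on
(dPf/dt > 0 or dPb/dt > 0), decompression waves lower it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .errors import EstimationError, LandmarkError, ParameterError, QuantificationError
from .waveio import EnsembleBeat

WAVE_TYPES = ("initial_FCW", "BCW", "e_BDW", "m_FCW", "m_FDW", "l_FDW")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SeparationResult:
    """Forward/backward components of one beat at a given pulse wave speed."""

    pws: float                   # m/s
    rho: float                   # kg/m^3
    p_forward: np.ndarray        # mmHg
    p_backward: np.ndarray       # mmHg
    u_forward: np.ndarray        # m/s
    u_backward: np.ndarray       # m/s
    net_wi: np.ndarray           # W m^-2 s^-2
    wi_forward: np.ndarray       # W m^-2 s^-2, >= 0
    wi_backward: np.ndarray      # W m^-2 s^-2, <= 0
    dpf_dt_pa: np.ndarray        # Pa/s
    dpb_dt_pa: np.ndarray        # Pa/s
    sampling_rate: float


@dataclass
class Landmarks:
    """Systolic landmarks A < B < C < D and the acceleration time.

    ``a_time_s`` is the sub-sample onset of the initial positive
    net-WI from the back-projection fit; ``a_idx`` is its nearest
    sample, used for windowing.
    """

    a_idx: int
    b_idx: int
    c_idx: int
    d_idx: int
    sampling_rate: float
    a_time_s: float | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.a_time_s is None:
            self.a_time_s = self.a_idx / self.sampling_rate

    @property
    def act(self) -> float:
        """Ventricular acceleration time A→B in seconds."""
        return self.b_idx / self.sampling_rate - self.a_time_s

    @property
    def phase1(self) -> tuple[int, int]:
        return (self.a_idx, self.b_idx)

    @property
    def phase2(self) -> tuple[int, int]:
        return (self.b_idx, self.c_idx)

    @property
    def phase3(self) -> tuple[int, int]:
        return (self.c_idx, self.d_idx)


@dataclass
class WaveSegment:
    """One classified wave with its intensity quantification.

    ``peak_wi`` and ``cumulative_wi`` are in raw SI units
    (W m^-2 s^-2 and W m^-2 s^-1); summary tables conventionally scale
    them by 1e-4 and 1e-2 respectively. ``cumulative_wi`` is signed
    (+ forward, − backward); ``relative_magnitude`` is defined on
    magnitudes and filled in by :func:`quantify_waves`.
    """

    wave_type: str
    onset_idx: int
    end_idx: int
    present: bool
    mask: np.ndarray = field(repr=False)
    onset_time_s: float = float("nan")   # sub-sample onset (BCW only)
    peak_wi: float = 0.0
    cumulative_wi: float = 0.0
    relative_magnitude: float = 0.0


@dataclass
class TimingResult:
    """Relative backward-compression-wave onset time."""

    td: float | None             # s, A → BCW onset
    act: float                   # s
    pct_td: float | None         # Td/AcT
    bcw_onset_idx: int | None
    absent: bool = False


@dataclass
class PhaseDeltas:
    """Offset-invariant changes of Pf and Pb across phases 1 and 2 (mmHg)."""

    dpb_phase1: float
    dpf_phase1: float
    dpb_phase2: float
    dpf_phase2: float


# ---------------------------------------------------------------------------
# operations


def compute_net_wi(dpdt_pa: np.ndarray, dudt: np.ndarray) -> np.ndarray:
    """Net wave intensity (dP/dt)(dU/dt) in W m^-2 s^-2 (dP/dt in Pa/s)."""
    dpdt_pa = np.asarray(dpdt_pa, dtype=float)
    dudt = np.asarray(dudt, dtype=float)
    if dpdt_pa.shape != dudt.shape:
        raise ParameterError(f"length mismatch: {dpdt_pa.shape} vs {dudt.shape}")
    return dpdt_pa * dudt


def _onset_backproject(y: np.ndarray, start: int, stop: int, theta: float,
                       floor_frac: float, min_run: int, fs: float
                       ) -> tuple[float, int, int] | None:
    """Onset of a smooth non-negative wave by two-threshold back-projection.

    Detection: first index in [start, stop) where ``y > theta`` for
    ``min_run`` consecutive samples. Refinement: a smooth compact wave
    intensity rises ~quartically from its foot, so y^(1/4) is
    near-linear there; the samples between ``floor_frac * theta`` and
    the detection crossing are fitted with a line in that root scale
    and the onset is its zero crossing. Returns
    (onset_time_s, onset_idx, detection_idx) or None.
    """
    detect = None
    hi = min(stop, y.size) - min_run + 1
    for i in range(start, hi):
        if np.all(y[i:i + min_run] > theta):
            detect = i
            break
    if detect is None:
        return None
    # walk back to the wave's foot; the floor adapts to the baseline
    # level (median of the pre-detection samples) so noise or a slow
    # diastolic drift cannot drag the fit segment arbitrarily far back
    baseline = float(np.median(y[start:detect])) if detect > start else 0.0
    floor = max(floor_frac * theta, 2.0 * baseline)
    lo = detect
    while lo > start and y[lo - 1] > floor:
        lo -= 1
    # template back-projection: a raised-cosine-like wave has
    # y = ymax * sin^4(pi (t - t0) / d) on its rising limb, so time is
    # linear in z = arcsin((y/ymax)^(1/4)) and the regression intercept
    # of t on z is the onset t0. This uses the whole signal-dominated
    # rise (up to 80 % amplitude), which keeps the estimate stable under
    # noise where a short near-foot fit would extrapolate wildly.
    run_hi = detect
    while run_hi + 1 < y.size and y[run_hi + 1] > 0:
        run_hi += 1
    ymax = float(np.max(y[lo:run_hi + 1]))
    hi = lo
    while hi + 1 <= run_hi and y[hi + 1] <= 0.8 * ymax:
        hi += 1
    if hi - lo >= 2 and ymax > 0:
        idx = np.arange(lo, hi + 1)
        z = np.arcsin(np.clip((y[idx] / ymax) ** 0.25, 0.0, 1.0))
        slope, intercept = np.polyfit(z, idx / fs, 1)
        onset_t = intercept if slope > 0 else lo / fs
    else:
        onset_t = lo / fs
    onset_t = float(np.clip(onset_t, start / fs, detect / fs))
    return onset_t, int(round(onset_t * fs)), detect


def detect_landmarks(net_wi: np.ndarray, beat: EnsembleBeat) -> Landmarks:
    """Locate points A–D on one beat.

    A is the onset of the initial positive net-WI: nominally the last
    non-positive sample before the global net-WI maximum, located
    robustly by back-projecting the early net-WI rise to zero (the
    plain zero-crossing rule is exquisitely sensitive to filter
    ringing at the 1e-6 level of the peak). B is the end of the
    initial positive net-WI — its first return to <= 0 after the peak
    — which corresponds to the (first) peak of flow velocity; the
    global velocity maximum is the cross-check, and a discrepancy
    beyond 10 ms is logged as a warning. C is the peak-pressure sample
    after B and D the first non-positive net-WI sample after the
    second positive net-WI peak.
    """
    net = np.asarray(net_wi, dtype=float)
    warnings: list[str] = []
    if net.size != beat.n_samples:
        raise ParameterError("net-WI length does not match beat")
    if np.max(net) <= 0:
        raise LandmarkError("net-WI has no positive systolic wave")
    imax = int(np.argmax(net))
    hit = _onset_backproject(np.clip(net, 0.0, None), 0, imax + 1,
                             theta=0.01 * net[imax], floor_frac=0.05,
                             min_run=3, fs=beat.sampling_rate)
    if hit is not None:
        a_t, a, _ = hit
    else:
        nonpos = np.flatnonzero(net[: imax + 1] <= 0)
        if nonpos.size:
            a = int(nonpos[-1])
        else:
            a = 0
            warnings.append("no non-positive net-WI before the systolic peak; A set to window start")
        a_t = a / beat.sampling_rate
    b_u = a + int(np.argmax(beat.velocity[a:]))
    # "return to zero" with a small tolerance (a purely forward beat keeps
    # net-WI marginally positive between waves), then refined to the local
    # velocity maximum — the threshold alone lands a few ms early on
    # slowly-closing waves
    zero_after = np.flatnonzero(net[imax:] <= 0.005 * net[imax])
    if zero_after.size:
        b0 = imax + int(zero_after[0])
        win = max(1, int(round(0.010 * beat.sampling_rate)))
        lo = max(a + 1, b0 - win)
        hi = min(beat.n_samples, b0 + win + 1)
        b = lo + int(np.argmax(beat.velocity[lo:hi]))
    else:
        b = b_u
    if abs(b - b_u) / beat.sampling_rate > 0.010:
        warnings.append(
            f"global peak velocity ({b_u}) is "
            f"{abs(b - b_u) / beat.sampling_rate * 1e3:.1f} ms from the end of the "
            f"initial positive net-WI ({b}); using the latter as B")
    c = b + int(np.argmax(beat.pressure[b:]))
    if c <= b:
        # no pressure rise beyond peak velocity (reflection-free beat):
        # fall back to C's defining property, the onset of the second
        # positive net-WI wave
        after = np.flatnonzero(net[b + 1:] > 0.005 * net[imax])
        if after.size == 0:
            raise LandmarkError("no peak pressure or second positive net-WI after B")
        c = b + 1 + int(after[0])
        warnings.append("peak pressure not beyond B; C set to onset of second positive net-WI")
    # second positive net-WI wave after C
    tail = net[c:]
    pos_tail = np.flatnonzero(tail > 0)
    if pos_tail.size:
        p2 = c + int(pos_tail[0] + np.argmax(tail[pos_tail[0]:]))
        after = np.flatnonzero(net[p2:] <= 0)
        d = p2 + int(after[0]) if after.size else net.size - 1
    else:
        d = net.size - 1
        warnings.append("no second positive net-WI wave found; D set to window end")
    if not (a < b < c < d):
        raise LandmarkError(f"landmark ordering violated: A={a}, B={b}, C={c}, D={d}")
    return Landmarks(a, b, c, d, beat.sampling_rate, a_time_s=a_t, warnings=warnings)


def _fit_slope(p_pa: np.ndarray, u: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope of P (Pa) on U with intercept.

    Returns (slope Pa per m/s, R^2, residual RMS in Pa).
    """
    if np.ptp(u) <= 1e-12:
        raise EstimationError("velocity has no excursion over the fit window")
    A = np.column_stack([u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(A, p_pa, rcond=None)
    resid = p_pa - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((p_pa - p_pa.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(coef[0]), r2, float(np.sqrt(ss_res / p_pa.size))


def _bcw_onset(sep: SeparationResult, lm: Landmarks,
               config: AnalysisConfig) -> tuple[float, int, int] | None:
    """Detect the backward compression wave and refine its onset time.

    Detection: first sample after A where |WIb| exceeds
    ``bcw_detect_frac`` of peak WIf for ``bcw_min_samples`` consecutive
    samples with dPb/dt > 0. Refinement: for a smooth compact wave,
    |WIb|^(1/4) rises near-linearly from the foot, so the samples
    between ``bcw_onset_floor_frac``·threshold and the detection
    crossing are fitted with a line in that root scale and the onset is
    its zero crossing (clamped to be >= A). Returns
    (onset_time_s, onset_idx, detection_idx) or None when no
    supra-threshold backward compression run exists.
    """
    peak_wif = float(np.max(sep.wi_forward))
    if peak_wif <= 0:
        return None
    # zero out decompression samples so only backward *compression* runs count
    y = np.where(sep.dpb_dt_pa > 0, np.abs(sep.wi_backward), 0.0)
    return _onset_backproject(y, lm.a_idx + 1, y.size,
                              theta=config.bcw_detect_frac * peak_wif,
                              floor_frac=config.bcw_onset_floor_frac,
                              min_run=config.bcw_min_samples,
                              fs=sep.sampling_rate)


def _first_backward_onset(sep: SeparationResult, lm: Landmarks,
                          config: AnalysisConfig) -> tuple[float, int, int] | None:
    """Onset of the first supra-threshold backward wave of either sign.

    The initial loop slope is linear only until *any* backward wave
    (compression or decompression) arrives, so the S1 / pulse-wave-speed
    window ends here rather than at the BCW specifically.
    """
    peak_wif = float(np.max(sep.wi_forward))
    if peak_wif <= 0:
        return None
    return _onset_backproject(np.abs(sep.wi_backward), lm.a_idx + 1,
                              sep.net_wi.size,
                              theta=config.bcw_detect_frac * peak_wif,
                              floor_frac=config.bcw_onset_floor_frac,
                              min_run=config.bcw_min_samples,
                              fs=sep.sampling_rate)


def estimate_pws(beat: EnsembleBeat, rho: float | None = None,
                 config: AnalysisConfig | None = None,
                 landmarks: Landmarks | None = None) -> tuple[float, dict]:
    """Estimate local pulse wave speed from the initial PU-loop slope.

    The water-hammer relation dP = rho·c·dU holds over the early
    upstroke until the first backward wave arrives, so c is the initial
    P-U slope divided by rho. Because the backward-wave onset is itself
    defined in terms of the separation (which needs c), a fixed point is
    computed: (i) a provisional slope over a greedy window grown from A
    while the fit stays linear (R^2 >= ``s1_r2_threshold``, or residual
    RMS below a noise floor); (ii) separation at that c; (iii) location
    of the BCW onset; (iv) refit over A → min(BCW onset, B); repeated
    until c changes < ``pws_rel_tol`` or ``pws_max_iter`` iterations.

    Returns (pws m/s, diagnostics dict).
    """
    config = config or AnalysisConfig()
    rho = config.rho_blood_kg_m3 if rho is None else rho
    if np.ptp(beat.velocity) <= 1e-12:
        raise EstimationError("velocity channel has no excursion")
    net = compute_net_wi(beat.dpdt_pa, beat.dudt)
    lm = landmarks or detect_landmarks(net, beat)
    p_pa = beat.pressure * beat.mmhg_to_pa
    u = beat.velocity
    a, b = lm.a_idx, lm.b_idx
    if b - a + 1 < config.s1_min_samples:
        raise EstimationError(f"A→B window of {b - a + 1} samples too short")

    # (i) greedy linear window from the loop origin
    j = a + config.s1_min_samples - 1
    best = j
    while j < b:
        _, r2, rms = _fit_slope(p_pa[a:j + 2], u[a:j + 2])
        if r2 < config.s1_r2_threshold and rms > config.s1_noise_floor_mmhg * beat.mmhg_to_pa:
            break
        j += 1
        best = j
    slope, r2, _ = _fit_slope(p_pa[a:best + 1], u[a:best + 1])
    if slope <= 0:
        raise EstimationError("negative or zero initial PU slope")
    pws = slope / rho
    greedy_window = (a, best)

    # (ii)-(iv) fixed point between the S1 window and the first backward
    # wave's onset
    n_iter = 0
    converged = False
    bcw = None
    bwd = None
    window_end = b
    for n_iter in range(1, config.pws_max_iter + 1):
        sep = separate_components(beat, pws, rho, config=config)
        bcw = _bcw_onset(sep, lm, config)
        bwd = _first_backward_onset(sep, lm, config)
        window_end = min(bwd[1], b) if bwd is not None else b
        if window_end - a + 1 < config.s1_min_samples:
            window_end = a + config.s1_min_samples - 1
        slope, r2, _ = _fit_slope(p_pa[a:window_end + 1], u[a:window_end + 1])
        if slope <= 0:
            # pathological refit window (backward-wave onset collided with
            # the foot): keep the previous estimate rather than fail
            window_end = best
            slope, r2, _ = _fit_slope(p_pa[a:best + 1], u[a:best + 1])
            break
        new = slope / rho
        done = abs(new - pws) / pws < config.pws_rel_tol
        pws = new
        if done:
            converged = True
            break
    diag = {
        "greedy_window": greedy_window,
        "s1_window": (a, window_end),
        "fit_r2": r2,
        "n_iter": n_iter,
        "converged": converged,
        "bcw_onset_idx": bcw[1] if bcw is not None else None,
        "backward_onset_idx": bwd[1] if bwd is not None else None,
        "landmarks": lm,
    }
    return pws, diag


def separate_components(beat: EnsembleBeat, pws: float, rho: float | None = None,
                        config: AnalysisConfig | None = None) -> SeparationResult:
    """Linear forward/backward separation at pulse wave speed ``pws``.

    Component derivatives are formed directly from the beat's dP/dt and
    dU/dt so the identities Pf+Pb = P, Uf+Ub = U and WIf+WIb = net-WI
    hold to machine precision for any ``pws``.
    """
    config = config or AnalysisConfig()
    rho = config.rho_blood_kg_m3 if rho is None else rho
    if pws <= 0:
        raise ParameterError(f"pulse wave speed must be positive, got {pws}")
    k = beat.mmhg_to_pa
    zc = rho * pws                     # water-hammer impedance, Pa per (m/s)
    p, u_ = beat.pressure, beat.velocity
    pf = 0.5 * (p + zc * u_ / k)       # mmHg
    pb = 0.5 * (p - zc * u_ / k)
    uf = 0.5 * (p * k / zc + u_)
    ub = -0.5 * (p * k / zc - u_)
    dpf = 0.5 * (beat.dpdt_pa + zc * beat.dudt)
    dpb = 0.5 * (beat.dpdt_pa - zc * beat.dudt)
    wif = dpf ** 2 / zc
    wib = -(dpb ** 2) / zc
    return SeparationResult(
        pws=pws, rho=rho, p_forward=pf, p_backward=pb,
        u_forward=uf, u_backward=ub,
        net_wi=compute_net_wi(beat.dpdt_pa, beat.dudt),
        wi_forward=wif, wi_backward=wib,
        dpf_dt_pa=dpf, dpb_dt_pa=dpb,
        sampling_rate=beat.sampling_rate,
    )


def _masked_segment(wave_type: str, wi: np.ndarray, mask: np.ndarray) -> WaveSegment:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return WaveSegment(wave_type, 0, 0, present=False, mask=mask)
    return WaveSegment(wave_type, int(idx[0]), int(idx[-1]) + 1, present=True, mask=mask,
                       onset_time_s=float("nan"))


def segment_waves(sep: SeparationResult, lm: Landmarks,
                  config: AnalysisConfig | None = None) -> list[WaveSegment]:
    """Classify the six wave types on one separated beat.

    Phase windows come from the landmarks: phase 1 [A,B), phase 2
    [B,C), phase 3 [C,D). Forward waves are WIf samples split by the
    sign of dPf/dt (compression vs decompression), backward waves WIb
    samples split by the sign of dPb/dt. The BCW additionally carries a
    sub-sample onset time from the two-threshold detection in
    :func:`_bcw_onset`. Absent waves are reported as zero-magnitude
    segments rather than omitted.
    """
    config = config or AnalysisConfig()
    n = sep.net_wi.size
    idx = np.arange(n)
    in1 = (idx >= lm.a_idx) & (idx < lm.b_idx)
    in2 = (idx >= lm.b_idx) & (idx < lm.c_idx)
    in3 = (idx >= lm.c_idx) & (idx < lm.d_idx)
    fwd_c = sep.dpf_dt_pa > 0
    fwd_d = sep.dpf_dt_pa < 0
    bwd_d = sep.dpb_dt_pa < 0

    segments = [
        _masked_segment("initial_FCW", sep.wi_forward, in1 & fwd_c),
        _segment_bcw(sep, lm, config),
        _masked_segment("e_BDW", sep.wi_backward, in1 & bwd_d & (np.abs(sep.wi_backward) > 0)),
        _masked_segment("m_FCW", sep.wi_forward, in2 & fwd_c),
        _masked_segment("m_FDW", sep.wi_forward, in2 & fwd_d),
        _masked_segment("l_FDW", sep.wi_forward, in3 & fwd_d),
    ]
    return segments


def _segment_bcw(sep: SeparationResult, lm: Landmarks, config: AnalysisConfig) -> WaveSegment:
    hit = _bcw_onset(sep, lm, config)
    n = sep.net_wi.size
    if hit is None:
        return WaveSegment("BCW", 0, 0, present=False, mask=np.zeros(n, dtype=bool))
    onset_t, onset_idx, detect = hit
    end = detect
    while end < n and sep.dpb_dt_pa[end] > 0:
        end += 1
    mask = np.zeros(n, dtype=bool)
    mask[onset_idx:end] = True
    return WaveSegment("BCW", onset_idx, end, present=True, mask=mask, onset_time_s=onset_t)


def quantify_waves(segments: list[WaveSegment], net_wi: np.ndarray, lm: Landmarks,
                   sampling_rate: float | None = None,
                   sep: SeparationResult | None = None) -> tuple[list[WaveSegment], float]:
    """Attach peak, cumulative and relative intensity to each segment.

    Cumulative WI is the trapezoidal time integral of the wave's
    intensity over its run; the reference is the integral of the
    positive part of net-WI over [A,B) (the initial positive net-WI),
    and each wave's relative magnitude is |cumulative| divided by that
    reference.
    """
    fs = sampling_rate or lm.sampling_rate
    dt = 1.0 / fs
    net = np.asarray(net_wi, dtype=float)
    ref_region = np.zeros_like(net)
    ref_region[lm.a_idx:lm.b_idx] = np.maximum(net[lm.a_idx:lm.b_idx], 0.0)
    ref = float(np.trapezoid(ref_region, dx=dt))
    if ref <= 0:
        raise QuantificationError("cumulative initial positive net-WI is non-positive")
    for seg in segments:
        if not seg.present:
            seg.peak_wi = seg.cumulative_wi = seg.relative_magnitude = 0.0
            continue
        if seg.wave_type in ("BCW", "e_BDW"):
            wi = (sep.wi_backward if sep is not None else None)
        else:
            wi = (sep.wi_forward if sep is not None else None)
        if wi is None:
            raise QuantificationError("quantify_waves requires the separation result")
        vals = np.where(seg.mask, wi, 0.0)
        seg.cumulative_wi = float(np.trapezoid(vals, dx=dt))
        seg.peak_wi = float(np.max(np.abs(vals)))
        seg.relative_magnitude = abs(seg.cumulative_wi) / ref
    return segments, ref


def compute_td(segments: list[WaveSegment], lm: Landmarks,
               sampling_rate: float | None = None) -> TimingResult:
    """Relative BCW onset time %Td = Td/AcT.

    Td is the time from A (onset of the initial positive net-WI) to the
    BCW onset. When no supra-threshold BCW exists the result is flagged
    absent rather than an error.
    """
    fs = sampling_rate or lm.sampling_rate
    act = lm.act
    bcw = next((s for s in segments if s.wave_type == "BCW"), None)
    if bcw is None or not bcw.present:
        return TimingResult(td=None, act=act, pct_td=None, bcw_onset_idx=None, absent=True)
    onset_t = bcw.onset_time_s if np.isfinite(bcw.onset_time_s) else bcw.onset_idx / fs
    td = onset_t - lm.a_time_s
    return TimingResult(td=td, act=act, pct_td=td / act, bcw_onset_idx=bcw.onset_idx)


def phase_pressure_deltas(sep: SeparationResult, lm: Landmarks) -> PhaseDeltas:
    """Changes of Pb and Pf across phase 1 (A→B) and phase 2 (B→C), mmHg.

    Being differences, these are invariant to any constant offset in P
    and hence to the baseline convention of the absolute separation.
    """
    a, b, c = lm.a_idx, lm.b_idx, lm.c_idx
    return PhaseDeltas(
        dpb_phase1=float(sep.p_backward[b] - sep.p_backward[a]),
        dpf_phase1=float(sep.p_forward[b] - sep.p_forward[a]),
        dpb_phase2=float(sep.p_backward[c] - sep.p_backward[b]),
        dpf_phase2=float(sep.p_forward[c] - sep.p_forward[b]),
    )
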