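"""Pressure-velocity loop construction and slope markers.

The PU-loop of one ensemble beat is traversed in time order from the
onset of ejection (A) to the end of the protodiastolic wave (D). Its
two slope markers are

* S1 — the initial linear A-B slope up to the onset of the first
  backward wave, divided by blood density (m/s; equals local pulse wave
  speed by the water-hammer relation when no reflection contaminates
  the window), and
* S2 — the slope of the B→C limb from peak velocity to peak pressure,
  divided by density. U normally falls while P still rises there, so
  the raw slope is negative; markers are reported as absolute values.

Composites S1+S2 and S2:S1 are formed from the absolute values. The
qualitative bending of the A-B limb relative to the extrapolated S1
line (upward with an early backward compression wave, downward with an
early backward decompression wave) is classified from the mean signed
pressure residual of the post-window A-B samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import EstimationError, ParameterError
from .waveio import EnsembleBeat
from .wia import Landmarks, _fit_slope


@dataclass
class PULoop:
    """Paired P/U samples of one beat restricted to [A, D], time-ordered."""

    u: np.ndarray                # m/s
    p: np.ndarray                # mmHg
    landmarks: Landmarks
    start_idx: int               # beat index of the first loop sample (= A)
    mmhg_to_pa: float
    degenerate: bool = False

    def beat_to_loop(self, beat_idx: int) -> int:
        return beat_idx - self.start_idx


@dataclass
class LoopMarkers:
    """Slope markers of the PU-loop (absolute values, m/s)."""

    s1: float
    s2: float
    s1_plus_s2: float
    s2_s1_ratio: float
    s1_window: tuple[int, int]    # beat indices, inclusive
    s2_fit_r2: float
    ab_bending: str               # upward | downward | none
    s1_raw_slope_pa: float = float("nan")   # Pa per (m/s), signed
    s2_raw_slope_pa: float = float("nan")


def build_loop(beat: EnsembleBeat, lm: Landmarks) -> PULoop:
    """Restrict the beat to [A, D] as a time-ordered PU-loop."""
    if lm is None:
        raise ParameterError("landmarks required to build the loop")
    sl = slice(lm.a_idx, lm.d_idx + 1)
    u = beat.velocity[sl].copy()
    p = beat.pressure[sl].copy()
    degenerate = bool(np.ptp(u) <= 1e-12 or np.ptp(p) <= 1e-12)
    return PULoop(u=u, p=p, landmarks=lm, start_idx=lm.a_idx,
                  mmhg_to_pa=beat.mmhg_to_pa, degenerate=degenerate)


def fit_s1(loop: PULoop, bcw_onset: int | None, rho: float,
           config: AnalysisConfig | None = None) -> tuple[float, tuple[int, int], float]:
    """Initial A-B loop slope up to the first backward wave's onset.

    Least-squares slope of P (Pa) on U over A → min(onset, B), divided
    by rho; returned as (s1 m/s, window beat-indices, raw slope Pa per
    m/s). ``bcw_onset`` is the sample index of the first backward wave
    of either sign (None when the beat is reflection-free).
    """
    config = config or AnalysisConfig()
    lm = loop.landmarks
    end = lm.b_idx if bcw_onset is None else min(bcw_onset, lm.b_idx)
    i0, i1 = loop.beat_to_loop(lm.a_idx), loop.beat_to_loop(end)
    if i1 - i0 + 1 < config.s1_min_samples:
        raise EstimationError(
            f"S1 window of {i1 - i0 + 1} samples (< {config.s1_min_samples}); "
            "review the backward-wave onset threshold")
    slope, _, _ = _fit_slope(loop.p[i0:i1 + 1] * loop.mmhg_to_pa, loop.u[i0:i1 + 1])
    return abs(slope) / rho, (lm.a_idx, end), slope


def fit_s2(loop: PULoop, lm: Landmarks, rho: float,
           config: AnalysisConfig | None = None) -> tuple[float, float, float]:
    """B→C limb slope (absolute value over rho).

    Returns (s2 m/s, fit R^2, raw signed slope Pa per m/s); a two-point
    B→C secant is used instead of least squares when
    ``config.s2_two_point`` is set. A degenerate limb (B = C, or
    constant U) yields s2 = 0 with R^2 = NaN.
    """
    config = config or AnalysisConfig()
    i0, i1 = loop.beat_to_loop(lm.b_idx), loop.beat_to_loop(lm.c_idx)
    if i1 - i0 + 1 < 2:
        return 0.0, float("nan"), float("nan")
    p_pa = loop.p[i0:i1 + 1] * loop.mmhg_to_pa
    u = loop.u[i0:i1 + 1]
    if np.ptp(u) <= 1e-12:
        return 0.0, float("nan"), float("nan")
    if config.s2_two_point or i1 - i0 + 1 < 3:
        slope = (p_pa[-1] - p_pa[0]) / (u[-1] - u[0])
        return abs(slope) / rho, float("nan"), float(slope)
    slope, r2, _ = _fit_slope(p_pa, u)
    return abs(slope) / rho, r2, slope


def composite_markers(s1: float, s2: float) -> tuple[float, float]:
    """S1+S2 and S2:S1 from the absolute-valued markers."""
    if s1 <= 0:
        raise ParameterError("S2:S1 undefined for S1 <= 0")
    return s1 + s2, s2 / s1


def detect_ab_bending(loop: PULoop, s1_window: tuple[int, int], s1_raw_slope: float,
                      config: AnalysisConfig | None = None) -> str:
    """Direction of A-B limb bending relative to the extrapolated S1 line.

    The S1 line is anchored on the fitted window and extrapolated over
    the remaining A-B samples. Because the deviation is zero by
    construction at the backward wave's onset and grows toward B, the
    judgement uses the mean signed pressure residual over the half of
    the post-window limb adjacent to B (a whole-limb mean would dilute
    even an unmistakable bend below threshold). Above
    ``bending_tol_mmhg`` → ``upward`` (an early backward compression
    wave pushes P above the water-hammer line), below the negative
    tolerance → ``downward`` (early backward decompression), otherwise
    ``none``.
    """
    config = config or AnalysisConfig()
    lm = loop.landmarks
    w0, w1 = s1_window
    i0, i1 = loop.beat_to_loop(w0), loop.beat_to_loop(w1)
    ib = loop.beat_to_loop(lm.b_idx)
    if ib <= i1:
        return "none"
    u_w, p_w = loop.u[i0:i1 + 1], loop.p[i0:i1 + 1] * loop.mmhg_to_pa
    intercept = float(np.mean(p_w) - s1_raw_slope * np.mean(u_w))
    half = (i1 + 1 + ib) // 2
    post_u = loop.u[half:ib + 1]
    post_p = loop.p[half:ib + 1] * loop.mmhg_to_pa
    resid_mmhg = float(np.mean(post_p - (s1_raw_slope * post_u + intercept))) / loop.mmhg_to_pa
    if resid_mmhg > config.bending_tol_mmhg:
        return "upward"
    if resid_mmhg < -config.bending_tol_mmhg:
        return "downward"
    return "none"
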