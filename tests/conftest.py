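import numpy as np
import pytest

from puwave.config import AnalysisConfig, MMHG_TO_PA
from puwave.simulate import SyntheticScenario, Wavelet, _closed_scenario, synthesize_beat
from puwave.waveio import EnsembleBeat, differentiate


def grid_scenario(pws=8.0, reflection=0.0, delay=0.0, noise_p=0.0, noise_u=0.0,
                  fcw_inc=45.0, fcw_dur=0.1, n_beats=8, seed=0, **kw):
    """Clean single-FCW scenario with a closing decompression wave."""
    return _closed_scenario(
        pws=pws, fcw_inc=fcw_inc, fcw_dur=fcw_dur,
        reflection_coefficient=reflection, reflection_delay=delay,
        lfdw_onset=0.17, lfdw_dur=0.15,
        noise_sd_p=noise_p, noise_sd_u=noise_u, n_beats=n_beats, seed=seed,
        name="test", **kw)


def beat_from_series(p, u, fs=500.0, config=None):
    """Wrap explicit P/U series into an EnsembleBeat with derivatives."""
    config = config or AnalysisConfig()
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    return EnsembleBeat(
        time=np.arange(p.size) / fs, pressure=p, velocity=u,
        dpdt=differentiate(p, fs, config.derivative_step_s),
        dudt=differentiate(u, fs, config.derivative_step_s),
        sampling_rate=fs, n_beats_averaged=1)


def water_hammer_beat(c=8.0, rho=1060.0, fs=500.0, p_dia=67.0):
    """One clean beat satisfying P − P_dia = rho·c·U exactly."""
    rec, truth = synthesize_beat(grid_scenario(pws=c, n_beats=1, lead_in_s=0.1))
    lead = truth.lead_in_samples
    p = rec.pressure[lead:lead + truth.cycle_samples]
    u = rec.velocity[lead:lead + truth.cycle_samples]
    return beat_from_series(p, u, fs), truth


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def mmhg():
    return MMHG_TO_PA
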