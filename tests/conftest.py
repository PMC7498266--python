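import numpy as np
import pytest

from mapkdyn.params import MigrationSimParams, PulseTrainParams, SustainedParams
from mapkdyn import simulate


@pytest.fixture(scope="session")
def pulse_trace_noiseless():
    params = PulseTrainParams(mean_rate=2.0, noise_sd=0.0, seed=11)
    trace, gt = simulate.simulate_trace(params)
    return trace, gt, params


@pytest.fixture(scope="session")
def sustained_trace_noiseless():
    params = SustainedParams(onset_min=60.0, noise_sd=0.0, seed=11)
    trace, gt = simulate.simulate_trace(params)
    return trace, gt, params


@pytest.fixture(scope="session")
def small_track_table():
    """Small coculture table shared by io/trace/migration tests."""
    motion = MigrationSimParams(n_cells=40, n_frames=36, seed=21,
                                inducible_fraction=0.1)
    trace_params = PulseTrainParams(seed=21)
    table, gt = simulate.simulate_track_population(trace_params, motion)
    return table, gt


def make_angles(kind: str, n: int, seed: int) -> np.ndarray:
    """Angle samples in degrees on [0, 180]: 'uniform' or 'biased' (von
    Mises about 0, folded)."""
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        return rng.uniform(0.0, 180.0, n)
    if kind == "biased":
        return np.degrees(np.abs(rng.vonmises(0.0, 1.0, n)))
    raise ValueError(kind)
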