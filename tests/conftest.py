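import numpy as np
import pytest

import hsafm as H


@pytest.fixture(scope="session")
def dilute_trace():
    """A 30 s simulated trace at the dilute study condition:
    1.0 trimer/µm² diffusing at 0.8 µm² s⁻¹, default noise and feedback.

    Session-scoped: several tests reuse it (events, mixture, windows).
    """
    species = H.SpeciesPopulation(geometry=H.SpeciesGeometry(), density=1.0,
                                  diffusion=0.8)
    cfg = H.SimulationConfig(box_side=2.0, species=(species,), duration=30.0,
                             seed=101)
    return H.simulate_diffusion_trace(cfg)


@pytest.fixture(scope="session")
def telegraph_no_jitter():
    """20 s two-state telegraph with default levels/noise but no per-dwell
    height jitter and short (2 ms) transitions: the idealizer benchmark."""
    cfg = H.TelegraphConfig(seed=5, jitter=(0.0, 0.0), transition_duration=0.002)
    return H.simulate_telegraph_trace(cfg, 20.0)


@pytest.fixture(scope="session")
def rotation_kymograph():
    """Kymograph with a mixed CW/CCW schedule and default 18 ms rotations."""
    schedule = [(0, 0.08), (60, 0.09), (0, 0.08), (-60, 0.09), (0, 0.08),
                (60, 0.07), (120, 0.08)]
    return H.simulate_rotation_kymograph(schedule, noise=H.NoiseModel(0.05), seed=1)


def gt_plateau_dwells(trace):
    """Ground-truth plateau dwells (s) and state labels of a telegraph trace."""
    st = trace.states
    change = np.flatnonzero(np.diff(st)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, st.size]
    vals = st[starts]
    keep = vals >= 0
    return ((ends - starts)[keep] / trace.sampling_rate, vals[keep],
            starts[keep], ends[keep])


def map_idealization_labels(ideal, trace):
    """Map idealizer states (0=lower level) onto generator states
    (0 = first configured height), per sample."""
    rec = ideal.sample_states(trace.n_samples)
    upper_is_state0 = trace.meta["config"].heights[0] > trace.meta["config"].heights[1]
    return np.where(rec == 1, 0 if upper_is_state0 else 1,
                    1 if upper_is_state0 else 0)
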