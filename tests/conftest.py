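import numpy as np
import pytest

from neorsa import scenario_a, scenario_b, simulate_recording


@pytest.fixture(scope="session")
def recording_a():
    """One clean-ish default scenario-A recording (process, beats, ECG)."""
    return simulate_recording(scenario_a(seed=7), subject_id="S_A")


@pytest.fixture(scope="session")
def recording_b():
    return simulate_recording(scenario_b(seed=7), subject_id="S_B")


@pytest.fixture(scope="session")
def clean_ecg_a():
    """Scenario-A ECG rendered without measurement noise or wander."""
    _, beats, ecg = simulate_recording(
        scenario_a(seed=3),
        ecg_params=dict(noise_sd=0.0, wander_amp=0.0),
        subject_id="S_clean",
    )
    return beats, ecg


def match_beats(detected, truth, tol_s=0.020):
    """Greedy matching of detected beat times to truth within a tolerance.

    Returns (recall, precision). Each true beat may be claimed once.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0:
        return 0.0, 0.0
    used = np.zeros(truth.size, dtype=bool)
    hits = 0
    for d in detected:
        dist = np.abs(truth - d)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tol_s:
            used[j] = True
            hits += 1
    return hits / truth.size, hits / detected.size
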