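"""Shared fixtures: a seeded item set, session plan, and noiseless helpers."""

import numpy as np
import pytest

from ctpcit import stimgen, synth_eeg

SRATE = 250.0
WINDOW = (-100.0, 1400.0)


@pytest.fixture(scope="session")
def item_set() -> stimgen.ItemSet:
    return stimgen.build_item_set("ANNA", (6, 19), "DOLPHIN", "standard", seed=1)


@pytest.fixture(scope="session")
def session_plan(item_set) -> stimgen.SessionPlan:
    return stimgen.make_session_plan(item_set, "standard", seed=2)


@pytest.fixture(scope="session")
def silent_noise() -> synth_eeg.NoiseModel:
    return synth_eeg.NoiseModel.silent()


@pytest.fixture(scope="session")
def noiseless_guilty_session(session_plan, silent_noise):
    """Noiseless guilty subject (no artifacts/errors): primary epochs only."""
    profile = synth_eeg.SubjectProfile(
        artifact_rate=0.0,
        error_rate={"probe": 0.0, "irrelevant": 0.0, "target": 0.0, "nontarget": 0.0},
    )
    prim, _, beh = synth_eeg.simulate_session(
        session_plan, profile, silent_noise, seed=3, include_secondary=False)
    return prim, beh, profile


def brute_force_p300pp(wave: np.ndarray, srate: float = SRATE,
                       tmin_ms: float = WINDOW[0],
                       seg_ms: float = 100.0,
                       max_lo: float = 400.0, max_hi: float = 800.0,
                       min_end: float = 1400.0):
    """Independent exhaustive segment scan (plain loops, no shared code).

    Returns (max_mean, max_mid_ms, min_mean, min_mid_ms).
    """
    n = len(wave)
    dt = 1000.0 / srate
    seg_n = round(seg_ms / 1000.0 * srate)
    best_max, best_max_start = None, None
    for i in range(n - seg_n + 1):
        t_start = tmin_ms + i * dt
        if t_start < max_lo - 1e-9 or t_start + seg_ms > max_hi + 1e-9:
            continue
        m = float(np.mean(wave[i:i + seg_n]))
        if best_max is None or m > best_max:
            best_max, best_max_start = m, i
    assert best_max is not None
    mid_ms = tmin_ms + best_max_start * dt + seg_ms / 2.0
    mid_idx = int(np.floor((mid_ms - tmin_ms) / dt))
    mid_grid = tmin_ms + mid_idx * dt
    best_min, best_min_start = None, None
    for i in range(n - seg_n + 1):
        t_start = tmin_ms + i * dt
        if t_start < mid_grid - 1e-9 or t_start + seg_ms > min_end + 1e-9:
            continue
        m = float(np.mean(wave[i:i + seg_n]))
        if best_min is None or m < best_min:
            best_min, best_min_start = m, i
    assert best_min is not None
    return (best_max, mid_ms, best_min,
            tmin_ms + best_min_start * dt + seg_ms / 2.0)
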