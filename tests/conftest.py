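import numpy as np
import pandas as pd
import pytest

import wristmotion as wm
from wristmotion.cli import extract_rows
from wristmotion.synthgen import CohortDesign, iter_cohort

START = pd.Timestamp("2024-03-04 08:00:00")


def trace_from(samples: np.ndarray, fs: float = 30.0, start=START, wear_id="t") -> wm.RawTrace:
    """Build a RawTrace from a raw (n, 3) sample array."""
    return wm.RawTrace(np.asarray(samples, dtype=float), fs, start, wear_id)


def sinusoid_trace(
    freq_hz: float,
    amplitude_g: float = 0.3,
    duration_s: float = 5400.0,
    fs: float = 30.0,
    direction=(0.5, 0.5, np.sqrt(0.5)),
) -> wm.RawTrace:
    """Gravity along z plus a single-frequency oscillation tilted into it."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    d = np.asarray(direction, dtype=float)
    sig = amplitude_g * np.sin(2 * np.pi * freq_hz * t)
    samples = np.array([0.0, 0.0, 1.0])[None, :] + sig[:, None] * d[None, :]
    return trace_from(samples)


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    """Metric table of a 30-per-group single-visit synthetic cohort.

    Wear periods are shortened to 8 daytime hours so the full
    simulate-and-extract pass stays fast; the group-graded structure of the
    default profiles is duration-robust.
    """
    design = CohortDesign(
        n_per_group=30,
        visits_per_dmd_participant=1,
        wear_hours_control=8.0,
        wear_days_dmd=8.0 / 24.0,
        transition_fraction=0.0,
        seed=42,
    )
    return extract_rows(iter_cohort(design))


@pytest.fixture(scope="session")
def control_trace() -> wm.RawTrace:
    """A 2 h healthy-control wear period."""
    return wm.simulate_trace(wm.DEFAULT_PROFILES["healthy_control"], 2.0, seed=5)
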