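"""Synthetic wrist-worn accelerometer wear for a three-group cohort.

Emulates dominant-wrist 30 Hz tri-axial wear for healthy controls,
ambulatory DMD and non-ambulatory DMD participants.  Each trace is the sum
of

* a quasi-static ~1 g gravity vector whose orientation drifts slowly;
* Poisson-timed movement *bouts* during waking hours — amplitude-modulated
  narrowband oscillation at a group-specific center frequency, plus a
  tremor-band component and a low-pass-shaped roughness component — zeroed
  during a fixed nightly sleep window; and
* a white sensor-noise floor.

The three default profiles are graded so that the downstream pipeline
reproduces the clinical ordinal pattern: movement amount, amplitude,
smoothness and regularity decrease, and spectral frequency content
increases, from healthy control → ambulatory DMD → non-ambulatory DMD.
The numeric profile values are this package's own calibration, not
measurements from any cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import RawTrace, write_manifest, write_raw_csv

__all__ = [
    "GroupProfile",
    "CohortDesign",
    "DEFAULT_PROFILES",
    "simulate_trace",
    "simulate_cohort",
]

GROUP_LABELS = ("healthy_control", "dmd_ambulatory", "dmd_non_ambulatory")

#: Band (Hz) in which the tremor-like high-frequency component is placed.
TREMOR_BAND_HZ = (5.5, 11.0)

#: Fixed cohort start of wear (device-local clock).
BASE_START = pd.Timestamp("2024-03-04 08:00:00")


@dataclass(frozen=True)
class GroupProfile:
    """Generative movement profile of one participant group.

    Rates and amplitudes control movement *quantity* (counts); the corner
    and tremor parameters control *quality* (jerk, entropy, spectral
    moments).  All frequencies must sit below the 15 Hz Nyquist limit of
    30 Hz sampling.
    """

    group_label: str
    bout_rate: float  # bouts per waking hour
    bout_amplitude: float  # mean peak acceleration per bout, g
    bout_duration: float  # mean bout length, s
    movement_center_freq: float  # Hz
    smoothness_corner: float  # Hz; lower => smoother => lower jerk
    tremor_fraction: float  # share of bout energy at tremor-band frequencies
    sleep_window: tuple[float, float] = (23.0, 7.0)  # clock hours
    noise_floor: float = 0.003  # g
    gravity_orientation_drift: float = 5e-4  # Hz

    def validate(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group_label {self.group_label!r}")
        positive = {
            "bout_amplitude": self.bout_amplitude,
            "bout_duration": self.bout_duration,
            "movement_center_freq": self.movement_center_freq,
            "smoothness_corner": self.smoothness_corner,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.bout_rate < 0 or self.noise_floor < 0:
            raise ValueError("bout_rate and noise_floor must be non-negative")
        if not 0 < self.movement_center_freq < 15:
            raise ValueError("movement_center_freq must lie in (0, 15) Hz")
        if not 0 < self.smoothness_corner < 15:
            raise ValueError("smoothness_corner must lie in (0, 15) Hz")
        if not 0 <= self.tremor_fraction <= 1:
            raise ValueError("tremor_fraction must lie in [0, 1]")


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "healthy_control": GroupProfile(
        group_label="healthy_control",
        bout_rate=100.0,
        bout_amplitude=0.62,
        bout_duration=28.0,
        movement_center_freq=2.4,
        smoothness_corner=6.0,
        tremor_fraction=0.06,
    ),
    "dmd_ambulatory": GroupProfile(
        group_label="dmd_ambulatory",
        bout_rate=45.0,
        bout_amplitude=0.28,
        bout_duration=18.0,
        movement_center_freq=2.9,
        smoothness_corner=4.5,
        tremor_fraction=0.18,
    ),
    "dmd_non_ambulatory": GroupProfile(
        group_label="dmd_non_ambulatory",
        bout_rate=22.0,
        bout_amplitude=0.13,
        bout_duration=12.0,
        movement_center_freq=3.4,
        smoothness_corner=3.2,
        tremor_fraction=0.38,
    ),
}


@dataclass
class CohortDesign:
    """Shape of a simulated multi-visit cohort.

    Defaults mirror the clinical wear protocol: one 48–96 h wear for
    controls (72 h default) and one 7-day wear per annual visit for DMD
    participants, with a fraction of ambulatory participants losing
    ambulation at a follow-up visit.
    """

    n_per_group: int = 30
    visits_per_dmd_participant: int = 2
    wear_hours_control: float = 72.0
    wear_days_dmd: float = 7.0
    transition_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.visits_per_dmd_participant not in (1, 2, 3):
            raise ValueError("visits_per_dmd_participant must be 1, 2 or 3")
        if self.wear_hours_control <= 0 or self.wear_days_dmd <= 0:
            raise ValueError("wear durations must be positive")
        if not 0 <= self.transition_fraction <= 1:
            raise ValueError("transition_fraction must lie in [0, 1]")


def _gravity(n: int, fs: float, drift_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit gravity vector with slowly precessing orientation, shape (n, 3)."""
    t = np.arange(n) / fs
    theta0, phi0 = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    theta = theta0 + 0.4 * np.sin(2 * np.pi * drift_hz * t + p1)
    phi = phi0 + 0.7 * np.sin(2 * np.pi * drift_hz * 0.73 * t + p2)
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _wake_mask_seconds(
    start_time: pd.Timestamp, n_seconds: int, sleep_window: tuple[float, float]
) -> np.ndarray:
    """Boolean waking mask per second of the record (device clock)."""
    start_hour = (
        start_time - start_time.normalize()
    ).total_seconds() / 3600.0
    hour = (start_hour + np.arange(n_seconds) / 3600.0) % 24.0
    lo, hi = sleep_window
    if lo <= hi:
        asleep = (hour >= lo) & (hour < hi)
    else:  # window wraps midnight
        asleep = (hour >= lo) | (hour < hi)
    return ~asleep


def _unit_noise(sos: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """White noise shaped by ``sos`` and rescaled to unit standard deviation."""
    x = signal.sosfilt(sos, rng.standard_normal(m))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_trace(
    profile: GroupProfile,
    duration_hours: float,
    seed: int,
    start_time: pd.Timestamp = BASE_START,
    sampling_rate: float = 30.0,
    wear_id: str = "",
) -> RawTrace:
    """Simulate one wear period for a participant with the given profile.

    The same ``(profile, duration, seed)`` always yields the identical
    trace.  Raises on non-positive duration or an invalid profile.
    """
    if not duration_hours > 0:
        raise ValueError("duration_hours must be positive")
    profile.validate()
    fs = sampling_rate
    n = int(round(duration_hours * 3600 * fs))
    rng = np.random.default_rng(seed)

    grav = _gravity(n, fs, profile.gravity_orientation_drift, rng)
    dyn = np.zeros((n, 3))

    n_seconds = int(np.ceil(n / fs))
    wake = _wake_mask_seconds(start_time, n_seconds, profile.sleep_window)
    waking_seconds = np.flatnonzero(wake)
    if profile.bout_rate > 0 and waking_seconds.size:
        lam = profile.bout_rate * waking_seconds.size / 3600.0
        n_bouts = rng.poisson(lam)
        tremor_sos = signal.butter(
            2, TREMOR_BAND_HZ, btype="bandpass", fs=fs, output="sos"
        )
        rough_sos = signal.butter(
            2, profile.smoothness_corner, btype="lowpass", fs=fs, output="sos"
        )
        # second-scale amplitude irregularity within bouts; keeps the 1 Hz
        # count series from being a predictable smooth envelope
        jitter_sos = signal.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        starts = rng.choice(waking_seconds, size=n_bouts, replace=True)
        for sec in np.sort(starts):
            dur = float(np.clip(rng.exponential(profile.bout_duration), 2.0, 120.0))
            m = int(round(dur * fs))
            i0 = int(sec * fs)
            m = min(m, n - i0)
            if m < 2:
                continue
            amp = profile.bout_amplitude * rng.lognormal(0.0, 0.4)
            t = np.arange(m) / fs
            f_c = profile.movement_center_freq * rng.lognormal(0.0, 0.08)
            osc = np.sin(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi))
            tremor = _unit_noise(tremor_sos, m, rng)
            rough = _unit_noise(rough_sos, m, rng)
            tf = profile.tremor_fraction
            sig = (1.0 - tf) * osc + tf * tremor + 0.3 * rough
            envelope = np.hanning(m) * np.exp(0.8 * _unit_noise(jitter_sos, m, rng) - 0.32)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            dyn[i0 : i0 + m] += (amp * envelope * sig)[:, None] * direction

    # movement stops during the sleep window
    wake_per_sample = np.repeat(wake, int(fs))[:n]
    dyn *= wake_per_sample[:, None]

    samples = grav + dyn
    if profile.noise_floor > 0:
        samples = samples + profile.noise_floor * rng.standard_normal((n, 3))
    return RawTrace(
        samples=samples,
        sampling_rate=fs,
        start_time=start_time,
        wear_id=wear_id,
    )


def _profile_for(group: str, ambulatory: int, profiles: dict[str, GroupProfile]) -> GroupProfile:
    if group == "control":
        return profiles["healthy_control"]
    return profiles["dmd_ambulatory"] if ambulatory else profiles["dmd_non_ambulatory"]


def _cohort_plan(design: CohortDesign) -> list[dict]:
    """One entry per wear period, with ambulatory-transition labels applied."""
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    visits = design.visits_per_dmd_participant
    n_transition = int(round(design.transition_fraction * n)) if visits > 1 else 0
    transition_visit = {i: int(rng.integers(2, visits + 1)) for i in range(n_transition)}

    plan: list[dict] = []
    for i in range(n):
        plan.append(
            dict(participant_id=f"CTL{i + 1:03d}", visit=1, group="control", ambulatory=1)
        )
    for i in range(n):
        for v in range(1, visits + 1):
            amb = 0 if (i in transition_visit and v >= transition_visit[i]) else 1
            plan.append(
                dict(participant_id=f"AMB{i + 1:03d}", visit=v, group="dmd", ambulatory=amb)
            )
    for i in range(n):
        for v in range(1, visits + 1):
            plan.append(
                dict(participant_id=f"NON{i + 1:03d}", visit=v, group="dmd", ambulatory=0)
            )
    return plan


def iter_cohort(
    design: CohortDesign, profiles: dict[str, GroupProfile] | None = None
):
    """Lazily yield ``(manifest_row_dict, RawTrace)`` per wear period.

    Memory-friendly form of :func:`simulate_cohort`: traces are generated
    one at a time and can be discarded after processing.  Deterministic for
    a fixed design seed.
    """
    design.validate()
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    for p in profiles.values():
        p.validate()
    plan = _cohort_plan(design)
    children = np.random.SeedSequence(design.seed).spawn(len(plan))
    for entry, child in zip(plan, children):
        wear_id = f"{entry['participant_id']}_{entry['visit']}"
        profile = _profile_for(entry["group"], entry["ambulatory"], profiles)
        duration = (
            design.wear_hours_control
            if entry["group"] == "control"
            else design.wear_days_dmd * 24.0
        )
        start = BASE_START + pd.Timedelta(days=365 * (entry["visit"] - 1))
        trace_seed = int(child.generate_state(1)[0] % (2**31))
        trace = simulate_trace(
            profile, duration, trace_seed, start_time=start, wear_id=wear_id
        )
        row = dict(
            participant_id=entry["participant_id"],
            visit=entry["visit"],
            group=entry["group"],
            ambulatory=entry["ambulatory"],
            wear_file=f"{wear_id}.csv",
            start_time=start.isoformat(),
        )
        yield row, trace


def simulate_cohort(
    design: CohortDesign,
    profiles: dict[str, GroupProfile] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, RawTrace]]:
    """Simulate a three-group cohort; optionally write traces + manifest.

    Controls get one wear period each; DMD participants get one per visit.
    ``round(transition_fraction × n_per_group)`` of the ambulatory DMD
    participants become non-ambulatory at a later visit (label and
    generative profile both change).  Returns the manifest DataFrame and a
    dict of traces keyed by wear id; with ``out_dir`` set, also writes one
    RAW CSV per wear period plus ``manifest.csv``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    traces: dict[str, RawTrace] = {}
    rows = []
    for row, trace in iter_cohort(design, profiles):
        traces[trace.wear_id] = trace
        rows.append(row)
        if out_path is not None:
            try:
                write_raw_csv(trace, out_path / row["wear_file"])
            except OSError as exc:
                raise OSError(
                    f"failed writing trace {out_path / row['wear_file']}: {exc}"
                ) from exc
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
    return manifest, traces
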