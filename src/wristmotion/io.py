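"""File formats and in-memory containers for the accelerometry pipeline.

Three plain-text formats are used throughout:

* **RAW CSV** — one tri-axial wear period at a fixed sampling rate, in
  gravitational units (g).  Three ``#key=value`` header lines
  (``sample_rate_hz``, ``start_time``, ``id``) precede a standard
  ``x_g,y_g,z_g`` CSV body, one row per sample.
* **Epoch CSV** — activity counts on a fixed 1 s or 15 s epoch grid:
  ``epoch_start,x_counts,y_counts,z_counts,vm_counts``.
* **Manifest CSV** — one row per wear period:
  ``participant_id,visit,group,ambulatory,wear_file,start_time``.

All readers validate rather than coerce: malformed headers, ragged rows,
NaN samples, impossible visits and control/ambulatory contradictions are
reported as errors naming the offending line or row.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawTrace",
    "EpochSeries",
    "WearRecord",
    "read_raw_csv",
    "write_raw_csv",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_manifest",
    "write_manifest",
]

EPOCH_LENGTHS_S = (1, 15)


class FormatError(ValueError):
    """A file did not conform to one of the pipeline's text dialects."""


@dataclass
class RawTrace:
    """Tri-axial acceleration samples in g at a fixed sampling rate.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)``; columns are the x, y, z axes in g.
    sampling_rate
        Samples per second (30 in this study design).
    start_time
        Wall-clock time of the first sample (device-local, naive).
    wear_id
        ``<participant>_<visit>`` identifier of the wear period.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: pd.Timestamp
    wear_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the three axes, per sample."""
        return np.linalg.norm(self.samples, axis=1)


@dataclass
class EpochSeries:
    """Per-axis and vector-magnitude activity counts on a fixed epoch grid."""

    epoch_length: int
    axis_counts: np.ndarray  # (n, 3) non-negative integers
    vm_counts: np.ndarray  # (n,) vector magnitude, 2-decimal floats
    start_time: pd.Timestamp

    def __post_init__(self) -> None:
        if self.epoch_length not in EPOCH_LENGTHS_S:
            raise ValueError(
                f"epoch_length must be one of {EPOCH_LENGTHS_S}, got {self.epoch_length}"
            )
        self.axis_counts = np.asarray(self.axis_counts, dtype=np.int64)
        self.vm_counts = np.asarray(self.vm_counts, dtype=float)
        if self.axis_counts.ndim != 2 or self.axis_counts.shape[1] != 3:
            raise ValueError("axis_counts must have shape (n, 3)")
        if self.axis_counts.shape[0] != self.vm_counts.shape[0]:
            raise ValueError("axis_counts and vm_counts length mismatch")
        if (self.axis_counts < 0).any() or (self.vm_counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return self.axis_counts.shape[0]

    def epoch_starts(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length, unit="s"
        )


@dataclass
class WearRecord:
    """One manifest row: who wore the device, when, and where the data live."""

    participant_id: str
    visit: int
    group: str  # "control" | "dmd"
    ambulatory: int  # 1 ambulatory, 0 non-ambulatory
    wear_file: str
    start_time: pd.Timestamp
    wear_duration_min: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.group not in ("control", "dmd"):
            raise ValueError(f"group must be control|dmd, got {self.group!r}")
        if not 1 <= int(self.visit) <= 3:
            raise ValueError(f"visit must be 1-3, got {self.visit}")
        if int(self.ambulatory) not in (0, 1):
            raise ValueError("ambulatory must be 0 or 1")
        if self.group == "control" and int(self.ambulatory) != 1:
            raise ValueError(
                f"control participant {self.participant_id} marked non-ambulatory"
            )
        self.visit = int(self.visit)
        self.ambulatory = int(self.ambulatory)
        self.start_time = pd.Timestamp(self.start_time)


# ---------------------------------------------------------------------------
# RAW CSV


def write_raw_csv(trace: RawTrace, path: str | Path) -> None:
    """Write a trace in the RAW CSV dialect (values at micro-g precision)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#sample_rate_hz={trace.sampling_rate:g}\n")
        fh.write(f"#start_time={trace.start_time.isoformat()}\n")
        fh.write(f"#id={trace.wear_id}\n")
        fh.write("x_g,y_g,z_g\n")
        np.savetxt(fh, trace.samples, fmt="%.6f", delimiter=",")


def read_raw_csv(path: str | Path) -> RawTrace:
    """Read a RAW CSV trace, validating headers and sample values."""
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for lineno in range(1, 4):
            line = fh.readline().strip()
            if not line.startswith("#") or "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected '#key=value' header")
            key, _, value = line[1:].partition("=")
            header[key] = value
        cols = fh.readline().strip()
        if cols != "x_g,y_g,z_g":
            raise FormatError(f"{path}: line 4: expected column header 'x_g,y_g,z_g'")
        body = fh.read()
    for key in ("sample_rate_hz", "start_time", "id"):
        if key not in header:
            raise FormatError(f"{path}: missing header '#{key}='")
    try:
        rate = float(header["sample_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad sample_rate_hz {header['sample_rate_hz']!r}") from exc
    if body.strip():
        try:
            data = np.loadtxt(_io.StringIO(body), delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed sample row: {exc}") from exc
    else:
        data = np.empty((0, 3))
    if data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns, found {data.shape[1]}")
    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if bad.size:
        raise FormatError(f"{path}: non-finite sample at data row {bad[0] + 1}")
    return RawTrace(
        samples=data,
        sampling_rate=rate,
        start_time=pd.Timestamp(header["start_time"]),
        wear_id=header["id"],
    )


# ---------------------------------------------------------------------------
# Epoch CSV


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epoch_start": series.epoch_starts().map(lambda t: t.isoformat()),
            "x_counts": series.axis_counts[:, 0],
            "y_counts": series.axis_counts[:, 1],
            "z_counts": series.axis_counts[:, 2],
            "vm_counts": [f"{v:.2f}" for v in series.vm_counts],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_epoch_csv(path: str | Path) -> EpochSeries:
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["epoch_start", "x_counts", "y_counts", "z_counts", "vm_counts"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # +header, 1-based
        raise FormatError(f"{path}: missing value at line {row}")
    starts = pd.to_datetime(df["epoch_start"])
    if len(df) >= 2:
        steps = starts.diff().dropna().dt.total_seconds().unique()
        if len(steps) != 1:
            raise FormatError(f"{path}: epoch grid is not uniform")
        epoch_length = int(steps[0])
    else:
        epoch_length = 1
    if epoch_length not in EPOCH_LENGTHS_S:
        raise FormatError(f"{path}: epoch length {epoch_length}s not in {EPOCH_LENGTHS_S}")
    return EpochSeries(
        epoch_length=epoch_length,
        axis_counts=df[["x_counts", "y_counts", "z_counts"]].to_numpy(),
        vm_counts=df["vm_counts"].to_numpy(dtype=float),
        start_time=starts.iloc[0] if len(df) else pd.Timestamp(0),
    )


# ---------------------------------------------------------------------------
# Manifest CSV

MANIFEST_COLUMNS = [
    "participant_id",
    "visit",
    "group",
    "ambulatory",
    "wear_file",
    "start_time",
]


def write_manifest(records: list[WearRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records[MANIFEST_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "visit": r.visit,
                    "group": r.group,
                    "ambulatory": r.ambulatory,
                    "wear_file": r.wear_file,
                    "start_time": pd.Timestamp(r.start_time).isoformat(),
                }
                for r in records
            ],
            columns=MANIFEST_COLUMNS,
        )
    df.to_csv(path, index=False, lineterminator="\n")


def read_manifest(path: str | Path, check_files: bool = True) -> list[WearRecord]:
    """Read and validate a cohort manifest.

    Duplicate ``(participant, visit)`` pairs, controls marked non-ambulatory,
    out-of-range visits and dangling ``wear_file`` references are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    records: list[WearRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        try:
            rec = WearRecord(
                participant_id=str(row["participant_id"]),
                visit=int(row["visit"]),
                group=str(row["group"]),
                ambulatory=int(row["ambulatory"]),
                wear_file=str(row["wear_file"]),
                start_time=pd.Timestamp(row["start_time"]),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: row {i + 1}: {exc}") from exc
        key = (rec.participant_id, rec.visit)
        if key in seen:
            raise FormatError(f"{path}: row {i + 1}: duplicate participant/visit {key}")
        seen.add(key)
        if check_files:
            wear_path = path.parent / rec.wear_file
            if not wear_path.exists():
                raise FormatError(
                    f"{path}: row {i + 1}: wear_file not found: {wear_path}"
                )
        records.append(rec)
    return records
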