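"""Recording container and plain-text file round-trip.

File format: comment header lines ``# subject=<id>``, ``# condition=<EO|EC>``,
``# trial=<int>``, ``# fs=<Hz>``, then a CSV header ``time_s,s01_x,s01_y,
s01_z,...`` and one row per sample. Accelerations are m/s^2; sensor axes are
x (nominally ML), y (nominally AP), z (nominally vertical) in the sensor's
own frame.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("EO", "EC")
DIRECTIONS_HORIZONTAL = ("ML", "AP")
AXES = ("x", "y", "z")


class RecordingFormatError(ValueError):
    """Raised when a recording file does not conform to the format."""


@dataclass
class RawRecording:
    """One trial: tri-axial acceleration for an ordered cranial-to-caudal
    sensor chain.

    `data` has shape (n_sensors, 3, T) with axis order (x, y, z), m/s^2.
    """

    subject_id: str
    condition: str
    trial_index: int
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 3:
            raise ValueError(f"data must be (n_sensors, 3, T); got {self.data.shape}")
        if self.data.shape[2] == 0:
            raise ValueError("recording has zero samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _sensor_columns(n_sensors: int) -> list[str]:
    return [f"s{n:02d}_{ax}" for n in range(1, n_sensors + 1) for ax in AXES]


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording to the plain-text format (exact float round-trip)."""
    cols = _sensor_columns(rec.n_sensors)
    # (T, n_sensors*3) with per-sensor axis triples interleaved
    flat = rec.data.transpose(2, 0, 1).reshape(rec.n_samples, -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "time_s", rec.time())
    with open(path, "w") as fh:
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# condition={rec.condition}\n")
        fh.write(f"# trial={rec.trial_index}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_recording(path) -> RawRecording:
    """Read a recording file; raises RecordingFormatError naming the line on
    malformed input."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    body_start = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not body_lines:
                body_start = lineno
            body_lines.append(line)

    for key in ("subject", "condition", "trial", "fs"):
        if key not in meta:
            raise RecordingFormatError(f"{path}: missing '# {key}=' header line")
    if not body_lines:
        raise RecordingFormatError(f"{path}: no column header row found")

    try:
        df = pd.read_csv(_io.StringIO("".join(body_lines)), float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise RecordingFormatError(
            f"{path}: malformed table (line offsets relative to line {body_start}): {exc}"
        ) from exc
    if len(df) == 0:
        raise RecordingFormatError(f"{path}: header present but zero data rows")

    if "time_s" not in df.columns:
        raise RecordingFormatError(f"{path}: missing required column 'time_s'")
    sensor_ids = sorted(
        {int(c[1:3]) for c in df.columns if c.startswith("s") and c[1:3].isdigit()}
    )
    if not sensor_ids or sensor_ids != list(range(1, len(sensor_ids) + 1)):
        raise RecordingFormatError(
            f"{path}: sensor columns must cover s01..s{len(sensor_ids):02d}; got {sensor_ids}"
        )
    expected = _sensor_columns(len(sensor_ids))
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"{path}: missing columns {missing}")

    for col in ["time_s", *expected]:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = body_start + 1 + int(bad[0]) if len(bad) else body_start
            raise RecordingFormatError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            )
        if df[col].isna().any():
            line = body_start + 1 + int(df.index[df[col].isna()][0])
            raise RecordingFormatError(
                f"{path}: missing/short row in column '{col}' at line {line}"
            )

    values = df[expected].to_numpy(dtype=float)
    data = values.reshape(len(df), len(sensor_ids), 3).transpose(1, 2, 0)
    try:
        fs = float(meta["fs"])
        trial = int(meta["trial"])
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: non-numeric fs/trial header: {exc}") from exc
    try:
        return RawRecording(
            subject_id=meta["subject"],
            condition=meta["condition"],
            trial_index=trial,
            fs=fs,
            data=data,
        )
    except ValueError as exc:
        raise RecordingFormatError(f"{path}: {exc}") from exc
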