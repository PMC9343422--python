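"""Orientation correction, ML/AP extraction and zero-phase low-pass filtering.

The initial-posture correction assumes the first `static_window` seconds of a
quiet-standing trial are quasi-static, so the window-mean sensor vector is
(up to sway and noise) gravity in the sensor frame. Each sensor is corrected
by the minimal-angle rotation that maps that mean vector onto the world
vertical axis; the remaining heading degree of freedom is left at the
sensor's nominal mounting (x -> ML, y -> AP).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import DIRECTIONS_HORIZONTAL, RawRecording, RecordingFormatError

GRAVITY = 9.81

DEFAULT_CUTOFF = 20.0  # Hz
DEFAULT_STATIC_WINDOW = 1.0  # s
FILTER_ORDER = 4


class DegenerateOrientationError(ValueError):
    """Static-window mean is too small to define 'down'."""


@dataclass
class OrientationEstimate:
    """Per-sensor rotations mapping sensor-frame vectors into the world frame
    (ML, AP, vertical). Shape (n_sensors, 3, 3), each orthonormal, det +1."""

    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n_sensors, 3, 3)")

    @property
    def n_sensors(self) -> int:
        return self.rotations.shape[0]

    def angles(self) -> np.ndarray:
        """Rotation angle of each sensor correction, radians."""
        traces = np.einsum("nii->n", self.rotations)
        return np.arccos(np.clip((traces - 1.0) / 2.0, -1.0, 1.0))


@dataclass
class PreprocessedRecording:
    """Filtered world-frame ML/AP acceleration, (n_sensors, T) per direction."""

    subject_id: str
    condition: str
    trial_index: int
    fs: float
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.shape != self.ap.shape or self.ml.ndim != 2:
            raise ValueError("ml and ap must be equal-shape (n_sensors, T) arrays")

    @property
    def n_sensors(self) -> int:
        return self.ml.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ml.shape[1]

    def direction(self, j: str) -> np.ndarray:
        if j not in DIRECTIONS_HORIZONTAL:
            raise ValueError(f"direction must be one of {DIRECTIONS_HORIZONTAL}")
        return self.ml if j == "ML" else self.ap


def _rotation_to_vertical(mean_vec: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation taking `mean_vec` onto +z (Rodrigues)."""
    norm = np.linalg.norm(mean_vec)
    u = mean_vec / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(u @ z, -1.0, 1.0))
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate by pi about ML axis (heading convention)
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def estimate_initial_orientation(
    raw: RawRecording, static_window: float = DEFAULT_STATIC_WINDOW
) -> OrientationEstimate:
    """Estimate per-sensor rotations from the quasi-static trial onset.

    Raises DegenerateOrientationError if any sensor's window-mean vector has
    norm below 0.5 * g (gravity not identifiable).
    """
    if static_window <= 0:
        raise ValueError("static_window must be positive")
    n_win = int(round(static_window * raw.fs))
    if n_win > raw.n_samples:
        raise ValueError(
            f"static_window {static_window}s exceeds duration {raw.duration}s"
        )
    means = raw.data[:, :, :n_win].mean(axis=2)
    rotations = np.empty((raw.n_sensors, 3, 3))
    for n in range(raw.n_sensors):
        norm = np.linalg.norm(means[n])
        if norm < 0.5 * GRAVITY:
            raise DegenerateOrientationError(
                f"sensor {n + 1}: static-window mean norm {norm:.3f} < 0.5*g"
            )
        rotations[n] = _rotation_to_vertical(means[n])
    return OrientationEstimate(rotations=rotations)


def correct_orientation(raw: RawRecording, orient: OrientationEstimate) -> RawRecording:
    """Rotate each sensor's series into the world frame (ML, AP, vertical)."""
    if orient.n_sensors != raw.n_sensors:
        raise ValueError(
            f"orientation for {orient.n_sensors} sensors, recording has {raw.n_sensors}"
        )
    corrected = np.einsum("nij,njt->nit", orient.rotations, raw.data)
    return RawRecording(
        subject_id=raw.subject_id,
        condition=raw.condition,
        trial_index=raw.trial_index,
        fs=raw.fs,
        data=corrected,
    )


def lowpass_filter(
    series: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Zero-phase low-pass (order-4 Butterworth, forward-backward).

    Accepts a 1-D series or an (..., T) array filtered along the last axis;
    output length equals input length.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2})")
    sos = signal.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default
    if series.shape[-1] <= padlen:
        raise ValueError(
            f"series length {series.shape[-1]} too short for filter padding {padlen}"
        )
    return signal.sosfiltfilt(sos, series, axis=-1)


def preprocess_recording(
    raw: RawRecording,
    cutoff: float = DEFAULT_CUTOFF,
    static_window: float = DEFAULT_STATIC_WINDOW,
) -> PreprocessedRecording:
    """Full preprocessing: orientation correction, ML/AP extraction,
    de-meaning, and 20 Hz zero-phase low-pass."""
    orient = estimate_initial_orientation(raw, static_window=static_window)
    world = correct_orientation(raw, orient)
    ml = world.data[:, 0, :]
    ap = world.data[:, 1, :]
    ml = ml - ml.mean(axis=1, keepdims=True)
    ap = ap - ap.mean(axis=1, keepdims=True)
    return PreprocessedRecording(
        subject_id=raw.subject_id,
        condition=raw.condition,
        trial_index=raw.trial_index,
        fs=raw.fs,
        ml=lowpass_filter(ml, raw.fs, cutoff=cutoff),
        ap=lowpass_filter(ap, raw.fs, cutoff=cutoff),
    )


# ---------------------------------------------------------------------------
# plain-text round-trip for CLI chaining


def write_preprocessed(rec: PreprocessedRecording, path) -> None:
    cols = {}
    for n in range(1, rec.n_sensors + 1):
        cols[f"s{n:02d}_ML"] = rec.ml[n - 1]
        cols[f"s{n:02d}_AP"] = rec.ap[n - 1]
    df = pd.DataFrame(cols)
    df.insert(0, "time_s", np.arange(rec.n_samples) / rec.fs)
    with open(path, "w") as fh:
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# condition={rec.condition}\n")
        fh.write(f"# trial={rec.trial_index}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_preprocessed(path) -> PreprocessedRecording:
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body.append(line)
    if not body:
        raise RecordingFormatError(f"{path}: no table found")
    df = pd.read_csv(_io.StringIO("".join(body)), float_precision="round_trip")
    n_sensors = sum(1 for c in df.columns if c.endswith("_ML"))
    if n_sensors == 0:
        raise RecordingFormatError(f"{path}: no sensor columns found")
    ml = np.stack([df[f"s{n:02d}_ML"].to_numpy() for n in range(1, n_sensors + 1)])
    ap = np.stack([df[f"s{n:02d}_AP"].to_numpy() for n in range(1, n_sensors + 1)])
    return PreprocessedRecording(
        subject_id=meta.get("subject", "?"),
        condition=meta.get("condition", "EO"),
        trial_index=int(meta.get("trial", 1)),
        fs=float(meta["fs"]),
        ml=ml,
        ap=ap,
    )
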