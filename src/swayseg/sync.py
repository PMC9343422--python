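"""Pairwise similarity and phase-synchronization statistics.

For a sensor pair (n, m), n cranial of m, in direction j:

* AC   — Pearson correlation of the two filtered acceleration series.
* v    — complex mean phasor (1/T) sum_t exp(i [phi_m(t) - phi_n(t)]),
         phases from the Hilbert analytic signal.
* PLV  — |v|, the time-averaged phase locking value in [0, 1].
* theta — arg(v) in (-pi, pi].
* V    — |v| * cos(theta) / |cos(theta)|, the signed synchronization index:
         near +1 in-phase locking, near -1 anti-phase, near 0 weak.

When cos(theta) is numerically zero (|cos| < 1e-12) the sign is undefined;
it is fixed at +1 and the result flagged `degenerate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io import DIRECTIONS_HORIZONTAL
from .preprocess import PreprocessedRecording

DEGENERATE_COS_TOL = 1e-12
DEFAULT_EDGE_TRIM = 0.5  # s discarded at each end of the phase series
MIN_PHASE_SAMPLES = 100


class UndefinedPhaseError(ValueError):
    """Constant (zero-variance) series has no instantaneous phase."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined for a zero-variance series."""


def instantaneous_phase(series: np.ndarray) -> np.ndarray:
    """Wrapped instantaneous phase in (-pi, pi] of a de-meaned, filtered series.

    The series is de-meaned (again) before the Hilbert transform; a nonzero
    mean corrupts the analytic-signal phase. No edge trim is applied here —
    trimming is done uniformly at the pair stage.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if series.size < MIN_PHASE_SAMPLES:
        raise ValueError(f"series too short ({series.size} < {MIN_PHASE_SAMPLES})")
    centered = series - series.mean()
    if not np.any(centered):
        raise UndefinedPhaseError("zero-variance series: phase undefined")
    phi = np.angle(hilbert(centered))
    # np.angle returns [-pi, pi]; map -pi to +pi for the (-pi, pi] contract
    phi[phi == -np.pi] = np.pi
    return phi


def complex_sync(phi_n: np.ndarray, phi_m: np.ndarray) -> complex:
    """Complex mean phasor of the phase difference phi_m - phi_n."""
    phi_n = np.asarray(phi_n, dtype=float)
    phi_m = np.asarray(phi_m, dtype=float)
    if phi_n.shape != phi_m.shape:
        raise ValueError(f"length mismatch: {phi_n.shape} vs {phi_m.shape}")
    return complex(np.mean(np.exp(1j * (phi_m - phi_n))))


def signed_sync_index(v: complex) -> float:
    """Signed synchronization index V = |v| * sign(cos(arg v))."""
    V, _ = signed_sync_index_flagged(v)
    return V


def signed_sync_index_flagged(v: complex) -> tuple[float, bool]:
    """As `signed_sync_index`, also reporting the degenerate-sign flag."""
    mag = abs(v)
    if mag > 1.0 + 1e-9:
        raise ValueError(f"|v| = {mag} exceeds 1")
    c = np.cos(np.angle(v))
    if abs(c) < DEGENERATE_COS_TOL:
        return mag, True
    return float(mag * np.sign(c)), False


def acceleration_correlation(x_n: np.ndarray, x_m: np.ndarray) -> float:
    """Pearson product-moment correlation of two acceleration series."""
    x_n = np.asarray(x_n, dtype=float)
    x_m = np.asarray(x_m, dtype=float)
    if x_n.shape != x_m.shape:
        raise ValueError(f"length mismatch: {x_n.shape} vs {x_m.shape}")
    if x_n.std() == 0 or x_m.std() == 0:
        raise UndefinedCorrelationError("zero-variance series: correlation undefined")
    return float(np.corrcoef(x_n, x_m)[0, 1])


@dataclass(frozen=True)
class PairwiseSync:
    """All pairwise statistics for one sensor pair and direction."""

    n: int
    m: int
    direction: str
    v: complex
    plv: float
    theta: float
    V: float
    ac: float
    degenerate: bool


def pair_sync(
    phi_n: np.ndarray,
    phi_m: np.ndarray,
    x_n: np.ndarray,
    x_m: np.ndarray,
    n: int,
    m: int,
    direction: str,
) -> PairwiseSync:
    v = complex_sync(phi_n, phi_m)
    V, degenerate = signed_sync_index_flagged(v)
    return PairwiseSync(
        n=n,
        m=m,
        direction=direction,
        v=v,
        plv=abs(v),
        theta=float(np.angle(v)),
        V=V,
        ac=acceleration_correlation(x_n, x_m),
        degenerate=degenerate,
    )


def _resolve_pairs(pairs, n_sensors: int) -> list[tuple[int, int]]:
    if pairs == "all" or pairs is None:
        return list(combinations(range(1, n_sensors + 1), 2))
    if pairs == "adjacent":
        return [(n, n + 1) for n in range(1, n_sensors)]
    out = []
    for n, m in pairs:
        if not (1 <= n < m <= n_sensors):
            raise ValueError(f"invalid pair ({n}, {m}) for {n_sensors} sensors")
        out.append((int(n), int(m)))
    return out


def all_pairs_sync(
    rec: PreprocessedRecording,
    pairs="all",
    trim: float = DEFAULT_EDGE_TRIM,
) -> list[PairwiseSync]:
    """Compute PairwiseSync for the requested pairs in both ML and AP.

    `pairs` is "all" (default, every n < m), "adjacent" (the n, n+1 chain),
    or an explicit iterable of (n, m). `trim` seconds are discarded at each
    end of every series (phase and acceleration alike) to suppress Hilbert
    edge artifacts; the same window is used for every sensor.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    k = int(round(trim * rec.fs))
    if 2 * k >= rec.n_samples:
        raise ValueError(f"trim {trim}s leaves no samples")
    window = slice(k, rec.n_samples - k) if k else slice(None)
    pair_list = _resolve_pairs(pairs, rec.n_sensors)

    results: list[PairwiseSync] = []
    for direction in DIRECTIONS_HORIZONTAL:
        series = rec.direction(direction)
        phases = np.stack([instantaneous_phase(series[i]) for i in range(rec.n_sensors)])
        for n, m in pair_list:
            results.append(
                pair_sync(
                    phases[n - 1, window],
                    phases[m - 1, window],
                    series[n - 1, window],
                    series[m - 1, window],
                    n,
                    m,
                    direction,
                )
            )
    return results


def sync_table(records: list[PairwiseSync], rec: PreprocessedRecording) -> pd.DataFrame:
    """Long-format table of pairwise statistics with recording metadata."""
    return pd.DataFrame(
        {
            "subject": rec.subject_id,
            "condition": rec.condition,
            "trial": rec.trial_index,
            "direction": [r.direction for r in records],
            "sensor_n": [r.n for r in records],
            "sensor_m": [r.m for r in records],
            "plv": [r.plv for r in records],
            "theta": [r.theta for r in records],
            "V": [r.V for r in records],
            "ac": [r.ac for r in records],
            "degenerate_flag": [r.degenerate for r in records],
        }
    )
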