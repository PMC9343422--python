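"""Synthetic multi-segment sway recordings with planted segmentation structure.

Sensors are partitioned into contiguous clusters; every sensor in a cluster
shares one band-limited Gaussian sway source per horizontal direction
(scaled by the cluster amplitude and a per-sensor polarity), optionally mixed
with a global source shared by all clusters. Gravity and a per-sensor static
tilt are applied before output, so the orientation-correction stage of the
pipeline is exercised. The planted partition gives an exact ground truth for
the downstream cluster/link-site analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import DIRECTIONS_HORIZONTAL, RawRecording

GRAVITY = 9.81  # m/s^2, world vertical

DEFAULT_BAND = (0.1, 3.0)  # Hz, typical postural-sway band


class SpecValidationError(ValueError):
    """Raised when a SegmentSpec violates its invariants."""


@dataclass
class ClusterBlock:
    """One contiguous block of sensors sharing a sway source.

    Parameters
    ----------
    sensors : (first, last) 1-based inclusive sensor range.
    band : (low, high) source frequency band in Hz, inside (0, fs/2).
    amplitude : source scale, m/s^2.
    polarity : per-sensor sign (+1 in-phase, -1 anti-phase); sensors not
        listed default to +1.
    lag : per-cluster delay in seconds, realized as a circular shift of the
        cluster source.
    """

    sensors: tuple[int, int]
    band: tuple[float, float] = DEFAULT_BAND
    amplitude: float = 1.0
    polarity: dict[int, int] = field(default_factory=dict)
    lag: float = 0.0

    def sensor_range(self) -> range:
        return range(self.sensors[0], self.sensors[1] + 1)


@dataclass
class SegmentSpec:
    """Generative description of one synthetic recording."""

    clusters: list[ClusterBlock]
    n_sensors: int = 22
    fs: float = 1000.0
    duration: float = 20.0
    cross_coupling: float = 0.0
    noise_sd: float = 0.0
    tilt: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sensors < 2:
            raise SpecValidationError("need at least 2 sensors")
        if self.fs <= 0 or self.duration <= 0:
            raise SpecValidationError("fs and duration must be positive")
        if not 0.0 <= self.cross_coupling <= 1.0:
            raise SpecValidationError("cross_coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be non-negative")
        covered: list[int] = []
        for block in self.clusters:
            first, last = block.sensors
            if first > last:
                raise SpecValidationError(f"cluster range {block.sensors} reversed")
            covered.extend(block.sensor_range())
            low, high = block.band
            if not 0 < low < high < self.fs / 2:
                raise SpecValidationError(
                    f"band {block.band} outside (0, Nyquist={self.fs / 2}) or inverted"
                )
            for s, p in block.polarity.items():
                if s not in block.sensor_range():
                    raise SpecValidationError(f"polarity sensor {s} outside {block.sensors}")
                if p not in (-1, 1):
                    raise SpecValidationError("polarity must be +1 or -1")
        if covered != list(range(1, self.n_sensors + 1)):
            raise SpecValidationError(
                "cluster blocks must be disjoint, contiguous and cover "
                f"1..{self.n_sensors}; got {covered}"
            )
        for s in self.tilt:
            if not 1 <= s <= self.n_sensors:
                raise SpecValidationError(f"tilt sensor {s} out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class GroundTruthSegmentation:
    """Planted link pairs and coherent sensor runs implied by a SegmentSpec."""

    link_pairs: frozenset[tuple[int, int]]
    cluster_runs: tuple[tuple[int, int], ...]


def ground_truth_segmentation(spec: SegmentSpec) -> GroundTruthSegmentation:
    """Return the adjacent pairs straddling cluster boundaries and the runs."""
    spec.validate()
    runs = tuple(block.sensors for block in spec.clusters)
    links = frozenset(
        (runs[i][1], runs[i][1] + 1) for i in range(len(runs) - 1)
    )
    return GroundTruthSegmentation(link_pairs=links, cluster_runs=runs)


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Unit-variance Gaussian noise whose spectrum lies exactly in `band`.

    Synthesized in the frequency domain (iid complex-Gaussian coefficients on
    the in-band rFFT bins, zero elsewhere). A time-domain Butterworth pass of
    white noise leaks several percent of power outside a narrow band like
    0.1-3 Hz; spectral synthesis keeps the out-of-band periodogram mass at
    zero and makes circular lag shifts exact.
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise SpecValidationError(f"band {band} outside (0, Nyquist)")
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    k = int(mask.sum())
    if k == 0:
        raise SpecValidationError(
            f"band {band} contains no frequency bin at n={n_samples}, fs={fs}"
        )
    coef = np.zeros(freqs.size, dtype=complex)
    coef[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(coef, n=n_samples)
    return x / x.std()


def generate_recording(
    spec: SegmentSpec,
    subject_id: str = "sim",
    condition: str = "EO",
    trial_index: int = 1,
) -> RawRecording:
    """Simulate one trial's raw (sensor-frame) tri-axial recording.

    Deterministic for a given spec (including seed). Per horizontal
    direction, sensor n in cluster c reads

        amplitude_c * polarity_n * source_c(t - lag_c)
        + cross_coupling * global(t) + noise_n(t)

    with gravity on the world vertical axis; the whole world vector is then
    rotated into the sensor frame by the per-sensor tilt (a pitch about the
    ML axis), emulating imperfect mounting.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = spec.n_samples

    # Draw order is fixed: global sources, then cluster sources, then noise.
    global_src = {
        d: band_limited_noise(rng, T, spec.fs, DEFAULT_BAND)
        for d in DIRECTIONS_HORIZONTAL
    }
    cluster_src = [
        {d: band_limited_noise(rng, T, spec.fs, block.band) for d in DIRECTIONS_HORIZONTAL}
        for block in spec.clusters
    ]

    world = np.zeros((spec.n_sensors, 3, T))  # axes: ML, AP, vertical
    for block, sources in zip(spec.clusters, cluster_src):
        shift = int(round(block.lag * spec.fs))
        for di, d in enumerate(DIRECTIONS_HORIZONTAL):
            src = np.roll(sources[d], shift)
            for s in block.sensor_range():
                pol = block.polarity.get(s, 1)
                world[s - 1, di] = (
                    block.amplitude * pol * src
                    + spec.cross_coupling * global_src[d]
                )
    world[:, 2, :] += GRAVITY

    if spec.noise_sd > 0:
        world += spec.noise_sd * rng.standard_normal(world.shape)

    data = np.empty_like(world)
    for s in range(1, spec.n_sensors + 1):
        angle = spec.tilt.get(s, 0.0)
        if angle == 0.0:
            data[s - 1] = world[s - 1]
        else:
            # sensor frame = R^T @ world, R = pitch about the ML (x) axis
            rot = _pitch_rotation(angle)
            data[s - 1] = rot.T @ world[s - 1]

    return RawRecording(
        subject_id=subject_id,
        condition=condition,
        trial_index=trial_index,
        fs=spec.fs,
        data=data,
    )


def _pitch_rotation(angle: float) -> np.ndarray:
    """Rotation about the ML (x) axis by `angle` radians (sensor-to-world)."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


# ---------------------------------------------------------------------------
# plain-text (YAML) serialization of SegmentSpec


def spec_to_dict(spec: SegmentSpec) -> dict:
    return {
        "n_sensors": spec.n_sensors,
        "fs": spec.fs,
        "duration": spec.duration,
        "cross_coupling": spec.cross_coupling,
        "noise_sd": spec.noise_sd,
        "tilt": {int(k): float(v) for k, v in spec.tilt.items()},
        "seed": spec.seed,
        "clusters": [
            {
                "sensors": list(b.sensors),
                "band": list(b.band),
                "amplitude": b.amplitude,
                "polarity": {int(k): int(v) for k, v in b.polarity.items()},
                "lag": b.lag,
            }
            for b in spec.clusters
        ],
    }


def spec_from_dict(d: dict) -> SegmentSpec:
    clusters = [
        ClusterBlock(
            sensors=tuple(c["sensors"]),
            band=tuple(c.get("band", DEFAULT_BAND)),
            amplitude=float(c.get("amplitude", 1.0)),
            polarity={int(k): int(v) for k, v in c.get("polarity", {}).items()},
            lag=float(c.get("lag", 0.0)),
        )
        for c in d["clusters"]
    ]
    spec = SegmentSpec(
        clusters=clusters,
        n_sensors=int(d.get("n_sensors", 22)),
        fs=float(d.get("fs", 1000.0)),
        duration=float(d.get("duration", 20.0)),
        cross_coupling=float(d.get("cross_coupling", 0.0)),
        noise_sd=float(d.get("noise_sd", 0.0)),
        tilt={int(k): float(v) for k, v in d.get("tilt", {}).items()},
        seed=int(d.get("seed", 0)),
    )
    spec.validate()
    return spec


def load_spec(path) -> SegmentSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec(spec: SegmentSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
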