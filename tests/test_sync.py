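import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.signal import chirp

from swayseg.preprocess import preprocess_recording
from swayseg.sync import (
    UndefinedCorrelationError,
    UndefinedPhaseError,
    acceleration_correlation,
    all_pairs_sync,
    complex_sync,
    instantaneous_phase,
    pair_sync,
    signed_sync_index,
    signed_sync_index_flagged,
    sync_table,
)
from swayseg.synthetic import (
    ClusterBlock,
    SegmentSpec,
    band_limited_noise,
    generate_recording,
)

FS = 1000.0


def central(x, frac=0.8):
    k = int(len(x) * (1 - frac) / 2)
    return x[k:-k]


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope(self):
        t = np.arange(int(4 * FS)) / FS
        phi = np.unwrap(instantaneous_phase(np.sin(2 * np.pi * 1.0 * t)))
        slope = np.polyfit(central(t), central(phi), 1)[0]
        assert slope == pytest.approx(2 * np.pi, rel=1e-3)

    def test_quadrature_pair_offset(self):
        t = np.arange(int(4 * FS)) / FS
        w = 2 * np.pi * 2.0
        pc = instantaneous_phase(np.cos(w * t))
        ps = instantaneous_phase(np.sin(w * t))
        diff = np.angle(np.exp(1j * (central(pc) - central(ps))))
        np.testing.assert_allclose(diff, np.pi / 2, atol=1e-3)

    def test_chirp_instantaneous_frequency(self):
        # finite-difference oracle: d(phase)/dt = 2*pi*f_inst(t)
        duration = 20.0
        t = np.arange(int(duration * FS)) / FS
        x = chirp(t, f0=0.5, f1=3.0, t1=duration, method="linear")
        phi = np.unwrap(instantaneous_phase(x))
        dphi = np.gradient(phi, 1 / FS)
        f_inst = 0.5 + (3.0 - 0.5) * t / duration
        rel = central(dphi, 0.6) / (2 * np.pi * central(f_inst, 0.6)) - 1
        assert np.abs(rel).max() < 0.01

    def test_phase_range_contract(self):
        rng = np.random.default_rng(0)
        phi = instantaneous_phase(rng.normal(size=2000))
        assert np.all(phi > -np.pi) and np.all(phi <= np.pi)

    def test_constant_series_raises(self):
        with pytest.raises(UndefinedPhaseError):
            instantaneous_phase(np.full(500, 2.0))

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            instantaneous_phase(np.zeros(50))


class TestComplexSync:
    def test_constant_offset_closed_form(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(-np.pi, np.pi, size=500)
        v = complex_sync(phi, phi + np.pi / 3)
        assert v == pytest.approx(complex(0.5, np.sqrt(3) / 2), abs=1e-12)

    def test_alternating_cancellation(self):
        phi_n = np.zeros(400)
        phi_m = np.tile([0.0, np.pi], 200)
        assert abs(complex_sync(phi_n, phi_m)) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            complex_sync(np.zeros(10), np.zeros(11))

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            T = rng.integers(50, 1000)
            a = rng.uniform(-np.pi, np.pi, size=T)
            b = rng.uniform(-np.pi, np.pi, size=T)
            acc = 0j
            for t in range(T):  # explicit per-sample summation oracle
                acc += np.exp(1j * (b[t] - a[t]))
            assert complex_sync(a, b) == pytest.approx(acc / T, abs=1e-12)

    def test_rayleigh_null_magnitude(self):
        # E|v| for T iid uniform phase differences = sqrt(pi / (4T))
        rng = np.random.default_rng(3)
        T, reps = 10_000, 300
        mags = [
            abs(complex_sync(np.zeros(T), rng.uniform(-np.pi, np.pi, size=T)))
            for _ in range(reps)
        ]
        assert np.mean(mags) == pytest.approx(np.sqrt(np.pi / (4 * T)), rel=0.10)

    def test_null_plv_scales_as_inverse_sqrt_T(self):
        rng = np.random.default_rng(4)
        Ts = [1_000, 10_000, 100_000]
        means = []
        for T in Ts:
            diffs = rng.uniform(-np.pi, np.pi, size=(60, T))
            means.append(np.mean(np.abs(np.exp(1j * diffs).mean(axis=1))))
        slope = np.polyfit(np.log(Ts), np.log(means), 1)[0]
        assert -0.55 < slope < -0.45


class TestSignedSyncIndex:
    def test_positive_cos(self):
        assert signed_sync_index(0.9 * np.exp(0.1j)) == pytest.approx(0.9, abs=1e-12)

    def test_negative_cos(self):
        assert signed_sync_index(0.7 * np.exp(3.0j)) == pytest.approx(-0.7, abs=1e-12)

    def test_degenerate_quadrature_flagged(self):
        V, flag = signed_sync_index_flagged(0.5 * np.exp(1j * np.pi / 2))
        assert V == pytest.approx(0.5, abs=1e-12)
        assert flag is True

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(ValueError):
            signed_sync_index(1.5 + 0j)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=-np.pi, max_value=np.pi),
    )
    @settings(max_examples=200, deadline=None)
    def test_abs_V_equals_plv(self, mag, angle):
        v = mag * np.exp(1j * angle)
        V, _ = signed_sync_index_flagged(v)
        assert abs(V) == pytest.approx(abs(v), abs=1e-12)


class TestAccelerationCorrelation:
    def test_self_and_negated(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        assert acceleration_correlation(x, x) == pytest.approx(1.0, abs=1e-12)
        assert acceleration_correlation(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_sin_cos_orthogonal(self):
        t = np.arange(1000) / 1000.0
        s = np.sin(2 * np.pi * 5 * t)
        c = np.cos(2 * np.pi * 5 * t)
        assert acceleration_correlation(s, c) == pytest.approx(0.0, abs=1e-9)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 4.0])
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert acceleration_correlation(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            acceleration_correlation(np.ones(100), np.arange(100.0))


class TestAllPairsSync:
    def test_noiseless_single_cluster_all_pairs_unity(self, small_single_cluster_spec):
        pre = preprocess_recording(generate_recording(small_single_cluster_spec))
        results = all_pairs_sync(pre, pairs="all")
        assert len(results) == 2 * 15  # C(6,2) per direction
        for r in results:
            assert r.V == pytest.approx(1.0, abs=1e-6)

    def test_adjacent_preset_count(self, small_single_cluster_spec):
        pre = preprocess_recording(generate_recording(small_single_cluster_spec))
        results = all_pairs_sync(pre, pairs="adjacent")
        assert {(r.n, r.m) for r in results} == {(n, n + 1) for n in range(1, 6)}

    def test_swap_conjugates_phasor(self):
        rng = np.random.default_rng(6)
        phi_a = rng.uniform(-np.pi, np.pi, size=2000)
        phi_b = rng.uniform(-np.pi, np.pi, size=2000)
        x_a, x_b = rng.normal(size=(2, 2000))
        fwd = pair_sync(phi_a, phi_b, x_a, x_b, 1, 2, "ML")
        rev = pair_sync(phi_b, phi_a, x_b, x_a, 1, 2, "ML")
        assert rev.v == pytest.approx(np.conj(fwd.v), abs=1e-12)
        assert rev.theta == pytest.approx(-fwd.theta, abs=1e-12)
        assert rev.plv == pytest.approx(fwd.plv, abs=1e-12)
        assert rev.V == pytest.approx(fwd.V, abs=1e-12)
        assert rev.ac == pytest.approx(fwd.ac, abs=1e-12)

    def test_within_cluster_beats_cross_cluster(self):
        wins = 0
        for seed in range(10):
            spec = SegmentSpec(
                clusters=[ClusterBlock((1, 3)), ClusterBlock((4, 6))],
                n_sensors=6, fs=250.0, duration=20.0, seed=seed,
            )
            pre = preprocess_recording(generate_recording(spec))
            results = all_pairs_sync(pre, pairs="adjacent")
            within = [r.V for r in results if (r.n, r.m) != (3, 4)]
            cross = [r.V for r in results if (r.n, r.m) == (3, 4)]
            wins += min(within) > max(cross)
        assert wins >= 9

    def test_time_shift_rotates_mean_angle(self):
        # common narrowband source at f = 1 Hz, relative delay tau
        # -> |theta| ~ 2 pi f tau
        rng = np.random.default_rng(8)
        src = band_limited_noise(rng, 20_000, 1000.0, band=(0.95, 1.05))
        k = 500
        phi_n = instantaneous_phase(src)[k:-k]
        for tau in (0.05, 0.1):
            shifted = np.roll(src, int(round(tau * 1000.0)))
            phi_m = instantaneous_phase(shifted)[k:-k]
            theta = np.angle(complex_sync(phi_n, phi_m))
            assert abs(theta) == pytest.approx(2 * np.pi * 1.0 * tau, rel=0.05)

    def test_trim_too_large_raises(self, small_single_cluster_spec):
        pre = preprocess_recording(generate_recording(small_single_cluster_spec))
        with pytest.raises(ValueError):
            all_pairs_sync(pre, trim=10.0)

    def test_sync_table_columns(self, small_single_cluster_spec):
        pre = preprocess_recording(generate_recording(small_single_cluster_spec))
        table = sync_table(all_pairs_sync(pre, pairs="adjacent"), pre)
        assert list(table.columns) == [
            "subject", "condition", "trial", "direction", "sensor_n", "sensor_m",
            "plv", "theta", "V", "ac", "degenerate_flag",
        ]
        assert set(table["direction"]) == {"ML", "AP"}

    @given(
        hnp.arrays(np.float64, (2, 300),
                   elements=st.floats(min_value=-np.pi, max_value=np.pi)),
    )
    @settings(max_examples=50, deadline=None)
    def test_plv_bounds_property(self, phases):
        v = complex_sync(phases[0], phases[1])
        assert abs(v) <= 1.0 + 1e-12
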