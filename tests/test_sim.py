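"""Generative-model tests: closed-form probabilities, OU moments,
trace simulation contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanonmr import (
    DetectionSpec,
    NoiseSpec,
    OUParams,
    ResolutionModel,
    SignalParams,
    angular,
    detection_probability,
    ou_path,
    resolution_probability,
    segment_raw_stream,
    simulate_dataset,
    simulate_resolution_trace,
    simulate_trace,
    success_probability,
)

TWO_PI = 2 * math.pi


def eq2_oracle(g, omega, phi, dt, t):
    """Independently coded one-line success probability."""
    return math.sin(
        (g / (2 * omega)) * (math.sin(omega * t + phi)
                             - math.sin(omega * (t - dt) + phi))
        + math.pi / 4
    ) ** 2


class TestSuccessProbability:
    def test_zero_amplitude_is_fair_coin(self):
        p = success_probability(SignalParams(0.0, 3.0, 1.2, 0.1, 10), t=0.5)
        assert p == pytest.approx(0.5)

    def test_matches_oracle_at_study_parameters(self):
        # amplitude = frequency = 10 rad/s, dt = 0.5 s, first measurement
        params = SignalParams(10.0, 10.0, 0.0, 0.5, 1000)
        expected = eq2_oracle(10.0, 10.0, 0.0, 0.5, 0.5)
        assert success_probability(params, 0.5) == pytest.approx(
            expected, abs=1e-14
        )

    def test_full_period_increment_cancels(self):
        # omega*dt = 2*pi: the bracket vanishes at any multiple of dt
        omega = 4.0
        dt = TWO_PI / omega
        params = SignalParams(5.0, omega, 0.0, dt, 10)
        p = success_probability(params, np.array([dt, 2 * dt, 5 * dt]))
        assert np.allclose(p, 0.5, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        g=st.floats(0, 100),
        omega=st.floats(0.01, 1e5),
        phi=st.floats(0, TWO_PI),
        dt=st.floats(1e-6, 10),
        j=st.integers(1, 50),
    )
    def test_matches_oracle_on_random_draws(self, g, omega, phi, dt, j):
        params = SignalParams(g, omega, phi, dt, 50)
        t = j * dt
        assert success_probability(params, t) == pytest.approx(
            eq2_oracle(g, omega, phi, dt, t), abs=1e-9, rel=1e-9
        )

    def test_rejects_time_before_first_interval(self):
        with pytest.raises(ValueError):
            success_probability(SignalParams(1.0, 1.0, 0.0, 1.0, 5), t=0.5)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            SignalParams(1.0, 0.0, 0.0, 0.5, 10)  # omega
        with pytest.raises(ValueError):
            SignalParams(1.0, 1.0, 0.0, -0.5, 10)  # dt
        with pytest.raises(ValueError):
            SignalParams(-1.0, 1.0, 0.0, 0.5, 10)  # g


class TestDetectionProbability:
    def test_perfect_detection_is_identity(self):
        det = DetectionSpec(1.0, 0.0)
        p = np.linspace(0, 1, 11)
        assert np.allclose(detection_probability(p, det), p)

    def test_equal_efficiencies_erase_signal(self):
        det = DetectionSpec(0.3, 0.3)
        assert detection_probability(0.9, det) == pytest.approx(0.3)
        assert detection_probability(0.1, det) == pytest.approx(0.3)

    def test_experimental_efficiencies(self):
        # eta_true 7.4%, eta_false = 0.7 * eta_true
        det = DetectionSpec(0.074, 0.0518)
        assert detection_probability(0.5, det) == pytest.approx(0.0629)

    def test_output_bounded_by_efficiencies(self):
        det = DetectionSpec(0.6, 0.2)
        q = detection_probability(np.linspace(0, 1, 101), det)
        assert q.min() >= det.eta_false - 1e-15
        assert q.max() <= det.eta_true + 1e-15

    def test_rejects_invalid_efficiency_order(self):
        with pytest.raises(ValueError):
            DetectionSpec(0.2, 0.6)
        with pytest.raises(ValueError):
            DetectionSpec(1.2, 0.1)


class TestOUPath:
    def test_noiseless_limit_decays_exponentially(self):
        ou = OUParams(mu=0.0, theta=2.0, sigma=0.0)
        dt = 0.01
        path = ou_path(ou, 200, dt, np.random.default_rng(0), x0=1.0)
        t = dt * np.arange(1, 201)
        assert np.allclose(path, np.exp(-2.0 * t), atol=1e-12)

    def test_euler_scheme_matches_decay_to_first_order(self):
        ou = OUParams(mu=0.0, theta=2.0, sigma=0.0)
        dt = 1e-4
        path = ou_path(ou, 100, dt, np.random.default_rng(0), x0=1.0,
                       scheme="euler")
        t = dt * np.arange(1, 101)
        assert np.allclose(path, np.exp(-2.0 * t), atol=1e-5)

    def test_stationary_moments(self):
        # long path: sample mean ~ mu, sample variance ~ sigma^2/(2 theta)
        ou = OUParams(mu=0.0, theta=1.0, sigma=0.5)
        path = ou_path(ou, 200_000, 0.5, np.random.default_rng(42))
        target_var = ou.sigma**2 / (2 * ou.theta)
        assert abs(path.mean()) < 0.01
        assert path.var() == pytest.approx(target_var, rel=0.05)

    def test_resolution_study_parameters(self):
        t2 = 256.0
        ou = OUParams.for_coherence_time(t2)
        assert ou.theta == pytest.approx(1.0 / t2)
        assert ou.sigma == pytest.approx(
            (math.pi / 10) * math.sqrt(4 / (math.pi * t2))
        )
        # stationary variance pi/50, independent of T2
        assert ou.stationary_std**2 == pytest.approx(math.pi / 50)

    def test_rejects_bad_theta(self):
        with pytest.raises(ValueError):
            OUParams(theta=0.0)


class TestResolutionProbability:
    def _model(self, sep=0.5):
        return ResolutionModel(delta_c=10.0, delta_sep=sep,
                               ou=OUParams.for_coherence_time(256.0),
                               dt=1.0, t_total=8.0)

    def test_zero_amplitudes_give_half(self):
        m = self._model()
        assert resolution_probability(m, [0, 0], [0, 0], 3.0) == pytest.approx(0.5)

    def test_single_component_reduces_to_signal_model(self):
        # the resolution bracket carries A_i/delta_i (the half is absorbed
        # into the quadrature amplitude), so A = g/2 recovers the
        # single-frequency model at phase zero
        m = ResolutionModel(delta_c=10.0, delta_sep=0.0,
                            ou=OUParams.for_coherence_time(256.0),
                            dt=1.0, t_total=8.0, n_components=1)
        params = SignalParams(6.0, 10.0, 0.0, 1.0, 8)
        for t in (1.0, 3.0, 7.0):
            assert resolution_probability(m, [3.0], [0.0], t) == pytest.approx(
                float(success_probability(params, t))
            )

    def test_matches_brute_force_oracle(self):
        m = self._model(sep=0.8)
        rng = np.random.default_rng(1)
        a = rng.normal(size=2)
        b = rng.normal(size=2)
        t = 5.0
        deltas = [m.delta_c - 0.4, m.delta_c + 0.4]
        bracket = sum(
            (a[i] / deltas[i]) * (math.sin(deltas[i] * t)
                                  - math.sin(deltas[i] * (t - 1.0)))
            + (b[i] / deltas[i]) * (math.cos(deltas[i] * t)
                                    - math.cos(deltas[i] * (t - 1.0)))
            for i in range(2)
        )
        expected = math.sin(bracket + math.pi / 4) ** 2
        assert resolution_probability(m, a, b, t) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_wrong_state_count(self):
        with pytest.raises(ValueError):
            resolution_probability(self._model(), [1.0], [0.0], 3.0)


class TestSimulateTrace:
    def test_zero_amplitude_bit_mean_is_half(self):
        params = SignalParams(0.0, 10.0, 0.0, 0.5, 10_000)
        tr = simulate_trace(params, rng=np.random.default_rng(0))
        # binomial 3-sigma band around 0.5
        assert abs(tr.bits.mean() - 0.5) < 3 * 0.5 / math.sqrt(10_000)

    def test_seeded_reproducibility(self):
        params = SignalParams(10.0, 10.0, 1.0, 0.5, 1000)
        a = simulate_trace(params, rng=np.random.default_rng(7))
        b = simulate_trace(params, rng=np.random.default_rng(7))
        assert np.array_equal(a.bits, b.bits)

    def test_dataset_reproducibility_and_metadata(self):
        params = SignalParams(10.0, 10.0, 0.0, 0.5, 200)
        d1 = simulate_dataset(params, 5, seed=3)
        d2 = simulate_dataset(params, 5, seed=3)
        assert np.array_equal(d1.bit_matrix, d2.bit_matrix)
        assert d1.metadata["seed"] == 3

    def test_detection_mean_matches_calibration_constraint(self):
        # with a uniform random phase per trace, <x> = (eta_t + eta_f)/2
        det = DetectionSpec(0.074, 0.0518)
        params = SignalParams(angular(12_500), angular(250), 0.0, 1e-5, 2000)
        data = simulate_dataset(params, 50, det=det, seed=11)
        mean = data.bit_matrix.mean()
        expected = (det.eta_true + det.eta_false) / 2
        se = math.sqrt(expected * (1 - expected) / (50 * 2000))
        assert abs(mean - expected) < 4 * se

    def test_noise_variants_produce_valid_traces(self):
        params = SignalParams(10.0, 10.0, 0.0, 0.5, 300)
        for variant in ("phase_jump", "magnetic_jump",
                        "amplitude_per_interval", "mixed"):
            noise = NoiseSpec(variant, magnetic_sigma=2.0,
                              amplitude_mean=10.0, amplitude_sigma=10.0)
            tr = simulate_trace(params, noise,
                                rng=np.random.default_rng(5))
            assert len(tr) == 300
            assert set(np.unique(tr.bits)) <= {0, 1}


class TestSimulateResolutionTrace:
    def test_study_grid_gives_512_bits(self):
        # T2 = 256 s, T_tot = 2*T2, dt = 1 s
        m = ResolutionModel(delta_c=10.0, delta_sep=0.1,
                            ou=OUParams.for_coherence_time(256.0),
                            dt=1.0, t_total=512.0)
        tr = simulate_resolution_trace(m, np.random.default_rng(0))
        assert len(tr) == 512

    def test_bit_mean_near_half(self):
        # zero-mean OU amplitudes make the bracket symmetric around pi/4
        m = ResolutionModel(delta_c=10.0, delta_sep=0.05,
                            ou=OUParams.for_coherence_time(64.0),
                            dt=1.0, t_total=128.0)
        rng = np.random.default_rng(4)
        bits = np.concatenate(
            [simulate_resolution_trace(m, rng).bits for _ in range(60)]
        )
        assert abs(bits.mean() - 0.5) < 3 * 0.5 / math.sqrt(len(bits))


class TestSegmentRawStream:
    def test_exact_multiple(self):
        d = segment_raw_stream(np.zeros(100, dtype=int), 25)
        assert len(d) == 4

    def test_remainder_discarded(self):
        d = segment_raw_stream(np.ones(100, dtype=int), 30)
        assert len(d) == 3
        assert d.metadata["discarded_bits"] == 10

    def test_window_time_span(self):
        # 25000-bit windows at dt = 10 us span 0.25 s
        d = segment_raw_stream(np.zeros(25_000, dtype=int), 25_000, dt=1e-5)
        assert d.times[-1] == pytest.approx(0.25)

    def test_short_stream_raises(self):
        with pytest.raises(ValueError):
            segment_raw_stream([0, 1, 0], 10)
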