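"""Generative models for binary NV-center measurement traces.

A single interrogation cycle of duration ``dt`` maps the instantaneous signal
onto the probability of reading out a one.  For a single-frequency signal of
amplitude ``g``, frequency ``omega`` and phase ``phi`` the success probability
at measurement time ``t`` is

    P(t) = sin^2( (g / 2 omega) [sin(omega t + phi) - sin(omega (t - dt) + phi)]
                  + pi/4 ),

i.e. the phase accumulated by the probe over one free-evolution interval,
offset to the pi/4 working point.  Low photon-collection efficiency is
modelled by mixing with true/false detection efficiencies, and several noise
scenarios (phase jump, magnetic detuning jump, per-interval amplitude noise)
perturb P before bits are drawn as Bernoulli samples.

For the frequency-resolution problem the signal is a sum of one or two
spectral components whose in-phase/quadrature amplitudes A_i(t), B_i(t)
fluctuate as independent Ornstein-Uhlenbeck processes.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np

from .types import (
    TWO_PI,
    Dataset,
    DetectionSpec,
    NoiseSpec,
    NoiseVariant,
    OUParams,
    ResolutionModel,
    SignalParams,
    Trace,
)

__all__ = [
    "success_probability",
    "detection_probability",
    "ou_path",
    "resolution_probability",
    "simulate_trace",
    "simulate_dataset",
    "simulate_discrimination_pair",
    "simulate_resolution_trace",
    "simulate_resolution_dataset",
    "segment_raw_stream",
]


def phase_increment(
    g: float,
    omega: float,
    phi: Union[float, np.ndarray],
    dt: float,
    t: Union[float, np.ndarray],
) -> np.ndarray:
    """Phase accumulated over one interrogation interval ending at ``t``:
    (g / 2 omega) * [sin(omega t + phi) - sin(omega (t - dt) + phi)]."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.asarray(t, dtype=float)
    return (g / (2.0 * omega)) * (
        np.sin(omega * t + phi) - np.sin(omega * (t - dt) + phi)
    )


def success_probability(
    params: SignalParams, t: Union[float, np.ndarray]
) -> np.ndarray:
    """Ideal probability of measuring a one at time ``t``.

    ``t`` must be at least one interval (the probe evolves over
    ``[t - dt, t]``); it may be a scalar or an array of measurement times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < params.dt - 1e-12):
        raise ValueError("t must be >= dt (one full interrogation interval)")
    b = phase_increment(params.g, params.omega, params.phi, params.dt, t)
    return np.sin(b + math.pi / 4.0) ** 2


def detection_probability(
    p: Union[float, np.ndarray], det: DetectionSpec
) -> np.ndarray:
    """Observed success probability under imperfect detection:
    Q = eta_true * p + eta_false * (1 - p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    return det.eta_true * p + det.eta_false * (1.0 - p)


def ou_path(
    ou: OUParams,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    x0: Optional[float] = None,
    scheme: str = "exact",
) -> np.ndarray:
    """Sample a discretized Ornstein-Uhlenbeck path at ``n_steps`` times.

    The default scheme is the exact AR(1) transition
    ``x' = mu + (x - mu) e^(-theta dt) + sqrt(sigma^2 (1 - e^(-2 theta dt)) /
    (2 theta)) z`` whose marginals are exact at any step size; ``scheme=
    "euler"`` uses the literal first-order update instead.  The initial state
    is drawn from the stationary distribution unless ``x0`` is given.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if scheme not in ("exact", "euler"):
        raise ValueError(f"unknown scheme {scheme!r}")
    x = np.empty(n_steps + 1)
    if x0 is None:
        x[0] = ou.mu + ou.stationary_std * rng.standard_normal()
    else:
        x[0] = x0
    z = rng.standard_normal(n_steps)
    if scheme == "exact":
        a = math.exp(-ou.theta * dt)
        s = ou.sigma * math.sqrt((1.0 - a * a) / (2.0 * ou.theta))
        for j in range(n_steps):
            x[j + 1] = ou.mu + (x[j] - ou.mu) * a + s * z[j]
    else:
        s = ou.sigma * math.sqrt(dt)
        for j in range(n_steps):
            x[j + 1] = x[j] - ou.theta * (x[j] - ou.mu) * dt + s * z[j]
    return x[1:]


def _ou_paths_matrix(
    ou: OUParams,
    n_paths: int,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized exact-AR(1) OU sampler: (n_paths, n_steps) array."""
    a = math.exp(-ou.theta * dt)
    s = ou.sigma * math.sqrt((1.0 - a * a) / (2.0 * ou.theta))
    x = np.empty((n_paths, n_steps))
    cur = ou.mu + ou.stationary_std * rng.standard_normal(n_paths)
    z = rng.standard_normal((n_paths, n_steps))
    for j in range(n_steps):
        cur = ou.mu + (cur - ou.mu) * a + s * z[:, j]
        x[:, j] = cur
    return x


def resolution_probability(
    model: ResolutionModel,
    a_states: Sequence[float],
    b_states: Sequence[float],
    t: Union[float, np.ndarray],
) -> np.ndarray:
    """Success probability of the OU-modulated multi-component signal.

    ``a_states``/``b_states`` hold the A_i, B_i values (one per spectral
    component) in effect over the interval ending at ``t``.
    """
    deltas = model.deltas
    if len(a_states) != len(deltas) or len(b_states) != len(deltas):
        raise ValueError("need one (A, B) pair per spectral component")
    t = np.asarray(t, dtype=float)
    if np.any(t < model.dt - 1e-12):
        raise ValueError("t must be >= dt")
    bracket = np.zeros_like(t)
    for a_i, b_i, d_i in zip(a_states, b_states, deltas):
        bracket = bracket + (a_i / d_i) * (
            np.sin(d_i * t) - np.sin(d_i * (t - model.dt))
        ) + (b_i / d_i) * (np.cos(d_i * t) - np.cos(d_i * (t - model.dt)))
    return np.sin(bracket + math.pi / 4.0) ** 2


def _trace_success_probabilities(
    params: SignalParams,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-interval success probability for one experiment, noise applied."""
    t = params.times
    n = params.n_meas
    variant = noise.variant

    phi = np.full(n, params.phi)
    if variant in (NoiseVariant.PHASE_JUMP, NoiseVariant.MIXED):
        # second uniform phase from a uniform jump index over the intervals
        jump = rng.integers(1, n) if n > 1 else 1
        phi2 = rng.uniform(0.0, TWO_PI)
        phi[jump:] = phi2

    if variant in (NoiseVariant.AMPLITUDE_PER_INTERVAL, NoiseVariant.MIXED):
        g = rng.normal(noise.amplitude_mean, noise.amplitude_sigma, size=n)
    else:
        g = np.full(n, params.g)

    bracket = (g / (2.0 * params.omega)) * (
        np.sin(params.omega * t + phi)
        - np.sin(params.omega * (t - params.dt) + phi)
    )

    if variant in (NoiseVariant.MAGNETIC_JUMP, NoiseVariant.MIXED):
        # detuning delta-b adds a free-evolution phase db*dt per interval,
        # redrawn once at a uniform jump index
        db = np.full(n, rng.normal(0.0, noise.magnetic_sigma))
        jump = rng.integers(1, n) if n > 1 else 1
        db[jump:] = rng.normal(0.0, noise.magnetic_sigma)
        bracket = bracket + db * params.dt

    return np.sin(bracket + math.pi / 4.0) ** 2


def simulate_trace(
    params: SignalParams,
    noise: Optional[NoiseSpec] = None,
    det: Optional[DetectionSpec] = None,
    rng: Optional[np.random.Generator] = None,
    label: Optional[int] = None,
    times: Optional[np.ndarray] = None,
) -> Trace:
    """Simulate one experiment: a Bernoulli bit per interrogation interval.

    ``times`` may pass a precomputed ``params.times`` grid; datasets share
    one grid array across traces to keep memory linear in the bits only.
    """
    rng = np.random.default_rng() if rng is None else rng
    noise = NoiseSpec() if noise is None else noise
    p = _trace_success_probabilities(params, noise, rng)
    if det is not None:
        p = detection_probability(p, det)
    bits = (rng.random(params.n_meas) < p).astype(np.uint8)
    return Trace(bits, params.times if times is None else times, label)


def simulate_dataset(
    params: SignalParams,
    n_traces: int,
    noise: Optional[NoiseSpec] = None,
    det: Optional[DetectionSpec] = None,
    seed: Optional[int] = None,
    random_phase: bool = True,
    label: Optional[int] = None,
) -> Dataset:
    """Simulate ``n_traces`` independent experiments of one hypothesis.

    With ``random_phase`` (the default) each experiment draws its own phase
    uniformly on [0, 2*pi); otherwise ``params.phi`` is used throughout.
    Each trace consumes a deterministic child stream of ``seed``, so datasets
    are bit-for-bit reproducible.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    streams = [np.random.default_rng(s) for s in ss.spawn(n_traces)]
    times = params.times  # one shared grid for the whole dataset
    traces = []
    for rng in streams:
        p = params.with_phase(rng.uniform(0.0, TWO_PI)) if random_phase else params
        traces.append(simulate_trace(p, noise, det, rng, label, times=times))
    meta = {
        "g": params.g,
        "omega": params.omega,
        "dt": params.dt,
        "n_meas": params.n_meas,
        "random_phase": random_phase,
        "noise": None if noise is None else noise.variant.value,
        "detection": None if det is None else (det.eta_true, det.eta_false),
        "seed": seed,
    }
    return Dataset(traces, meta)


def simulate_discrimination_pair(
    params1: SignalParams,
    params2: SignalParams,
    n_per_class: int,
    noise: Optional[NoiseSpec] = None,
    det: Optional[DetectionSpec] = None,
    seed: Optional[int] = None,
    random_phase: bool = True,
) -> Dataset:
    """Balanced two-hypothesis dataset; labels 0 (params1) and 1 (params2)."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    d1 = simulate_dataset(params1, n_per_class, noise, det,
                          seed=s1, random_phase=random_phase, label=0)
    d2 = simulate_dataset(params2, n_per_class, noise, det,
                          seed=s2, random_phase=random_phase, label=1)
    meta = {"class0": d1.metadata, "class1": d2.metadata, "seed": seed}
    return Dataset(d1.traces + d2.traces, meta)


def simulate_resolution_trace(
    model: ResolutionModel,
    rng: Optional[np.random.Generator] = None,
    label: Optional[int] = None,
    times: Optional[np.ndarray] = None,
) -> Trace:
    """Simulate one experiment of the single-/double-frequency model.

    Each component's A_i and B_i follow independent OU processes sampled at
    the measurement times and held constant within each interval.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = model.n_meas
    t = model.times if times is None else times
    deltas = model.deltas
    bracket = np.zeros(n)
    for d_i in deltas:
        a_i = ou_path(model.ou, n, model.dt, rng)
        b_i = ou_path(model.ou, n, model.dt, rng)
        bracket += (a_i / d_i) * (np.sin(d_i * t) - np.sin(d_i * (t - model.dt)))
        bracket += (b_i / d_i) * (np.cos(d_i * t) - np.cos(d_i * (t - model.dt)))
    p = np.sin(bracket + math.pi / 4.0) ** 2
    bits = (rng.random(n) < p).astype(np.uint8)
    return Trace(bits, t, label)


def simulate_resolution_dataset(
    single: ResolutionModel,
    double: ResolutionModel,
    n_per_class: int,
    seed: Optional[int] = None,
) -> Dataset:
    """Balanced dataset; label 0 = single frequency, 1 = two frequencies."""
    ss = np.random.SeedSequence(seed)
    traces = []
    for model, label, child in zip((single, double), (0, 1), ss.spawn(2)):
        times = model.times
        for s in child.spawn(n_per_class):
            traces.append(
                simulate_resolution_trace(model, np.random.default_rng(s),
                                          label, times=times)
            )
    meta = {
        "delta_sep": (single.delta_sep, double.delta_sep),
        "delta_c": single.delta_c,
        "dt": single.dt,
        "t_total": single.t_total,
        "seed": seed,
    }
    return Dataset(traces, meta)


def segment_raw_stream(
    bits: Sequence[int],
    window: int,
    dt: float = 1.0,
    label: Optional[int] = None,
) -> Dataset:
    """Split a raw 0/1 detection stream into consecutive fixed-length windows.

    The trailing remainder shorter than one window is discarded.  Raises if
    the stream does not contain even one full window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.ndim != 1:
        raise ValueError("stream must be one-dimensional")
    n_windows = len(bits) // window
    if n_windows == 0:
        raise ValueError(
            f"stream of length {len(bits)} is shorter than one window ({window})"
        )
    times = dt * np.arange(1, window + 1)
    traces = [
        Trace(bits[i * window:(i + 1) * window], times, label)
        for i in range(n_windows)
    ]
    meta = {
        "window": window,
        "dt": dt,
        "n_windows": n_windows,
        "discarded_bits": int(len(bits) - n_windows * window),
    }
    return Dataset(traces, meta)
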