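"""Full-Bayesian likelihood-ratio classifiers.

Discrimination between two known frequencies treats the per-experiment random
phase as a nuisance: each hypothesis' Bernoulli log-likelihood

    L(phi | x, omega) = sum_j [ x_j log P(t_j) + (1 - x_j) log(1 - P(t_j)) ]

is maximized over a uniform phase grid (optionally refined), and the trace is
assigned to the hypothesis with the larger maximum; ties go to the
second-listed hypothesis.  For the frequency-resolution problem the nuisance
is the unobserved pair of OU amplitude paths per spectral component, and the
maximum is taken over a pre-drawn bank of OU realizations shared between the
single- and double-frequency hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .sim import _ou_paths_matrix, detection_probability, phase_increment
from .types import (
    TWO_PI,
    Dataset,
    DetectionSpec,
    OUParams,
    ResolutionModel,
    SignalParams,
    Trace,
)

__all__ = [
    "LikelihoodResult",
    "OUSampleBank",
    "log_likelihood",
    "max_likelihood_over_phase",
    "classify_frequency",
    "classify_frequency_batch",
    "ou_max_likelihood",
    "classify_resolution",
    "classify_resolution_batch",
]

#: probabilities are clipped to [EPS, 1-EPS] before taking logs so that
#: measure-zero events keep the log-likelihood finite
EPS = 1e-12


@dataclass(frozen=True)
class LikelihoodResult:
    """Maximal log-likelihood and the nuisance value achieving it."""

    log_likelihood: float
    argmax_nuisance: float  # phase in radians, or OU sample index


def _success_prob_grid(
    params: SignalParams,
    phis: np.ndarray,
    times: np.ndarray,
    det: Optional[DetectionSpec],
) -> np.ndarray:
    """P (or Q) evaluated on a phase grid: shape (len(phis), len(times))."""
    b = phase_increment(params.g, params.omega, phis[:, None], params.dt,
                        times[None, :])
    p = np.sin(b + math.pi / 4.0) ** 2
    if det is not None:
        p = detection_probability(p, det)
    return np.clip(p, EPS, 1.0 - EPS)


def log_likelihood(
    trace: Trace,
    params: SignalParams,
    det: Optional[DetectionSpec] = None,
) -> float:
    """Bernoulli log-likelihood of a trace under one fully specified signal."""
    if len(trace) != params.n_meas:
        raise ValueError(
            f"trace length {len(trace)} != params.n_meas {params.n_meas}"
        )
    p = _success_prob_grid(params, np.array([params.phi]), trace.times, det)[0]
    x = trace.bits.astype(float)
    return float(np.sum(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def max_likelihood_over_phase(
    trace: Trace,
    params: SignalParams,
    grid_size: int = 128,
    det: Optional[DetectionSpec] = None,
    refine: bool = True,
) -> LikelihoodResult:
    """Maximize the log-likelihood over the unknown uniform phase.

    Evaluates a uniform ``grid_size``-point grid on [0, 2*pi) (the phase of
    ``params`` is ignored) and, with ``refine``, polishes the best grid point
    with a bounded golden-section search in the bracketing grid cell.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    phis = np.arange(grid_size) * TWO_PI / grid_size
    p = _success_prob_grid(params, phis, trace.times, det)
    x = trace.bits.astype(float)
    ll = p_logls = np.log(p) @ x + np.log1p(-p) @ (1.0 - x)
    k = int(np.argmax(ll))
    best_phi, best_ll = float(phis[k]), float(ll[k])
    if refine and grid_size >= 2:
        step = TWO_PI / grid_size

        def neg(phi: float) -> float:
            return -log_likelihood(trace, params.with_phase(phi), det)

        res = minimize_scalar(neg, bounds=(best_phi - step, best_phi + step),
                              method="bounded",
                              options={"xatol": step * 1e-3})
        if -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_phi = float(res.x % TWO_PI)
    return LikelihoodResult(best_ll, best_phi)


def classify_frequency(
    trace: Trace,
    params1: SignalParams,
    params2: SignalParams,
    grid_size: int = 128,
    det: Optional[DetectionSpec] = None,
    refine: bool = True,
) -> Tuple[int, float, float]:
    """Likelihood-ratio decision between two signal hypotheses.

    Returns ``(label, L1, L2)`` where label 0 means hypothesis 1 (strictly
    larger likelihood) and 1 means hypothesis 2 (the tie-breaking branch).
    """
    if math.isclose(params1.omega, params2.omega) and math.isclose(
        params1.g, params2.g
    ):
        raise ValueError("hypotheses must differ")
    l1 = max_likelihood_over_phase(trace, params1, grid_size, det, refine)
    l2 = max_likelihood_over_phase(trace, params2, grid_size, det, refine)
    label = 0 if l1.log_likelihood > l2.log_likelihood else 1
    return label, l1.log_likelihood, l2.log_likelihood


def _grid_logl_matrix(
    bits: np.ndarray,
    params: SignalParams,
    phis: np.ndarray,
    times: np.ndarray,
    det: Optional[DetectionSpec],
) -> np.ndarray:
    """Log-likelihood of every trace at every grid phase: (n_traces, n_phis).

    The success probabilities depend only on (hypothesis, phase), not on the
    trace, so the whole dataset reduces to one matrix product.
    """
    p = _success_prob_grid(params, phis, times, det)
    logit = (np.log(p) - np.log1p(-p)).T  # (n_times, n_phis)
    const = np.log1p(-p).sum(axis=1)  # (n_phis,)
    return bits.astype(np.float32) @ logit.astype(np.float32) + const


def classify_frequency_batch(
    dataset: Dataset,
    params1: SignalParams,
    params2: SignalParams,
    grid_size: int = 128,
    det: Optional[DetectionSpec] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized likelihood-ratio classification of a whole dataset.

    Exploits the shared time grid: success probabilities are computed once
    per (hypothesis, grid phase) and applied to all traces by matrix
    multiplication (no per-trace refinement).  Returns ``(labels, L1, L2)``.
    """
    bits = dataset.bit_matrix
    times = dataset.times
    phis = np.arange(grid_size) * TWO_PI / grid_size
    l1 = _grid_logl_matrix(bits, params1, phis, times, det).max(axis=1)
    l2 = _grid_logl_matrix(bits, params2, phis, times, det).max(axis=1)
    labels = np.where(l1 > l2, 0, 1)
    return labels, l1, l2


class OUSampleBank:
    """Pre-drawn OU realizations serving as the nuisance grid for resolution.

    Holds ``k`` independent sets of (A_i, B_i) paths on the measurement grid
    of ``model``.  The same bank (same seed, hence the same Monte-Carlo draw)
    should be evaluated under both the single- and the double-frequency
    hypothesis so the two likelihoods differ only through the model.
    """

    def __init__(self, model: ResolutionModel, k: int = 1000,
                 seed: Optional[int] = None):
        if k < 1:
            raise ValueError("bank size k must be >= 1")
        self.model = model
        self.k = k
        self.seed = seed
        rng = np.random.default_rng(seed)
        n = model.n_meas
        nc = model.n_components
        # (k, n_components, 2, n_meas): A and B path per component per sample
        self.paths = _ou_paths_matrix(
            model.ou, k * nc * 2, n, model.dt, rng
        ).reshape(k, nc, 2, n)

    def probability_matrix(self, model: Optional[ResolutionModel] = None
                           ) -> np.ndarray:
        """Success probability of every bank sample at every time: (k, n).

        ``model`` may override the bank's own (e.g. the same draws evaluated
        at a different frequency separation); it must share grid and
        component count.
        """
        model = self.model if model is None else model
        if model.n_meas != self.model.n_meas or (
            model.n_components != self.model.n_components
        ):
            raise ValueError("model grid/components do not match the bank")
        t = model.times
        bracket = np.zeros((self.k, model.n_meas))
        for i, d_i in enumerate(model.deltas):
            sa = np.sin(d_i * t) - np.sin(d_i * (t - model.dt))
            ca = np.cos(d_i * t) - np.cos(d_i * (t - model.dt))
            bracket += (self.paths[:, i, 0, :] / d_i) * sa
            bracket += (self.paths[:, i, 1, :] / d_i) * ca
        return np.sin(bracket + math.pi / 4.0) ** 2


def _bank_logl(bits: np.ndarray, bank: OUSampleBank,
               model: Optional[ResolutionModel] = None) -> np.ndarray:
    """Log-likelihood of each trace under each bank sample: (n_traces, k)."""
    p = np.clip(bank.probability_matrix(model), EPS, 1.0 - EPS)
    logit = (np.log(p) - np.log1p(-p)).T
    const = np.log1p(-p).sum(axis=1)
    return bits.astype(np.float32) @ logit.astype(np.float32) + const


def ou_max_likelihood(
    trace: Trace,
    model: ResolutionModel,
    bank: OUSampleBank,
) -> LikelihoodResult:
    """Maximal log-likelihood of a trace over the bank's OU realizations."""
    if len(trace) != bank.model.n_meas:
        raise ValueError("trace grid does not match the bank")
    ll = _bank_logl(trace.bits[None, :], bank, model)[0]
    k = int(np.argmax(ll))
    return LikelihoodResult(float(ll[k]), k)


def classify_resolution(
    trace: Trace,
    single: ResolutionModel,
    double: ResolutionModel,
    bank: OUSampleBank,
) -> Tuple[int, float, float]:
    """Single- vs double-frequency decision for one trace.

    Returns ``(label, L_single, L_double)``; label 0 = single frequency
    (strictly larger likelihood), 1 = two frequencies (tie branch).
    """
    l1 = ou_max_likelihood(trace, single, bank).log_likelihood
    l2 = ou_max_likelihood(trace, double, bank).log_likelihood
    return (0 if l1 > l2 else 1), l1, l2


def classify_resolution_batch(
    dataset: Dataset,
    single: ResolutionModel,
    double: ResolutionModel,
    bank: OUSampleBank,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single- vs double-frequency classification of a dataset."""
    bits = dataset.bit_matrix
    l1 = _bank_logl(bits, bank, single).max(axis=1)
    l2 = _bank_logl(bits, bank, double).max(axis=1)
    return np.where(l1 > l2, 0, 1), l1, l2
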