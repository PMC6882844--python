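"""Domain types for NV-center measurement-trace simulation and classification.

All frequencies and amplitudes are angular (rad/s) throughout the package.
Values quoted in ordinary Hz must be converted on ingestion (``angular``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi


def angular(hz: float) -> float:
    """Convert an ordinary frequency in Hz to angular units (rad/s)."""
    return TWO_PI * hz


@dataclass(frozen=True)
class SignalParams:
    """One single-frequency signal hypothesis.

    Parameters
    ----------
    g : float
        Signal amplitude (angular, rad/s).
    omega : float
        Signal frequency (angular, rad/s).
    phi : float
        Signal phase in radians; normalized to [0, 2*pi).
    dt : float
        Interrogation interval in seconds (free-evolution time per
        initialize-evolve-measure cycle).
    n_meas : int
        Number of repeated cycles, i.e. the trace length in bits.
    """

    g: float
    omega: float
    phi: float = 0.0
    dt: float = 1.0
    n_meas: int = 1000

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"amplitude g must be >= 0, got {self.g}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_meas < 1:
            raise ValueError(f"n_meas must be >= 1, got {self.n_meas}")
        object.__setattr__(self, "phi", self.phi % TWO_PI)

    def with_phase(self, phi: float) -> "SignalParams":
        return SignalParams(self.g, self.omega, phi, self.dt, self.n_meas)

    @property
    def times(self) -> np.ndarray:
        """Measurement times t_j = j*dt, j = 1..n_meas."""
        return self.dt * np.arange(1, self.n_meas + 1)


class NoiseVariant(str, Enum):
    NONE = "none"
    PHASE_JUMP = "phase_jump"
    MAGNETIC_JUMP = "magnetic_jump"
    AMPLITUDE_PER_INTERVAL = "amplitude_per_interval"
    MIXED = "mixed"


@dataclass(frozen=True)
class NoiseSpec:
    """Which noise scenario perturbs the ideal success probability.

    ``phase_jump``: the uniform random phase is redrawn once, at an interval
    index uniform over the trace.  ``magnetic_jump``: a Normal(0,
    magnetic_sigma) detuning adds an extra phase ``db*dt`` per interval and is
    redrawn once at a uniform interval index.  ``amplitude_per_interval``: the
    amplitude is redrawn ``Normal(amplitude_mean, amplitude_sigma)``
    independently every interval (negative draws are kept as-is).  ``mixed``
    applies all three at once.
    """

    variant: NoiseVariant = NoiseVariant.NONE
    magnetic_sigma: float = 0.0
    amplitude_mean: float = 0.0
    amplitude_sigma: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", NoiseVariant(self.variant))
        if self.magnetic_sigma < 0 or self.amplitude_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class DetectionSpec:
    """True/false photon-detection efficiencies of the readout.

    The observed success probability is the mixture
    ``Q = eta_true * P + eta_false * (1 - P)``.
    """

    eta_true: float
    eta_false: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_false <= self.eta_true <= 1.0):
            raise ValueError(
                "require 0 <= eta_false <= eta_true <= 1, got "
                f"eta_true={self.eta_true}, eta_false={self.eta_false}"
            )


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck process parameters.

    ``theta`` is the mean-reversion speed (1/s), ``sigma`` the volatility;
    the stationary distribution is Normal(mu, sigma^2 / (2*theta)).
    """

    mu: float = 0.0
    theta: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def stationary_std(self) -> float:
        return self.sigma / math.sqrt(2.0 * self.theta)

    @classmethod
    def for_coherence_time(cls, t2: float) -> "OUParams":
        """OU parameters used in the frequency-resolution study for a signal
        with coherence time ``t2``: mu=0, theta=1/T2,
        sigma=(pi/10)*sqrt(4/(pi*T2))."""
        if t2 <= 0:
            raise ValueError("t2 must be > 0")
        sigma = (math.pi / 10.0) * math.sqrt(4.0 / (math.pi * t2))
        return cls(mu=0.0, theta=1.0 / t2, sigma=sigma)


@dataclass(frozen=True)
class ResolutionModel:
    """Single- vs double-frequency signal with OU-fluctuating quadratures.

    Component frequencies are ``delta_c +/- delta_sep / 2``; ``delta_sep = 0``
    collapses both onto the central frequency (the single-frequency
    hypothesis).  Each component carries two independent OU processes, the
    in-phase and quadrature amplitudes A_i(t), B_i(t).
    """

    delta_c: float
    delta_sep: float
    ou: OUParams
    dt: float = 1.0
    t_total: float = 512.0
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.delta_c <= 0:
            raise ValueError(f"delta_c must be > 0, got {self.delta_c}")
        if self.delta_sep < 0:
            raise ValueError(f"delta_sep must be >= 0, got {self.delta_sep}")
        if self.dt <= 0 or self.t_total < self.dt:
            raise ValueError("require dt > 0 and t_total >= dt")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if any(abs(d) < 1e-15 for d in self.deltas):
            raise ValueError("component frequency delta_i = 0 is singular")

    @property
    def deltas(self) -> tuple[float, ...]:
        if self.n_components == 1:
            return (self.delta_c,)
        return (self.delta_c - self.delta_sep / 2.0,
                self.delta_c + self.delta_sep / 2.0)

    @property
    def n_meas(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(1, self.n_meas + 1)


@dataclass
class Trace:
    """A binary measurement string with its time grid."""

    bits: np.ndarray
    times: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.times = np.asarray(self.times, dtype=float)
        if self.bits.ndim != 1 or self.bits.shape != self.times.shape:
            raise ValueError("bits and times must be 1-D and equal length")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be 0/1")
        if len(self.times) > 1:
            d = np.diff(self.times)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9):
                raise ValueError("times must increase with constant spacing")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def dt(self) -> float:
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return float(self.times[0])


@dataclass
class Dataset:
    """A labelled collection of traces sharing one time grid."""

    traces: list[Trace]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.traces:
            n = len(self.traces[0])
            dt = self.traces[0].dt
            for tr in self.traces:
                if len(tr) != n or not math.isclose(tr.dt, dt, rel_tol=1e-9):
                    raise ValueError("all traces must share length and dt")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def times(self) -> np.ndarray:
        return self.traces[0].times

    @property
    def bit_matrix(self) -> np.ndarray:
        """(n_traces, n_meas) uint8 matrix of all bits."""
        return np.stack([tr.bits for tr in self.traces])

    @property
    def labels(self) -> np.ndarray:
        if any(tr.label is None for tr in self.traces):
            raise ValueError("dataset contains unlabelled traces")
        return np.array([tr.label for tr in self.traces], dtype=int)

    @classmethod
    def from_arrays(
        cls,
        bits: np.ndarray,
        times: np.ndarray,
        labels: Optional[Sequence[int]] = None,
        metadata: Optional[dict] = None,
    ) -> "Dataset":
        bits = np.asarray(bits)
        if labels is None:
            labels = [None] * len(bits)
        traces = [Trace(row, times, lab) for row, lab in zip(bits, labels)]
        return cls(traces, metadata or {})
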