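"""Correlation-template classifier.

Each trace is summarized by its autocorrelation vector C_k = <s_i s_{i+k}>_i
with bits mapped 0 -> -1, 1 -> +1 and the average taken over the n - k valid
positions.  Class templates are the element-wise means of the training
traces' vectors; a test trace is assigned to the class whose template is
nearest in L2, ties going to the second class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .types import Dataset, Trace

__all__ = [
    "CorrelationVector",
    "ClassTemplates",
    "correlation_vector",
    "fit_templates",
    "classify_corr",
    "classify_corr_batch",
]


@dataclass(frozen=True)
class CorrelationVector:
    values: np.ndarray  # C_k for k = 1..k_max
    k_max: int

    def __post_init__(self) -> None:
        if len(self.values) != self.k_max:
            raise ValueError("values must have length k_max")


@dataclass(frozen=True)
class ClassTemplates:
    """Class-averaged correlation vectors for the two hypotheses."""

    template0: np.ndarray
    template1: np.ndarray
    k_max: int
    lags: np.ndarray  # the lag subset actually used
    n0: int = 0
    n1: int = 0


def _corr_values(bits: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """C_k at the requested lags for a matrix of traces (n_traces, n)."""
    s = 2.0 * bits.astype(np.float64) - 1.0
    n = s.shape[1]
    out = np.empty((s.shape[0], len(lags)))
    for j, k in enumerate(lags):
        out[:, j] = np.mean(s[:, : n - k] * s[:, k:], axis=1)
    return out


def _lag_subset(k_max: int, stride: int) -> np.ndarray:
    return np.arange(1, k_max + 1, stride)


def correlation_vector(trace: Trace, k_max: Optional[int] = None
                       ) -> CorrelationVector:
    """Autocorrelation vector of one trace at lags 1..k_max (default n-1)."""
    n = len(trace)
    if k_max is None:
        k_max = n - 1
    if not (1 <= k_max < n):
        raise ValueError(f"require 1 <= k_max < trace length, got {k_max}")
    lags = _lag_subset(k_max, 1)
    return CorrelationVector(_corr_values(trace.bits[None, :], lags)[0], k_max)


def fit_templates(
    train: Dataset,
    k_max: Optional[int] = None,
    lag_stride: int = 1,
) -> ClassTemplates:
    """Average the per-trace correlation vectors within each class.

    ``lag_stride`` > 1 subsamples the lag axis (every stride-th lag), the
    practical fallback for very long windows where all n - 1 lags are
    unaffordable.
    """
    labels = train.labels
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("training set must contain both classes 0 and 1")
    n = len(train.times)
    if k_max is None:
        k_max = n - 1
    if not (1 <= k_max < n):
        raise ValueError(f"require 1 <= k_max < trace length, got {k_max}")
    if lag_stride < 1:
        raise ValueError("lag_stride must be >= 1")
    lags = _lag_subset(k_max, lag_stride)
    vecs = _corr_values(train.bit_matrix, lags)
    m0 = labels == 0
    return ClassTemplates(
        template0=vecs[m0].mean(axis=0),
        template1=vecs[~m0].mean(axis=0),
        k_max=k_max,
        lags=lags,
        n0=int(m0.sum()),
        n1=int((~m0).sum()),
    )


def classify_corr(trace: Trace, templates: ClassTemplates
                  ) -> Tuple[int, float, float]:
    """Nearest-template decision for one trace.

    Returns ``(label, D0, D1)``; label 0 iff D0 < D1, ties -> 1.
    """
    v = _corr_values(trace.bits[None, :], templates.lags)[0]
    d0 = float(np.linalg.norm(v - templates.template0))
    d1 = float(np.linalg.norm(v - templates.template1))
    return (0 if d0 < d1 else 1), d0, d1


def classify_corr_batch(dataset: Dataset, templates: ClassTemplates
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-template decisions for a whole dataset: (labels, D0, D1)."""
    vecs = _corr_values(dataset.bit_matrix, templates.lags)
    d0 = np.linalg.norm(vecs - templates.template0, axis=1)
    d1 = np.linalg.norm(vecs - templates.template1, axis=1)
    return np.where(d0 < d1, 0, 1), d0, d1
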