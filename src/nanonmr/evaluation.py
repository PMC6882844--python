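"""Scoring and experiment orchestration.

Performance of a two-hypothesis classifier is the balanced error probability

    P_error = 1/2 [ P(pred = 1 | class 0) + P(pred = 0 | class 1) ],

chance level 0.5 regardless of class frequencies.  ROC curves and AUC are
computed from a real-valued score per trace (a probability for the network,
the likelihood difference L0 - L1 for the likelihood-ratio method, and the
distance difference D1 - D0 for the correlation method — higher score means
"class 0" is ranked, er, lower; see ``method_scores``).  The sweep drivers
re-run the frequency-discrimination and frequency-resolution experiments
over a list of separations with every requested method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from . import bayes, corr, dl
from .sim import simulate_discrimination_pair, simulate_resolution_dataset
from .types import (
    Dataset,
    DetectionSpec,
    NoiseSpec,
    NoiseVariant,
    OUParams,
    ResolutionModel,
    SignalParams,
)

__all__ = [
    "ErrorReport",
    "ROCResult",
    "error_probability",
    "roc_auc",
    "linear_baseline_error",
    "DiscriminationConfig",
    "ResolutionConfig",
    "run_discrimination_sweep",
    "run_resolution_sweep",
]


@dataclass(frozen=True)
class ErrorReport:
    """Balanced error probability with its per-class components."""

    p_error: float
    error_given_0: float
    error_given_1: float
    n0: int
    n1: int


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def error_probability(true_labels: Sequence[int],
                      pred_labels: Sequence[int]) -> ErrorReport:
    """Class-balanced misclassification rate of binary predictions."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    m0 = y == 0
    m1 = y == 1
    if not (m0.any() and m1.any()):
        raise ValueError("both classes must be present in true_labels")
    e0 = float(np.mean(p[m0] != 0))
    e1 = float(np.mean(p[m1] != 1))
    return ErrorReport(0.5 * (e0 + e1), e0, e1, int(m0.sum()), int(m1.sum()))


def roc_auc(scores: Sequence[float], true_labels: Sequence[int]) -> ROCResult:
    """Threshold-sweep ROC of scores for the positive class (label 1)."""
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both classes must be present in true_labels")
    fpr, tpr, thr = roc_curve(y, s)
    return ROCResult(fpr, tpr, thr, float(roc_auc_score(y, s)))


def linear_baseline_error(train: Dataset, test: Dataset,
                          seed: int = 0) -> ErrorReport:
    """Balanced error of a purely linear classifier (logistic regression on
    raw bits, no interactions).  A control: with a per-trace random phase
    the two classes share identical per-bit means, so no linear read-out of
    the bits can beat chance."""
    clf = LogisticRegression(max_iter=200, random_state=seed)
    clf.fit(train.bit_matrix.astype(np.float32), train.labels)
    pred = clf.predict(test.bit_matrix.astype(np.float32))
    return error_probability(test.labels, pred)


# ---------------------------------------------------------------------------
# sweep drivers

_SCENARIOS = {
    "ideal": dict(variant=NoiseVariant.NONE),
    "phase_jump": dict(variant=NoiseVariant.PHASE_JUMP),
    "magnetic": dict(variant=NoiseVariant.MAGNETIC_JUMP),
    "amplitude": dict(variant=NoiseVariant.AMPLITUDE_PER_INTERVAL),
    "mixed": dict(variant=NoiseVariant.MIXED),
    "low_efficiency": dict(variant=NoiseVariant.NONE),
}


@dataclass
class DiscriminationConfig:
    """One frequency-discrimination sweep.

    Defaults are the ideal-scenario study conditions: amplitude and base
    frequency g = omega1 = 10 rad/s, dt = 0.5 s, 1000 measurements
    (T_tot = 500 s), per-trace uniform random phase.
    """

    scenario: str = "ideal"
    # default grid spans the transition from chance to near-certain
    # discrimination for the ideal study conditions below
    separations: Sequence[float] = (1e-4, 2e-4, 5e-4, 1e-3, 2e-3)  # rad/s
    methods: Sequence[str] = ("fb", "corr", "dl")
    g1: float = 10.0
    g2: Optional[float] = None  # default: equal to g1
    omega1: float = 10.0
    dt: float = 0.5
    n_meas: int = 1000
    eta_true: Optional[float] = None
    eta_false: Optional[float] = None
    n_train: int = 2000
    n_test: int = 1000
    phase_grid: int = 64
    k_max: Optional[int] = None
    lag_stride: int = 1
    dl_config: Optional["dl.TrainConfig"] = None
    seeds: Sequence[int] = (0,)

    def noise(self) -> NoiseSpec:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        variant = _SCENARIOS[self.scenario]["variant"]
        return NoiseSpec(
            variant=variant,
            magnetic_sigma=self.g1 / 5.0,
            amplitude_mean=self.g1,
            amplitude_sigma=self.g1,
        )

    def detection(self) -> Optional[DetectionSpec]:
        if self.eta_true is None:
            return None
        eta_false = (0.7 * self.eta_true if self.eta_false is None
                     else self.eta_false)
        return DetectionSpec(self.eta_true, eta_false)


def _method_scores_discrimination(
    method: str,
    cfg: DiscriminationConfig,
    train: Dataset,
    test: Dataset,
    params1: SignalParams,
    params2: SignalParams,
    det: Optional[DetectionSpec],
    seed: int,
):
    """Fit (if needed) and score one method; returns (pred, score) where a
    higher score ranks the trace toward class 1."""
    if method == "fb":
        pred, l1, l2 = bayes.classify_frequency_batch(
            test, params1, params2, cfg.phase_grid, det
        )
        return pred, l2 - l1
    if method == "corr":
        templates = corr.fit_templates(train, cfg.k_max, cfg.lag_stride)
        pred, d0, d1 = corr.classify_corr_batch(test, templates)
        return pred, d0 - d1
    if method == "dl":
        tc = cfg.dl_config or dl.TrainConfig(seed=seed)
        net = dl.build_net(dl.NetSpec(input_dim=cfg.n_meas), seed=seed)
        net = dl.train_net(net, train, tc)
        scores, pred = dl.predict_batch(net, test)
        return pred, scores
    if method == "linear":
        rep_pred = LogisticRegression(max_iter=200, random_state=seed)
        rep_pred.fit(train.bit_matrix.astype(np.float32), train.labels)
        X = test.bit_matrix.astype(np.float32)
        return rep_pred.predict(X), rep_pred.predict_proba(X)[:, 1]
    raise ValueError(f"unknown method {method!r}")


def _mix_seed(seed: int, sep: float, tag: int) -> int:
    """Deterministic per-(seed, separation, problem) dataset seed."""
    ss = np.random.SeedSequence([int(seed), int(round(sep * 1e9)), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def _maybe_write_roc(roc_dir, method, sep, seed, score, labels) -> None:
    if roc_dir is None:
        return
    from pathlib import Path

    out = Path(roc_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = roc_auc(score, labels)
    pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
        out / f"roc_{method}_{sep:g}_s{seed}.csv", index=False
    )


def run_discrimination_sweep(cfg: DiscriminationConfig,
                             roc_dir=None) -> pd.DataFrame:
    """Simulate, classify and score over the configured separations.

    Returns one row per (separation, method, seed) with columns
    ``separation, method, seed, p_error, auc, n_train, n_test``; with
    ``roc_dir`` the per-method ROC points are written as CSV there.
    """
    rows = []
    noise = cfg.noise()
    det = cfg.detection()
    g2 = cfg.g1 if cfg.g2 is None else cfg.g2
    for sep in cfg.separations:
        for seed in cfg.seeds:
            params1 = SignalParams(cfg.g1, cfg.omega1, 0.0, cfg.dt, cfg.n_meas)
            params2 = SignalParams(g2, cfg.omega1 + sep, 0.0, cfg.dt,
                                   cfg.n_meas)
            mix = _mix_seed(seed, sep, tag=1)
            data = simulate_discrimination_pair(
                params1, params2, (cfg.n_train + cfg.n_test) // 2,
                noise, det, seed=mix,
            )
            # class-stratified split: first n_train/2 of each class train
            labels = data.labels
            tr_idx, te_idx = [], []
            for lab in (0, 1):
                idx = np.flatnonzero(labels == lab)
                tr_idx.extend(idx[: cfg.n_train // 2])
                te_idx.extend(idx[cfg.n_train // 2:])
            train = Dataset([data.traces[i] for i in tr_idx], data.metadata)
            test = Dataset([data.traces[i] for i in te_idx], data.metadata)
            for method in cfg.methods:
                pred, score = _method_scores_discrimination(
                    method, cfg, train, test, params1, params2, det, seed
                )
                rep = error_probability(test.labels, pred)
                auc = roc_auc(score, test.labels).auc
                _maybe_write_roc(roc_dir, method, sep, seed, score,
                                 test.labels)
                rows.append(dict(separation=sep, method=method, seed=seed,
                                 p_error=rep.p_error, auc=auc,
                                 n_train=len(train), n_test=len(test)))
    return pd.DataFrame(rows)


@dataclass
class ResolutionConfig:
    """One frequency-resolution sweep.

    Defaults are the resolution study conditions: coherence time T2 = 256 s,
    total time 2*T2 with dt = 1 s (512 bits), OU quadrature amplitudes with
    mu = 0, theta = 1/T2, sigma = (pi/10) sqrt(4 / (pi T2)); the central
    frequency, never critical, defaults to 10 rad/s.
    """

    separations: Sequence[float] = (0.02, 0.05, 0.1)  # rad/s
    methods: Sequence[str] = ("fb", "corr", "dl")
    t2: float = 256.0
    dt: float = 1.0
    t_total: Optional[float] = None  # default 2*T2
    delta_c: float = 10.0
    bank_size: int = 1000
    n_train: int = 2000
    n_test: int = 1000
    k_max: Optional[int] = None
    lag_stride: int = 1
    dl_config: Optional["dl.TrainConfig"] = None
    seeds: Sequence[int] = (0,)

    def model(self, delta_sep: float) -> ResolutionModel:
        return ResolutionModel(
            delta_c=self.delta_c,
            delta_sep=delta_sep,
            ou=OUParams.for_coherence_time(self.t2),
            dt=self.dt,
            t_total=2.0 * self.t2 if self.t_total is None else self.t_total,
        )


def run_resolution_sweep(cfg: ResolutionConfig,
                         roc_dir=None) -> pd.DataFrame:
    """Single- vs double-frequency discrimination over the configured
    separations; same output schema as ``run_discrimination_sweep``."""
    rows = []
    for sep in cfg.separations:
        single = cfg.model(0.0)
        double = cfg.model(sep)
        for seed in cfg.seeds:
            mix = _mix_seed(seed, sep, tag=2)
            data = simulate_resolution_dataset(
                single, double, (cfg.n_train + cfg.n_test) // 2, seed=mix
            )
            labels = data.labels
            tr_idx, te_idx = [], []
            for lab in (0, 1):
                idx = np.flatnonzero(labels == lab)
                tr_idx.extend(idx[: cfg.n_train // 2])
                te_idx.extend(idx[cfg.n_train // 2:])
            train = Dataset([data.traces[i] for i in tr_idx], data.metadata)
            test = Dataset([data.traces[i] for i in te_idx], data.metadata)
            for method in cfg.methods:
                if method == "fb":
                    bank = bayes.OUSampleBank(single, cfg.bank_size,
                                              seed=mix + 1)
                    pred, l1, l2 = bayes.classify_resolution_batch(
                        test, single, double, bank
                    )
                    score = l2 - l1
                elif method == "corr":
                    templates = corr.fit_templates(train, cfg.k_max,
                                                   cfg.lag_stride)
                    pred, d0, d1 = corr.classify_corr_batch(test, templates)
                    score = d0 - d1
                elif method == "dl":
                    tc = cfg.dl_config or dl.TrainConfig(seed=seed)
                    net = dl.build_net(dl.NetSpec(input_dim=single.n_meas),
                                       seed=seed)
                    net = dl.train_net(net, train, tc)
                    score, pred = dl.predict_batch(net, test)
                else:
                    raise ValueError(f"unknown method {method!r}")
                rep = error_probability(test.labels, pred)
                auc = roc_auc(score, test.labels).auc
                _maybe_write_roc(roc_dir, method, sep, seed, score,
                                 test.labels)
                rows.append(dict(separation=sep, method=method, seed=seed,
                                 p_error=rep.p_error, auc=auc,
                                 n_train=len(train), n_test=len(test)))
    return pd.DataFrame(rows)
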