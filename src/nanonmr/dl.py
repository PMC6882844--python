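"""Feed-forward network classifier for measurement traces.

The architecture is deliberately small and fixed: an input layer the length
of the trace, two hidden ReLU layers of 20 and 35 units, and a single
Sigmoid output trained with mean-squared-error loss against 0/1 class
labels; a trace is labelled 1 when the output exceeds 0.5.  Restricting the
node count is the only capacity control — no explicit regularization.

The implementation is plain numpy (dense forward/backward passes and an
Adam or momentum-SGD update loop), which keeps training single-threaded,
dependency-light and bit-for-bit reproducible from a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Tuple, Union

import numpy as np

from .types import Dataset, Trace

__all__ = [
    "NetSpec",
    "TrainConfig",
    "TrainedNet",
    "build_net",
    "train_net",
    "train_net_online",
    "predict",
    "predict_batch",
    "save_net",
    "load_net",
]


@dataclass(frozen=True)
class NetSpec:
    """Architecture: input -> hidden ReLU layers -> 1 Sigmoid output."""

    input_dim: int
    hidden: Tuple[int, ...] = (20, 35)

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not self.hidden or any(h < 1 for h in self.hidden):
            raise ValueError("hidden layer sizes must be positive")

    @property
    def layer_dims(self) -> Tuple[int, ...]:
        return (self.input_dim, *self.hidden, 1)

    @property
    def n_parameters(self) -> int:
        dims = self.layer_dims
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (plumbing; the model itself fixes the
    architecture and loss).

    ``optimizer`` is "adam" or "sgd" (momentum 0.9).  Inputs are encoded as
    {0,1} floats by default ("binary"); "pm1" maps bits to -1/+1.  With
    ``standardize`` the training-set scalar bit mean/std is subtracted/
    divided (stored on the trained net and re-applied at prediction time).
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    validation_fraction: float = 0.2
    patience: int = 20
    seed: int = 0
    input_encoding: str = "binary"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if not (0.0 < self.validation_fraction <= 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5]")
        if min(self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("batch_size, max_epochs, patience must be >= 1")
        if self.input_encoding not in ("binary", "pm1"):
            raise ValueError("input_encoding must be 'binary' or 'pm1'")


@dataclass
class TrainedNet:
    """Weights/biases per layer plus the input transform and history."""

    spec: NetSpec
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    input_shift: float = 0.0
    input_scale: float = 1.0
    input_encoding: str = "binary"
    history: List[dict] = field(default_factory=list)

    def encode(self, bits: np.ndarray) -> np.ndarray:
        x = bits.astype(np.float32)
        if self.input_encoding == "pm1":
            x = 2.0 * x - 1.0
        return (x - self.input_shift) / self.input_scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid scores for encoded inputs (n, input_dim) -> (n,)."""
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        z = h @ self.weights[-1] + self.biases[-1]
        return (1.0 / (1.0 + np.exp(-z))).ravel()


def build_net(spec: NetSpec, seed: int = 0) -> TrainedNet:
    """He-initialized network; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    dims = spec.layer_dims
    weights = [
        (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32)
        for a, b in zip(dims[:-1], dims[1:])
    ]
    biases = [np.zeros(b, dtype=np.float32) for b in dims[1:]]
    return TrainedNet(spec, weights, biases)


def _backward(net: TrainedNet, x: np.ndarray, y: np.ndarray
              ) -> Tuple[List[np.ndarray], float]:
    """MSE gradients for one batch; returns (grads, batch loss)."""
    acts = [x]
    h = x
    for w, b in zip(net.weights[:-1], net.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
        acts.append(h)
    out = (1.0 / (1.0 + np.exp(-(h @ net.weights[-1] + net.biases[-1])))).ravel()
    loss = float(np.mean((out - y) ** 2))
    # d(MSE)/dz through the sigmoid
    delta = ((2.0 / len(y)) * (out - y) * out * (1.0 - out))[:, None]
    delta = delta.astype(np.float32)
    gw: List[np.ndarray] = []
    gb: List[np.ndarray] = []
    for i in range(len(net.weights) - 1, -1, -1):
        gw.append(acts[i].T @ delta)
        gb.append(delta.sum(axis=0))
        if i > 0:
            delta = delta @ net.weights[i].T
            delta[acts[i] <= 0] = 0.0
    return list(reversed(gw)) + list(reversed(gb)), loss


class _Optimizer:
    def __init__(self, cfg: TrainConfig, params: List[np.ndarray]):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        lr = self.cfg.learning_rate
        self.t += 1
        if self.cfg.optimizer == "adam":
            for p, g, m, v in zip(params, grads, self.m, self.v):
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                mhat = m / (1.0 - 0.9 ** self.t)
                vhat = v / (1.0 - 0.999 ** self.t)
                p -= lr * mhat / (np.sqrt(vhat) + 1e-8)
        else:  # momentum SGD
            for p, g, m in zip(params, grads, self.m):
                m *= 0.9
                m += g
                p -= lr * m


def _set_binary_input_stats(net: TrainedNet, bits: np.ndarray,
                            encoding: str) -> None:
    """Scalar shift/scale from 0/1 inputs without materializing a float
    copy: for Bernoulli data the std is sqrt(m (1 - m)) exactly."""
    m = float(bits.mean())
    if encoding == "pm1":
        net.input_shift = 2.0 * m - 1.0
        net.input_scale = 2.0 * math.sqrt(max(m * (1.0 - m), 1e-12))
    else:
        net.input_shift = m
        net.input_scale = math.sqrt(max(m * (1.0 - m), 1e-12))


def _balanced_error(scores: np.ndarray, y: np.ndarray) -> float:
    e0 = float(np.mean(scores[y == 0] > 0.5)) if (y == 0).any() else 0.0
    e1 = float(np.mean(scores[y == 1] <= 0.5)) if (y == 1).any() else 0.0
    return 0.5 * (e0 + e1)


def train_net(net: TrainedNet, train: Dataset, cfg: TrainConfig) -> TrainedNet:
    """Train on a fixed labelled dataset with early stopping.

    A stratified ``validation_fraction`` split is held out; training stops
    when the held-out MSE has not improved for ``patience`` epochs and the
    best-so-far weights are restored.
    """
    labels = train.labels
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    bits = train.bit_matrix
    if bits.shape[1] != net.spec.input_dim:
        raise ValueError("trace length does not match the input layer")
    rng = np.random.default_rng(cfg.seed)

    # stratified validation split
    val_idx, tr_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_val = max(1, int(round(cfg.validation_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        tr_idx.extend(idx[n_val:])
    tr_idx = np.array(tr_idx)
    val_idx = np.array(val_idx)

    net.input_encoding = cfg.input_encoding
    if cfg.standardize:
        _set_binary_input_stats(net, bits[tr_idx], cfg.input_encoding)
    y_all = labels.astype(np.float32)
    # bits stay uint8; batches are encoded to float32 on the fly so peak
    # memory is one batch, not the whole training matrix
    xv, yv = net.encode(bits[val_idx]), y_all[val_idx]

    params = net.weights + net.biases
    opt = _Optimizer(cfg, params)
    best_loss = np.inf
    best_state = None
    bad = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr_idx))
        ep_loss = 0.0
        n_batches = 0
        for s in range(0, len(order), cfg.batch_size):
            bi = tr_idx[order[s:s + cfg.batch_size]]
            grads, loss = _backward(net, net.encode(bits[bi]), y_all[bi])
            opt.step(params, grads)
            ep_loss += loss
            n_batches += 1
        sv = net.forward(xv)
        val_loss = float(np.mean((sv - yv) ** 2))
        net.history.append(dict(epoch=epoch, train_loss=ep_loss / n_batches,
                                val_loss=val_loss,
                                val_error=_balanced_error(sv, yv)))
        if val_loss < best_loss - 1e-7:
            best_loss = val_loss
            best_state = [p.copy() for p in params]
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_state is not None:
        for p, s in zip(params, best_state):
            p[...] = s
    return net


def train_net_online(
    net: TrainedNet,
    batch_source: Callable[[np.random.Generator], Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    n_batches: int,
    validation: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    eval_every: int = 200,
) -> TrainedNet:
    """Train on a stream of freshly simulated batches (single-pass data).

    ``batch_source(rng)`` must return one ``(bits, labels)`` batch per call;
    every example is seen once, so generalization tracks the training loss
    and no early-stopping split is needed.  If ``validation`` bits/labels
    are given, the held-out MSE is recorded every ``eval_every`` batches and
    the best-scoring weights are restored at the end.
    """
    rng = np.random.default_rng(cfg.seed)
    net.input_encoding = cfg.input_encoding
    if cfg.standardize:
        probe_bits, _ = batch_source(rng)
        raw = probe_bits.astype(np.float32)
        if cfg.input_encoding == "pm1":
            raw = 2.0 * raw - 1.0
        net.input_shift = float(raw.mean())
        net.input_scale = float(raw.std()) or 1.0
    params = net.weights + net.biases
    opt = _Optimizer(cfg, params)
    best = (np.inf, None)
    xv = yv = None
    if validation is not None:
        xv = net.encode(np.asarray(validation[0]))
        yv = np.asarray(validation[1], dtype=np.float32)
    for k in range(n_batches):
        bits, y = batch_source(rng)
        grads, loss = _backward(net, net.encode(bits),
                                np.asarray(y, dtype=np.float32))
        opt.step(params, grads)
        if xv is not None and ((k + 1) % eval_every == 0 or k == n_batches - 1):
            sv = net.forward(xv)
            val_loss = float(np.mean((sv - yv) ** 2))
            net.history.append(dict(batch=k + 1, train_loss=loss,
                                    val_loss=val_loss,
                                    val_error=_balanced_error(sv, yv)))
            if val_loss < best[0]:
                best = (val_loss, [p.copy() for p in params])
    if best[1] is not None:
        for p, s in zip(params, best[1]):
            p[...] = s
    return net


def predict(net: TrainedNet, trace: Trace) -> Tuple[float, int]:
    """Score one trace; label 1 iff the Sigmoid output is strictly > 0.5."""
    if len(trace) != net.spec.input_dim:
        raise ValueError(
            f"trace length {len(trace)} != input_dim {net.spec.input_dim}"
        )
    score = float(net.forward(net.encode(trace.bits[None, :]))[0])
    return score, int(score > 0.5)


def predict_batch(net: TrainedNet, data: Union[Dataset, np.ndarray]
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Scores and labels for a dataset (or a raw bit matrix)."""
    bits = data.bit_matrix if isinstance(data, Dataset) else np.asarray(data)
    if bits.shape[1] != net.spec.input_dim:
        raise ValueError("trace length does not match the input layer")
    scores = net.forward(net.encode(bits))
    return scores, (scores > 0.5).astype(int)


def save_net(net: TrainedNet, path: Union[str, Path]) -> None:
    """Persist a trained network as a self-describing .npz archive."""
    meta = dict(
        input_dim=net.spec.input_dim,
        hidden=list(net.spec.hidden),
        input_shift=net.input_shift,
        input_scale=net.input_scale,
        input_encoding=net.input_encoding,
    )
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.biases)})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_net(path: Union[str, Path]) -> TrainedNet:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        n_layers = len(meta["hidden"]) + 1
        weights = [f[f"w{i}"] for i in range(n_layers)]
        biases = [f[f"b{i}"] for i in range(n_layers)]
    spec = NetSpec(meta["input_dim"], tuple(meta["hidden"]))
    return TrainedNet(spec, weights, biases, meta["input_shift"],
                      meta["input_scale"], meta["input_encoding"])
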