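# nanonmr

Simulation and classification toolkit for single-spin (NV-center) nano-NMR
frequency **discrimination** and frequency **resolution** on binary
measurement traces.

A single NV center interrogating a weak oscillating magnetic signal yields,
per initialize–evolve–measure cycle of length Δt, one bit with success
probability

    P(t) = sin²( (g / 2ω) [sin(ωt + φ) − sin(ω(t − Δt) + φ)] + π/4 )

for a signal of amplitude `g`, angular frequency `ω` and (per-experiment
random) phase `φ`.  An experiment is a string of N such bits.  The package
generates these strings under several noise models — phase jumps, magnetic
detuning jumps, per-interval amplitude noise, low detection efficiency
`Q = η_true P + η_false (1 − P)` — and under an Ornstein–Uhlenbeck-modulated
multi-line model for the resolution problem, and implements three
classifiers:

* **likelihood ratio (full Bayesian)** — Bernoulli log-likelihood maximized
  over the nuisance (a phase grid, or a bank of sampled OU realizations);
  the statistically efficient benchmark when the model is known;
* **correlation templates** — nearest class-averaged ±1 autocorrelation
  vector in L2 distance; model-free;
* **feed-forward network** — fixed 20- and 35-unit ReLU hidden layers, one
  Sigmoid output, MSE loss, 0.5 decision threshold; model-free.

Performance is reported as the class-balanced error probability
`P_err = ½ [P(pred=2|1) + P(pred=1|2)]` plus ROC/AUC.

All frequencies and amplitudes inside the package are angular (rad/s);
`nanonmr.angular(hz)` converts ordinary Hz.

## Worked example

```python
from nanonmr import (SignalParams, simulate_discrimination_pair,
                     classify_frequency_batch, error_probability)

p1 = SignalParams(g=10.0, omega=10.0, dt=0.5, n_meas=1000)
p2 = SignalParams(g=10.0, omega=10.0005, dt=0.5, n_meas=1000)
test = simulate_discrimination_pair(p1, p2, n_per_class=200, seed=42)
pred, l1, l2 = classify_frequency_batch(test, p1, p2, grid_size=64)
print(error_probability(test.labels, pred).p_error)
```

prints `0.1625`: with a frequency separation of 5·10⁻⁴ rad/s over a 500 s
record and an unknown phase per trace, the likelihood-ratio test mislabels
about 16% of traces — midway between chance (0.5) and certainty (0).
Larger separations drive the error to zero (see
`examples/02_likelihood_ratio_discrimination.py`; each script in
`examples/` is a short narrative of one capability).

A thin CLI mirrors the library: `nanonmr simulate`, `nanonmr classify`,
`nanonmr train-dl`, `nanonmr benchmark-discrimination`,
`nanonmr benchmark-resolution`; see `nanonmr --help`.

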