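"""The DASS severity feedforward network (layer 3).

A fully-connected net mapping a flattened 31x30 facial-matrix window
(930 inputs) through two hidden layers to three outputs in (0, 1), one per
DASS scale:

* hidden layer 1: 75 neurons, tanh, bias fixed at 0;
* hidden layer 2: 65 neurons, sigmoid, bias fixed at 0;
* output layer: 3 neurons, sigmoid, trainable bias.

Weights are initialized with the Nguyen-Widrow rule (each neuron's incoming
weight vector scaled to magnitude 0.7 * h**(1/n) for h neurons fed by n
inputs), except that hidden biases stay at 0 throughout.  Training is
backpropagation with classical momentum (defaults: learning rate 0.2,
momentum 0.4, at most 7000 epochs) minimizing the average absolute
relative error (AARE)

    AARE = (1/N) * sum_p | (y_p - e_p) / e_p |

with y_p the desired and e_p the estimated output, averaged over samples
and the three output components; denominators are clamped at eps = 0.05.
Training stops when the training AARE drops below 0.02 or at the epoch
cap.

Output activations band into the five severity levels at thresholds
0.15 / 0.3 / 0.6 / 0.8; training targets encode bands as the midpoints of
those intervals so that targets are never zero.

A disorder variant with hidden sizes 30/25 produces three binary flags
(MDD, GAD, PTSD) by thresholding the outputs at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .levels import SeverityBand
from .matrix import Window

N_INPUT = 930
HIDDEN_SIZES = (75, 65)
DISORDER_HIDDEN_SIZES = (30, 25)
N_OUTPUT = 3
DISORDERS = ("MDD", "GAD", "PTSD")

#: Thresholds separating the five bands on the output activations:
#: [0, 0.15) Normal, [0.15, 0.3) Mild, [0.3, 0.6) Moderate,
#: [0.6, 0.8] Severe, (0.8, 1] Extremely Severe.
BAND_THRESHOLDS = (0.15, 0.3, 0.6, 0.8)

#: Band targets for training: midpoints of the banding intervals, so that
#: desired outputs are always strictly positive.
BAND_MIDPOINTS: dict[SeverityBand, float] = {
    SeverityBand.NORMAL: 0.075,
    SeverityBand.MILD: 0.225,
    SeverityBand.MODERATE: 0.45,
    SeverityBand.SEVERE: 0.7,
    SeverityBand.EXTREMELY_SEVERE: 0.9,
}

AARE_EPS = 0.05


def band_output(activation: float) -> SeverityBand:
    """Band of a single output activation in [0, 1].

    The printed intervals share endpoints; they are resolved half-open,
    lower-inclusive, except that 0.8 belongs to Severe ("over 0.8" is
    strict for Extremely Severe).
    """
    a = float(activation)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation {a} outside [0, 1]")
    t1, t2, t3, t4 = BAND_THRESHOLDS
    if a < t1:
        return SeverityBand.NORMAL
    if a < t2:
        return SeverityBand.MILD
    if a < t3:
        return SeverityBand.MODERATE
    if a <= t4:
        return SeverityBand.SEVERE
    return SeverityBand.EXTREMELY_SEVERE


def encode_bands(bands: Sequence[SeverityBand]) -> np.ndarray:
    """Band triple -> midpoint target triple."""
    return np.array([BAND_MIDPOINTS[SeverityBand(b)] for b in bands])


@dataclass(frozen=True)
class DASSPrediction:
    """Network output for one window: activations and their bands."""

    activations: tuple[float, float, float]
    bands: tuple[SeverityBand, SeverityBand, SeverityBand]
    start_time: float = 0.0

    @classmethod
    def from_activations(cls, acts: Sequence[float],
                         start_time: float = 0.0) -> "DASSPrediction":
        acts = tuple(float(a) for a in acts)
        return cls(
            activations=acts,
            bands=tuple(band_output(a) for a in acts),
            start_time=start_time,
        )


@dataclass
class FFNNParams:
    """All weights of the network; hidden biases are fixed at 0."""

    weights: list[np.ndarray]  # [W1 (n_in,h1), W2 (h1,h2), W3 (h2,3)]
    output_bias: np.ndarray  # (3,)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(
            w.shape[1] for w in self.weights
        )

    @property
    def hidden_biases(self) -> tuple[np.ndarray, np.ndarray]:
        h1, h2 = self.weights[0].shape[1], self.weights[1].shape[1]
        return np.zeros(h1), np.zeros(h2)

    def copy(self) -> "FFNNParams":
        return FFNNParams(
            weights=[w.copy() for w in self.weights],
            output_bias=self.output_bias.copy(),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def nguyen_widrow_init(
    layer_sizes: Sequence[int] = (N_INPUT, *HIDDEN_SIZES, N_OUTPUT),
    seed: int = 0,
) -> FFNNParams:
    """Nguyen-Widrow weight initialization.

    For a layer with ``n`` inputs and ``h`` neurons, each neuron's incoming
    weight vector is drawn uniformly at random and rescaled to magnitude
    ``beta = 0.7 * h**(1/n)``, spreading the active regions of the neurons
    evenly.  The classic rule also draws biases; here the hidden biases are
    fixed at 0 (an architecture constraint) and the output bias starts at 0.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) != 4:
        raise ValueError("expected four layer sizes (input, h1, h2, output)")
    if any(s <= 0 for s in sizes):
        raise ValueError(f"layer sizes must be positive, got {sizes}")
    rng = np.random.default_rng(seed)
    weights = []
    for n_in, h in zip(sizes[:-1], sizes[1:]):
        beta = 0.7 * h ** (1.0 / n_in)
        w = rng.uniform(-1.0, 1.0, size=(n_in, h))
        norms = np.linalg.norm(w, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        weights.append(w / norms * beta)
    return FFNNParams(weights=weights, output_bias=np.zeros(sizes[-1]))


def _forward_batch(params: FFNNParams, X: np.ndarray):
    """Forward pass on a (n, N) batch; returns hidden and output activations."""
    H1 = np.tanh(X @ params.weights[0])
    H2 = _sigmoid(H1 @ params.weights[1])
    Y = _sigmoid(H2 @ params.weights[2] + params.output_bias)
    return H1, H2, Y


def forward(params: FFNNParams, x: np.ndarray) -> np.ndarray:
    """Network outputs (3 reals in (0,1)) for one flattened window."""
    x = np.asarray(x, dtype=float)
    n_in = params.weights[0].shape[0]
    if x.shape != (n_in,):
        raise ValueError(
            f"input must have length {n_in}, got shape {x.shape}"
        )
    return _forward_batch(params, x[None, :])[2][0]


def aare(predicted: np.ndarray, desired: np.ndarray,
         eps: float = AARE_EPS) -> float:
    """Average absolute relative error between desired and estimated values.

    ``predicted`` are the network estimates (the denominators, clamped at
    ``eps``); ``desired`` are the targets.  Averages over all components.
    """
    p = np.asarray(predicted, dtype=float)
    d = np.asarray(desired, dtype=float)
    if p.shape != d.shape or p.size == 0:
        raise ValueError(
            f"predicted and desired must be same non-empty shape, "
            f"got {p.shape} and {d.shape}"
        )
    return float(np.mean(np.abs(d - p) / np.maximum(p, eps)))


def _aare_output_grad(Y: np.ndarray, T: np.ndarray,
                      eps: float = AARE_EPS) -> np.ndarray:
    """d AARE / d Y for the clamped-denominator loss, averaged over all entries."""
    s = np.sign(T - Y)
    d = np.maximum(Y, eps)
    grad = np.where(Y >= eps, -s * T / d**2, -s / eps)
    return grad / T.size


def _gradients(params: FFNNParams, X: np.ndarray, T: np.ndarray):
    """Analytic gradients of the batch AARE w.r.t. all trainable parameters."""
    H1, H2, Y = _forward_batch(params, X)
    dY = _aare_output_grad(Y, T)
    dZ3 = dY * Y * (1.0 - Y)
    gW3 = H2.T @ dZ3
    gb3 = dZ3.sum(axis=0)
    dZ2 = (dZ3 @ params.weights[2].T) * H2 * (1.0 - H2)
    gW2 = H1.T @ dZ2
    dZ1 = (dZ2 @ params.weights[1].T) * (1.0 - H1**2)
    gW1 = X.T @ dZ1
    return [gW1, gW2, gW3], gb3


@dataclass(frozen=True)
class TrainingConfig:
    """Backpropagation hyperparameters (defaults as tuned for the task)."""

    learning_rate: float = 0.2
    momentum: float = 0.4
    max_epochs: int = 7000
    target_error: float = 0.02
    validation_fraction: float = 0.2
    mode: Literal["batch", "per_sample"] = "batch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.target_error <= 0:
            raise ValueError("target_error must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainingHistory:
    train_aare: list[float] = field(default_factory=list)
    val_aare: list[float] = field(default_factory=list)
    stop_reason: Literal["error-target", "epoch-cap"] = "epoch-cap"

    @property
    def n_epochs(self) -> int:
        return len(self.train_aare)


def _as_design_matrix(windows, n_in: int) -> np.ndarray:
    rows = []
    for w in windows:
        rows.append(w.flatten() if isinstance(w, Window) else np.asarray(w, float))
    X = np.stack(rows)
    if X.shape[1] != n_in:
        raise ValueError(f"inputs must have length {n_in}, got {X.shape[1]}")
    return X


def train(
    windows,
    targets,
    cfg: TrainingConfig | None = None,
    layer_sizes: Sequence[int] = (N_INPUT, *HIDDEN_SIZES, N_OUTPUT),
    params: FFNNParams | None = None,
) -> tuple[FFNNParams, TrainingHistory]:
    """Train the network by momentum backpropagation on the AARE loss.

    ``windows`` is a sequence of :class:`Window` (or pre-flattened arrays);
    ``targets`` an (n, 3) array of desired outputs in (0, 1], typically
    band midpoints from :func:`encode_bands`.  A validation split
    (``cfg.validation_fraction``, seeded shuffle) is monitored but does not
    gate stopping: training stops when the *training* AARE falls below
    ``cfg.target_error``, or at the epoch cap.  Hidden biases stay at 0
    throughout.
    """
    cfg = cfg or TrainingConfig()
    sizes = tuple(int(s) for s in layer_sizes)
    T = np.asarray(targets, dtype=float)
    if T.ndim != 2 or T.shape[1] != sizes[-1]:
        raise ValueError(f"targets must be (n, {sizes[-1]}), got {T.shape}")
    if len(T) == 0:
        raise ValueError("dataset is empty")
    if np.any(T <= 0) or np.any(T > 1):
        raise ValueError("targets must lie in (0, 1]")
    X = _as_design_matrix(windows, sizes[0])
    if len(X) != len(T):
        raise ValueError("windows and targets must be aligned")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    n_val = int(round(cfg.validation_fraction * len(X)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split leaves no training samples")
    Xtr, Ttr = X[tr_idx], T[tr_idx]
    Xval, Tval = X[val_idx], T[val_idx]

    if params is None:
        params = nguyen_widrow_init(sizes, seed=cfg.seed)
    else:
        params = params.copy()
    vel = [np.zeros_like(w) for w in params.weights]
    vel_b = np.zeros_like(params.output_bias)

    history = TrainingHistory()
    for _epoch in range(cfg.max_epochs):
        train_loss = aare(_forward_batch(params, Xtr)[2], Ttr)
        history.train_aare.append(train_loss)
        if len(Xval):
            history.val_aare.append(aare(_forward_batch(params, Xval)[2], Tval))
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                "training diverged (non-finite AARE); try a smaller "
                "learning rate"
            )
        if train_loss < cfg.target_error:
            history.stop_reason = "error-target"
            return params, history

        if cfg.mode == "batch":
            grads, gb = _gradients(params, Xtr, Ttr)
            for w, g, v in zip(params.weights, grads, vel):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                w += v
            vel_b *= cfg.momentum
            vel_b -= cfg.learning_rate * gb
            params.output_bias += vel_b
        else:  # per-sample (pattern mode); gradient scale matches batch mode
            for i in rng.permutation(len(Xtr)):
                grads, gb = _gradients(params, Xtr[i:i + 1], Ttr[i:i + 1])
                scale = cfg.learning_rate / len(Xtr)
                for w, g, v in zip(params.weights, grads, vel):
                    v *= cfg.momentum
                    v -= scale * g
                    w += v
                vel_b *= cfg.momentum
                vel_b -= scale * gb
                params.output_bias += vel_b

    history.stop_reason = "epoch-cap"
    final = aare(_forward_batch(params, Xtr)[2], Ttr)
    history.train_aare.append(final)
    if len(Xval):
        history.val_aare.append(aare(_forward_batch(params, Xval)[2], Tval))
    if final < cfg.target_error:
        history.stop_reason = "error-target"
    return params, history


def predict_window(params: FFNNParams, window: Window) -> DASSPrediction:
    """Severity prediction (activations + bands) for one window."""
    acts = forward(params, window.flatten())
    return DASSPrediction.from_activations(acts, start_time=window.start_time)


def predict_disorders(params: FFNNParams, window: Window) -> dict[str, int]:
    """Binary MDD/GAD/PTSD flags from the disorder-variant network.

    Outputs are thresholded at 0.5; an output exactly at 0.5 resolves to 0.
    """
    expected = (N_INPUT, *DISORDER_HIDDEN_SIZES, N_OUTPUT)
    if params.layer_sizes != expected:
        raise ValueError(
            f"disorder variant requires layer sizes {expected}, "
            f"got {params.layer_sizes}"
        )
    acts = forward(params, window.flatten())
    return {name: int(a > 0.5) for name, a in zip(DISORDERS, acts)}


def encode_disorder_targets(flags) -> np.ndarray:
    """Disorder flags -> training targets.

    Positive flags map to 0.9 and negative to 0.1: the AARE loss divides by
    the estimated output, so exact 0/1 targets are replaced by values
    comfortably inside (0, 1) on either side of the 0.5 decision threshold.
    """
    F = np.asarray(flags, dtype=float)
    return np.where(F > 0.5, 0.9, 0.1)
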