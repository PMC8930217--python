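"""Two-hidden-layer feedforward classifier trained with RMSprop.

A deliberately small, pure-numpy multilayer perceptron: ReLU hidden units,
softmax output, and a choice of negative log-likelihood or half squared
error as the loss. The optimizer keeps an exponentially decaying average of
squared gradients,

    G_t = beta * G_{t-1} + (1 - beta) * g (.) g
    theta <- theta - alpha * g / sqrt(G_t + eps)

with beta = 0.9 by default. Everything is seeded and deterministic:
identical seeds give bit-identical parameters and training history.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

EPS_PROB = 1e-12  # probability floor inside the NLL


@dataclasses.dataclass
class NetworkSpec:
    """Architecture: (input, hidden..., output) sizes; two hidden layers by
    default. Output size equals the number of classes."""

    layer_sizes: tuple[int, ...] = (2, 64, 32, 2)
    hidden_activation: str = "relu"
    output_activation: str = "softmax"
    init_scheme: str = "he_uniform"
    init_seed: int = 0

    def validate(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least input, one hidden and output layer")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        if self.hidden_activation != "relu":
            raise ValueError("only ReLU hidden units are supported")
        if self.output_activation != "softmax":
            raise ValueError("only softmax output is supported")


@dataclasses.dataclass
class NetworkParams:
    """Per-layer weight matrices (fan_in x fan_out) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclasses.dataclass
class RMSpropState:
    """Squared-gradient accumulator plus the optimizer's constants."""

    g_weights: list[np.ndarray]
    g_biases: list[np.ndarray]
    alpha: float = 1e-3
    beta: float = 0.9
    epsilon: float = 1e-8
    t: int = 0

    @classmethod
    def for_params(
        cls, params: NetworkParams, alpha: float = 1e-3, beta: float = 0.9, epsilon: float = 1e-8
    ) -> "RMSpropState":
        if not (0 <= beta < 1):
            raise ValueError("beta must lie in [0, 1)")
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        return cls(
            g_weights=[np.zeros_like(w) for w in params.weights],
            g_biases=[np.zeros_like(b) for b in params.biases],
            alpha=alpha,
            beta=beta,
            epsilon=epsilon,
        )


@dataclasses.dataclass
class TrainingOptions:
    epochs: int = 200
    batch_size: int = 16
    loss: str = "nll"  # or "squared"
    shuffle_seed: int = 0
    record_history: bool = True

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("nll", "squared"):
            raise ValueError("loss must be 'nll' or 'squared'")


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float] | None = None
    val_accuracy: list[float] | None = None


# ---------------------------------------------------------------------------
# initialisation and forward pass
# ---------------------------------------------------------------------------

def init_params(spec: NetworkSpec) -> NetworkParams:
    """He-style scaled-uniform fan-in initialisation, seeded."""
    spec.validate()
    rng = np.random.default_rng(spec.init_seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights=weights, biases=biases)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclasses.dataclass
class Activations:
    """Everything ``backward`` needs from a forward pass."""

    inputs: np.ndarray  # (batch, m)
    pre: list[np.ndarray]  # per layer pre-activations Z
    post: list[np.ndarray]  # per layer activations (last = softmax probs)

    @property
    def probabilities(self) -> np.ndarray:
        return self.post[-1]


def forward(params: NetworkParams, x: np.ndarray) -> Activations:
    """ReLU hidden layers, softmax output; accepts a vector or a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input size {x.shape[1]} != network input size {params.weights[0].shape[0]}"
        )
    pre, post = [], []
    a = x
    last = params.n_layers - 1
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        pre.append(z)
        a = softmax(z) if l == last else np.maximum(z, 0.0)
        post.append(a)
    return Activations(inputs=x, pre=pre, post=post)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_squared(t: np.ndarray, p: np.ndarray) -> float:
    """Half squared error ||t - p||^2 / 2 (mean over a batch)."""
    t = np.atleast_2d(np.asarray(t, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if t.shape != p.shape:
        raise ValueError("target and prediction shapes differ")
    return float((((t - p) ** 2).sum(axis=1) / 2.0).mean())


def loss_nll(t: int | np.ndarray, p: np.ndarray) -> float:
    """Negative log-likelihood -log p[t] (mean over a batch), with the
    probability floored at 1e-12."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=int))
    picked = p[np.arange(len(t)), t]
    return float(-np.log(np.maximum(picked, EPS_PROB)).mean())


def _onehot(t: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(t), n_classes))
    out[np.arange(len(t)), t] = 1.0
    return out


# ---------------------------------------------------------------------------
# backward pass and optimizer
# ---------------------------------------------------------------------------

def backward(
    params: NetworkParams, acts: Activations, t: np.ndarray, loss: str = "nll"
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the mean batch loss w.r.t. every weight and bias.

    For softmax + NLL the output delta collapses to (p - onehot(t)); for the
    squared loss the full softmax Jacobian-vector product is used.
    """
    p = acts.probabilities
    batch, n_classes = p.shape
    t = np.atleast_1d(np.asarray(t, dtype=int))
    onehot = _onehot(t, n_classes)
    if loss == "nll":
        delta = (p - onehot) / batch
    elif loss == "squared":
        dLdp = p - onehot  # d/dp of ||t - p||^2 / 2
        # softmax JVP: J^T v = p * (v - sum(v * p))
        delta = p * (dLdp - (dLdp * p).sum(axis=1, keepdims=True)) / batch
    else:
        raise ValueError("loss must be 'nll' or 'squared'")

    grads_w = [np.empty(0)] * params.n_layers
    grads_b = [np.empty(0)] * params.n_layers
    for l in range(params.n_layers - 1, -1, -1):
        a_prev = acts.inputs if l == 0 else acts.post[l - 1]
        grads_w[l] = a_prev.T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ params.weights[l].T) * (acts.pre[l - 1] > 0)
    return grads_w, grads_b


def rmsprop_update(
    state: RMSpropState,
    params: NetworkParams,
    grads: tuple[list[np.ndarray], list[np.ndarray]],
) -> tuple[NetworkParams, RMSpropState]:
    """One RMSprop step; returns updated copies of parameters and state."""
    grads_w, grads_b = grads
    new_params = params.copy()
    new_gw, new_gb = [], []
    for w, gw, acc in zip(new_params.weights, grads_w, state.g_weights):
        acc = state.beta * acc + (1.0 - state.beta) * gw * gw
        w -= state.alpha * gw / np.sqrt(acc + state.epsilon)
        new_gw.append(acc)
    for b, gb, acc in zip(new_params.biases, grads_b, state.g_biases):
        acc = state.beta * acc + (1.0 - state.beta) * gb * gb
        b -= state.alpha * gb / np.sqrt(acc + state.epsilon)
        new_gb.append(acc)
    new_state = RMSpropState(
        g_weights=new_gw,
        g_biases=new_gb,
        alpha=state.alpha,
        beta=state.beta,
        epsilon=state.epsilon,
        t=state.t + 1,
    )
    return new_params, new_state


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    opts: TrainingOptions | None = None,
    rms: RMSpropState | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[NetworkParams, TrainingHistory]:
    """Seeded mini-batch training; returns final parameters and per-epoch
    history (loss and accuracy on the full training set, plus validation
    curves when a validation set is supplied)."""
    opts = opts or TrainingOptions()
    opts.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    params = init_params(spec)
    if rms is None:
        rms = RMSpropState.for_params(params)
    else:
        rms = RMSpropState(
            g_weights=[np.zeros_like(w) for w in params.weights],
            g_biases=[np.zeros_like(b) for b in params.biases],
            alpha=rms.alpha,
            beta=rms.beta,
            epsilon=rms.epsilon,
        )
    rng = np.random.default_rng(opts.shuffle_seed)
    n = len(X)
    hist = TrainingHistory(
        train_loss=[],
        train_accuracy=[],
        val_loss=[] if X_val is not None else None,
        val_accuracy=[] if X_val is not None else None,
    )
    loss_fn = (lambda t, p: loss_nll(t, p)) if opts.loss == "nll" else (
        lambda t, p: loss_squared(_onehot(t, p.shape[1]), p)
    )
    for _epoch in range(opts.epochs):
        order = rng.permutation(n)
        for start in range(0, n, opts.batch_size):
            idx = order[start : start + opts.batch_size]
            acts = forward(params, X[idx])
            grads = backward(params, acts, y[idx], opts.loss)
            params, rms = rmsprop_update(rms, params, grads)
        probs = forward(params, X).probabilities
        loss_val = loss_fn(y, probs)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at epoch {_epoch}: {loss_val!r}; "
                "reduce the learning rate"
            )
        if opts.record_history or _epoch == opts.epochs - 1:
            hist.train_loss.append(loss_val)
            hist.train_accuracy.append(float((probs.argmax(axis=1) == y).mean()))
            if X_val is not None:
                vprobs = forward(params, X_val).probabilities
                hist.val_loss.append(loss_fn(np.asarray(y_val, dtype=int), vprobs))
                hist.val_accuracy.append(
                    float((vprobs.argmax(axis=1) == np.asarray(y_val)).mean())
                )
    return params, hist


def predict(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax, ties to the lower index) and softmax rows."""
    probs = forward(params, X).probabilities
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# serialization (pure JSON: shapes, seeds and weights as nested lists)
# ---------------------------------------------------------------------------

def save_model(path: str | Path, spec: NetworkSpec, params: NetworkParams) -> None:
    payload = {
        "format": "weedfs-mlp-json-v1",
        "spec": dataclasses.asdict(spec),
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[NetworkSpec, NetworkParams]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "weedfs-mlp-json-v1":
        raise ValueError("not a weedfs model file")
    spec_d = payload["spec"]
    spec_d["layer_sizes"] = tuple(spec_d["layer_sizes"])
    spec = NetworkSpec(**spec_d)
    params = NetworkParams(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
    )
    return spec, params
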