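"""Two-hidden-layer feedforward classifier: forward pass, loss, gradients.

The architecture is fixed: input -> tanh hidden layer 1 -> tanh hidden
layer 2 -> softmax output, trained by minimizing the mean cross-entropy
against one-hot targets.  Gradients are exact (reverse-mode accumulation)
and are verified against central finite differences in the test suite.

All computations are pure functions of (weights, data): no global state,
no in-place mutation of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HIDDEN_ACTIVATIONS = ("tanh",)
OUTPUT_ACTIVATIONS = ("softmax",)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of a two-hidden-layer classifier."""

    n_inputs: int
    layer1: int
    layer2: int
    n_outputs: int
    hidden_activation: str = "tanh"
    output_activation: str = "softmax"

    def __post_init__(self) -> None:
        for name in ("n_inputs", "layer1", "layer2", "n_outputs"):
            value = getattr(self, name)
            if not float(value).is_integer() or value < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ValueError(f"hidden_activation must be one of {HIDDEN_ACTIVATIONS}")
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ValueError(f"output_activation must be one of {OUTPUT_ACTIVATIONS}")

    @property
    def layer_dims(self) -> tuple[int, int, int, int]:
        return (self.n_inputs, self.layer1, self.layer2, self.n_outputs)

    @property
    def n_parameters(self) -> int:
        d0, d1, d2, d3 = self.layer_dims
        return d1 * d0 + d1 + d2 * d1 + d2 + d3 * d2 + d3


@dataclass
class NetworkWeights:
    """Weight matrices and bias vectors of one network.

    Shapes: W1 (layer1, n_inputs), W2 (layer2, layer1),
    W3 (n_outputs, layer2); b1/b2/b3 match the row counts.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3)]
        self.W1, self.b1, self.W2, self.b2, self.W3, self.b3 = arrays
        if self.W1.ndim != 2 or self.W2.ndim != 2 or self.W3.ndim != 2:
            raise ValueError("weight matrices must be 2-D")
        if (self.b1.shape != (self.W1.shape[0],)
                or self.b2.shape != (self.W2.shape[0],)
                or self.b3.shape != (self.W3.shape[0],)):
            raise ValueError("bias shapes inconsistent with weight matrices")
        if (self.W2.shape[1] != self.W1.shape[0]
                or self.W3.shape[1] != self.W2.shape[0]):
            raise ValueError("layer dimensions do not chain")
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValueError("weights must be finite")

    @property
    def spec(self) -> NetworkSpec:
        return NetworkSpec(self.W1.shape[1], self.W1.shape[0],
                           self.W2.shape[0], self.W3.shape[0])

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.W1.copy(), self.b1.copy(), self.W2.copy(),
                              self.b2.copy(), self.W3.copy(), self.b3.copy())


@dataclass
class LabeledBatch:
    """Feature rows paired with one-hot target rows."""

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal row counts")
        if self.inputs.shape[0] == 0:
            raise ValueError("batch must contain at least one case")
        if not np.all(np.isfinite(self.inputs)):
            raise ValueError("inputs contain non-finite values")
        onehot = np.isin(self.targets, (0.0, 1.0)).all()
        if not onehot or not np.allclose(self.targets.sum(axis=1), 1.0):
            raise ValueError("each target row must be one-hot")

    @property
    def n_cases(self) -> int:
        return self.inputs.shape[0]


def init_network(spec: NetworkSpec, seed: int) -> NetworkWeights:
    """Deterministic fan-based uniform initialization.

    Weights are drawn uniformly in +/- sqrt(6 / (fan_in + fan_out)) per
    layer (keeping early tanh activations in their linear range); biases
    start at zero.
    """
    rng = np.random.default_rng(seed)
    dims = spec.layer_dims

    def layer(fan_out: int, fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    return NetworkWeights(
        W1=layer(dims[1], dims[0]), b1=np.zeros(dims[1]),
        W2=layer(dims[2], dims[1]), b2=np.zeros(dims[2]),
        W3=layer(dims[3], dims[2]), b3=np.zeros(dims[3]),
    )


def _hidden_pass(weights: NetworkWeights, X: np.ndarray):
    A1 = np.tanh(X @ weights.W1.T + weights.b1)
    A2 = np.tanh(A1 @ weights.W2.T + weights.b2)
    Z3 = A2 @ weights.W3.T + weights.b3
    return A1, A2, Z3


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    return P


def forward_batch(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Class-probability rows for a matrix of input rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.W1.shape[1]:
        raise ValueError(f"inputs must have {weights.W1.shape[1]} columns, "
                         f"got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs contain non-finite values")
    _, _, Z3 = _hidden_pass(weights, X)
    return _softmax(Z3)


def forward(weights: NetworkWeights, x: np.ndarray) -> np.ndarray:
    """Probability vector over classes for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a 1-D vector")
    return forward_batch(weights, x[None, :])[0]


def cross_entropy(weights: NetworkWeights, batch: LabeledBatch) -> float:
    """Mean cross-entropy of the batch (strictly positive for finite weights)."""
    _, _, Z3 = _hidden_pass(weights, batch.inputs)
    # log-sum-exp form avoids log(softmax) underflow
    zmax = Z3.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(Z3 - zmax).sum(axis=1))
    z_target = (Z3 * batch.targets).sum(axis=1)
    return float(np.mean(lse - z_target))


def gradient(weights: NetworkWeights, batch: LabeledBatch) -> NetworkWeights:
    """Exact gradient of :func:`cross_entropy` w.r.t. every parameter."""
    X, T = batch.inputs, batch.targets
    n = batch.n_cases
    A1, A2, Z3 = _hidden_pass(weights, X)
    P = _softmax(Z3)
    G3 = (P - T) / n
    dW3 = G3.T @ A2
    db3 = G3.sum(axis=0)
    G2 = (G3 @ weights.W3) * (1.0 - A2 ** 2)
    dW2 = G2.T @ A1
    db2 = G2.sum(axis=0)
    G1 = (G2 @ weights.W2) * (1.0 - A1 ** 2)
    dW1 = G1.T @ X
    db1 = G1.sum(axis=0)
    return NetworkWeights(dW1, db1, dW2, db2, dW3, db3)


# -- flat-vector views used by the optimizers ------------------------------

def pack_weights(weights: NetworkWeights) -> np.ndarray:
    """Concatenate all parameters into one flat vector."""
    return np.concatenate([a.ravel() for a in
                           (weights.W1, weights.b1, weights.W2,
                            weights.b2, weights.W3, weights.b3)])


def unpack_weights(spec: NetworkSpec, vector: np.ndarray) -> NetworkWeights:
    """Inverse of :func:`pack_weights` for a given architecture."""
    d0, d1, d2, d3 = spec.layer_dims
    sizes = [d1 * d0, d1, d2 * d1, d2, d3 * d2, d3]
    if vector.shape != (sum(sizes),):
        raise ValueError("parameter vector length does not match spec")
    parts = []
    offset = 0
    for size in sizes:
        parts.append(vector[offset:offset + size])
        offset += size
    return NetworkWeights(
        parts[0].reshape(d1, d0), parts[1],
        parts[2].reshape(d2, d1), parts[3],
        parts[4].reshape(d3, d2), parts[5],
    )
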