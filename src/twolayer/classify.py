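"""End-to-end classifier: sizing, standardization, training, persistence.

`train_classifier` wires the pieces together the way the study protocol
prescribes: hidden layers sized by the Huang formulas from the full
sample count and the class count, features z-scored on the training
split only (identifier columns standardized like any other feature),
weights initialized deterministically from the seed, and the network
trained full-batch with the configured algorithm under the
consecutive-correct-validation stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ClassDecision, decide_batch, DEFAULT_THRESHOLD
from .features import build_targets
from .network import (NetworkSpec, NetworkWeights, forward_batch,
                      init_network)
from .sizing import huang_layer_sizes
from .training import Split, TrainConfig, TrainHistory, split_dataset, train_network

FORMAT_VERSION = "twolayer-model-1"


@dataclass
class FeedForwardClassifier:
    """Trained two-hidden-layer classifier plus its feature scaler."""

    spec: NetworkSpec
    weights: NetworkWeights
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.spec.n_outputs

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.feature_mean) / self.feature_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability rows for raw (unstandardized) feature rows."""
        return forward_batch(self.weights, self.standardize(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1-based argmax class labels."""
        return self.predict_proba(X).argmax(axis=1) + 1

    def decide(self, X: np.ndarray,
               threshold: float = DEFAULT_THRESHOLD) -> list[ClassDecision]:
        """Thresholded category selections (may be ``missed``)."""
        return decide_batch(self.predict_proba(X), threshold)

    def save(self, path) -> None:
        """Write a single portable container (NumPy .npz, bit-exact)."""
        np.savez(
            path,
            format_version=np.array(FORMAT_VERSION),
            dims=np.array(self.spec.layer_dims, dtype=np.int64),
            hidden_activation=np.array(self.spec.hidden_activation),
            output_activation=np.array(self.spec.output_activation),
            W1=self.weights.W1, b1=self.weights.b1,
            W2=self.weights.W2, b2=self.weights.b2,
            W3=self.weights.W3, b3=self.weights.b3,
            feature_mean=self.feature_mean,
            feature_scale=self.feature_scale,
        )

    @classmethod
    def load(cls, path) -> "FeedForwardClassifier":
        with np.load(path, allow_pickle=False) as data:
            version = str(data["format_version"])
            if version != FORMAT_VERSION:
                raise ValueError(f"unsupported model format {version!r}")
            dims = data["dims"]
            spec = NetworkSpec(int(dims[0]), int(dims[1]), int(dims[2]),
                               int(dims[3]),
                               hidden_activation=str(data["hidden_activation"]),
                               output_activation=str(data["output_activation"]))
            weights = NetworkWeights(data["W1"], data["b1"], data["W2"],
                                     data["b2"], data["W3"], data["b3"])
            return cls(spec=spec, weights=weights,
                       feature_mean=np.array(data["feature_mean"]),
                       feature_scale=np.array(data["feature_scale"]))


def fit_scaler(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and scale from the training split.

    Constant features get scale 1 so standardization maps them to zero
    rather than dividing by zero.
    """
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_classifier(inputs: np.ndarray,
                     labels,
                     config: TrainConfig = TrainConfig(),
                     n_classes: int | None = None,
                     ) -> tuple[FeedForwardClassifier, TrainHistory, Split]:
    """Size, split, standardize and train a classifier on labeled rows.

    ``labels`` are 1-based class indices.  Hidden-layer widths come from
    the Huang formulas with N = total sample count and m = class count.
    """
    X = np.asarray(inputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("inputs must be (n_cases, n_features) aligned with labels")
    m = n_classes or int(labels.max())
    targets = build_targets(labels, m)
    layer1, layer2 = huang_layer_sizes(X.shape[0], m)
    spec = NetworkSpec(X.shape[1], layer1, layer2, m)

    split = split_dataset(X.shape[0], config.split_fractions, config.seed)
    mean, scale = fit_scaler(X[split.train])
    X_std = (X - mean) / scale

    weights = init_network(spec, config.seed)
    trained, history = train_network(weights, X_std, targets, split, config)
    model = FeedForwardClassifier(spec=spec, weights=trained,
                                  feature_mean=mean, feature_scale=scale)
    return model, history, split
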