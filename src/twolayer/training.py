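"""Training protocol: 70/15/15 split, SCG and Rprop, run-length stopping.

Both optimizers are full-batch.  Scaled conjugate gradient follows
Moller's algorithm (conjugate directions with a finite-difference
curvature estimate and Levenberg-style damping); Rprop is the iRprop-
variant of resilient backpropagation (sign-based per-parameter step
sizes; on a gradient sign change the step size shrinks and the pending
update is skipped).

Early stopping mirrors the consecutive-correct-validation protocol: after
each epoch the validation split is classified in one fixed seeded order,
and training stops once some run of ``consecutive_correct`` correct
classifications occurs within that pass.  An epoch cap and a gradient
tolerance guard against non-convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .network import (LabeledBatch, NetworkWeights, cross_entropy, gradient,
                      forward_batch, pack_weights, unpack_weights)

ALGORITHMS = ("scg", "rprop")

STOP_VALIDATION_RUN = "validation_run"
STOP_MAX_EPOCHS = "max_epochs"
STOP_GRADIENT_TOLERANCE = "gradient_tolerance"


@dataclass(frozen=True)
class TrainConfig:
    """Algorithm choice, split, stopping rule and optimizer constants."""

    algorithm: str = "scg"
    consecutive_correct: int = 100
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 2000
    gradient_tolerance: float = 1e-6
    seed: int = 0
    scg_sigma: float = 5e-5
    scg_lambda0: float = 5e-7
    rprop_eta_plus: float = 1.2
    rprop_eta_minus: float = 0.5
    rprop_delta0: float = 0.07
    rprop_delta_max: float = 50.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.consecutive_correct < 1:
            raise ValueError("consecutive_correct must be positive")
        if len(self.split_fractions) != 3 or any(f < 0 for f in self.split_fractions):
            raise ValueError("split_fractions must be three non-negative reals")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.max_epochs < 1 or self.gradient_tolerance <= 0:
            raise ValueError("max_epochs and gradient_tolerance must be positive")
        if self.scg_sigma <= 0 or self.scg_lambda0 <= 0:
            raise ValueError("SCG constants must be positive")
        if not (self.rprop_eta_minus < 1.0 < self.rprop_eta_plus):
            raise ValueError("require eta_minus < 1 < eta_plus")
        if self.rprop_delta0 <= 0 or self.rprop_delta_max <= 0:
            raise ValueError("Rprop step bounds must be positive")


@dataclass(frozen=True)
class Split:
    """Disjoint index sets partitioning a dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split_dataset(n_cases: int,
                  fractions: Sequence[float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> Split:
    """Seeded 70/15/15-style partition of ``range(n_cases)``.

    Validation and test receive ``floor(fraction * n)`` cases each; the
    remainder goes to training.  Raises if any set would be empty.
    """
    if n_cases < 3:
        raise ValueError("need at least 3 cases to split")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be a triple summing to 1")
    n_val = int(np.floor(fractions[1] * n_cases))
    n_test = int(np.floor(fractions[2] * n_cases))
    n_train = n_cases - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n_cases} cases with fractions {tuple(fractions)} "
                         "leaves an empty set")
    order = np.random.default_rng(seed).permutation(n_cases)
    return Split(train=np.sort(order[:n_train]),
                 validation=np.sort(order[n_train:n_train + n_val]),
                 test=np.sort(order[n_train + n_val:]))


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    validation_accuracy: float
    longest_run: int
    gradient_norm: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    stop_reason: str | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.records)

    @property
    def losses(self) -> np.ndarray:
        return np.array([r.loss for r in self.records])


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: str | None = None


def longest_true_run(outcomes: Sequence[bool]) -> int:
    """Length of the longest run of True values."""
    best = current = 0
    for value in outcomes:
        current = current + 1 if value else 0
        best = max(best, current)
    return best


def check_stopping(validation_outcomes: Sequence[bool],
                   consecutive_correct: int,
                   epoch: int,
                   gradient_norm: float,
                   config: TrainConfig) -> StopDecision:
    """Stop decision after one epoch's validation pass.

    Fires ``validation_run`` iff a run of >= ``consecutive_correct``
    correct classifications occurs within the pass; otherwise checks the
    gradient tolerance and the epoch cap.
    """
    if consecutive_correct > len(validation_outcomes):
        raise ValueError(
            f"consecutive_correct={consecutive_correct} exceeds the validation "
            f"set size {len(validation_outcomes)}; the rule can never fire")
    if longest_true_run(validation_outcomes) >= consecutive_correct:
        return StopDecision(True, STOP_VALIDATION_RUN)
    if gradient_norm < config.gradient_tolerance:
        return StopDecision(True, STOP_GRADIENT_TOLERANCE)
    if epoch >= config.max_epochs:
        return StopDecision(True, STOP_MAX_EPOCHS)
    return StopDecision(False, None)


# -- optimizers (operate on flat parameter vectors) ------------------------

FunGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


class ScgStepper:
    """One Moller scaled-conjugate-gradient iteration per :meth:`step`.

    State carries the conjugate direction, the damping parameter lambda
    and the success flag; the direction restarts to steepest descent
    every ``restart_period`` successful steps (the parameter count).
    """

    def __init__(self, fun_grad: FunGrad, w0: np.ndarray, *,
                 sigma: float = 5e-5, lambda0: float = 5e-7,
                 restart_period: int | None = None) -> None:
        self.fun_grad = fun_grad
        self.sigma0 = sigma
        self.lam = lambda0
        self.lam_bar = 0.0
        self.f, self.g = fun_grad(w0)
        self.r = -self.g
        self.p = self.r.copy()
        self.success = True
        self.delta = 0.0
        self.k = 0
        self.restart_period = restart_period or w0.size

    @property
    def gradient_norm(self) -> float:
        return float(np.linalg.norm(self.g))

    def step(self, w: np.ndarray) -> np.ndarray:
        p, r = self.p, self.r
        pnorm2 = float(p @ p)
        if pnorm2 == 0.0:
            return w  # stationary: gradient tolerance will stop the loop
        if self.success:
            sigma = self.sigma0 / np.sqrt(pnorm2)
            _, g_plus = self.fun_grad(w + sigma * p)
            s = (g_plus - self.g) / sigma
            self.delta = float(p @ s)
        delta = self.delta + (self.lam - self.lam_bar) * pnorm2
        if delta <= 0:  # make the curvature estimate positive definite
            self.lam_bar = 2.0 * (self.lam - delta / pnorm2)
            delta = -delta + self.lam * pnorm2
            self.lam = self.lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = self.fun_grad(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError(f"non-finite loss at SCG step {self.k}")
        comparison = 2.0 * delta * (self.f - f_new) / mu ** 2
        if comparison >= 0:  # successful reduction
            w = w + alpha * p
            r_new = -g_new
            self.lam_bar = 0.0
            self.success = True
            self.k += 1
            if self.k % self.restart_period == 0:
                self.p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                self.p = r_new + beta * p
            self.r = r_new
            self.g = g_new
            self.f = f_new
            if comparison >= 0.75:
                self.lam = max(self.lam * 0.25, 1e-20)
        else:
            self.lam_bar = self.lam
            self.success = False
        if comparison < 0.25:
            self.lam = min(self.lam + delta * (1.0 - comparison) / pnorm2, 1e20)
        return w


class RpropStepper:
    """iRprop- resilient backpropagation: one full-batch step per call."""

    def __init__(self, fun_grad: FunGrad, w0: np.ndarray, *,
                 eta_plus: float = 1.2, eta_minus: float = 0.5,
                 delta0: float = 0.07, delta_max: float = 50.0) -> None:
        self.fun_grad = fun_grad
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta_max = delta_max
        self.delta = np.full_like(w0, delta0, dtype=float)
        self.prev_g = np.zeros_like(w0, dtype=float)
        self.f, self.g = fun_grad(w0)

    @property
    def gradient_norm(self) -> float:
        return float(np.linalg.norm(self.g))

    def step(self, w: np.ndarray) -> np.ndarray:
        g = self.g.copy()
        prod = self.prev_g * g
        grow = prod > 0
        shrink = prod < 0
        self.delta[grow] = np.minimum(self.delta[grow] * self.eta_plus,
                                      self.delta_max)
        self.delta[shrink] *= self.eta_minus
        g[shrink] = 0.0  # skip the pending update after a sign change
        w = w - np.sign(g) * self.delta
        self.prev_g = g
        self.f, self.g = self.fun_grad(w)
        if not np.isfinite(self.f):
            raise FloatingPointError("non-finite loss during Rprop step")
        return w


def _make_stepper(fun_grad: FunGrad, w0: np.ndarray,
                  config: TrainConfig) -> ScgStepper | RpropStepper:
    if config.algorithm == "scg":
        return ScgStepper(fun_grad, w0, sigma=config.scg_sigma,
                          lambda0=config.scg_lambda0)
    return RpropStepper(fun_grad, w0, eta_plus=config.rprop_eta_plus,
                        eta_minus=config.rprop_eta_minus,
                        delta0=config.rprop_delta0,
                        delta_max=config.rprop_delta_max)


def minimize(fun_grad: FunGrad, w0: np.ndarray, config: TrainConfig,
             callback: Callable[[int, np.ndarray, float, float], bool] | None = None,
             ) -> tuple[np.ndarray, str]:
    """Run the configured optimizer on an arbitrary smooth objective.

    ``callback(epoch, w, loss, gradient_norm)`` may return True to stop.
    Returns the final parameter vector and the stop reason.
    """
    w = np.asarray(w0, dtype=float).copy()
    stepper = _make_stepper(fun_grad, w, config)
    if stepper.gradient_norm < config.gradient_tolerance:
        return w, STOP_GRADIENT_TOLERANCE
    for epoch in range(1, config.max_epochs + 1):
        w = stepper.step(w)
        if callback is not None and callback(epoch, w, stepper.f,
                                             stepper.gradient_norm):
            return w, STOP_VALIDATION_RUN
        if stepper.gradient_norm < config.gradient_tolerance:
            return w, STOP_GRADIENT_TOLERANCE
    return w, STOP_MAX_EPOCHS


def train_network(weights: NetworkWeights,
                  inputs: np.ndarray,
                  targets: np.ndarray,
                  split: Split,
                  config: TrainConfig) -> tuple[NetworkWeights, TrainHistory]:
    """Train on the training split with validation-run early stopping.

    ``inputs``/``targets`` hold every case; ``split`` selects the rows
    used for gradient evaluation and for the stopping rule.  "Classified
    correctly" means the argmax of the output probabilities equals the
    one-hot target class.
    """
    if config.consecutive_correct > split.validation.size:
        raise ValueError(
            f"consecutive_correct={config.consecutive_correct} exceeds the "
            f"validation split size {split.validation.size}")
    spec = weights.spec
    train_batch = LabeledBatch(inputs[split.train], targets[split.train])
    # one fixed seeded order for every epoch's validation pass
    val_order = np.random.default_rng(config.seed).permutation(split.validation)
    X_val = inputs[val_order]
    y_val = targets[val_order].argmax(axis=1)

    def fun_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        net = unpack_weights(spec, w)
        return cross_entropy(net, train_batch), pack_weights(gradient(net, train_batch))

    history = TrainHistory()

    def callback(epoch: int, w: np.ndarray, loss: float, gnorm: float) -> bool:
        probs = forward_batch(unpack_weights(spec, w), X_val)
        outcomes = probs.argmax(axis=1) == y_val
        history.records.append(EpochRecord(
            epoch=epoch, loss=loss,
            validation_accuracy=float(np.mean(outcomes)),
            longest_run=longest_true_run(outcomes),
            gradient_norm=gnorm))
        decision = check_stopping(outcomes, config.consecutive_correct,
                                  epoch, gnorm, config)
        return decision.stop and decision.reason == STOP_VALIDATION_RUN

    w_final, reason = minimize(fun_grad, pack_weights(weights), config, callback)
    history.stop_reason = reason
    return unpack_weights(spec, w_final), history


def train_scg(weights: NetworkWeights, inputs: np.ndarray, targets: np.ndarray,
              split: Split, config: TrainConfig) -> tuple[NetworkWeights, TrainHistory]:
    """Scaled-conjugate-gradient training (thin wrapper)."""
    return train_network(weights, inputs, targets, split,
                         replace(config, algorithm="scg"))


def train_rprop(weights: NetworkWeights, inputs: np.ndarray, targets: np.ndarray,
                split: Split, config: TrainConfig) -> tuple[NetworkWeights, TrainHistory]:
    """Resilient-backpropagation training (thin wrapper)."""
    return train_network(weights, inputs, targets, split,
                         replace(config, algorithm="rprop"))
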