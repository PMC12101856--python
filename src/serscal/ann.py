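"""Feedforward regression networks trained with resilient backpropagation.

The calibration networks map six PC scores to a hormone concentration in
ng/ml.  Hidden layers use ReLU; the output is linear.  Training is full-batch
Rprop+ (resilient backpropagation with weight backtracking): each parameter
keeps its own step size, grown by ``eta_plus`` while the gradient sign is
stable and shrunk by ``eta_minus`` — with the previous update reverted — when
it flips.  Step sizes, not gradient magnitudes, set the update, which makes
the optimizer robust to the poorly scaled loss surfaces of deep ReLU stacks.

Two preset architectures are provided: ``12:10:10:10:6`` hidden units for the
growth-hormone model and ``10:8:8:8:6`` for the testosterone model, both on
six inputs with a single linear output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "MLPArchitecture",
    "MLPModel",
    "MLPEnsemble",
    "TrainConfig",
    "ensemble_forward",
    "train_ensemble",
    "GH_ARCHITECTURE",
    "TE_ARCHITECTURE",
    "init_mlp",
    "forward",
    "gradients",
    "n_parameters",
    "train_rprop_plus",
    "holdout_split",
    "kfold_indices",
    "kfold_cv",
]


@dataclasses.dataclass(frozen=True)
class MLPArchitecture:
    """Layer sizes of a fully connected regression network."""

    input_size: int = 6
    hidden_sizes: tuple[int, ...] = ()
    output_size: int = 1

    def __post_init__(self) -> None:
        sizes = (self.input_size, *self.hidden_sizes, self.output_size)
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, self.output_size)


#: Growth-hormone calibration network: 6 -> 12:10:10:10:6 -> 1.
GH_ARCHITECTURE = MLPArchitecture(6, (12, 10, 10, 10, 6), 1)
#: Testosterone calibration network: 6 -> 10:8:8:8:6 -> 1.
TE_ARCHITECTURE = MLPArchitecture(6, (10, 8, 8, 8, 6), 1)


@dataclasses.dataclass
class TrainConfig:
    """Rprop+ hyperparameters (Riedmiller's defaults, delta0 reduced for
    PC-score-scaled inputs) and the stopping rule.

    ``standardize_inputs`` z-scores each input feature on the training set.
    It defaults to off: PCA scores arrive on their natural scale, where
    low-variance components are almost pure measurement noise, and inflating
    them to unit variance measurably worsens validation error (see the
    methods notes).  The option remains for non-PCA inputs.
    """

    max_epochs: int = 6000
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.01
    delta_min: float = 1e-6
    delta_max: float = 50.0
    early_stop_tolerance: float = 1e-8
    patience: int = 50
    standardize_inputs: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.eta_minus < 1 < self.eta_plus):
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not (0 < self.delta_min <= self.delta0 <= self.delta_max):
            raise ValueError("require delta_min <= delta0 <= delta_max")


@dataclasses.dataclass
class MLPModel:
    """Weights, biases and optional input standardization of one network.

    ``weights[i]`` has shape (fan_in, fan_out).  ``x_mean``/``x_scale`` hold
    the per-feature z-scoring constants learned from the training scores (the
    identity until :func:`train_rprop_plus` sets them).  ``training_history``
    is the full-batch MSE per epoch.
    """

    architecture: MLPArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    training_history: list[float] = dataclasses.field(default_factory=list)

    def to_payload(self) -> dict:
        return {
            "architecture": dataclasses.asdict(self.architecture),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "final_loss": self.training_history[-1] if self.training_history else None,
            "epochs_trained": len(self.training_history),
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MLPModel":
        arch = dict(payload["architecture"])
        arch["hidden_sizes"] = tuple(arch["hidden_sizes"])
        return cls(
            MLPArchitecture(**arch),
            [np.asarray(w, dtype=float) for w in payload["weights"]],
            [np.asarray(b, dtype=float) for b in payload["biases"]],
            None if payload["x_mean"] is None else np.asarray(payload["x_mean"]),
            None if payload["x_scale"] is None else np.asarray(payload["x_scale"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_payload(), fh)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_payload(json.load(fh))


def n_parameters(architecture: MLPArchitecture) -> int:
    """Total weight and bias count."""
    sizes = architecture.layer_sizes
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def init_mlp(architecture: MLPArchitecture, seed: int) -> MLPModel:
    """He-style initialization: weights uniform on +/- sqrt(6/fan_in), zero
    biases; reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    sizes = architecture.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(architecture, weights, biases)


def _standardize(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.x_mean is None:
        return X
    return (X - model.x_mean) / model.x_scale


def _forward_cached(model: MLPModel, X: np.ndarray):
    """Activations of every layer (post-ReLU for hidden, linear output)."""
    activations = [X]
    a = X
    last = len(model.weights) - 1
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        a = z if i == last else np.maximum(z, 0.0)
        activations.append(a)
    return activations


def forward(model: MLPModel, scores: np.ndarray) -> np.ndarray:
    """Predicted concentrations for a score matrix (rows = spectra).

    Applies the stored input standardization, then affine-ReLU layers and the
    linear output.  Returns a 1-D array for single-output networks.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != model.architecture.input_size:
        raise ValueError(
            f"scores have {X.shape[1]} features, network expects "
            f"{model.architecture.input_size}"
        )
    out = _forward_cached(model, _standardize(model, X))[-1]
    return out[:, 0] if model.architecture.output_size == 1 else out


def gradients(model: MLPModel, X: np.ndarray, y: np.ndarray):
    """Full-batch MSE loss and its gradients by backpropagation.

    ``X`` is assumed already standardized.  Returns
    ``(loss, grad_weights, grad_biases)``.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
    acts = _forward_cached(model, X)
    n = X.shape[0]
    residual = acts[-1] - y
    loss = float(np.mean(residual**2))
    delta = 2.0 * residual / residual.size
    grad_w = [np.empty_like(w) for w in model.weights]
    grad_b = [np.empty_like(b) for b in model.biases]
    for i in range(len(model.weights) - 1, -1, -1):
        grad_w[i] = acts[i].T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    return loss, grad_w, grad_b


class _RpropState:
    """Per-parameter step sizes, previous gradients and previous updates."""

    def __init__(self, params: list[np.ndarray], delta0: float):
        self.step = [np.full_like(p, delta0) for p in params]
        self.prev_grad = [np.zeros_like(p) for p in params]
        self.prev_update = [np.zeros_like(p) for p in params]


def _rprop_update(params, grads, state: _RpropState, cfg: TrainConfig) -> None:
    """One Rprop+ step, in place.

    sign agreement  -> grow step (capped), take signed step
    sign flip       -> shrink step (floored), revert previous update,
                       zero the gradient memory (no step this epoch)
    zero product    -> plain signed step at the current size
    """
    for p, g, step, g_prev, u_prev in zip(
        params, grads, state.step, state.prev_grad, state.prev_update
    ):
        s = g_prev * g
        same = s > 0
        flip = s < 0
        step[same] = np.minimum(step[same] * cfg.eta_plus, cfg.delta_max)
        step[flip] = np.maximum(step[flip] * cfg.eta_minus, cfg.delta_min)
        update = -np.sign(g) * step
        update[flip] = -u_prev[flip]  # backtrack
        p += update
        u_prev[...] = np.where(flip, 0.0, update)
        g_prev[...] = np.where(flip, 0.0, g)


def train_rprop_plus(
    model: MLPModel, scores: np.ndarray, targets: np.ndarray, config: TrainConfig
) -> MLPModel:
    """Train in place with full-batch Rprop+; returns the model.

    Inputs are z-scored per feature using the training statistics when
    ``config.standardize_inputs`` (constants stored on the model so later
    predictions reuse them).  Stops at ``max_epochs`` or when the loss has not
    improved by ``early_stop_tolerance`` for ``patience`` consecutive epochs.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(targets, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite training data")
    if config.standardize_inputs:
        model.x_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        model.x_scale = np.where(scale > 0, scale, 1.0)
    X = _standardize(model, X)

    params = model.weights + model.biases
    state = _RpropState(params, config.delta0)
    best = np.inf
    stall = 0
    for epoch in range(config.max_epochs):
        loss, grad_w, grad_b = gradients(model, X, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; inspect target scale"
            )
        model.training_history.append(loss)
        if best - loss > config.early_stop_tolerance:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        _rprop_update(params, grad_w + grad_b, state, config)
    return model


@dataclasses.dataclass
class MLPEnsemble:
    """A small committee of independently initialized Rprop+ networks.

    Full-batch Rprop+ on a deep ReLU stack occasionally settles in a poor
    basin (or, rarely, diverges); the elementwise *median* over a few
    restarts is robust to a single bad member while leaving good fits
    untouched.  All members share one architecture and training protocol and
    differ only in their initialization seed.
    """

    members: list[MLPModel]

    @property
    def architecture(self) -> MLPArchitecture:
        return self.members[0].architecture

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"members": [m.to_payload() for m in self.members]}, fh)

    @classmethod
    def from_json(cls, path) -> "MLPEnsemble":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls([MLPModel.from_payload(p) for p in payload["members"]])


def ensemble_forward(ensemble: MLPEnsemble, scores: np.ndarray) -> np.ndarray:
    """Median prediction over the committee."""
    return np.median([forward(m, scores) for m in ensemble.members], axis=0)


def train_ensemble(
    architecture: MLPArchitecture,
    scores: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    n_restarts: int = 3,
    seed: int = 0,
) -> MLPEnsemble:
    """Train ``n_restarts`` networks from different seeds on the same data."""
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    members = []
    for r in range(n_restarts):
        model = init_mlp(architecture, seed=seed + r)
        train_rprop_plus(model, scores, targets, config)
        members.append(model)
    return MLPEnsemble(members)


# ------------------------------------------------------------- data splits


def holdout_split(
    strata: Sequence, train_fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out split; returns (train_idx, test_idx).

    ``strata`` labels each sample (here: its concentration level).  The total
    train size is ``round(train_fraction * n)``; within strata the split is as
    even as the fraction allows, so every level with enough replicates appears
    in both partitions.  A stratum with a single sample goes to training with
    a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    strata = np.asarray(strata)
    n = strata.size
    rng = np.random.default_rng(seed)
    levels, inverse = np.unique(strata, return_inverse=True)
    groups = [np.flatnonzero(inverse == i) for i in range(levels.size)]
    n_train_total = int(round(train_fraction * n))
    base = [int(np.floor(train_fraction * g.size)) for g in groups]
    # distribute the remainder by largest fractional part, random ties
    frac = np.array([train_fraction * g.size - b for g, b in zip(groups, base)])
    order = rng.permutation(len(groups))
    order = order[np.argsort(-frac[order], kind="stable")]
    remainder = n_train_total - sum(base)
    for i in order[:remainder]:
        base[i] += 1
    train_idx, test_idx = [], []
    for g, k in zip(groups, base):
        if g.size == 1:
            warnings.warn(
                "stratum with a single sample placed in the training set",
                stacklevel=2,
            )
            train_idx.append(g)
            continue
        k = min(max(k, 1), g.size - 1)  # keep both partitions non-empty
        perm = rng.permutation(g)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    return train, test


def kfold_indices(strata: Sequence, k: int, seed: int = 0) -> list[np.ndarray]:
    """Concentration-stratified k folds with sizes differing by at most one."""
    strata = np.asarray(strata)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > strata.size:
        raise ValueError("k cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    assignment = np.empty(strata.size, dtype=int)
    offset = 0
    for level in np.unique(strata):
        idx = rng.permutation(np.flatnonzero(strata == level))
        assignment[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size
    return [np.flatnonzero(assignment == fold) for fold in range(k)]


def kfold_cv(
    scores: np.ndarray,
    targets: np.ndarray,
    architecture: MLPArchitecture,
    config: TrainConfig,
    k: int = 4,
    seed: int = 0,
    strata: Sequence | None = None,
) -> list[dict]:
    """Concentration-stratified k-fold cross-validation.

    Trains one network per fold (seeds derived from ``seed``) and returns a
    fold-metric dict (``fold``, ``rmse``, ``r2``, ``n``) per held-out fold.
    """
    from .metrics import r_squared, rmse  # local import: metrics depends on nothing here

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    targets = np.asarray(targets, dtype=float)
    strata = targets if strata is None else np.asarray(strata)
    folds = kfold_indices(strata, k, seed)
    results = []
    for fold, held in enumerate(folds):
        train = np.setdiff1d(np.arange(targets.size), held)
        model = init_mlp(architecture, seed=seed + 1000 + fold)
        train_rprop_plus(
            model, scores[train], targets[train], config
        )
        pred = forward(model, scores[held])
        results.append(
            {
                "fold": fold,
                "rmse": rmse(pred, targets[held]),
                "r2": r_squared(pred, targets[held]),
                "n": int(held.size),
            }
        )
    return results
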