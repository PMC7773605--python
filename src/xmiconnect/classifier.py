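"""Dual-output multilayer feedforward classifier and its training protocol.

The model is a densely connected feedforward network: input features feed
through four hidden layers of 12 rectified linear units (batch-normalized),
onto one or two logistic-sigmoid output units trained to minimize squared
error against 0/1 targets.  With two outputs the network classifies each
connectivity vector simultaneously by clinical diagnosis (ADHD = 0,
Control = 1) and by IGT performance (low = 0, high = 1) through shared
weights, so training constrains the hidden representation to features
informative for *both* decisions — the joint-probability reading of the
classification problem.

Training protocol: the majority diagnosis class is under-sampled at the
vector level so chance accuracy is 0.5, input features are randomly zeroed
with probability 0.4 at every presentation (feature dropout as data
augmentation), and stratified k-fold cross-validation on the joint
(diagnosis x IGT) label yields one trained model per fold.  The whole
procedure repeats over independent batches (default 6 batches x 5 folds
= 30 models), each with a fresh under-sample and fold plan, to give
distributional statistics of validation performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._exceptions import DegenerateInputError, SpecValidationError, TrainingError
from .connectivity import ConnectivityDataset

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "MultilayerClassifier",
    "ExperimentResult",
    "undersample_balance",
    "stratified_kfold",
    "input_dropout",
    "train_model",
    "predict_class",
    "run_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: input-feature dropout 0.4, squared-error loss, four 12-unit
    hidden layers; the optimizer settings (adam, 1e-3, 200 epochs,
    minibatch 16) are this package's recorded defaults."""

    dropout_p: float = 0.4
    epochs: int = 200
    minibatch: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "squared_error"
    hidden_layers: int = 4
    hidden_units: int = 12
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_p < 1.0):
            raise SpecValidationError("dropout_p must lie in [0, 1)")
        if self.epochs < 0 or self.minibatch < 1:
            raise SpecValidationError("epochs >= 0 and minibatch >= 1 required")
        if self.optimizer not in ("adam", "sgd"):
            raise SpecValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "squared_error":
            raise SpecValidationError(f"unsupported loss {self.loss!r}")


@dataclass(frozen=True)
class FoldPlan:
    """Cross-validation plan: fold index per sample, stratified on a joint label."""

    k: int
    assignment: np.ndarray  # fold index per sample
    strata: np.ndarray  # stratification label per sample

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def input_dropout(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Zero each entry independently with probability ``p`` (training-time
    data augmentation; identity when p == 0)."""
    if not (0.0 <= p < 1.0):
        raise SpecValidationError("dropout probability must lie in [0, 1)")
    if p == 0.0:
        return x
    mask = rng.random(x.shape) >= p
    return x * mask


def predict_class(outputs: np.ndarray) -> np.ndarray:
    """Threshold sigmoid outputs at 0.5 (values below 0.5 -> 0, else 1)."""
    return (np.asarray(outputs, dtype=float) >= 0.5).astype(int)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MultilayerClassifier(BaseEstimator, ClassifierMixin):
    """Feedforward network with batch-normalized ReLU hidden layers and
    sigmoid outputs, trained by minibatch gradient descent on squared error.

    scikit-learn estimator conventions apply: hyperparameters are
    constructor arguments, fitted state lives in trailing-underscore
    attributes (``weights_``, ``biases_``, batch-norm parameters,
    ``loss_curve_``), and ``fit``/``predict`` operate on arrays.  ``y`` may
    be (n,) for a single-output model or (n, 2) for the dual-output model
    (diagnosis, IGT class) with shared hidden weights.

    Parameters mirror :class:`TrainConfig`; ``dropout_p`` is *input-feature*
    dropout resampled at every presentation, not hidden-unit dropout.
    """

    def __init__(
        self,
        hidden_layers: int = 4,
        hidden_units: int = 12,
        dropout_p: float = 0.4,
        epochs: int = 200,
        minibatch: int = 16,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        bn_momentum: float = 0.9,
        bn_eps: float = 1e-5,
        random_state: int | None = None,
    ):
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.dropout_p = dropout_p
        self.epochs = epochs
        self.minibatch = minibatch
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.bn_momentum = bn_momentum
        self.bn_eps = bn_eps
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    def _init_params(self, n_features: int, n_outputs: int, rng: np.random.Generator):
        widths = [n_features] + [self.hidden_units] * self.hidden_layers + [n_outputs]
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.biases_ = [np.zeros(w) for w in widths[1:]]
        h = self.hidden_units
        self.bn_gamma_ = [np.ones(h) for _ in range(self.hidden_layers)]
        self.bn_beta_ = [np.zeros(h) for _ in range(self.hidden_layers)]
        self.bn_mean_ = [np.zeros(h) for _ in range(self.hidden_layers)]
        self.bn_var_ = [np.ones(h) for _ in range(self.hidden_layers)]
        self.n_features_in_ = n_features
        self.n_outputs_ = n_outputs

    # -- forward / backward ----------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """Run the network; returns (outputs, caches).  In training mode the
        batch-norm layers use minibatch statistics and update the running
        averages; otherwise the running statistics are used."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SpecValidationError(
                f"input width {X.shape[1]} != model input width {self.n_features_in_}"
            )
        caches = []
        a = X
        for l in range(self.hidden_layers):
            z = a @ self.weights_[l] + self.biases_[l]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                m = self.bn_momentum
                self.bn_mean_[l] = m * self.bn_mean_[l] + (1 - m) * mu
                self.bn_var_[l] = m * self.bn_var_[l] + (1 - m) * var
            else:
                mu, var = self.bn_mean_[l], self.bn_var_[l]
            inv_sd = 1.0 / np.sqrt(var + self.bn_eps)
            z_hat = (z - mu) * inv_sd
            z_bn = self.bn_gamma_[l] * z_hat + self.bn_beta_[l]
            h = np.maximum(z_bn, 0.0)
            caches.append((a, z_hat, inv_sd, z_bn, h))
            a = h
        z_out = a @ self.weights_[-1] + self.biases_[-1]
        y = _sigmoid(z_out)
        caches.append((a, y))
        return y, caches

    def _backward(self, caches, targets: np.ndarray):
        """Gradients of mean squared error wrt all trainable parameters."""
        a_last, y = caches[-1]
        b = y.shape[0]
        # L = mean over samples and outputs of (y - t)^2
        d_out = 2.0 * (y - targets) / (b * y.shape[1])
        d_z = d_out * y * (1.0 - y)
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        grads_g = [None] * self.hidden_layers
        grads_be = [None] * self.hidden_layers
        grads_w[-1] = a_last.T @ d_z
        grads_b[-1] = d_z.sum(axis=0)
        d_h = d_z @ self.weights_[-1].T
        for l in range(self.hidden_layers - 1, -1, -1):
            a_in, z_hat, inv_sd, z_bn, _h = caches[l]
            d_zbn = d_h * (z_bn > 0)
            grads_g[l] = (d_zbn * z_hat).sum(axis=0)
            grads_be[l] = d_zbn.sum(axis=0)
            d_zhat = d_zbn * self.bn_gamma_[l]
            d_z_lin = inv_sd * (
                d_zhat
                - d_zhat.mean(axis=0)
                - z_hat * (d_zhat * z_hat).mean(axis=0)
            )
            grads_w[l] = a_in.T @ d_z_lin
            grads_b[l] = d_z_lin.sum(axis=0)
            if l > 0:
                d_h = d_z_lin @ self.weights_[l].T
        return grads_w, grads_b, grads_g, grads_be

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultilayerClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise SpecValidationError("X must be 2-dimensional")
        self._single_output = y.ndim == 1
        targets = y.reshape(-1, 1) if self._single_output else y
        targets = targets.astype(float)
        if targets.shape[0] != X.shape[0]:
            raise SpecValidationError("X and y row counts differ")
        if not np.isin(targets, (0.0, 1.0)).all():
            raise SpecValidationError("targets must be binary 0/1")
        for col in range(targets.shape[1]):
            if np.ptp(targets[:, col]) == 0:
                raise DegenerateInputError(
                    f"output {col} has a single class in the training data"
                )

        rng = np.random.default_rng(self.random_state)
        self._init_params(X.shape[1], targets.shape[1], rng)
        self.classes_ = np.array([0, 1])
        self.loss_curve_ = []
        if self.epochs == 0:
            return self

        params = (
            self.weights_ + self.biases_ + self.bn_gamma_ + self.bn_beta_
        )
        if self.optimizer == "adam":
            m_state = [np.zeros_like(p) for p in params]
            v_state = [np.zeros_like(p) for p in params]
        step = 0
        n = X.shape[0]
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.minibatch):
                idx = order[start : start + self.minibatch]
                xb = input_dropout(X[idx], self.dropout_p, rng)
                yout, caches = self.forward(xb, training=True)
                loss = float(np.mean((yout - targets[idx]) ** 2))
                if not np.isfinite(loss):
                    raise TrainingError("non-finite training loss")
                epoch_loss += loss
                n_batches += 1
                gw, gb, gg, gbe = self._backward(caches, targets[idx])
                grads = gw + gb + gg + gbe
                step += 1
                lr = self.learning_rate
                if self.optimizer == "adam":
                    b1, b2, eps = 0.9, 0.999, 1e-8
                    for p, g, ms, vs in zip(params, grads, m_state, v_state):
                        ms *= b1
                        ms += (1 - b1) * g
                        vs *= b2
                        vs += (1 - b2) * g * g
                        mhat = ms / (1 - b1**step)
                        vhat = vs / (1 - b2**step)
                        p -= lr * mhat / (np.sqrt(vhat) + eps)
                else:
                    for p, g in zip(params, grads):
                        p -= lr * g
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
        return self

    # -- inference --------------------------------------------------------

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid output activations in (0, 1), shape (n, n_outputs)."""
        y, _ = self.forward(X, training=False)
        return y

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = predict_class(self.decision_function(X))
        return out.ravel() if getattr(self, "_single_output", False) else out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "n_features_in": self.n_features_in_,
            "n_outputs": self.n_outputs_,
            "single_output": bool(getattr(self, "_single_output", self.n_outputs_ == 1)),
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "bn_gamma": [g.tolist() for g in self.bn_gamma_],
            "bn_beta": [b.tolist() for b in self.bn_beta_],
            "bn_mean": [m.tolist() for m in self.bn_mean_],
            "bn_var": [v.tolist() for v in self.bn_var_],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MultilayerClassifier":
        model = cls(**payload["params"])
        model.n_features_in_ = payload["n_features_in"]
        model.n_outputs_ = payload["n_outputs"]
        model._single_output = payload["single_output"]
        model.classes_ = np.array([0, 1])
        model.weights_ = [np.asarray(w) for w in payload["weights"]]
        model.biases_ = [np.asarray(b) for b in payload["biases"]]
        model.bn_gamma_ = [np.asarray(g) for g in payload["bn_gamma"]]
        model.bn_beta_ = [np.asarray(b) for b in payload["bn_beta"]]
        model.bn_mean_ = [np.asarray(m) for m in payload["bn_mean"]]
        model.bn_var_ = [np.asarray(v) for v in payload["bn_var"]]
        return model

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "MultilayerClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    random_state: int | None = None,
) -> MultilayerClassifier:
    """Train one classifier from a :class:`TrainConfig` (thin estimator wrapper)."""
    model = MultilayerClassifier(
        hidden_layers=config.hidden_layers,
        hidden_units=config.hidden_units,
        dropout_p=config.dropout_p,
        epochs=config.epochs,
        minibatch=config.minibatch,
        learning_rate=config.learning_rate,
        optimizer=config.optimizer,
        random_state=random_state if random_state is not None else config.seed,
    )
    return model.fit(X, y)


def undersample_balance(data: ConnectivityDataset, seed: int | None = None) -> ConnectivityDataset:
    """Balance the dataset on diagnosis by vector-level under-sampling.

    All vectors of the minority diagnosis are kept; an equal number of
    majority vectors is drawn uniformly without replacement.  Chance
    accuracy on diagnosis is thereby fixed at 0.5.
    """
    diag = data.tags["diagnosis"].to_numpy()
    n0 = int((diag == 0).sum())
    n1 = int((diag == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateInputError("both diagnosis classes must be present")
    if n0 == n1:
        return data
    minority = 0 if n0 < n1 else 1
    rng = np.random.default_rng(seed)
    keep_minority = np.flatnonzero(diag == minority)
    majority_idx = np.flatnonzero(diag != minority)
    keep_majority = rng.choice(majority_idx, size=keep_minority.size, replace=False)
    keep = np.sort(np.concatenate([keep_minority, keep_majority]))
    return data.select_rows(keep)


def stratified_kfold(
    labels: np.ndarray, k: int, seed: int | None = None
) -> FoldPlan:
    """Stratified k-fold plan over a joint label vector.

    Validation folds partition the samples (each sample in exactly one
    validation fold) with per-fold class proportions matching the overall
    proportions within one sample.  Raises when a stratum is smaller than k.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:  # joint stratification on (diagnosis, igt_class)
        labels = np.array(["|".join(map(str, row)) for row in labels])
    if k < 2:
        raise SpecValidationError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise SpecValidationError(
            f"smallest stratum has {int(counts.min())} members < k={k}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(labels.shape[0], -1, dtype=int)
    for fold, (_, val_idx) in enumerate(splitter.split(np.zeros_like(labels), labels)):
        assignment[val_idx] = fold
    return FoldPlan(k=k, assignment=assignment, strata=labels)


@dataclass
class ExperimentResult:
    """All models and validation predictions from a batched k-fold experiment."""

    models: list[MultilayerClassifier]
    predictions: pd.DataFrame
    fold_plans: list[FoldPlan]
    outputs: tuple[str, ...]
    config: TrainConfig

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model_accuracies(self, output: str) -> np.ndarray:
        """Per-model validation accuracy for one output, in model order."""
        acc = []
        for (_, _), grp in self.predictions.groupby(["batch", "fold"], sort=True):
            acc.append(
                float((grp[f"{output}_pred"] == grp[f"{output}_true"]).mean())
            )
        return np.asarray(acc)

    def accuracy_summary(self) -> pd.DataFrame:
        rows = []
        for out in self.outputs:
            acc = self.model_accuracies(out)
            rows.append(
                {"output": out, "mean": acc.mean(), "sd": acc.std(ddof=1), "n_models": acc.size}
            )
        return pd.DataFrame(rows)


def run_experiment(
    data: ConnectivityDataset,
    n_batches: int = 6,
    k: int = 5,
    config: TrainConfig = TrainConfig(),
    outputs: Sequence[str] = ("diagnosis", "igt_class"),
    seed: int | None = None,
) -> ExperimentResult:
    """Batched stratified k-fold training (default 6 batches x 5 folds = 30 models).

    Per batch: fresh diagnosis under-sampling (a different random majority
    subset each batch), a fresh stratified fold plan on the joint label, one
    model per fold, and validation predictions so that every balanced-set
    sample is predicted exactly once within the batch.
    """
    outputs = tuple(outputs)
    root = np.random.SeedSequence(seed)
    batch_seeds = root.spawn(n_batches)
    models: list[MultilayerClassifier] = []
    fold_plans: list[FoldPlan] = []
    records = []
    for b in range(n_batches):
        us_seed, fold_seed, *model_seeds = [
            int(s.generate_state(1)[0] % (2**31)) for s in batch_seeds[b].spawn(2 + k)
        ]
        balanced = undersample_balance(data, seed=us_seed)
        strata = balanced.targets(("diagnosis", "igt_class"))
        plan = stratified_kfold(strata, k=k, seed=fold_seed)
        fold_plans.append(plan)
        X = balanced.features
        Y = balanced.targets(outputs)
        y_fit = Y[:, 0] if len(outputs) == 1 else Y
        for fold in range(k):
            tr = plan.train_indices(fold)
            va = plan.validation_indices(fold)
            model = train_model(X[tr], y_fit[tr] if y_fit.ndim == 1 else y_fit[tr, :],
                                config=config, random_state=model_seeds[fold])
            models.append(model)
            act = model.decision_function(X[va])
            pred = predict_class(act)
            for row, vi in enumerate(va):
                rec = {
                    "batch": b,
                    "fold": fold,
                    "participant_id": balanced.tags.iloc[vi]["participant_id"],
                    "run_id": balanced.tags.iloc[vi]["run_id"],
                }
                for col, out in enumerate(outputs):
                    rec[f"{out}_true"] = int(Y[vi, col])
                    rec[f"{out}_output"] = float(act[row, col])
                    rec[f"{out}_pred"] = int(pred[row, col])
                records.append(rec)
    return ExperimentResult(
        models=models,
        predictions=pd.DataFrame(records),
        fold_plans=fold_plans,
        outputs=outputs,
        config=config,
    )
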