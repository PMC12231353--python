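"""Small feed-forward surrogates trained with second-order least squares.

Two network roles, mirroring the study design:

* *classifier* — collision detector: [14, 25, 1], tanh hidden layer, linear
  output thresholded at 0.5 against {0, 1} targets, trained by
  Levenberg-Marquardt (LM) backpropagation with validation-based early
  stopping.
* *regressor* — strain predictor: [16 or 14, 10, 5, 1], two tanh hidden
  layers, linear output, trained by Bayesian-regularization backpropagation
  (LM steps on the penalized objective F = beta*E_D + alpha*E_W with MacKay
  evidence updates of alpha and beta).

Inputs are min-max scaled to [-1, 1] (fitted on training rows only);
regressor targets likewise.  Both trainers build the exact per-sample
Jacobian of the network output by backpropagation, so an LM step is
``dw = (J'J + mu*I)^-1 J'e`` with the usual accept/reject damping schedule.

Training a robustness ensemble repeats the fit from distinct initialization
seeds on the same data split; the reported model is the replicate with the
best metric on a designated evaluation table (ties break to the lowest
replicate index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "MLPModel",
    "TrainConfig",
    "ReplicateEnsemble",
    "TrainingError",
    "init_model",
    "forward",
    "forward_batched",
    "predict_label",
    "train_lm",
    "train_bayes_reg",
    "train_model",
    "train_replicates",
    "select_best",
    "ensemble_summary",
    "n_parameters",
    "strain16_features",
    "strain14_features",
    "CLASSIFIER_LAYERS",
    "REGRESSOR16_LAYERS",
    "REGRESSOR14_LAYERS",
]

CLASSIFIER_LAYERS = (14, 25, 1)
REGRESSOR16_LAYERS = (16, 10, 5, 1)
REGRESSOR14_LAYERS = (14, 10, 5, 1)


def strain16_features(angles: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Feature matrix for the 16-input strain regressor.

    The collision information is one-hot encoded as two complementary
    indicators (collision, no-collision) next to the 14 angles, for 16 inputs
    in total.  At training time ``flags`` are the dataset's true labels; at
    prediction time they are the collision classifier's predicted labels.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    f = np.asarray(flags, dtype=float).reshape(-1, 1)
    return np.hstack([angles, f, 1.0 - f])


def strain14_features(angles: np.ndarray) -> np.ndarray:
    """Feature matrix for the 14-input (angles-only) strain regressor."""
    return np.atleast_2d(np.asarray(angles, dtype=float))


class TrainingError(RuntimeError):
    """Raised when training encounters a non-finite objective."""


@dataclass
class MLPModel:
    """Feed-forward net with stored input/output normalization.

    ``weights[l]`` has shape (n_out, n_in); hidden activations are tanh, the
    output is linear.  ``input_min``/``input_max`` map features to [-1, 1];
    ``output_min``/``output_max`` (regressors only) map the target likewise.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    role: str = "regressor"  # "classifier" | "regressor"
    input_min: np.ndarray | None = None
    input_max: np.ndarray | None = None
    output_min: float | None = None
    output_max: float | None = None
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "MLPModel":
        return MLPModel(
            tuple(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.role,
            None if self.input_min is None else self.input_min.copy(),
            None if self.input_max is None else self.input_max.copy(),
            self.output_min,
            self.output_max,
            dict(self.metadata),
        )


@dataclass
class TrainConfig:
    """Trainer settings shared by the LM and Bayesian-regularization paths."""

    algorithm: str = "lm"  # "lm" | "bayes"
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    val_patience: int = 6
    grad_tol: float = 1e-7
    alpha_init: float = 0.0
    beta_init: float = 1.0
    evidence_tol: float = 1e-4  # relative alpha/beta/gamma stabilization
    evidence_patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (self.mu_increase > 1.0 > self.mu_decrease > 0.0):
            raise ValueError("need mu_increase > 1 > mu_decrease > 0")


def n_parameters(layer_sizes: Sequence[int]) -> int:
    return sum(
        layer_sizes[l + 1] * layer_sizes[l] + layer_sizes[l + 1]
        for l in range(len(layer_sizes) - 1)
    )


def init_model(
    layer_sizes: Sequence[int], seed: int = 0, role: str = "regressor"
) -> MLPModel:
    """Nguyen-Widrow-style initialization, reproducible from the seed.

    Hidden rows are random directions scaled to 0.7 * h^(1/n_in) with biases
    spread across the active region; the output layer starts small uniform.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError("invalid layer sizes")
    if sizes[-1] != 1:
        raise ValueError("only single-output networks are supported")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        n_in, n_out = sizes[l], sizes[l + 1]
        if l < len(sizes) - 2:  # hidden tanh layer
            w = rng.uniform(-1.0, 1.0, size=(n_out, n_in))
            norms = np.linalg.norm(w, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            beta = 0.7 * n_out ** (1.0 / n_in)
            w = beta * w / norms
            b = beta * np.linspace(-1.0, 1.0, n_out) * np.sign(w[:, 0] + 1e-300)
        else:  # linear output layer
            w = rng.uniform(-0.5, 0.5, size=(n_out, n_in))
            b = rng.uniform(-0.5, 0.5, size=n_out)
        weights.append(w)
        biases.append(np.asarray(b, dtype=float))
    return MLPModel(sizes, weights, biases, role=role)


# ---------------------------------------------------------------------------
# normalization


def _fit_input_norm(model: MLPModel, X: np.ndarray) -> None:
    model.input_min = X.min(axis=0).astype(float)
    model.input_max = X.max(axis=0).astype(float)


def _fit_output_norm(model: MLPModel, y: np.ndarray) -> None:
    model.output_min = float(y.min())
    model.output_max = float(y.max())


def _norm_inputs(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.input_min is None:
        return X
    span = model.input_max - model.input_min
    span = np.where(span == 0, 1.0, span)
    return 2.0 * (X - model.input_min) / span - 1.0


def _norm_target(model: MLPModel, y: np.ndarray) -> np.ndarray:
    if model.role != "regressor" or model.output_min is None:
        return y
    span = model.output_max - model.output_min
    if span == 0:  # constant target maps to 0 so regularization can zero the net
        return y - model.output_min
    return 2.0 * (y - model.output_min) / span - 1.0


def _denorm_output(model: MLPModel, yn: np.ndarray) -> np.ndarray:
    if model.role != "regressor" or model.output_min is None:
        return yn
    span = model.output_max - model.output_min
    if span == 0:
        return yn + model.output_min
    return (yn + 1.0) * span / 2.0 + model.output_min


# ---------------------------------------------------------------------------
# forward pass and Jacobian


def _forward_normed(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], Xn: np.ndarray
) -> list[np.ndarray]:
    """Activations per layer (input first, linear output last)."""
    acts = [Xn]
    a = Xn
    last = len(weights) - 1
    for l, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w.T + b
        a = z if l == last else np.tanh(z)
        acts.append(a)
    return acts


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Vectorized prediction; row outputs are independent of batch makeup."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"expected {model.layer_sizes[0]} input columns, got {X.shape[1]}"
        )
    yn = _forward_normed(model.weights, model.biases, _norm_inputs(model, X))[-1][:, 0]
    return _denorm_output(model, yn)


def forward_batched(
    model: MLPModel, X: np.ndarray, batch_size: int = 200_000
) -> np.ndarray:
    """Streamed prediction for very large design matrices."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0])
    for start in range(0, X.shape[0], batch_size):
        out[start : start + batch_size] = forward(model, X[start : start + batch_size])
    return out


def predict_label(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Classifier labels: raw linear output thresholded at 0.5."""
    if model.role != "classifier":
        raise ValueError("predict_label applies to classifier models")
    return (forward(model, X) >= 0.5).astype(int)


def _jacobian(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], Xn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Jacobian d yhat_i / d w (N, P) and predictions (N,).

    Parameter order: layer 0 weights (row-major), layer 0 biases, layer 1
    weights, ... matching :func:`_pack`.
    """
    acts = _forward_normed(weights, biases, Xn)
    N = Xn.shape[0]
    P = sum(w.size + b.size for w, b in zip(weights, biases))
    J = np.empty((N, P))
    # delta wrt pre-activation of each layer, starting from the linear output
    delta = np.ones((N, 1))
    # walk backwards, filling blocks; record column offsets first
    offsets = []
    off = 0
    for w, b in zip(weights, biases):
        offsets.append(off)
        off += w.size + b.size
    for l in range(len(weights) - 1, -1, -1):
        a_prev = acts[l]
        block = np.einsum("nj,ni->nji", delta, a_prev).reshape(N, -1)
        o = offsets[l]
        J[:, o : o + weights[l].size] = block
        J[:, o + weights[l].size : o + weights[l].size + biases[l].size] = delta
        if l > 0:
            delta = (delta @ weights[l]) * (1.0 - acts[l] ** 2)
    return J, acts[-1][:, 0]


def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([w.ravel(), b.ravel()]) for w, b in zip(model.weights, model.biases)]
    )


def _unpack(vec: np.ndarray, layer_sizes: Sequence[int]) -> tuple[list, list]:
    weights, biases, off = [], [], 0
    for l in range(len(layer_sizes) - 1):
        n_in, n_out = layer_sizes[l], layer_sizes[l + 1]
        weights.append(vec[off : off + n_out * n_in].reshape(n_out, n_in))
        off += n_out * n_in
        biases.append(vec[off : off + n_out].copy())
        off += n_out
    return weights, biases


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


def _sse(weights, biases, Xn, t) -> float:
    yhat = _forward_normed(weights, biases, Xn)[-1][:, 0]
    e = t - yhat
    return float(e @ e)


def train_lm(
    model: MLPModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
) -> tuple[MLPModel, dict]:
    """Levenberg-Marquardt backpropagation on the (normalized) SSE.

    Each epoch builds the per-sample Jacobian once; the damped step
    ``dw = (J'J + mu*I)^-1 J'e`` is retried with mu inflated until the SSE
    drops.  Stops at max_epochs, mu overflow, a vanishing gradient, or
    ``val_patience`` consecutive validation-SSE increases (restoring the
    best-validation weights).
    """
    Xn = _norm_inputs(model, np.atleast_2d(train[0]))
    t = _norm_target(model, np.asarray(train[1], dtype=float).reshape(-1))
    if Xn.shape[0] == 0:
        raise ValueError("training set is empty")
    has_val = val is not None and len(val[1]) > 0
    if has_val:
        Xv = _norm_inputs(model, np.atleast_2d(val[0]))
        tv = _norm_target(model, np.asarray(val[1], dtype=float).reshape(-1))
    w = _pack(model)
    sizes = model.layer_sizes
    mu = cfg.mu_init
    history = {"sse": [], "mu": [], "val_sse": []}
    best_val = math.inf
    best_w = w.copy()
    bad_epochs = 0
    P = w.size
    eye = np.eye(P)
    weights, biases = _unpack(w, sizes)
    for epoch in range(cfg.max_epochs):
        J, yhat = _jacobian(weights, biases, Xn)
        e = t - yhat
        sse = float(e @ e)
        if not np.isfinite(sse):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        g = J.T @ e
        if np.max(np.abs(g)) < cfg.grad_tol:
            break
        A = J.T @ J
        accepted = False
        while mu <= cfg.mu_max:
            try:
                c, low = linalg.cho_factor(A + mu * eye, check_finite=False)
                delta = linalg.cho_solve((c, low), g, check_finite=False)
            except linalg.LinAlgError:
                mu *= cfg.mu_increase
                continue
            w_try = w + delta
            weights_try, biases_try = _unpack(w_try, sizes)
            sse_try = _sse(weights_try, biases_try, Xn, t)
            if np.isfinite(sse_try) and sse_try < sse:
                w, weights, biases = w_try, weights_try, biases_try
                sse = sse_try
                mu = max(mu * cfg.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_increase
        history["sse"].append(sse)
        history["mu"].append(mu)
        if not accepted:
            break
        if has_val:
            vsse = _sse(weights, biases, Xv, tv)
            history["val_sse"].append(vsse)
            if vsse < best_val:
                best_val = vsse
                best_w = w.copy()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.val_patience:
                    w = best_w
                    weights, biases = _unpack(w, sizes)
                    break
    if has_val and best_val < _sse(weights, biases, Xv, tv):
        # keep the best-validation weights if they beat the final ones
        w = best_w
        weights, biases = _unpack(w, sizes)
    model.weights, model.biases = [a.copy() for a in weights], [b.copy() for b in biases]
    model.metadata.update(
        epochs_run=len(history["sse"]),
        final_objective=history["sse"][-1] if history["sse"] else _sse(weights, biases, Xn, t),
        algorithm="lm",
    )
    return model, history


# ---------------------------------------------------------------------------
# Bayesian regularization (MacKay evidence framework, Foresee-Hagan updates)


def train_bayes_reg(
    model: MLPModel,
    train: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[MLPModel, dict]:
    """Bayesian-regularization backpropagation.

    Minimizes F = beta*E_D + alpha*E_W (E_D = sum of squared errors,
    E_W = sum of squared weights) by damped LM steps; after each accepted
    step the evidence hyperparameters are updated:

        gamma = N_w - 2*alpha*tr(H^-1),  H = 2*beta*J'J + 2*alpha*I
        alpha = gamma / (2*E_W),         beta = (N - gamma) / (2*E_D)

    No validation set is consumed (validation rows are folded into training
    upstream, as is standard for this trainer).
    """
    Xn = _norm_inputs(model, np.atleast_2d(train[0]))
    t = _norm_target(model, np.asarray(train[1], dtype=float).reshape(-1))
    N = Xn.shape[0]
    if N == 0:
        raise ValueError("training set is empty")
    w = _pack(model)
    sizes = model.layer_sizes
    Nw = w.size
    eye = np.eye(Nw)
    alpha, beta = cfg.alpha_init, cfg.beta_init
    mu = cfg.mu_init
    history = {"sse": [], "alpha": [], "beta": [], "gamma": [], "objective": []}
    weights, biases = _unpack(w, sizes)
    stable = 0
    prev = None
    for epoch in range(cfg.max_epochs):
        J, yhat = _jacobian(weights, biases, Xn)
        e = t - yhat
        ED = float(e @ e)
        EW = float(w @ w)
        if not np.isfinite(ED):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        F = beta * ED + alpha * EW
        g = 2.0 * beta * (J.T @ e) - 2.0 * alpha * w  # -grad F
        if np.max(np.abs(g)) < cfg.grad_tol:
            break
        JtJ = J.T @ J
        H = 2.0 * beta * JtJ + 2.0 * alpha * eye
        accepted = False
        while mu <= cfg.mu_max:
            try:
                c, low = linalg.cho_factor(H + mu * eye, check_finite=False)
                delta = linalg.cho_solve((c, low), g, check_finite=False)
            except linalg.LinAlgError:
                mu *= cfg.mu_increase
                continue
            w_try = w + delta
            weights_try, biases_try = _unpack(w_try, sizes)
            ED_try = _sse(weights_try, biases_try, Xn, t)
            F_try = beta * ED_try + alpha * float(w_try @ w_try)
            if np.isfinite(F_try) and F_try < F:
                w, weights, biases = w_try, weights_try, biases_try
                ED, EW = ED_try, float(w @ w)
                mu = max(mu * cfg.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_increase
        if not accepted:
            break
        # evidence update at the new point
        J, yhat = _jacobian(weights, biases, Xn)
        H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * eye
        try:
            c, low = linalg.cho_factor(H, check_finite=False)
            tr_hinv = float(np.trace(linalg.cho_solve((c, low), eye, check_finite=False)))
        except linalg.LinAlgError:
            tr_hinv = float(np.trace(np.linalg.pinv(H)))
        gamma = Nw - 2.0 * alpha * tr_hinv
        # the effective number of well-determined parameters can exceed
        # neither the weight count nor the data count (keeps beta positive)
        gamma = min(max(gamma, 1e-12), float(Nw), float(max(N - 1, 1)))
        alpha = max(gamma / (2.0 * max(EW, 1e-300)), 1e-300)
        beta = max((N - gamma), 1e-3) / (2.0 * max(ED, 1e-300))
        history["sse"].append(ED)
        history["alpha"].append(alpha)
        history["beta"].append(beta)
        history["gamma"].append(gamma)
        history["objective"].append(beta * ED + alpha * EW)
        if prev is not None:
            rel = max(
                abs(alpha - prev[0]) / max(abs(prev[0]), 1e-300),
                abs(beta - prev[1]) / max(abs(prev[1]), 1e-300),
                abs(gamma - prev[2]) / max(abs(prev[2]), 1e-300),
            )
            stable = stable + 1 if rel < cfg.evidence_tol else 0
            if stable >= cfg.evidence_patience:
                break
        prev = (alpha, beta, gamma)
    model.weights, model.biases = [a.copy() for a in weights], [b.copy() for b in biases]
    model.metadata.update(
        epochs_run=len(history["sse"]),
        final_objective=history["objective"][-1] if history["objective"] else None,
        algorithm="bayes",
        alpha=alpha,
        beta=beta,
        gamma=history["gamma"][-1] if history["gamma"] else None,
    )
    return model, history


# ---------------------------------------------------------------------------
# high-level training


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    layer_sizes: Sequence[int],
    cfg: TrainConfig,
    seed: int | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    role: str = "regressor",
) -> tuple[MLPModel, dict]:
    """Initialize, fit normalization on training rows, and train.

    For the Bayesian-regularization path any validation rows are folded into
    the training set (the trainer regularizes instead of early-stopping).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    if cfg.algorithm == "bayes" and X_val is not None and len(X_val) > 0:
        X = np.vstack([X, np.atleast_2d(X_val)])
        y = np.concatenate([y, np.asarray(y_val, dtype=float).reshape(-1)])
        X_val, y_val = None, None
    model = init_model(layer_sizes, seed=cfg.seed if seed is None else seed, role=role)
    _fit_input_norm(model, X)
    if role == "regressor":
        _fit_output_norm(model, y)
    if cfg.algorithm == "bayes":
        return train_bayes_reg(model, (X, y), cfg)
    val = None if X_val is None else (np.atleast_2d(X_val), np.asarray(y_val, float).reshape(-1))
    return train_lm(model, (X, y), val, cfg)


@dataclass
class ReplicateEnsemble:
    """Repeated fits from distinct seeds, with per-model held-out metrics."""

    models: list
    metrics: list  # one dict per replicate: {"accuracy": ...} or {"rmse": ...}
    seeds: list
    failures: list  # (replicate_index, message)
    metric_name: str


def _metric_value(model: MLPModel, X_eval, y_eval, metric: str) -> float:
    if metric == "accuracy":
        pred = predict_label(model, X_eval)
        return float(100.0 * np.mean(pred == np.asarray(y_eval).astype(int)))
    if metric == "rmse":
        pred = forward(model, X_eval)
        return float(np.sqrt(np.mean((pred - np.asarray(y_eval, float)) ** 2)))
    raise ValueError(f"unknown metric {metric!r}")


def train_replicates(
    X: np.ndarray,
    y: np.ndarray,
    layer_sizes: Sequence[int],
    cfg: TrainConfig,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    n_replicates: int = 100,
    base_seed: int = 0,
    role: str = "regressor",
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> ReplicateEnsemble:
    """Train ``n_replicates`` models from distinct seeds on the same split.

    Each replicate's metric (classification accuracy or RMSE) is recorded on
    the designated evaluation table.  Individual training failures are
    recorded, not fatal, unless more than half the replicates fail.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    metric = "accuracy" if role == "classifier" else "rmse"
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(n_replicates, dtype=np.uint32)]
    models, metrics, failures = [], [], []
    for i, s in enumerate(seeds):
        try:
            model, _ = train_model(
                X, y, layer_sizes, cfg, seed=s, X_val=X_val, y_val=y_val, role=role
            )
            model.metadata["seed"] = s
            models.append(model)
            metrics.append({metric: _metric_value(model, X_eval, y_eval, metric)})
        except TrainingError as err:
            models.append(None)
            metrics.append(None)
            failures.append((i, str(err)))
    if len(failures) > n_replicates / 2:
        raise TrainingError(f"{len(failures)}/{n_replicates} replicates failed")
    return ReplicateEnsemble(models, metrics, seeds, failures, metric)


def select_best(ensemble: ReplicateEnsemble, metric: str | None = None) -> MLPModel:
    """Best replicate by accuracy (max) or rmse (min); ties -> lowest index."""
    metric = metric or ensemble.metric_name
    best_idx, best_val = None, None
    for i, m in enumerate(ensemble.metrics):
        if m is None:
            continue
        v = m[metric]
        better = (
            best_val is None
            or (metric == "accuracy" and v > best_val)
            or (metric != "accuracy" and v < best_val)
        )
        if better:
            best_idx, best_val = i, v
    if best_idx is None:
        raise ValueError("ensemble has no successful replicates")
    return ensemble.models[best_idx]


def ensemble_summary(ensemble: ReplicateEnsemble) -> dict:
    """Best and mean-of-replicates metric, mirroring best (mean) reporting."""
    vals = [m[ensemble.metric_name] for m in ensemble.metrics if m is not None]
    best = max(vals) if ensemble.metric_name == "accuracy" else min(vals)
    return {
        "metric": ensemble.metric_name,
        "best": float(best),
        "mean": float(np.mean(vals)),
        "n": len(vals),
    }
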