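"""Differentiable surrogate models B(xi1, xi2, xi3, tau) fitted to scaled data.

The extrapolation step replaces the scattered measurements by a smooth map
from scaled space-time to the scaled field, so that values and partial
derivatives can be evaluated anywhere.  Two interchangeable backends satisfy
the same contract:

``MLPSurrogate``
    A small dense feed-forward network (default 4 -> 16 -> 32 -> 32 -> 32 -> 1,
    tanh activations) trained by mini-batch Adam on the mean-squared data
    misfit with per-layer L2 weight regularization.  Input derivatives up to
    second order are computed by forward-mode propagation of directional
    derivatives through the layers, which is exact (identical to automatic
    differentiation, up to floating point).

``AnalyticSurrogate``
    Wraps a user-supplied smooth function together with its closed-form
    derivatives.  It makes every downstream stage exact, so differentiation
    and identification can be validated independently of training noise.

The printed training objective is

    J1(alpha) = 1/2 sum_i |B_alpha(xi_i, tau_i) - B_i|^2 + c_alpha/2 ||alpha||^2

exposed as :func:`j1_loss`; the optimizer works on the equivalent per-batch
mean-squared form with L2 on the kernels only (biases unpenalized), the usual
deep-learning realization of the same objective.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .datasets import ScaledDataset

__all__ = [
    "SurrogateConfig",
    "SurrogateModel",
    "MLPSurrogate",
    "AnalyticSurrogate",
    "FitHistory",
    "build_surrogate",
    "fit_surrogate",
    "j1_loss",
    "predict",
    "save_surrogate",
    "load_surrogate",
]

# activations available for the network backend; the differentiation step
# needs second derivatives, so only C^2 functions are admitted
_SMOOTH_ACTIVATIONS = {
    "tanh": (
        np.tanh,
        lambda s: 1.0 - s * s,          # f' expressed through s = f(z)
    ),
}
_NON_SMOOTH = {"relu", "leaky_relu", "hardtanh", "abs", "heaviside"}


class ConfigError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


class CapabilityError(NotImplementedError):
    pass


@dataclasses.dataclass(frozen=True)
class SurrogateConfig:
    """Hyperparameters of the network surrogate.

    Defaults: hidden layers 16, 32, 32, 32 with
    tanh activations, L2 kernel coefficient 1e-6, Adam learning rate 1e-4,
    batch size 16 (2 and 64 are the other studied values), 100 epochs.
    """

    hidden_layers: tuple[int, ...] = (16, 32, 32, 32)
    activation: str = "tanh"
    l2_coef: float = 1e-6
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation in _NON_SMOOTH:
            raise ConfigError(
                f"activation {self.activation!r} is not twice differentiable; "
                "the differentiation step requires second derivatives"
            )
        if self.activation not in _SMOOTH_ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")
        if any(w < 1 for w in self.hidden_layers):
            raise ConfigError("layer widths must be >= 1")
        if self.l2_coef < 0:
            raise ConfigError("l2_coef must be >= 0")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("learning_rate, batch_size, epochs must be positive")
        object.__setattr__(self, "hidden_layers", tuple(int(w) for w in self.hidden_layers))


@dataclasses.dataclass(frozen=True)
class FitHistory:
    """Per-epoch training loss (data misfit + regularization), and the seed used."""

    losses: np.ndarray
    seed: int

    @property
    def final_loss(self) -> float:
        return float(self.losses[-1])


class SurrogateModel:
    """Common contract: evaluate the field and its input derivatives anywhere."""

    backend = "abstract"

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Field values at points of shape (n, 4): columns xi1, xi2, xi3, tau."""
        raise NotImplementedError

    def input_derivative(self, points: np.ndarray, axis: int, order: int) -> np.ndarray:
        """Pure partial derivative d^order B / d u_axis^order, axis in 0..3 (3 = tau)."""
        raise NotImplementedError


class MLPSurrogate(SurrogateModel):
    """Dense feed-forward network 4 -> hidden_layers -> 1, linear output layer."""

    backend = "network"

    def __init__(self, config: SurrogateConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (4, *config.hidden_layers, 1)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # Glorot-uniform initialization, deterministic under the seed
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._act, self._dact = _SMOOTH_ACTIVATIONS[config.activation]

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    # ---- forward passes -------------------------------------------------

    def _forward(self, X: np.ndarray, keep: bool = False):
        a = X
        acts = [a]
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = self._act(z) if i < len(self.weights) - 1 else z
            acts.append(a)
        return (acts if keep else a)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return self._forward(points)[:, 0]

    def input_derivative(self, points: np.ndarray, axis: int, order: int) -> np.ndarray:
        """Exact pure derivative along one input axis, by forward-mode propagation.

        Directional first and second derivatives are pushed through each layer:
        a linear layer maps them linearly, and an elementwise activation f gives
        s' = f'(z) z' and s'' = f'(z) z'' + f''(z) (z')^2.
        """
        if order == 0:
            return self.evaluate(points)
        if order not in (1, 2):
            raise CapabilityError("network backend supports derivative order <= 2")
        points = np.atleast_2d(np.asarray(points, float))
        a = points
        da = np.zeros_like(a)
        da[:, axis] = 1.0
        dda = np.zeros_like(a)
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            dz = da @ W
            ddz = dda @ W
            if i < last:
                s = self._act(z)
                fp = self._dact(s)
                ds = fp * dz
                # tanh: f'' = -2 s f', written via already-computed quantities
                dds = fp * ddz - 2.0 * s * ds * dz
                a, da, dda = s, ds, dds
            else:
                a, da, dda = z, dz, ddz
        return (da if order == 1 else dda)[:, 0]

    # ---- training -------------------------------------------------------

    def _batch_grad(self, Xb: np.ndarray, yb: np.ndarray):
        """Loss and parameter gradients of mean-squared misfit + L2 kernel penalty."""
        acts = self._forward(Xb, keep=True)
        pred = acts[-1][:, 0]
        resid = pred - yb
        m = Xb.shape[0]
        c = self.config.l2_coef
        loss = float(np.mean(resid**2)) + c * sum(float(np.sum(W * W)) for W in self.weights)
        delta = (2.0 / m) * resid[:, None]  # dL/dz at the linear output
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            gW[i] = a_prev.T @ delta + 2.0 * c * self.weights[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * self._dact(acts[i])
        return loss, gW, gb


class AnalyticSurrogate(SurrogateModel):
    """Oracle backend: a smooth closed-form field with exact derivatives.

    Parameters
    ----------
    value : callable (n, 4) -> (n,)
        The field B(xi, tau).
    derivative : callable (points, axis, order) -> (n,)
        Its exact pure partial derivatives, same axis convention as the
        network backend (axis 3 is tau).  If omitted, only order 0 works.
    """

    backend = "analytic-oracle"

    def __init__(
        self,
        value: Callable[[np.ndarray], np.ndarray],
        derivative: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
    ):
        self._value = value
        self._derivative = derivative

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return np.asarray(self._value(points), float)

    def input_derivative(self, points: np.ndarray, axis: int, order: int) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        if order == 0:
            return self.evaluate(points)
        if self._derivative is None:
            raise CapabilityError("this analytic oracle was built without derivatives")
        return np.asarray(self._derivative(points, axis, order), float)


def build_surrogate(config: SurrogateConfig | None = None) -> MLPSurrogate:
    """Untrained network surrogate; initialization is deterministic given the seed."""
    return MLPSurrogate(config or SurrogateConfig())


def j1_loss(model: SurrogateModel, data: ScaledDataset, c_alpha: float = 0.0) -> float:
    """The extrapolation objective: half the sum of squared residuals over the
    data points plus (c_alpha/2) times the squared parameter norm."""
    resid = model.evaluate(data.points()) - data.B
    value = 0.5 * float(np.sum(resid**2))
    if c_alpha > 0:
        if not isinstance(model, MLPSurrogate):
            raise CapabilityError("parameter norm is only defined for the network backend")
        value += 0.5 * c_alpha * float(np.sum(model.parameter_vector() ** 2))
    return value


def fit_surrogate(
    model: MLPSurrogate,
    data: ScaledDataset,
    config: SurrogateConfig | None = None,
) -> tuple[MLPSurrogate, FitHistory]:
    """Train the network by mini-batch Adam; per-epoch shuffling is seeded.

    The recorded epoch loss is the mean over batches of the batch loss.
    Adam runs with the conventional constants beta1=0.9, beta2=0.999,
    eps=1e-7.  Raises :class:`DivergenceError` if the loss turns non-finite.
    """
    config = config or model.config
    if data.p == 0:
        raise ValueError("cannot fit on an empty dataset")
    if config.batch_size > data.p:
        raise ValueError(f"batch_size {config.batch_size} exceeds p={data.p}")
    X = data.points()
    y = data.B
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from init
    params = model.weights + model.biases
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-7
    step = 0
    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(data.p)
        epoch_losses = []
        for start in range(0, data.p, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, gW, gb = model._batch_grad(X[idx], y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            epoch_losses.append(loss)
            grads = gW + gb
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for p, g, mi, vi in zip(params, grads, m_adam, v_adam):
                mi += (1 - b1) * (g - mi)
                vi += (1 - b2) * (g * g - vi)
                p -= lr_t * mi / (np.sqrt(vi) + eps)
        losses[epoch] = np.mean(epoch_losses)
    return model, FitHistory(losses=losses, seed=config.seed)


def predict(model: SurrogateModel, points: np.ndarray) -> np.ndarray:
    """Field values at arbitrary scaled space-time points."""
    return model.evaluate(points)


def save_surrogate(model: MLPSurrogate, path: str | Path) -> None:
    """Checkpoint the network (weights, biases, config) into one npz archive."""
    payload = {f"W{i}": W for i, W in enumerate(model.weights)}
    payload.update({f"b{i}": b for i, b in enumerate(model.biases)})
    payload["config"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **payload)


def load_surrogate(path: str | Path) -> MLPSurrogate:
    with np.load(Path(path)) as f:
        cfg_dict = json.loads(bytes(f["config"]).decode())
        cfg_dict["hidden_layers"] = tuple(cfg_dict["hidden_layers"])
        model = MLPSurrogate(SurrogateConfig(**cfg_dict))
        model.weights = [f[f"W{i}"] for i in range(len(model.weights))]
        model.biases = [f[f"b{i}"] for i in range(len(model.biases))]
    return model
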