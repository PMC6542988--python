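"""Feed-forward multilayer network: layer specs, initialization, forward pass.

The networks here are plain fully connected stacks

    y_i = W_i · a_{i-1},   a_i = f(y_i),   a_0 = x

with no bias terms. Weight matrices are stored as (fan_out × fan_in) so a
column vector of activations propagates by left multiplication. Activation
derivatives are expressed as functions of the activation *output* a rather
than the pre-activation y (for tanh, f'(a) = 1 − a²), which is the form the
local credit-assignment rules consume.

Everything runs in float64; inputs may be single vectors of shape (fan_in,)
or batches of shape (fan_in, n_examples) — the trace keeps whichever shape
was given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ActivationKind",
    "LayerSpec",
    "NetworkParams",
    "ForwardTrace",
    "InitRule",
    "init_weights",
    "forward",
    "activation",
    "activation_derivative_from_output",
    "validate_chain",
]


class ValidationError(ValueError):
    """Raised when a structural precondition on inputs is violated."""


class ShapeError(ValidationError):
    """Raised when array dimensions do not chain."""


class ActivationKind(str, Enum):
    """Supported elementwise nonlinearities.

    Each kind provides f and a derivative expressible in terms of the
    activation output a. The relu derivative at exactly 0 is defined as 0.
    """

    TANH = "tanh"
    RELU = "relu"
    SIGMOID = "sigmoid"
    LINEAR = "linear"


_ACT_F: dict[ActivationKind, Callable[[np.ndarray], np.ndarray]] = {
    ActivationKind.TANH: np.tanh,
    ActivationKind.RELU: lambda y: np.maximum(y, 0.0),
    ActivationKind.SIGMOID: lambda y: 1.0 / (1.0 + np.exp(-y)),
    ActivationKind.LINEAR: lambda y: np.asarray(y, dtype=float),
}

_ACT_DF: dict[ActivationKind, Callable[[np.ndarray], np.ndarray]] = {
    ActivationKind.TANH: lambda a: 1.0 - a * a,
    ActivationKind.RELU: lambda a: (a > 0).astype(float),
    ActivationKind.SIGMOID: lambda a: a * (1.0 - a),
    ActivationKind.LINEAR: lambda a: np.ones_like(np.asarray(a, dtype=float)),
}


def activation(kind: ActivationKind, y: np.ndarray) -> np.ndarray:
    """Apply f elementwise to a pre-activation array."""
    kind = ActivationKind(kind)
    return _ACT_F[kind](np.asarray(y, dtype=float))


def activation_derivative_from_output(kind: ActivationKind, a: np.ndarray) -> np.ndarray:
    """Evaluate f' from the activation output a, consistently with `forward`.

    tanh: 1 − a²; sigmoid: a(1 − a); relu: 1 where a > 0 else 0; linear: 1.
    """
    try:
        kind = ActivationKind(kind)
    except ValueError as exc:
        raise ValidationError(f"unknown activation kind: {kind!r}") from exc
    return _ACT_DF[kind](np.asarray(a, dtype=float))


@dataclass(frozen=True)
class LayerSpec:
    """One fully connected layer: fan_in inputs, fan_out units, activation."""

    fan_in: int
    fan_out: int
    activation: ActivationKind = ActivationKind.TANH

    def __post_init__(self) -> None:
        if self.fan_in <= 0 or self.fan_out <= 0:
            raise ValidationError(
                f"layer dimensions must be positive, got {self.fan_in}x{self.fan_out}"
            )
        object.__setattr__(self, "activation", ActivationKind(self.activation))


def validate_chain(specs: Sequence[LayerSpec]) -> None:
    """Check fan_in of layer i equals fan_out of layer i−1."""
    if not specs:
        raise ValidationError("network needs at least one layer")
    for prev, cur in zip(specs, specs[1:]):
        if cur.fan_in != prev.fan_out:
            raise ShapeError(
                f"layer specs do not chain: fan_out {prev.fan_out} feeds fan_in {cur.fan_in}"
            )


@dataclass
class NetworkParams:
    """Ordered forward weight matrices W_i, shape (fan_out_i × fan_in_i)."""

    weights: list[np.ndarray]
    specs: list[LayerSpec] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights], list(self.specs))


@dataclass
class ForwardTrace:
    """Per-layer pre-activations y_i and activations a_i retained for the
    backward pass, plus the input x (a_0)."""

    x: np.ndarray
    preactivations: list[np.ndarray]
    activations: list[np.ndarray]

    @property
    def output(self) -> np.ndarray:
        return self.activations[-1]

    def activation_input(self, layer: int) -> np.ndarray:
        """a_{layer-1}: the input the given 1-based layer saw."""
        return self.x if layer == 1 else self.activations[layer - 2]


# --- initialization ---------------------------------------------------------

#: Built-in weight-init bound rules, as functions of fan_out. The uniform
#: range is [−c, +c] with c given by the active rule.
INIT_RULES: dict[str, Callable[[int], float]] = {
    "inv_sqrt_fan_out": lambda fan_out: 1.0 / np.sqrt(fan_out),
    "inv_fan_out": lambda fan_out: 1.0 / fan_out,
}

#: Standard uniform fan-based scaling.
DEFAULT_INIT_RULE = "inv_sqrt_fan_out"

InitRule = Callable[[int], float]


def init_weights(
    specs: Sequence[LayerSpec],
    seed: int,
    init_rule: str | InitRule = DEFAULT_INIT_RULE,
) -> NetworkParams:
    """Draw each W_i i.i.d. uniform on [−c_i, +c_i], c_i = rule(fan_out_i).

    Identical seed (and rule) gives bitwise-identical parameters.
    """
    validate_chain(specs)
    rule: InitRule = INIT_RULES[init_rule] if isinstance(init_rule, str) else init_rule
    rng = np.random.default_rng(seed)
    weights = []
    for spec in specs:
        c = float(rule(spec.fan_out))
        weights.append(rng.uniform(-c, c, size=(spec.fan_out, spec.fan_in)))
    return NetworkParams(weights, list(specs))


def forward(params: NetworkParams, x: np.ndarray) -> ForwardTrace:
    """Run the feed-forward pass, retaining all intermediates.

    x may be (fan_in,) for one example or (fan_in, n) for a batch.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in network input")
    fan_in = params.weights[0].shape[1]
    if x.shape[0] != fan_in:
        raise ShapeError(f"input length {x.shape[0]} != first-layer fan_in {fan_in}")
    preacts: list[np.ndarray] = []
    acts: list[np.ndarray] = []
    a = x
    for w, spec in zip(params.weights, params.specs):
        if w.shape[1] != a.shape[0]:
            raise ShapeError(
                f"weight shape {w.shape} cannot consume activation of length {a.shape[0]}"
            )
        y = w @ a
        a = activation(spec.activation, y)
        preacts.append(y)
        acts.append(a)
    return ForwardTrace(x=x, preactivations=preacts, activations=acts)
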