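"""Error signals under BP, DFA and sparse DFA, gradients, and SGD updates.

Three credit-assignment rules share one interface. Writing δa_l for the error
delivered to layer l and e for the output error (softmax output minus the
one-hot target, so δa_n = e is the exact loss gradient at the logits):

BP (backpropagation)
    δa_l = W_{l+1}ᵀ · δa_{l+1} ⊙ f'(a_l) — the chain rule; every hidden layer
    needs the transposed weights of the layer above (the weight transport
    problem).
DFA (direct feedback alignment)
    δa_l = B_l · e ⊙ f'(a_l) — a fixed random matrix B_l carries the output
    error straight to layer l; no layer's error depends on any other layer.
SDFA / SSDFA
    Identical to DFA except B_l is sparse. In the single-connection extreme
    (SSDFA, one nonzero per row) each neuron's error is the product of three
    scalars: its one feedback weight, the one error component it is wired to,
    and its own f'(a).

All rules produce weight gradients by the same outer product
δW_l = δa_l ⊗ a_{l-1} (averaged over the batch) and update with plain SGD
with multiplicative per-epoch decay. Feedback matrices are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .feedback import FeedbackMatrix
from .network import (
    ActivationKind,
    ForwardTrace,
    NetworkParams,
    ShapeError,
    ValidationError,
    activation_derivative_from_output,
)

__all__ = [
    "CreditRule",
    "ErrorSignals",
    "UpdateConfig",
    "output_error",
    "softmax",
    "bp_errors",
    "dfa_errors",
    "dfa_layer_error",
    "sdfa_neuron_error",
    "weight_gradients",
    "sgd_step",
    "cross_entropy_loss",
]


class CreditRule(str, Enum):
    """Which rule supplies the hidden-layer error signals.

    SDFA with a dense feedback matrix reproduces DFA exactly; SSDFA is SDFA
    whose feedback rows each hold exactly one nonzero. The computation is
    shared — only the feedback matrices differ — so a single SDFA code path
    serves DFA, SDFA and SSDFA.
    """

    BP = "BP"
    DFA = "DFA"
    SDFA = "SDFA"


@dataclass
class ErrorSignals:
    """Per-layer error vectors δa_l plus the output error e (δa_n = e)."""

    deltas: list[np.ndarray]
    output_error: np.ndarray


@dataclass(frozen=True)
class UpdateConfig:
    """SGD hyperparameters: rate after k epochs = learning_rate · decay^k."""

    learning_rate: float
    decay: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0.0 < self.decay <= 1.0):
            raise ValidationError("decay must lie in (0, 1]")

    def rate_at(self, epoch: int) -> float:
        return self.learning_rate * self.decay**epoch


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along axis 0 (class axis)."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=0, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=0, keepdims=True)


def _check_one_hot(target: np.ndarray) -> None:
    t = np.asarray(target)
    ok = np.all((t == 0) | (t == 1)) and np.all(t.sum(axis=0) == 1)
    if not ok:
        raise ValidationError("target must be one-hot (columns summing to 1)")


def output_error(a_n: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Classification error e = softmax(a_n) − target.

    a_n is the output layer's (linear) activation, read as logits; with
    softmax cross-entropy loss this e is exactly the loss gradient with
    respect to the logits, so δa_n = e needs no further activation gate.
    Components of e sum to 0 for every example.
    """
    a_n = np.asarray(a_n, dtype=float)
    target = np.asarray(target, dtype=float)
    if a_n.shape != target.shape:
        raise ShapeError(f"output shape {a_n.shape} != target shape {target.shape}")
    _check_one_hot(target)
    return softmax(a_n) - target


def cross_entropy_loss(a_n: np.ndarray, target: np.ndarray) -> float:
    """Mean softmax cross-entropy over the batch (scalar, natural log)."""
    p = softmax(a_n)
    target = np.asarray(target, dtype=float)
    eps = np.finfo(float).tiny
    per_example = -(target * np.log(p + eps)).sum(axis=0)
    return float(np.mean(per_example))


def bp_errors(params: NetworkParams, trace: ForwardTrace, e: np.ndarray) -> ErrorSignals:
    """Backpropagation: δa_n = e; δa_l = W_{l+1}ᵀ · δa_{l+1} ⊙ f'(a_l)."""
    n = params.n_layers
    deltas: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    deltas[n - 1] = np.asarray(e, dtype=float)
    for l in range(n - 1, 0, -1):  # 1-based layer l computed from layer l+1
        w_down = params.weights[l]
        a_l = trace.activations[l - 1]
        kind = params.specs[l - 1].activation
        deltas[l - 1] = (w_down.T @ deltas[l]) * activation_derivative_from_output(kind, a_l)
    return ErrorSignals(deltas=deltas, output_error=deltas[n - 1])


def dfa_layer_error(
    B: np.ndarray, e: np.ndarray, a_l: np.ndarray, kind: ActivationKind
) -> np.ndarray:
    """One hidden layer's direct feedback error: B · e ⊙ f'(a_l).

    Deliberately takes only this layer's feedback matrix, the output error
    and this layer's own activation — the locality of DFA is structural, the
    function cannot see any forward weight or any other layer's error.
    """
    B = np.asarray(B, dtype=float)
    e = np.asarray(e, dtype=float)
    if B.shape[1] != e.shape[0]:
        raise ShapeError(f"feedback shape {B.shape} cannot consume error of length {e.shape[0]}")
    return (B @ e) * activation_derivative_from_output(kind, a_l)


def dfa_errors(
    feedbacks: list[FeedbackMatrix | np.ndarray | None],
    trace: ForwardTrace,
    e: np.ndarray,
    kinds: list[ActivationKind] | None = None,
    specs=None,
) -> ErrorSignals:
    """Direct feedback: δa_n = e; δa_l = B_l · e ⊙ f'(a_l) for hidden l.

    `feedbacks` holds one matrix per hidden layer (entry for the output layer,
    if present, is ignored — δa_n = e always). Activation kinds come from
    `specs` (LayerSpec list) or `kinds`.
    """
    if specs is not None:
        kinds = [s.activation for s in specs]
    if kinds is None:
        raise ValidationError("dfa_errors needs activation kinds (pass specs or kinds)")
    n = len(kinds)
    e = np.asarray(e, dtype=float)
    deltas: list[np.ndarray] = []
    for l in range(1, n):  # hidden layers, 1-based
        fb = feedbacks[l - 1] if l - 1 < len(feedbacks) else None
        if fb is None:
            raise ValidationError(f"missing feedback matrix for hidden layer {l}")
        B = fb.values if isinstance(fb, FeedbackMatrix) else np.asarray(fb, dtype=float)
        deltas.append(dfa_layer_error(B, e, trace.activations[l - 1], kinds[l - 1]))
    deltas.append(e)
    return ErrorSignals(deltas=deltas, output_error=e)


def sdfa_neuron_error(
    b_row: np.ndarray,
    e: np.ndarray,
    a_li: float,
    kind: ActivationKind,
    mac_counter: list[int] | None = None,
) -> float:
    """One neuron's sparse-DFA error: (b_row · e) · f'(a_li).

    Touches only the error components where b_row is nonzero; with a single
    nonzero B_{l,i,j} this is the three-scalar product B_{l,i,j}·e_j·f'(a_li).
    If `mac_counter` (a one-element list) is given, it is incremented by one
    multiply-accumulate per nonzero plus one final multiply, the count the
    hardware cost model charges per neuron.
    """
    b_row = np.asarray(b_row, dtype=float)
    e = np.asarray(e, dtype=float)
    if b_row.shape != e.shape:
        raise ShapeError(f"row length {b_row.shape} != error length {e.shape}")
    nz = np.nonzero(b_row)[0]
    acc = float(b_row[nz] @ e[nz]) if nz.size else 0.0
    result = acc * float(activation_derivative_from_output(kind, np.asarray(a_li, dtype=float)))
    if mac_counter is not None:
        mac_counter[0] += int(nz.size) + 1
    return result


def weight_gradients(trace: ForwardTrace, errors: ErrorSignals) -> list[np.ndarray]:
    """Outer-product gradients δW_l = δa_l ⊗ a_{l-1}, batch-averaged.

    With single-example vectors this is a rank-1 outer product; with batch
    matrices (width × n) the matrix product divides by n so mini-batches
    average per-example gradients.
    """
    grads = []
    for l, delta in enumerate(errors.deltas, start=1):
        a_prev = trace.activation_input(l)
        if delta.ndim == 1:
            grads.append(np.outer(delta, a_prev))
        else:
            if delta.shape[1] != a_prev.shape[1]:
                raise ShapeError("batch sizes of delta and activation disagree")
            grads.append((delta @ a_prev.T) / delta.shape[1])
    return grads


def sgd_step(
    params: NetworkParams,
    grads: list[np.ndarray],
    cfg: UpdateConfig,
    epoch: int = 0,
) -> NetworkParams:
    """W_l ← W_l − learning_rate·decay^epoch · δW_l (in place; returns params).

    Feedback matrices are not part of NetworkParams and are never modified.
    """
    rate = cfg.rate_at(epoch)
    for l, (w, g) in enumerate(zip(params.weights, grads), start=1):
        if w.shape != g.shape:
            raise ShapeError(f"gradient shape {g.shape} != weight shape {w.shape} at layer {l}")
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at layer {l}")
        w -= rate * g
    return params
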