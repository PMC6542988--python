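"""Analytic hardware cost model: reads, writes, MACs and data movement.

Counts the per-training-example backward-pass cost of each credit rule in
"words" (one weight, activation, or error = one word), per layer:

    rule   reads        writes   MACs         movement
    BP     |W| + |A|    |W|      2|W|         |W| + |A| + |E_next|
    DFA    |W| + |B|    |W|      |W| + |B|    |E| per neuron × |A|
    SDFA   |W| + |b|    |W|      |W| + |b|    |e| per neuron × |A|

|W| weights, |A| neurons, |B| dense feedback weights, |b| nonzero feedback
weights, |E| error signals (output classes), |e| errors actually received per
neuron under sparse feedback, |E_next| the length of the downstream error
vector the layer must fetch under BP.

Data movement means information a neuron must send or receive per weight
update: BP on a von Neumann machine moves weights and activations through
main memory, while DFA/SDFA on a near-memory substrate move only error words,
so their movement is errors-per-neuron × neuron count (the output layer is
counted the same way). MACs stay ≥ |W| under every rule because the partial
error at each forward weight must still be computed, which bounds the
BP→SDFA MAC reduction below 2×.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .credit import CreditRule
from .network import LayerSpec, ValidationError, validate_chain

__all__ = [
    "LayerCounts",
    "CostReport",
    "layer_costs",
    "network_costs",
    "architecture_counts",
    "reduction_factor",
    "format_2sig",
    "COST_FIELDS",
]

COST_FIELDS = ("reads", "writes", "macs", "movement")


@dataclass(frozen=True)
class LayerCounts:
    """Word counts describing one layer for the cost formulas.

    weight_count |W|, neuron_count |A|, feedback_dense |B| (0 for the output
    layer, which needs no feedback matrix), feedback_nnz |b|, error_count |E|,
    errors_per_neuron |e| (words of error a neuron receives under sparse
    feedback), downstream_error_count |E_next| (error vector BP must fetch).
    """

    weight_count: int
    neuron_count: int
    error_count: int
    feedback_dense: int = 0
    feedback_nnz: int = 0
    errors_per_neuron: int = 1
    downstream_error_count: int = 0

    def __post_init__(self) -> None:
        for name in (
            "weight_count", "neuron_count", "error_count", "feedback_dense",
            "feedback_nnz", "errors_per_neuron", "downstream_error_count",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.feedback_nnz > self.feedback_dense:
            raise ValidationError("|b| cannot exceed |B|")
        if self.errors_per_neuron > self.error_count:
            raise ValidationError("|e| cannot exceed |E|")


@dataclass
class CostReport:
    """Per-layer and total reads/writes/MACs/movement under one credit rule."""

    rule: CreditRule
    per_layer: list[dict[str, int]]

    def total(self, field: str) -> int:
        if field not in COST_FIELDS:
            raise ValidationError(f"unknown cost field {field!r}")
        return sum(layer[field] for layer in self.per_layer)

    @property
    def totals(self) -> dict[str, int]:
        return {f: self.total(f) for f in COST_FIELDS}


def _one_layer(c: LayerCounts, rule: CreditRule) -> dict[str, int]:
    W, A, E = c.weight_count, c.neuron_count, c.error_count
    if rule is CreditRule.BP:
        return {
            "reads": W + A,
            "writes": W,
            "macs": 2 * W,
            "movement": W + A + c.downstream_error_count,
        }
    if rule is CreditRule.DFA:
        return {
            "reads": W + c.feedback_dense,
            "writes": W,
            "macs": W + c.feedback_dense,
            "movement": E * A,
        }
    if rule is CreditRule.SDFA:
        return {
            "reads": W + c.feedback_nnz,
            "writes": W,
            "macs": W + c.feedback_nnz,
            "movement": c.errors_per_neuron * A,
        }
    raise ValidationError(f"unknown credit rule {rule!r}")


def layer_costs(counts: LayerCounts | Sequence[LayerCounts], rule: CreditRule) -> CostReport:
    """Apply the cost formulas to explicit per-layer counts."""
    rule = CreditRule(rule)
    if isinstance(counts, LayerCounts):
        counts = [counts]
    return CostReport(rule=rule, per_layer=[_one_layer(c, rule) for c in counts])


def architecture_counts(
    arch: Sequence[LayerSpec], feedback_nnz_per_row: int = 1
) -> list[LayerCounts]:
    """Derive per-layer counts from a fully connected stack.

    Hidden layer l gets a dense feedback matrix of fan_out_l × |E| words and
    a sparse one of fan_out_l × nnz words; the output layer needs none (its
    error is the classification error itself). Under sparse feedback every
    neuron, output neurons included, receives `feedback_nnz_per_row` error
    words, which is what the movement row charges.
    """
    validate_chain(arch)
    if feedback_nnz_per_row < 1:
        raise ValidationError("feedback_nnz_per_row must be >= 1")
    n_classes = arch[-1].fan_out
    counts = []
    for i, spec in enumerate(arch):
        is_output = i == len(arch) - 1
        downstream = n_classes if is_output else arch[i + 1].fan_out
        counts.append(
            LayerCounts(
                weight_count=spec.fan_in * spec.fan_out,
                neuron_count=spec.fan_out,
                error_count=n_classes,
                feedback_dense=0 if is_output else spec.fan_out * n_classes,
                feedback_nnz=0 if is_output else spec.fan_out * feedback_nnz_per_row,
                errors_per_neuron=min(feedback_nnz_per_row, n_classes),
                downstream_error_count=downstream,
            )
        )
    return counts


def network_costs(
    arch: Sequence[LayerSpec],
    rule: CreditRule,
    feedback_nnz_per_row: int = 1,
) -> CostReport:
    """Cost report for a whole fully connected stack under one rule."""
    return layer_costs(architecture_counts(arch, feedback_nnz_per_row), rule)


def reduction_factor(a: CostReport, b: CostReport, field: str) -> float:
    """Ratio a/b of one cost field's totals (e.g. BP movement / SDFA movement)."""
    denom = b.total(field)
    if denom == 0:
        raise ZeroDivisionError(f"reduction factor undefined: {field} total of {b.rule} is 0")
    return a.total(field) / denom


def format_2sig(x: float) -> str:
    """Render a ratio at two significant figures, e.g. 6379.1 → '6400'."""
    if x == 0:
        return "0"
    from math import floor, log10

    exp = floor(log10(abs(x)))
    scale = 10 ** (exp - 1)
    return f"{round(x / scale) * scale:g}"
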