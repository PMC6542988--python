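"""Training driver, rank/sparsity sweeps, cost reporting, and config handling.

A run is fully described by an `ExperimentConfig` (architecture, credit rule,
feedback spec, SGD settings, task parameters, root seed); everything random
is derived deterministically from the root seed, so re-running a config
reproduces the metric stream byte for byte.

The sweep runner trains one network per (rank, sparsity, seed) cell of a
grid, skipping infeasible cells — those with rank × (1 − sparsity) < 1, where
some error signal could never reach the hidden layer — and records final test
accuracy and the alignment angle of every hidden layer's feedback matrix
against the product of its downstream forward weights.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import credit, feedback as fb, network, tasks
from .costs import COST_FIELDS, CostReport, network_costs, reduction_factor
from .credit import CreditRule, UpdateConfig
from .feedback import FeedbackMatrix, FeedbackSpec, alignment_angle, generate_feedback, generate_ssdfa
from .network import ActivationKind, LayerSpec, NetworkParams, ValidationError

__all__ = [
    "ExperimentConfig",
    "EpochMetrics",
    "SweepRecord",
    "TrainingDiverged",
    "train",
    "evaluate",
    "sweep_rank_sparsity",
    "aggregate_sweep",
    "report_costs",
    "build_feedbacks",
    "load_config",
    "save_config",
    "write_metrics_csv",
    "write_sweep_csv",
]

logger = logging.getLogger("sdfa")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class TrainingDiverged(FloatingPointError):
    """Loss became non-finite; carries the epoch index."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


# Seed streams derived from the root seed; kept < 2**31 by masking.
def _derive_seed(root: int, stream: int) -> int:
    return int((root * 1_000_003 + stream) % (2**31 - 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one training run."""

    architecture: tuple[LayerSpec, ...]
    rule: CreditRule = CreditRule.BP
    feedback_rank: int | None = None       # None → full rank (min(N, M))
    feedback_sparsity: float = 0.0
    ssdfa: bool = False                    # one nonzero per feedback row
    learning_rate: float = 0.1
    decay: float = 1.0
    epochs: int = 5
    batch_size: int = 64
    repeats: int = 10
    seed: int = 0
    task: dict = field(default_factory=lambda: {
        "kind": "clusters", "n_samples": 6000, "n_features": 784,
        "n_classes": 10, "margin": 6.0, "noise_scale": 1.0,
    })

    def __post_init__(self) -> None:
        network.validate_chain(self.architecture)
        object.__setattr__(self, "rule", CreditRule(self.rule))
        if self.epochs < 0 or self.batch_size < 1 or self.repeats < 1:
            raise ValidationError("epochs >= 0, batch_size >= 1, repeats >= 1 required")

    @property
    def n_classes(self) -> int:
        return self.architecture[-1].fan_out

    def update_config(self) -> UpdateConfig:
        return UpdateConfig(self.learning_rate, self.decay, self.seed)


@dataclass
class EpochMetrics:
    epoch: int
    train_acc: float
    test_acc: float
    loss: float
    angles: list[float]  # one per hidden layer; empty under BP

    @property
    def mean_angle(self) -> float:
        return float(np.mean(self.angles)) if self.angles else float("nan")


@dataclass
class SweepRecord:
    """One (rank, sparsity, seed) cell result."""

    rank: int
    sparsity: float
    seed: int
    final_test_accuracy: float
    final_angle_per_layer: list[float]


def build_task(cfg: ExperimentConfig) -> tasks.SyntheticTask:
    params = dict(cfg.task)
    kind = params.pop("kind", "clusters")
    params.setdefault("seed", _derive_seed(cfg.seed, 3))
    if kind == "clusters":
        return tasks.make_cluster_task(**params)
    if kind == "teacher":
        specs = tuple(cfg.architecture)
        return tasks.make_teacher_task(specs, **params)
    if kind == "idx":
        return tasks.read_idx(params["images_path"], params["labels_path"],
                              n_classes=cfg.n_classes)
    raise ValidationError(f"unknown task kind {kind!r}")


def build_feedbacks(cfg: ExperimentConfig) -> list[FeedbackMatrix] | None:
    """Feedback matrices for every hidden layer, or None under BP.

    Feasibility is validated here, before any training starts. A warning is
    logged if any error column of a generated matrix is all-zero (that error
    would never propagate backwards).
    """
    if cfg.rule is CreditRule.BP:
        return None
    M = cfg.n_classes
    out: list[FeedbackMatrix] = []
    for i, spec in enumerate(cfg.architecture[:-1]):
        N = spec.fan_out
        seed = _derive_seed(cfg.seed, 100 + i)
        if cfg.ssdfa:
            mat = generate_ssdfa(N, M, seed=seed)
        else:
            rank = cfg.feedback_rank if cfg.feedback_rank is not None else min(N, M)
            mat = generate_feedback(FeedbackSpec(
                n_rows=N, n_cols=M, rank=rank,
                sparsity=cfg.feedback_sparsity, seed=seed,
            ))
        if np.any(np.all(mat.values == 0.0, axis=0)):
            logger.warning("feedback matrix for hidden layer %d leaves some "
                           "error columns unconnected", i + 1)
        out.append(mat)
    return out


def evaluate(params: NetworkParams, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """(accuracy, cross-entropy loss) over samples-as-rows X with one-hot Y."""
    out = network.forward(params, X.T).output
    acc = float(np.mean(out.argmax(axis=0) == Y.T.argmax(axis=0)))
    loss = credit.cross_entropy_loss(out, Y.T)
    return acc, loss


def _layer_angles(params: NetworkParams, feedbacks: list[FeedbackMatrix] | None) -> list[float]:
    if not feedbacks:
        return []
    return [
        alignment_angle(feedbacks[l].values, params.weights[l + 1:])
        for l in range(len(feedbacks))
    ]


def train(
    cfg: ExperimentConfig,
    task: tasks.SyntheticTask | None = None,
) -> tuple[list[EpochMetrics], NetworkParams, list[FeedbackMatrix] | None]:
    """Run one training experiment; returns (history, params, feedbacks).

    history[0] is the evaluation before any update (so epochs=0 still yields
    one row); history[k] is the state after epoch k. Raises TrainingDiverged
    with the epoch index if the loss goes non-finite.
    """
    if task is None:
        task = build_task(cfg)
    feedbacks = build_feedbacks(cfg)  # validates feasibility up front
    params = network.init_weights(cfg.architecture, seed=_derive_seed(cfg.seed, 1))
    update = cfg.update_config()
    shuffle_rng = np.random.default_rng(_derive_seed(cfg.seed, 2))
    X_train, Y_train, X_test, Y_test = task.split()
    n_train = X_train.shape[0]

    def snapshot(epoch: int) -> EpochMetrics:
        train_acc, loss = evaluate(params, X_train, Y_train)
        test_acc, _ = evaluate(params, X_test, Y_test) if len(X_test) else (float("nan"), 0.0)
        if not np.isfinite(loss):
            raise TrainingDiverged(epoch)
        return EpochMetrics(epoch, train_acc, test_acc, loss,
                            _layer_angles(params, feedbacks))

    history = [snapshot(0)]
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X_train[idx].T, Y_train[idx].T
            trace = network.forward(params, xb)
            e = credit.output_error(trace.output, yb)
            if cfg.rule is CreditRule.BP:
                errs = credit.bp_errors(params, trace, e)
            else:
                errs = credit.dfa_errors(feedbacks, trace, e, specs=list(cfg.architecture))
            grads = credit.weight_gradients(trace, errs)
            credit.sgd_step(params, grads, update, epoch=epoch)
        history.append(snapshot(epoch + 1))
        logger.info("epoch %d rule=%s train_acc=%.4f test_acc=%.4f loss=%.4f",
                    epoch + 1, cfg.rule.value, history[-1].train_acc,
                    history[-1].test_acc, history[-1].loss)
    return history, params, feedbacks


# --- sweeps -------------------------------------------------------------------

def sweep_rank_sparsity(
    cfg: ExperimentConfig,
    ranks: Sequence[int],
    sparsities: Sequence[float],
    task: tasks.SyntheticTask | None = None,
) -> tuple[list[SweepRecord], list[dict]]:
    """Train `cfg.repeats` seeds per feasible (rank, sparsity) cell.

    Returns (records, skipped): infeasible cells are recorded as skipped with
    the feasibility reason and never trained. The same task instance is
    shared across cells so cells differ only in their feedback matrices.
    """
    if not ranks or not sparsities:
        raise ValidationError("ranks and sparsities must be nonempty")
    if task is None:
        task = build_task(cfg)
    records: list[SweepRecord] = []
    skipped: list[dict] = []
    any_feasible = False
    M = cfg.n_classes
    for rank in ranks:
        for sparsity in sparsities:
            try:
                FeedbackSpec(n_rows=cfg.architecture[0].fan_out, n_cols=M,
                             rank=rank, sparsity=sparsity).check_feasible()
            except ValidationError as exc:
                skipped.append({"rank": rank, "sparsity": sparsity, "reason": str(exc)})
                logger.info("skipping infeasible cell rank=%d sparsity=%.2f: %s",
                            rank, sparsity, exc)
                continue
            any_feasible = True
            for rep in range(cfg.repeats):
                run_cfg = replace(cfg, rule=CreditRule.SDFA, feedback_rank=rank,
                                  feedback_sparsity=sparsity, ssdfa=False,
                                  seed=_derive_seed(cfg.seed, 10_000 + rep))
                history, _, _ = train(run_cfg, task=task)
                records.append(SweepRecord(
                    rank=rank, sparsity=sparsity, seed=run_cfg.seed,
                    final_test_accuracy=history[-1].test_acc,
                    final_angle_per_layer=history[-1].angles,
                ))
    if not any_feasible:
        raise ValidationError("every (rank, sparsity) cell is infeasible")
    return records, skipped


def aggregate_sweep(records: list[SweepRecord]) -> list[dict]:
    """Mean and standard deviation of accuracy and angle per (rank, sparsity)."""
    cells: dict[tuple[int, float], list[SweepRecord]] = {}
    for r in records:
        cells.setdefault((r.rank, r.sparsity), []).append(r)
    out = []
    for (rank, sparsity), rs in sorted(cells.items()):
        accs = np.array([r.final_test_accuracy for r in rs])
        angles = np.array([np.mean(r.final_angle_per_layer) for r in rs])
        out.append({
            "rank": rank, "sparsity": sparsity, "n_seeds": len(rs),
            "acc_mean": float(accs.mean()), "acc_std": float(accs.std(ddof=0)),
            "angle_mean": float(angles.mean()), "angle_std": float(angles.std(ddof=0)),
        })
    return out


def report_costs(
    arch: Sequence[LayerSpec], feedback_nnz_per_row: int = 1
) -> tuple[dict[str, CostReport], list[dict]]:
    """BP/DFA/SDFA cost reports plus all pairwise reduction factors."""
    reports = {
        rule.value: network_costs(arch, rule, feedback_nnz_per_row)
        for rule in CreditRule
    }
    factors = []
    names = list(reports)
    for a in names:
        for b in names:
            if a == b:
                continue
            for f in COST_FIELDS:
                factors.append({
                    "numerator": a, "denominator": b, "field": f,
                    "factor": reduction_factor(reports[a], reports[b], f),
                })
    return reports, factors


# --- config & CSV I/O ---------------------------------------------------------

def _config_to_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["architecture"] = [
        {"fan_in": s.fan_in, "fan_out": s.fan_out, "activation": s.activation.value}
        for s in cfg.architecture
    ]
    d["rule"] = cfg.rule.value
    return d


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    arch = tuple(
        LayerSpec(int(a["fan_in"]), int(a["fan_out"]),
                  ActivationKind(a.get("activation", "tanh")))
        for a in raw.pop("architecture")
    )
    return ExperimentConfig(architecture=arch, **raw)


def write_metrics_csv(history: list[EpochMetrics], path: str | Path) -> None:
    """One row per epoch: epoch, train_acc, test_acc, loss, mean_angle, angles."""
    n_hidden = len(history[0].angles)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_acc", "test_acc", "loss", "mean_angle"]
                   + [f"angle_layer_{i+1}" for i in range(n_hidden)])
        for m in history:
            w.writerow([m.epoch, f"{m.train_acc:.6f}", f"{m.test_acc:.6f}",
                        f"{m.loss:.6f}", f"{m.mean_angle:.6f}"]
                       + [f"{a:.6f}" for a in m.angles])


def write_sweep_csv(
    records: list[SweepRecord], skipped: list[dict], out_dir: str | Path
) -> tuple[Path, Path]:
    """Per-seed and aggregate sweep CSVs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_seed = out_dir / "sweep_records.csv"
    with open(per_seed, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "sparsity", "seed", "final_test_accuracy", "mean_final_angle"])
        for r in records:
            w.writerow([r.rank, r.sparsity, r.seed, f"{r.final_test_accuracy:.6f}",
                        f"{float(np.mean(r.final_angle_per_layer)):.6f}"])
        for s in skipped:
            w.writerow([s["rank"], s["sparsity"], "skipped", s["reason"], ""])
    agg = out_dir / "sweep_aggregate.csv"
    rows = aggregate_sweep(records)
    with open(agg, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "sparsity", "n_seeds", "acc_mean", "acc_std",
                    "angle_mean", "angle_std"])
        for row in rows:
            w.writerow([row["rank"], row["sparsity"], row["n_seeds"],
                        f"{row['acc_mean']:.6f}", f"{row['acc_std']:.6f}",
                        f"{row['angle_mean']:.6f}", f"{row['angle_std']:.6f}"])
    return per_seed, agg
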