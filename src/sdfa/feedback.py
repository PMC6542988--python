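"""Fixed random feedback matrices with controlled rank and sparsity.

Direct feedback alignment replaces the transposed forward weights of the
backward pass with a fixed random matrix B_l (hidden width N × number of
error signals M) per hidden layer. This module constructs such matrices with
a prescribed rank R and sparsity S (fraction of exactly-zero entries),
measures both properties, and computes the alignment angle between a feedback
matrix and the product of the downstream forward weights — the diagnostic
that tracks how well the random feedback approximates true gradients.

Feasibility: every error signal must reach at least one neuron, which
requires rank × connectivity = R·(1 − S) ≥ 1; infeasible requests raise.

Construction: R linearly independent base rows whose supports jointly cover
all M columns (columns are dealt round-robin across the base rows, then each
support is filled to k = per-row nonzero count with random extra columns);
the remaining N − R rows are nonzero scalar multiples of randomly chosen base
rows, so they share the base row's zero pattern and add no rank. The achieved
rank is verified by SVD and the base rows are resampled (bounded retries) on
the measure-zero failure event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import ShapeError, ValidationError

__all__ = [
    "FeedbackSpec",
    "FeedbackMatrix",
    "InfeasibleFeedbackError",
    "generate_feedback",
    "generate_ssdfa",
    "measure_sparsity",
    "measure_rank",
    "alignment_angle",
    "save_feedback",
    "load_feedback",
]

#: Default uniform init bound for feedback entries; mirrors the forward-weight
#: scheme (see network.INIT_RULES) applied to the error count.
def default_feedback_bound(n_cols: int) -> float:
    return 1.0 / math.sqrt(n_cols)


class InfeasibleFeedbackError(ValidationError):
    """Requested (rank, sparsity) cannot cover every error column."""


@dataclass(frozen=True)
class FeedbackSpec:
    """Parameters of one feedback matrix.

    n_rows
        N, the hidden-layer width receiving the feedback.
    n_cols
        M, the number of error signals (output classes).
    rank
        R in [1, min(N, M)]: number of linearly independent rows.
    sparsity
        S in [0, 1): target fraction of zero entries.
    init_bound
        Entries are drawn uniform on [−init_bound, +init_bound].
    seed
        Fixes the random stream; identical spec ⇒ identical matrix.
    """

    n_rows: int
    n_cols: int
    rank: int
    sparsity: float = 0.0
    init_bound: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("feedback dimensions must be positive")
        if not (1 <= self.rank <= min(self.n_rows, self.n_cols)):
            raise ValidationError(
                f"rank {self.rank} outside [1, min(N, M)] = "
                f"[1, {min(self.n_rows, self.n_cols)}]"
            )
        if not (0.0 <= self.sparsity < 1.0):
            raise ValidationError(f"sparsity {self.sparsity} outside [0, 1)")
        if self.init_bound is not None and self.init_bound <= 0:
            raise ValidationError("init_bound must be positive")

    @property
    def connectivity(self) -> float:
        return 1.0 - self.sparsity

    def check_feasible(self) -> None:
        """Rank × connectivity must be ≥ 1 so every error column is covered."""
        if self.rank * self.connectivity < 1.0 - 1e-12:
            raise InfeasibleFeedbackError(
                f"rank*(1-sparsity) = {self.rank * self.connectivity:.3g} < 1: "
                "some error signals could never propagate backwards"
            )
        if self.nnz_per_row < 1:
            raise InfeasibleFeedbackError("per-row support size rounds to zero")

    @property
    def nnz_per_row(self) -> int:
        """Per-row support size k.

        round-half-up of M·(1−S), raised to ceil(M/R) when necessary so the R
        base rows can jointly cover all M columns; under feasibility this
        keeps the achieved sparsity within 1/M of the request.
        """
        k = int(math.floor(self.n_cols * self.connectivity + 0.5))
        k_cover = math.ceil(self.n_cols / self.rank)
        return max(k, k_cover, 1)

    def resolved_bound(self) -> float:
        if self.init_bound is not None:
            return self.init_bound
        return default_feedback_bound(self.n_cols)


@dataclass
class FeedbackMatrix:
    """A concrete N × M feedback matrix with its measured properties."""

    values: np.ndarray
    measured_rank: int
    measured_sparsity: float
    spec: FeedbackSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))


def measure_sparsity(B: np.ndarray) -> float:
    """Fraction of exactly-zero entries (structural zeros, no thresholding)."""
    B = np.asarray(B)
    if B.size == 0:
        raise ValidationError("cannot measure sparsity of an empty matrix")
    return float(np.count_nonzero(B == 0.0) / B.size)


def measure_rank(B: np.ndarray, tol: float | None = None) -> int:
    """Number of singular values above tol (default: the numpy convention,
    max(N, M) · eps · σ_max)."""
    B = np.asarray(B, dtype=float)
    return int(np.linalg.matrix_rank(B, tol=tol))


def _nonzero_uniform(rng: np.random.Generator, size, bound: float) -> np.ndarray:
    """Uniform on [−bound, bound] with exact zeros resampled (measure zero)."""
    v = rng.uniform(-bound, bound, size=size)
    while np.any(v == 0.0):
        v[v == 0.0] = rng.uniform(-bound, bound, size=int(np.count_nonzero(v == 0.0)))
    return v


def _base_row_supports(
    rng: np.random.Generator, n_cols: int, rank: int, k: int
) -> list[np.ndarray]:
    """Choose R supports of size k whose union covers all M columns.

    Columns are dealt round-robin (in shuffled order) across the base rows,
    then each support is topped up to k with random unused columns.
    """
    deal = rng.permutation(n_cols)
    supports: list[set[int]] = [set() for _ in range(rank)]
    for i, col in enumerate(deal):
        supports[i % rank].add(int(col))
    out = []
    for s in supports:
        if len(s) > k:  # cannot happen when R*k >= M, guarded by nnz_per_row
            raise InfeasibleFeedbackError("support overflow: rank too low for sparsity")
        extra = [c for c in range(n_cols) if c not in s]
        if len(s) < k:
            s |= set(rng.choice(extra, size=k - len(s), replace=False).tolist())
        out.append(np.fromiter(sorted(s), dtype=int))
    return out


_MAX_RANK_RETRIES = 100


def generate_feedback(spec: FeedbackSpec) -> FeedbackMatrix:
    """Generate a feedback matrix with exact rank R and per-row support k.

    Raises InfeasibleFeedbackError when R·(1−S) < 1 — such matrices would
    leave some error column all-zero, silencing those classes.
    """
    spec.check_feasible()
    N, M, R = spec.n_rows, spec.n_cols, spec.rank
    k = spec.nnz_per_row
    bound = spec.resolved_bound()

    for attempt in range(_MAX_RANK_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt)
        supports = _base_row_supports(rng, M, R, k)
        base = np.zeros((R, M))
        for r, cols in enumerate(supports):
            base[r, cols] = _nonzero_uniform(rng, len(cols), bound)

        B = np.zeros((N, M))
        # scatter base rows across random positions, dependents fill the rest
        order = rng.permutation(N)
        base_pos = order[:R]
        B[base_pos] = base
        for pos in order[R:]:
            parent = int(rng.integers(R))
            scale = float(rng.uniform(0.1, 1.0) * rng.choice([-1.0, 1.0]))
            B[pos] = scale * base[parent]

        achieved = measure_rank(B)
        if achieved == R:
            return FeedbackMatrix(
                values=B,
                measured_rank=achieved,
                measured_sparsity=measure_sparsity(B),
                spec=spec,
            )
    raise RuntimeError(
        f"failed to hit rank {R} after {_MAX_RANK_RETRIES} resamples (N={N}, M={M})"
    )


def generate_ssdfa(
    N: int, M: int, init_bound: float | None = None, seed: int = 0
) -> FeedbackMatrix:
    """Single-connection feedback: exactly one nonzero per row, every column
    covered, rank M, sparsity (M−1)/M.

    The first M rows (in random order) are dealt one distinct column each
    (round-robin over a random permutation); remaining rows get a uniformly
    random column. Requires N ≥ M, else some error signal would be unused.
    """
    if N < M:
        raise InfeasibleFeedbackError(
            f"SSDFA needs at least as many neurons as errors (N={N} < M={M})"
        )
    spec = FeedbackSpec(
        n_rows=N, n_cols=M, rank=M, sparsity=(M - 1) / M,
        init_bound=init_bound, seed=seed,
    )
    rng = np.random.default_rng(seed)
    row_order = rng.permutation(N)
    col_perm = rng.permutation(M)
    # round-robin over the permutation covers every column at least floor(N/M) times
    cols = np.empty(N, dtype=int)
    cols[row_order] = col_perm[np.arange(N) % M]
    B = np.zeros((N, M))
    B[np.arange(N), cols] = _nonzero_uniform(rng, N, spec.resolved_bound())
    return FeedbackMatrix(
        values=B,
        measured_rank=measure_rank(B),
        measured_sparsity=measure_sparsity(B),
        spec=spec,
    )


def alignment_angle(B_l: np.ndarray, downstream_weights: list[np.ndarray]) -> float:
    """Angle in degrees between vec(B_l) and vec(Pᵀ), P = ∏_{i=l+1..n} W_i.

    P maps the hidden layer's activations to the output, so its natural shape
    (M × width_l) is the transpose of B_l; Pᵀ is vectorized to compare like
    with like. 0° means the feedback points exactly along the true backward
    weights; random matrices sit near 90°.
    """
    B_l = np.asarray(B_l, dtype=float)
    if not downstream_weights:
        raise ValidationError("alignment angle needs at least one downstream matrix")
    P = downstream_weights[-1]
    for w in reversed(downstream_weights[:-1]):
        P = P @ w
    if P.shape != (B_l.shape[1], B_l.shape[0]):
        raise ShapeError(
            f"downstream product shape {P.shape} is not the transpose of "
            f"feedback shape {B_l.shape}"
        )
    u = B_l.ravel()
    v = P.T.ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("alignment angle undefined for a zero-norm operand")
    cos = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


# --- plain-text triplet serialization ---------------------------------------

_HEADER = "# sdfa-feedback v1 N={N} M={M} R={R} S={S} seed={seed}"


def save_feedback(fb: FeedbackMatrix, path: str | Path) -> None:
    """Write a sparse triplet file: header line, then `row col value` rows.

    Values are written with repr-round-trip precision so reload is bitwise.
    """
    s = fb.spec
    lines = [_HEADER.format(N=s.n_rows, M=s.n_cols, R=s.rank, S=repr(s.sparsity),
                            seed=s.seed)]
    rows, cols = np.nonzero(fb.values)
    for r, c in zip(rows, cols):
        lines.append(f"{r} {c} {float(fb.values[r, c])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_feedback(path: str | Path) -> FeedbackMatrix:
    """Reload a triplet file written by `save_feedback` (bitwise round-trip)."""
    text = Path(path).read_text().strip().splitlines()
    header = text[0]
    if not header.startswith("# sdfa-feedback v1 "):
        raise ValidationError(f"not a feedback triplet file: {path}")
    fields = dict(kv.split("=") for kv in header.split()[3:])
    spec = FeedbackSpec(
        n_rows=int(fields["N"]), n_cols=int(fields["M"]), rank=int(fields["R"]),
        sparsity=float(fields["S"]), seed=int(fields["seed"]),
    )
    B = np.zeros((spec.n_rows, spec.n_cols))
    for line in text[1:]:
        r, c, v = line.split()
        B[int(r), int(c)] = float(v)
    return FeedbackMatrix(
        values=B,
        measured_rank=measure_rank(B),
        measured_sparsity=measure_sparsity(B),
        spec=spec,
    )
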