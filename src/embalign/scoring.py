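"""Residue- and column-level compatibility scoring.

Three interchangeable backends produce the dense score matrix the aligner
consumes: a learned symmetric compatibility network evaluated on residue
embeddings, a cosine-similarity control, and a BLOSUM62 control.  All
scoring happens here, before dynamic programming; the DP layer receives
only fixed numbers and never calls back into this module.

The learned scorer is a small feedforward network over a symmetric feature
map phi(x, y) = [x + y, x * y, |x - y|].  Each feature block is invariant
under swapping x and y (IEEE addition and multiplication are commutative),
so f(x, y) == f(y, x) holds bit-for-bit by construction rather than by
averaging two evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_io import GAP, PROTEIN_ALPHABET, SequenceRecord

#: Standard BLOSUM62 half-bit substitution scores over the 20 canonical
#: amino acids, row/column order ACDEFGHIKLMNPQRSTVWY.
BLOSUM62: dict[str, tuple[int, ...]] = {
    "A": (  4,   0,  -2,  -1,  -2,   0,  -2,  -1,  -1,  -1,  -1,  -2,  -1,  -1,  -1,   1,   0,   0,  -3,  -2),
    "C": (  0,   9,  -3,  -4,  -2,  -3,  -3,  -1,  -3,  -1,  -1,  -3,  -3,  -3,  -3,  -1,  -1,  -1,  -2,  -2),
    "D": ( -2,  -3,   6,   2,  -3,  -1,  -1,  -3,  -1,  -4,  -3,   1,  -1,   0,  -2,   0,  -1,  -3,  -4,  -3),
    "E": ( -1,  -4,   2,   5,  -3,  -2,   0,  -3,   1,  -3,  -2,   0,  -1,   2,   0,   0,  -1,  -2,  -3,  -2),
    "F": ( -2,  -2,  -3,  -3,   6,  -3,  -1,   0,  -3,   0,   0,  -3,  -4,  -3,  -3,  -2,  -2,  -1,   1,   3),
    "G": (  0,  -3,  -1,  -2,  -3,   6,  -2,  -4,  -2,  -4,  -3,   0,  -2,  -2,  -2,   0,  -2,  -3,  -2,  -3),
    "H": ( -2,  -3,  -1,   0,  -1,  -2,   8,  -3,  -1,  -3,  -2,   1,  -2,   0,   0,  -1,  -2,  -3,  -2,   2),
    "I": ( -1,  -1,  -3,  -3,   0,  -4,  -3,   4,  -3,   2,   1,  -3,  -3,  -3,  -3,  -2,  -1,   3,  -3,  -1),
    "K": ( -1,  -3,  -1,   1,  -3,  -2,  -1,  -3,   5,  -2,  -1,   0,  -1,   1,   2,   0,  -1,  -2,  -3,  -2),
    "L": ( -1,  -1,  -4,  -3,   0,  -4,  -3,   2,  -2,   4,   2,  -3,  -3,  -2,  -2,  -2,  -1,   1,  -2,  -1),
    "M": ( -1,  -1,  -3,  -2,   0,  -3,  -2,   1,  -1,   2,   5,  -2,  -2,   0,  -1,  -1,  -1,   1,  -1,  -1),
    "N": ( -2,  -3,   1,   0,  -3,   0,   1,  -3,   0,  -3,  -2,   6,  -2,   0,   0,   1,   0,  -3,  -4,  -2),
    "P": ( -1,  -3,  -1,  -1,  -4,  -2,  -2,  -3,  -1,  -3,  -2,  -2,   7,  -1,  -2,  -1,  -1,  -2,  -4,  -3),
    "Q": ( -1,  -3,   0,   2,  -3,  -2,   0,  -3,   1,  -2,   0,   0,  -1,   5,   1,   0,  -1,  -2,  -2,  -1),
    "R": ( -1,  -3,  -2,   0,  -3,  -2,   0,  -3,   2,  -2,  -1,   0,  -2,   1,   5,  -1,  -1,  -3,  -3,  -2),
    "S": (  1,  -1,   0,   0,  -2,   0,  -1,  -2,   0,  -2,  -1,   1,  -1,   0,  -1,   4,   1,  -2,  -3,  -2),
    "T": (  0,  -1,  -1,  -1,  -2,  -2,  -2,  -1,  -1,  -1,  -1,   0,  -1,  -1,  -1,   1,   5,   0,  -2,  -2),
    "V": (  0,  -1,  -3,  -2,  -1,  -3,  -3,   3,  -2,   1,   1,  -3,  -2,  -2,  -3,  -2,   0,   4,  -3,  -1),
    "W": ( -3,  -2,  -4,  -3,   1,  -2,  -2,  -3,  -3,  -2,  -1,  -4,  -4,  -2,  -3,  -3,  -2,  -3,  11,   2),
    "Y": ( -2,  -2,  -3,  -2,   3,  -3,   2,  -1,  -2,  -1,  -1,  -2,  -3,  -1,  -2,  -2,  -2,  -1,   2,   7),
}

_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
BLOSUM62_ARRAY = np.array([BLOSUM62[a] for a in PROTEIN_ALPHABET], dtype=float)


class ScoringError(ValueError):
    pass


class BackendConfigError(ScoringError):
    """Backend asked to score a representation it cannot consume."""


class _CallCounter:
    """Counts backend scoring invocations; used to prove scoring/DP purity."""

    def __init__(self) -> None:
        self.count = 0

    def bump(self, n: int = 1) -> None:
        self.count += n

    def reset(self) -> None:
        self.count = 0


SCORING_CALLS = _CallCounter()


def cosine_score(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; 0 if either vector has zero norm."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ScoringError(f"dimension mismatch: {x.shape} vs {y.shape}")
    SCORING_CALLS.bump()
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def blosum62_score(a: str, b: str) -> int:
    if a not in _AA_INDEX:
        raise ScoringError(f"symbol {a!r} is not a canonical amino acid")
    if b not in _AA_INDEX:
        raise ScoringError(f"symbol {b!r} is not a canonical amino acid")
    SCORING_CALLS.bump()
    return BLOSUM62[a][_AA_INDEX[b]]


@dataclass
class LearnedScorerParams:
    """Parameters of the symmetric compatibility network.

    ``weights``/``biases`` hold the feedforward layers over the symmetric
    feature map (input width 3*d).  ``calibration`` is an affine transform
    (scale, offset) applied to the raw network output.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    d: int
    activation: str = "relu"
    calibration: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.weights[0].shape[0] != 3 * self.d:
            raise ScoringError(
                f"first layer expects input width {self.weights[0].shape[0]}, "
                f"but d={self.d} implies {3 * self.d}"
            )
        if self.activation not in ("relu", "tanh"):
            raise ScoringError(f"unknown activation {self.activation!r}")

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.weights[:-1])

    def architecture(self) -> dict:
        return {
            "feature_map": "sum-product-absdiff",
            "hidden": list(self.hidden_sizes),
            "activation": self.activation,
        }


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    return np.tanh(z)


def symmetric_features(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """phi(x, y): concatenation of x+y, x*y and |x-y| along the last axis."""
    return np.concatenate([x + y, x * y, np.abs(x - y)], axis=-1)


def _forward(params: LearnedScorerParams, feats: np.ndarray) -> np.ndarray:
    h = feats
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        h = _activate(h @ w + b, params.activation)
    out = h @ params.weights[-1] + params.biases[-1]
    scale, offset = params.calibration
    return scale * out[..., 0] + offset


def learned_score(params: LearnedScorerParams, x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (params.d,) or y.shape != (params.d,):
        raise ScoringError(
            f"expected two vectors of dimension {params.d}, got {x.shape} and {y.shape}"
        )
    SCORING_CALLS.bump()
    return float(_forward(params, symmetric_features(x, y)))


def learned_score_matrix(
    params: LearnedScorerParams, left: np.ndarray, right: np.ndarray
) -> np.ndarray:
    """Vectorized all-pairs evaluation: left (n, d) x right (m, d) -> (n, m)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape[1] != params.d or right.shape[1] != params.d:
        raise ScoringError(
            f"embedding dimension mismatch: scorer expects d={params.d}, "
            f"got {left.shape[1]} and {right.shape[1]}"
        )
    n, m = left.shape[0], right.shape[0]
    lx = np.repeat(left, m, axis=0)
    ry = np.tile(right, (n, 1))
    feats = symmetric_features(lx, ry)
    return _forward(params, feats).reshape(n, m)


@dataclass(frozen=True)
class ScoreMatrix:
    """Dense unit-by-residue compatibility scores, fixed before DP."""

    scores: np.ndarray
    row_source: str
    col_source: str
    backend_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2:
            raise ScoringError("score matrix must be two-dimensional")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ScoringError(f"non-finite score at ({bad[0]}, {bad[1]})")
        object.__setattr__(self, "scores", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


@dataclass(frozen=True)
class SideView:
    """One side of a scoring instance: a sequence or the columns of a profile.

    ``embeddings`` holds one vector per unit (residue or column mean);
    ``symbol_columns`` holds the non-gap member symbols of each unit, which
    is what the BLOSUM62 backend consumes.
    """

    source_id: str
    embeddings: np.ndarray | None = None
    symbol_columns: tuple[str, ...] | None = None

    @property
    def n_units(self) -> int:
        if self.embeddings is not None:
            return self.embeddings.shape[0]
        assert self.symbol_columns is not None
        return len(self.symbol_columns)


def side_from_sequence(seq: SequenceRecord, embeddings: np.ndarray | None) -> SideView:
    return SideView(
        source_id=seq.id,
        embeddings=embeddings,
        symbol_columns=tuple(seq.residues),
    )


class Backend:
    """Scoring backend interface: turn two SideViews into a score array."""

    backend_id: str = "abstract"

    def matrix(self, left: SideView, right: SideView) -> np.ndarray:
        raise NotImplementedError


class CosineBackend(Backend):
    backend_id = "cosine"

    def matrix(self, left: SideView, right: SideView) -> np.ndarray:
        if left.embeddings is None or right.embeddings is None:
            raise BackendConfigError("cosine backend requires embeddings on both sides")
        le, re = left.embeddings, right.embeddings
        if le.shape[1] != re.shape[1]:
            raise ScoringError(
                f"dimension mismatch: {le.shape[1]} vs {re.shape[1]}"
            )
        SCORING_CALLS.bump(le.shape[0] * re.shape[0])
        ln = np.linalg.norm(le, axis=1)
        rn = np.linalg.norm(re, axis=1)
        denom = np.outer(ln, rn)
        raw = le @ re.T
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0.0, raw / np.where(denom > 0.0, denom, 1.0), 0.0)
        return out


class LearnedBackend(Backend):
    def __init__(self, params: LearnedScorerParams) -> None:
        self.params = params
        self.backend_id = "learned"

    def matrix(self, left: SideView, right: SideView) -> np.ndarray:
        if left.embeddings is None or right.embeddings is None:
            raise BackendConfigError("learned backend requires embeddings on both sides")
        SCORING_CALLS.bump(left.embeddings.shape[0] * right.embeddings.shape[0])
        return learned_score_matrix(self.params, left.embeddings, right.embeddings)


class Blosum62Backend(Backend):
    """Static-table control; profile columns score as the mean substitution
    score over their non-gap members (sum-of-pairs style)."""

    backend_id = "blosum62"

    def matrix(self, left: SideView, right: SideView) -> np.ndarray:
        if left.symbol_columns is None or right.symbol_columns is None:
            raise BackendConfigError(
                "blosum62 backend requires residue symbols on both sides "
                "(it cannot score embeddings)"
            )
        out = np.empty((left.n_units, right.n_units), dtype=float)
        for j, col_r in enumerate(right.symbol_columns):
            members_r = [s for s in col_r if s != GAP]
            if not members_r:
                raise ScoringError("empty (all-gap) unit on right side")
            for i, col_l in enumerate(left.symbol_columns):
                members_l = [s for s in col_l if s != GAP]
                if not members_l:
                    raise ScoringError("empty (all-gap) unit on left side")
                total = 0.0
                for a in members_l:
                    row = BLOSUM62[a] if a in BLOSUM62 else None
                    if row is None:
                        raise ScoringError(f"symbol {a!r} is not a canonical amino acid")
                    for b in members_r:
                        if b not in _AA_INDEX:
                            raise ScoringError(f"symbol {b!r} is not a canonical amino acid")
                        total += row[_AA_INDEX[b]]
                out[i, j] = total / (len(members_l) * len(members_r))
        SCORING_CALLS.bump(left.n_units * right.n_units)
        return out


def compute_score_matrix(backend: Backend, left: SideView, right: SideView) -> ScoreMatrix:
    """Evaluate every (left unit, right unit) pair before any DP runs."""
    scores = backend.matrix(left, right)
    return ScoreMatrix(
        scores=scores,
        row_source=left.source_id,
        col_source=right.source_id,
        backend_id=backend.backend_id,
    )
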