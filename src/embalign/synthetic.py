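"""Synthetic homologous families with a known true alignment.

An ancestor sequence is sampled from background amino-acid frequencies and
evolved down a balanced binary tree.  Substitutions are biased toward
biochemically similar residues (exchange probabilities proportional to
exp(BLOSUM62/2)); insertions and deletions have geometric lengths.  Every
indel is threaded through a master column coordinate system, so the true
multiple alignment — and hence residue-level homology — is known exactly.

Synthetic residue embeddings place each residue identity on one of 20
near-orthogonal unit basis vectors in R^d, blended with the mean basis
vector over a local window and perturbed by Gaussian noise, so embedding
geometry carries residue identity plus local context.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np

from .scoring import BLOSUM62, _AA_INDEX
from .seq_io import (
    CODON_TO_AA,
    PROTEIN_ALPHABET,
    MultipleAlignment,
    SequenceRecord,
    translate,
)

_BASIS_CONSTRUCTION_SEED = 20_240_001  # shared across runs; not user-settable
_CONTEXT_BLEND = 0.3


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyParams:
    n_taxa: int = 8
    ancestor_length: int = 100
    substitution_rate: float = 0.1
    indel_rate: float = 0.02
    indel_extension: float = 0.4  # geometric continuation probability
    background: tuple[float, ...] | None = None  # per-amino-acid; uniform if None

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise SimulationError("family size must be at least 2")
        if self.ancestor_length < 1:
            raise SimulationError("ancestor length must be at least 1")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SimulationError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.indel_extension < 1.0):
            raise SimulationError("indel_extension must lie in [0, 1)")
        if self.background is not None and len(self.background) != 20:
            raise SimulationError("background must have 20 frequencies")

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "ancestor_length": self.ancestor_length,
            "substitution_rate": self.substitution_rate,
            "indel_rate": self.indel_rate,
            "indel_extension": self.indel_extension,
            "background": list(self.background) if self.background else None,
        }


@dataclass
class SimulatedFamily:
    family_id: str
    true_msa: MultipleAlignment
    sequences: list[SequenceRecord]
    params: FamilyParams
    seed: int
    cds: list[SequenceRecord] | None = None


# exchange distributions: P(a -> b) propto exp(BLOSUM62[a][b] / 2), b != a
def _exchange_matrix() -> np.ndarray:
    mat = np.zeros((20, 20))
    for i, a in enumerate(PROTEIN_ALPHABET):
        w = np.exp(np.array(BLOSUM62[a], dtype=float) / 2.0)
        w[i] = 0.0
        mat[i] = w / w.sum()
    return mat


_EXCHANGE = _exchange_matrix()


def _geometric_length(rng: np.random.Generator, extension: float) -> int:
    if extension <= 0.0:
        return 1
    return int(rng.geometric(1.0 - extension))


class _MasterColumns:
    """Ordered master coordinate system; ids are stable, order mutable."""

    def __init__(self, n: int) -> None:
        self.order: list[int] = list(range(n))
        self._counter = itertools.count(n)

    def insert_after(self, col_id: int | None, count: int) -> list[int]:
        """Insert new columns immediately after col_id (None = at front)."""
        pos = 0 if col_id is None else self.order.index(col_id) + 1
        new_ids = [next(self._counter) for _ in range(count)]
        self.order[pos:pos] = new_ids
        return new_ids


def _evolve_edge(
    state: dict[int, str],
    master: _MasterColumns,
    params: FamilyParams,
    rng: np.random.Generator,
    background: np.ndarray,
) -> dict[int, str]:
    child = dict(state)
    present = [c for c in master.order if c in child]

    # substitutions
    for col in present:
        if rng.random() < params.substitution_rate:
            a = _AA_INDEX[child[col]]
            b = rng.choice(20, p=_EXCHANGE[a])
            child[col] = PROTEIN_ALPHABET[int(b)]

    # deletions: geometric runs over currently present residues
    half_rate = params.indel_rate / 2.0
    k = 0
    while k < len(present):
        if rng.random() < half_rate:
            run = _geometric_length(rng, params.indel_extension)
            for col in present[k : k + run]:
                del child[col]
            k += run
        else:
            k += 1

    # insertions: at each boundary (before first residue and after each one)
    survivors = [c for c in present if c in child]
    boundaries: list[int | None] = [None] + survivors
    for anchor in boundaries:
        if rng.random() < half_rate:
            run = _geometric_length(rng, params.indel_extension)
            new_ids = master.insert_after(anchor, run)
            for col in new_ids:
                aa = rng.choice(20, p=background)
                child[col] = PROTEIN_ALPHABET[int(aa)]
    return child


def simulate_family(
    params: FamilyParams,
    seed: int,
    family_id: str | None = None,
    with_cds: bool = False,
) -> SimulatedFamily:
    """Evolve a family of params.n_taxa sequences with an exact true MSA."""
    rng = np.random.default_rng(seed)
    family_id = family_id or f"fam{seed}"
    if params.background is None:
        background = np.full(20, 1.0 / 20.0)
    else:
        background = np.asarray(params.background, dtype=float)
        background = background / background.sum()

    master = _MasterColumns(params.ancestor_length)
    ancestor_idx = rng.choice(20, size=params.ancestor_length, p=background)
    root = {c: PROTEIN_ALPHABET[int(a)] for c, a in zip(master.order, ancestor_idx)}

    leaves: list[dict[int, str]] = []

    def descend(state: dict[int, str], count: int) -> None:
        if count == 1:
            leaves.append(state)
            return
        left_n = count // 2
        left = _evolve_edge(state, master, params, rng, background)
        right = _evolve_edge(state, master, params, rng, background)
        descend(left, left_n)
        descend(right, count - left_n)

    descend(root, params.n_taxa)

    # keep only columns where at least one leaf has a residue
    live_cols = [c for c in master.order if any(c in leaf for leaf in leaves)]
    if not live_cols:
        raise SimulationError("all residues deleted; raise ancestor length or lower rates")

    rows: list[SequenceRecord] = []
    sequences: list[SequenceRecord] = []
    for i, leaf in enumerate(leaves):
        name = f"{family_id}_t{i}"
        gapped = "".join(leaf.get(c, "-") for c in live_cols)
        rows.append(SequenceRecord(id=name, residues=gapped, alphabet="gapped-protein"))
        ungapped = gapped.replace("-", "")
        if not ungapped:
            raise SimulationError(
                f"leaf {name} lost all residues; lower indel_rate or lengthen ancestor"
            )
        sequences.append(SequenceRecord(id=name, residues=ungapped, alphabet="protein20"))

    true_msa = MultipleAlignment(rows=rows)
    cds = None
    if with_cds:
        cds = [reverse_translate(s, seed=_derive_seed(seed, s.id)) for s in sequences]
    return SimulatedFamily(
        family_id=family_id,
        true_msa=true_msa,
        sequences=sequences,
        params=params,
        seed=seed,
        cds=cds,
    )


def _derive_seed(seed: int, token: str) -> int:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


def reverse_translate(
    protein: SequenceRecord, seed: int, add_stop: bool = False
) -> SequenceRecord:
    """Replace each residue with a uniformly chosen synonymous codon."""
    if protein.alphabet != "protein20":
        raise SimulationError("reverse_translate expects a protein20 record")
    rng = np.random.default_rng(seed)
    codons = []
    for aa in protein.residues:
        options = _AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    if add_stop:
        codons.append("TAA")
    cds = SequenceRecord(
        id=protein.id,
        residues="".join(codons),
        alphabet="dna4",
        description=protein.description,
    )
    assert translate(cds).residues == protein.residues
    return cds


def _identity_basis(d: int) -> np.ndarray:
    """20 near-orthogonal unit vectors in R^d, fixed across runs."""
    if d < 21:
        raise SimulationError(f"embedding dimension must be >= 21, got {d}")
    rng = np.random.default_rng(_BASIS_CONSTRUCTION_SEED)
    g = rng.normal(size=(d, d))
    q, _ = np.linalg.qr(g)
    return np.ascontiguousarray(q[:20, :])


_BASIS_CACHE: dict[int, np.ndarray] = {}


def identity_basis(d: int) -> np.ndarray:
    if d not in _BASIS_CACHE:
        _BASIS_CACHE[d] = _identity_basis(d)
    return _BASIS_CACHE[d]


def synth_embeddings(
    seq: SequenceRecord,
    d: int,
    noise_sd: float,
    window: int,
    seed: int,
) -> np.ndarray:
    """Per-residue embeddings carrying identity + local context + noise.

    Noise is keyed on (seed, sequence text) so the same sequence always
    yields the same matrix, as the embedding-provider contract requires.
    """
    if seq.alphabet != "protein20":
        raise SimulationError("synth_embeddings expects a protein20 record")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be non-negative")
    if window < 0:
        raise SimulationError("window must be non-negative")
    basis = identity_basis(d)
    idx = np.array([_AA_INDEX[a] for a in seq.residues])
    own = basis[idx]
    n = len(idx)
    if window == 0:
        vectors = own.copy()
    else:
        context = np.empty_like(own)
        for i in range(n):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            context[i] = own[lo:hi].mean(axis=0)
        vectors = (1.0 - _CONTEXT_BLEND) * own + _CONTEXT_BLEND * context
    if noise_sd > 0:
        rng = np.random.default_rng([seed, _derive_seed(0, seq.residues)])
        vectors = vectors + rng.normal(scale=noise_sd, size=vectors.shape)
    return vectors
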