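"""Progressive profile-sequence assembly of a multiple alignment.

Sequences are inserted under an explicit order policy (UPGMA on centroid
cosine distances, input order, or a seeded random shuffle); the growing
profile is aligned to each next sequence with the exact affine-gap DP.
Column embeddings are the arithmetic mean of member residue embeddings at
non-gap positions, maintained incrementally as (sum, count) so they can be
recomputed from scratch and compared exactly.

The order policy controls assembly only; it is not a phylogenetic
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align_core import GapPenalties, gotoh_align
from .embeddings import ResidueEmbeddingMatrix, sequence_centroid
from .scoring import Backend, SideView, compute_score_matrix, side_from_sequence
from .seq_io import GAP, MultipleAlignment, SequenceRecord

logger = logging.getLogger(__name__)

ORDER_POLICIES = ("upgma", "input", "random")


class ProgressiveError(ValueError):
    pass


@dataclass
class ProfileAlignment:
    """A partial MSA plus per-column aggregate embeddings."""

    ids: list[str]
    rows: list[list[str]]  # characters, '-' for gap
    row_embeddings: list[np.ndarray]  # ungapped n_i x d per member
    col_sums: np.ndarray  # C x d
    col_counts: np.ndarray  # C

    @property
    def column_count(self) -> int:
        return len(self.col_counts)

    @property
    def column_embeddings(self) -> np.ndarray:
        return self.col_sums / self.col_counts[:, None]

    def symbol_columns(self) -> tuple[str, ...]:
        cols = []
        for c in range(self.column_count):
            cols.append("".join(row[c] for row in self.rows if row[c] != GAP))
        return tuple(cols)

    def recompute_column_embeddings(self) -> np.ndarray:
        """From-scratch recomputation used to audit incremental maintenance."""
        d = self.col_sums.shape[1]
        sums = np.zeros((self.column_count, d))
        counts = np.zeros(self.column_count)
        for row, emb in zip(self.rows, self.row_embeddings):
            k = 0
            for c, sym in enumerate(row):
                if sym != GAP:
                    sums[c] += emb[k]
                    counts[c] += 1
                    k += 1
        return sums / counts[:, None]

    def side_view(self) -> SideView:
        return SideView(
            source_id="profile:" + "+".join(self.ids),
            embeddings=self.column_embeddings,
            symbol_columns=self.symbol_columns(),
        )


def _profile_from_sequence(seq: SequenceRecord, emb: ResidueEmbeddingMatrix) -> ProfileAlignment:
    return ProfileAlignment(
        ids=[seq.id],
        rows=[list(seq.residues)],
        row_embeddings=[emb.vectors],
        col_sums=emb.vectors.copy(),
        col_counts=np.ones(emb.n),
    )


def centroid_distance_matrix(embeddings: list[ResidueEmbeddingMatrix]) -> np.ndarray:
    """Pairwise 1 - cosine(centroid_i, centroid_j); zero-norm centroids sit
    at distance 1 from everything (logged)."""
    if len(embeddings) < 2:
        raise ProgressiveError("need at least two sequences for a distance matrix")
    cents = np.array([sequence_centroid(e) for e in embeddings])
    norms = np.linalg.norm(cents, axis=1)
    n = len(cents)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0.0 or norms[j] == 0.0:
                logger.warning("zero-norm centroid at index %d or %d; distance set to 1", i, j)
                d = 1.0
            else:
                d = 1.0 - float(np.dot(cents[i], cents[j]) / (norms[i] * norms[j]))
            dist[i, j] = dist[j, i] = d
    return dist


def upgma_order(distances: np.ndarray) -> list[int]:
    """Left-to-right leaf order of an average-linkage (UPGMA) dendrogram.

    Closest pair merges first (ties: lexicographically smallest index
    pair); within each merge the subtree containing the smaller original
    index goes left.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    _check_distances(d)
    clusters: dict[int, dict] = {
        i: {"leaves": [i], "size": 1, "min_leaf": i} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    next_id = n
    while len(clusters) > 1:
        best_pair = None
        best = np.inf
        for (i, j), v in sorted(dist.items()):
            if v < best:
                best = v
                best_pair = (i, j)
        assert best_pair is not None
        a, b = best_pair
        ca, cb = clusters.pop(a), clusters.pop(b)
        left, right = (ca, cb) if ca["min_leaf"] < cb["min_leaf"] else (cb, ca)
        merged = {
            "leaves": left["leaves"] + right["leaves"],
            "size": ca["size"] + cb["size"],
            "min_leaf": min(ca["min_leaf"], cb["min_leaf"]),
        }
        new_dist = {}
        for k in clusters:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            new_dist[k] = (ca["size"] * da + cb["size"] * db) / (ca["size"] + cb["size"])
        del dist[(a, b)]
        clusters[next_id] = merged
        for k, v in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return next(iter(clusters.values()))["leaves"]


def _check_distances(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ProgressiveError("distance matrix must be square")
    if np.any(d < 0):
        raise ProgressiveError("distance matrix has negative entries")
    if not np.allclose(d, d.T):
        raise ProgressiveError("distance matrix is not symmetric")


def order_sequences(
    distances: np.ndarray | None,
    policy: str,
    n: int,
    seed: int | None = None,
) -> list[int]:
    if policy not in ORDER_POLICIES:
        raise ProgressiveError(f"unknown order policy {policy!r}")
    if policy == "input":
        return list(range(n))
    if policy == "random":
        if seed is None:
            raise ProgressiveError("random order policy requires a seed")
        rng = np.random.default_rng(seed)
        return [int(i) for i in rng.permutation(n)]
    if distances is None:
        raise ProgressiveError("upgma policy requires a distance matrix")
    return upgma_order(distances)


def progressive_align(
    sequences: list[SequenceRecord],
    embeddings: list[ResidueEmbeddingMatrix],
    backend: Backend,
    penalties: GapPenalties,
    policy: str = "upgma",
    order_seed: int | None = None,
    profiler=None,
) -> MultipleAlignment:
    """Assemble an MSA; output rows are restored to input order."""
    if len(sequences) != len(embeddings):
        raise ProgressiveError("sequences and embeddings must correspond 1:1")
    if len(sequences) == 1:
        logger.warning("single input sequence; returning a trivial one-row alignment")
        seq = sequences[0]
        return MultipleAlignment(
            rows=[SequenceRecord(id=seq.id, residues=seq.residues, alphabet="gapped-protein")]
        )
    providers = {e.provider_id for e in embeddings}
    if len(providers) != 1:
        raise ProgressiveError(f"embeddings come from several providers: {sorted(providers)}")

    dist = centroid_distance_matrix(embeddings) if policy == "upgma" else None
    order = order_sequences(dist, policy, n=len(sequences), seed=order_seed)

    profile = _profile_from_sequence(sequences[order[0]], embeddings[order[0]])
    for idx in order[1:]:
        seq, emb = sequences[idx], embeddings[idx]
        left = profile.side_view()
        right = side_from_sequence(seq, emb.vectors)
        if profiler is not None:
            with profiler.phase("scoring"):
                scores = compute_score_matrix(backend, left, right)
            with profiler.phase("dp"):
                result = gotoh_align(scores, penalties)
        else:
            scores = compute_score_matrix(backend, left, right)
            result = gotoh_align(scores, penalties)
        profile = _merge(profile, seq, emb, result)

    by_id = {rid: "".join(row) for rid, row in zip(profile.ids, profile.rows)}
    rows = [
        SequenceRecord(id=s.id, residues=by_id[s.id], alphabet="gapped-protein")
        for s in sequences
    ]
    msa = MultipleAlignment(rows=rows)
    return msa


def _merge(
    profile: ProfileAlignment,
    seq: SequenceRecord,
    emb: ResidueEmbeddingMatrix,
    result,
) -> ProfileAlignment:
    d = profile.col_sums.shape[1]
    n_pos = len(result.aligned_left)
    new_rows = [[] for _ in profile.rows]
    new_row: list[str] = []
    sums = np.zeros((n_pos, d))
    counts = np.zeros(n_pos)
    for k, (ci, rj) in enumerate(zip(result.aligned_left, result.aligned_right)):
        if ci is not None:
            for r, row in enumerate(profile.rows):
                new_rows[r].append(row[ci])
            sums[k] = profile.col_sums[ci]
            counts[k] = profile.col_counts[ci]
        else:
            for r in range(len(profile.rows)):
                new_rows[r].append(GAP)
        if rj is not None:
            new_row.append(seq.residues[rj])
            sums[k] += emb.vectors[rj]
            counts[k] += 1
        else:
            new_row.append(GAP)
    return ProfileAlignment(
        ids=profile.ids + [seq.id],
        rows=new_rows + [new_row],
        row_embeddings=profile.row_embeddings + [emb.vectors],
        col_sums=sums,
        col_counts=counts,
    )


def guide_tree_newick(distances: np.ndarray, labels: list[str]) -> str:
    """Newick rendering of the UPGMA merge order (assembly order only,
    explicitly not a phylogenetic estimate)."""
    d = np.asarray(distances, dtype=float)
    _check_distances(d)
    n = d.shape[0]
    reps: dict[int, dict] = {
        i: {"nwk": labels[i], "size": 1, "min_leaf": i} for i in range(n)
    }
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(reps) > 1:
        (a, b) = min(sorted(dist), key=lambda p: (dist[p], p))
        ca, cb = reps.pop(a), reps.pop(b)
        left, right = (ca, cb) if ca["min_leaf"] < cb["min_leaf"] else (cb, ca)
        merged = {
            "nwk": f"({left['nwk']},{right['nwk']})",
            "size": ca["size"] + cb["size"],
            "min_leaf": min(ca["min_leaf"], cb["min_leaf"]),
        }
        new_dist = {}
        for k in reps:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            new_dist[k] = (ca["size"] * da + cb["size"] * db) / (ca["size"] + cb["size"])
        del dist[(a, b)]
        reps[next_id] = merged
        for k, v in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return next(iter(reps.values()))["nwk"] + ";"
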