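"""Training of the learned compatibility scorer from families with known
alignments.

Supervision is binary: positive pairs are cross-row residue embeddings
taken from residue-residue columns of a true alignment; negatives are
uniformly sampled cross-sequence residue pairs that are not aligned in the
truth.  The symmetric network is optimized with Adam on a logistic loss
over its logit, so unrelated pairs score negative in expectation.  The
train/validation split is at the family level to avoid leakage between
pairs of one family.

Checkpoints are JSON: weights serialize as nested lists whose decimal
repr round-trips IEEE doubles exactly, so reloaded scorers reproduce
outputs bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingProvider
from .scoring import LearnedScorerParams, symmetric_features
from .synthetic import SimulatedFamily

CHECKPOINT_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


class BenchmarkIsolationError(TrainingError):
    """A training family appears on the evaluation-exclusion list."""


class TrainingDivergedError(TrainingError):
    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class CheckpointError(ValueError):
    pass


class CheckpointVersionError(CheckpointError):
    pass


@dataclass
class PairDataset:
    x1: np.ndarray  # (N, d)
    x2: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,) in {0, 1}
    family_ids: list[str]
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.x1) == len(self.x2) == len(self.labels) == len(self.family_ids)):
            raise TrainingError("dataset arrays have inconsistent lengths")
        if self.x1.shape[1] != self.x2.shape[1]:
            raise TrainingError("pair members have different embedding dimensions")

    @property
    def d(self) -> int:
        return self.x1.shape[1]

    def __len__(self) -> int:
        return len(self.labels)


def true_aligned_pairs(family: SimulatedFamily) -> set[tuple[int, int, int, int]]:
    """All homologous residue pairs (rowA, posA, rowB, posB) with rowA < rowB."""
    pairs = set()
    msa = family.true_msa
    ordinals = []
    for row in msa.rows:
        k = -1
        cur = []
        for sym in row.residues:
            if sym != "-":
                k += 1
                cur.append(k)
            else:
                cur.append(None)
        ordinals.append(cur)
    for c in range(msa.column_count):
        members = [
            (r, ordinals[r][c]) for r in range(len(msa.rows)) if ordinals[r][c] is not None
        ]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ra, pa = members[a]
                rb, pb = members[b]
                pairs.add((ra, pa, rb, pb))
    return pairs


def build_pair_dataset(
    families: list[SimulatedFamily],
    provider: EmbeddingProvider,
    negatives_per_positive: int = 1,
    seed: int = 0,
    exclude_ids: set[str] | None = None,
) -> PairDataset:
    """Assemble labeled embedding pairs from families with true alignments."""
    if negatives_per_positive < 1:
        raise TrainingError("negatives_per_positive must be a positive integer")
    rng = np.random.default_rng(seed)
    exclude_ids = exclude_ids or set()
    x1_parts, x2_parts, label_parts, fam_parts = [], [], [], []
    n_pos_total = 0
    for family in families:
        if family.family_id in exclude_ids:
            raise BenchmarkIsolationError(
                f"family {family.family_id!r} is on the evaluation-exclusion list; "
                "refusing to train on it"
            )
        if len(family.sequences) < 2:
            import warnings

            warnings.warn(f"family {family.family_id} has < 2 rows; skipped")
            continue
        embs = [provider.embed(s).vectors for s in family.sequences]
        truth = true_aligned_pairs(family)
        pos = sorted(truth)
        if not pos:
            continue
        n_pos_total += len(pos)
        for ra, pa, rb, pb in pos:
            x1_parts.append(embs[ra][pa])
            x2_parts.append(embs[rb][pb])
            label_parts.append(1.0)
            fam_parts.append(family.family_id)
        lengths = [len(s.residues) for s in family.sequences]
        n_rows = len(lengths)
        needed = len(pos) * negatives_per_positive
        got = 0
        attempts = 0
        while got < needed and attempts < needed * 50:
            attempts += 1
            ra = int(rng.integers(n_rows))
            rb = int(rng.integers(n_rows))
            if ra == rb:
                continue
            if ra > rb:
                ra, rb = rb, ra
            pa = int(rng.integers(lengths[ra]))
            pb = int(rng.integers(lengths[rb]))
            if (ra, pa, rb, pb) in truth:
                continue
            x1_parts.append(embs[ra][pa])
            x2_parts.append(embs[rb][pb])
            label_parts.append(0.0)
            fam_parts.append(family.family_id)
            got += 1
    if n_pos_total == 0:
        raise TrainingError("no positive pairs could be extracted from the families")
    x1 = np.array(x1_parts)
    x2 = np.array(x2_parts)
    labels = np.array(label_parts)
    fams = fam_parts
    perm = rng.permutation(len(labels))
    return PairDataset(
        x1=x1[perm],
        x2=x2[perm],
        labels=labels[perm],
        family_ids=[fams[i] for i in perm],
        seed=seed,
        provenance={
            "families": sorted({f.family_id for f in families}),
            "provider_id": provider.provider_id,
            "negatives_per_positive": negatives_per_positive,
        },
    )


@dataclass(frozen=True)
class TrainConfig:
    hidden: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 256
    val_fraction: float = 0.1
    activation: str = "relu"


@dataclass
class ScorerCheckpoint:
    params: LearnedScorerParams
    metadata: dict
    format_version: int = CHECKPOINT_FORMAT_VERSION


def _init_params(d: int, config: TrainConfig, rng: np.random.Generator) -> LearnedScorerParams:
    sizes = [3 * d, *config.hidden, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(scale=scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return LearnedScorerParams(
        weights=weights, biases=biases, d=d, activation=config.activation
    )


def _forward_backward(params, feats, labels):
    """Logistic loss on the network logit; returns (loss, grads)."""
    acts = [feats]
    h = feats
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        z = h @ w + b
        h = np.maximum(z, 0.0) if params.activation == "relu" else np.tanh(z)
        acts.append(h)
    logits = (h @ params.weights[-1] + params.biases[-1])[:, 0]
    # stable softplus(z) - y*z
    loss = float(np.mean(np.logaddexp(0.0, logits) - labels * logits))
    n = len(labels)
    dlogit = ((1.0 / (1.0 + np.exp(-logits))) - labels) / n

    grads_w = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    delta = dlogit[:, None]  # (n, 1)
    grads_w[-1] = acts[-1].T @ delta
    grads_b[-1] = delta.sum(axis=0)
    dh = delta @ params.weights[-1].T
    for layer in range(len(params.weights) - 2, -1, -1):
        h_out = acts[layer + 1]
        if params.activation == "relu":
            dz = dh * (h_out > 0)
        else:
            dz = dh * (1.0 - h_out**2)
        grads_w[layer] = acts[layer].T @ dz
        grads_b[layer] = dz.sum(axis=0)
        dh = dz @ params.weights[layer].T
    return loss, grads_w, grads_b, logits


def _pair_features(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    return symmetric_features(x1, x2)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (equivalent to the Mann-Whitney statistic)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def train_scorer(
    dataset: PairDataset, config: TrainConfig = TrainConfig(), seed: int = 0
) -> ScorerCheckpoint:
    """Deterministic Adam training of the symmetric scorer."""
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise TrainingError("dataset must contain both positive and negative pairs")
    rng = np.random.default_rng(seed)

    families = sorted(set(dataset.family_ids))
    fam_perm = [families[i] for i in rng.permutation(len(families))]
    n_val_fams = max(1, int(round(config.val_fraction * len(families)))) if len(families) > 1 else 0
    val_fams = set(fam_perm[:n_val_fams])
    fam_arr = np.array(dataset.family_ids)
    val_mask = np.isin(fam_arr, sorted(val_fams))
    train_idx = np.where(~val_mask)[0]
    val_idx = np.where(val_mask)[0]
    if train_idx.size == 0:
        raise TrainingError("family-level split left no training pairs")

    feats = _pair_features(dataset.x1, dataset.x2)
    params = _init_params(dataset.d, config, rng)

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in params.weights]
    v_w = [np.zeros_like(w) for w in params.weights]
    m_b = [np.zeros_like(b) for b in params.biases]
    v_b = [np.zeros_like(b) for b in params.biases]
    step = 0
    losses = []
    for epoch in range(config.epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, gw, gb, _ = _forward_backward(params, feats[batch], labels[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_loss += loss
            n_batches += 1
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in range(len(params.weights)):
                m_w[k] = beta1 * m_w[k] + (1 - beta1) * gw[k]
                v_w[k] = beta2 * v_w[k] + (1 - beta2) * gw[k] ** 2
                params.weights[k] -= lr_t * m_w[k] / (np.sqrt(v_w[k]) + eps)
                m_b[k] = beta1 * m_b[k] + (1 - beta1) * gb[k]
                v_b[k] = beta2 * v_b[k] + (1 - beta2) * gb[k] ** 2
                params.biases[k] -= lr_t * m_b[k] / (np.sqrt(v_b[k]) + eps)
        losses.append(epoch_loss / max(1, n_batches))

    metrics: dict = {"train_loss_first": losses[0], "train_loss_last": losses[-1]}
    if val_idx.size:
        val_loss, _, _, val_logits = _forward_backward(params, feats[val_idx], labels[val_idx])
        metrics["val_loss"] = val_loss
        if len(np.unique(labels[val_idx])) == 2:
            metrics["val_auc"] = auc_score(val_logits, labels[val_idx])
        metrics["val_families"] = sorted(val_fams)

    metadata = {
        "seed": seed,
        "config": {
            "hidden": list(config.hidden),
            "learning_rate": config.learning_rate,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "val_fraction": config.val_fraction,
            "activation": config.activation,
        },
        "dataset": dataset.provenance | {"n_pairs": len(dataset), "seed": dataset.seed},
        "loss_curve": {"first": losses[0], "last": losses[-1]},
        "metrics": metrics,
    }
    return ScorerCheckpoint(params=params, metadata=metadata)


def shuffled_label_dataset(dataset: PairDataset, seed: int) -> PairDataset:
    """Label-permuted control used for parameter-recovery comparisons."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    return PairDataset(
        x1=dataset.x1,
        x2=dataset.x2,
        labels=dataset.labels[perm],
        family_ids=dataset.family_ids,
        seed=dataset.seed,
        provenance=dataset.provenance | {"labels": "shuffled", "shuffle_seed": seed},
    )


def save_checkpoint(checkpoint: ScorerCheckpoint, path: str | Path) -> None:
    params = checkpoint.params
    payload = {
        "format_version": checkpoint.format_version,
        "d": params.d,
        "activation": params.activation,
        "calibration": list(params.calibration),
        "architecture": params.architecture(),
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "metadata": checkpoint.metadata,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_checkpoint(path: str | Path, expected_d: int | None = None) -> ScorerCheckpoint:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot parse checkpoint {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointVersionError(
            f"checkpoint format version {version} is not supported "
            f"(this build reads version {CHECKPOINT_FORMAT_VERSION})"
        )
    d = int(payload["d"])
    if expected_d is not None and d != expected_d:
        raise CheckpointError(
            f"checkpoint was trained for embedding dimension {d}, "
            f"but dimension {expected_d} was requested"
        )
    params = LearnedScorerParams(
        weights=[np.array(w, dtype=float) for w in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        d=d,
        activation=payload.get("activation", "relu"),
        calibration=tuple(payload.get("calibration", (1.0, 0.0))),
    )
    return ScorerCheckpoint(
        params=params,
        metadata=payload.get("metadata", {}),
        format_version=version,
    )
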