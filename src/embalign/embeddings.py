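"""Per-residue embedding providers with deterministic caching.

The synthetic provider is the default, self-contained backend; external
protein-language-model providers can be registered as plug-ins that
conform to :class:`EmbeddingProvider`.  Providers must be deterministic:
the same sequence always yields the same matrix, and results are cached
keyed by (provider_id, exact sequence text).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import SequenceRecord
from .synthetic import synth_embeddings


class EmbeddingError(ValueError):
    pass


class ProviderUnavailableError(EmbeddingError):
    """Requested provider is not installed/registered; never a silent fallback."""


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    sequence_id: str
    vectors: np.ndarray
    provider_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.vectors, dtype=float)
        if arr.ndim != 2:
            raise EmbeddingError("embedding matrix must be 2-D (n residues x d)")
        if arr.shape[0] < 1:
            raise EmbeddingError("embedding matrix must have at least one row")
        if not np.all(np.isfinite(arr)):
            raise EmbeddingError("embedding matrix contains non-finite entries")
        object.__setattr__(self, "vectors", arr)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


class EmbeddingProvider:
    """Deterministic embedding source with transparent caching."""

    provider_id: str = "abstract"
    d: int = 0
    deterministic: bool = True

    def __init__(self, cache_dir: str | Path | None = None) -> None:
        self._memory_cache: dict[str, np.ndarray] = {}
        self._cache_dir = Path(cache_dir) if cache_dir else None
        self.n_computes = 0  # instrumented: cache hits do not bump this

    def _compute(self, seq: SequenceRecord) -> np.ndarray:
        raise NotImplementedError

    def _cache_paths(self, key: str) -> tuple[Path, Path]:
        assert self._cache_dir is not None
        digest = hashlib.sha256(key.encode()).hexdigest()
        stem = self._cache_dir / digest
        return stem.with_suffix(".npy"), stem.with_suffix(".json")

    def embed(self, seq: SequenceRecord) -> ResidueEmbeddingMatrix:
        if seq.alphabet != "protein20":
            raise EmbeddingError(
                f"record {seq.id!r}: embeddings require an ungapped protein sequence"
            )
        key = f"{self.provider_id}\x00{seq.residues}"
        vectors = self._memory_cache.get(key)
        if vectors is None and self._cache_dir is not None:
            npy, meta = self._cache_paths(key)
            if npy.exists() and meta.exists():
                vectors = np.load(npy)
                self._memory_cache[key] = vectors
        if vectors is None:
            vectors = self._compute(seq)
            self.n_computes += 1
            self._memory_cache[key] = vectors
            if self._cache_dir is not None:
                self._cache_dir.mkdir(parents=True, exist_ok=True)
                npy, meta = self._cache_paths(key)
                np.save(npy, vectors)
                meta.write_text(
                    json.dumps(
                        {
                            "provider_id": self.provider_id,
                            "sequence_sha256": hashlib.sha256(
                                seq.residues.encode()
                            ).hexdigest(),
                            "n": int(vectors.shape[0]),
                            "d": int(vectors.shape[1]),
                        }
                    )
                )
        return ResidueEmbeddingMatrix(
            sequence_id=seq.id, vectors=vectors, provider_id=self.provider_id
        )


class SyntheticEmbeddingProvider(EmbeddingProvider):
    """Deterministic synthetic embeddings (identity basis + context + noise)."""

    def __init__(
        self,
        d: int = 32,
        noise_sd: float = 0.0,
        window: int = 1,
        seed: int = 0,
        cache_dir: str | Path | None = None,
    ) -> None:
        super().__init__(cache_dir=cache_dir)
        self.d = d
        self.noise_sd = noise_sd
        self.window = window
        self.seed = seed
        self.provider_id = f"synthetic-v1-d{d}-noise{noise_sd}-w{window}-s{seed}"

    def _compute(self, seq: SequenceRecord) -> np.ndarray:
        return synth_embeddings(
            seq, d=self.d, noise_sd=self.noise_sd, window=self.window, seed=self.seed
        )


_PROVIDER_REGISTRY: dict[str, type] = {}


def register_provider(name: str, cls: type) -> None:
    _PROVIDER_REGISTRY[name] = cls


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    """Instantiate a provider by name; unknown names raise, never fall back."""
    if name == "synthetic":
        return SyntheticEmbeddingProvider(**kwargs)
    if name in _PROVIDER_REGISTRY:
        return _PROVIDER_REGISTRY[name](**kwargs)
    raise ProviderUnavailableError(
        f"embedding provider {name!r} is not available; "
        f"known providers: synthetic{', ' + ', '.join(_PROVIDER_REGISTRY) if _PROVIDER_REGISTRY else ''}"
    )


def sequence_centroid(emb: ResidueEmbeddingMatrix) -> np.ndarray:
    """Arithmetic mean of the residue vectors."""
    if emb.n < 1:
        raise EmbeddingError("cannot take the centroid of an empty matrix")
    return emb.vectors.mean(axis=0)
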