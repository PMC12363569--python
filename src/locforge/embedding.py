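"""Global protein representations from per-residue embeddings.

The representation channel is pluggable: any *backend* that maps a
sanitized sequence to a residues x dim matrix can feed it.  The package
ships a deterministic mock backend (no model weights, no download) used
throughout the test suite; an adapter stub for a real 1280-dimensional
protein language model documents the integration point.

Long sequences that exceed a backend's context window are handled by
non-overlapping segmentation: the sequence is cut into consecutive
segments, each segment is embedded and average-pooled, and the pooled
segment vectors are combined with weights proportional to segment
length.  Length weighting makes segmentation *exact* for average
pooling — the segmented result equals the whole-sequence pooled
embedding whenever the backend embeds a residue independently of its
absolute position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .descriptors import ALPHABET, _AA_INDEX

__all__ = [
    "ResidueEmbeddings",
    "GlobalEmbedding",
    "EmbeddingBackend",
    "MockEmbedder",
    "Esm2Backend",
    "embed_residues",
    "pool_global",
    "embed_long_sequence",
]


@dataclass
class ResidueEmbeddings:
    """Per-residue embedding matrix (length x dim) for one protein."""

    matrix: np.ndarray
    protein_id: str = ""
    backend: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("residue embeddings must be a 2D matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("residue embeddings must be finite")


@dataclass
class GlobalEmbedding:
    """Fixed-length pooled representation of one protein."""

    vector: np.ndarray
    protein_id: str = ""
    segment_count: int = 1

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.ndim != 1 or not np.all(np.isfinite(self.vector)):
            raise ValueError("global embedding must be a finite 1D vector")


class EmbeddingBackend(Protocol):
    """Contract a per-residue embedder must satisfy."""

    name: str
    dim: int
    max_length: int

    def embed(self, sequence: str) -> np.ndarray:
        """Return a len(sequence) x dim matrix."""
        ...


class MockEmbedder:
    """Deterministic stand-in embedder for tests and desk-scale runs.

    Each residue vector is the concatenation of a residue-identity block
    (a seeded random projection of the residue's one-hot code, identical
    wherever the residue occurs) and a smooth positional block (sinusoids
    of seeded frequencies/phases evaluated at the residue's position).
    Setting ``positional=False`` zeroes the positional block, which makes
    the embedder position-independent — the regime in which length-
    weighted segmentation is exactly equivalent to whole-sequence pooling.
    """

    def __init__(
        self,
        dim: int = 64,
        seed: int = 0,
        max_length: int = 1000,
        positional: bool = True,
    ) -> None:
        if dim < 2 or dim % 2:
            raise ValueError("mock dim must be an even integer >= 2")
        self.name = "mock"
        self.dim = dim
        self.seed = seed
        self.max_length = max_length
        self.positional = positional
        half = dim // 2
        rng = np.random.default_rng(seed)
        self._identity_codes = rng.normal(size=(len(ALPHABET), half))
        self._freqs = rng.uniform(0.01, 0.2, size=half)
        self._phases = rng.uniform(0, 2 * np.pi, size=half)

    def embed(self, sequence: str) -> np.ndarray:
        idx = np.fromiter((_AA_INDEX[ch] for ch in sequence), dtype=int, count=len(sequence))
        identity = self._identity_codes[idx]
        if self.positional:
            pos = np.arange(len(sequence))[:, None]
            positional = np.sin(pos * self._freqs[None, :] + self._phases[None, :])
        else:
            positional = np.zeros((len(sequence), self.dim // 2))
        return np.concatenate([identity, positional], axis=1)


class Esm2Backend:
    """Adapter slot for a real 1280-dimensional protein language model.

    The model weights are an optional external dependency; constructing
    this backend without them raises immediately with a pointer to the
    mock backend so pipelines fail fast and loudly.
    """

    name = "esm2"
    dim = 1280
    max_length = 1022

    def __init__(self) -> None:
        try:
            import esm  # type: ignore  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the esm2 backend needs the optional 'fair-esm' package and "
                "model weights; use MockEmbedder (backend='mock') for "
                "download-free runs"
            ) from exc

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional path
        raise NotImplementedError("load weights through the fair-esm API")


def embed_residues(sequence: str, backend: EmbeddingBackend, protein_id: str = "") -> ResidueEmbeddings:
    """Embed one sanitized sequence that fits the backend's context window."""
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    if len(sequence) > backend.max_length:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds backend max "
            f"{backend.max_length}; use embed_long_sequence"
        )
    return ResidueEmbeddings(
        matrix=backend.embed(sequence), protein_id=protein_id, backend=backend.name
    )


def pool_global(residue_embeddings: ResidueEmbeddings) -> GlobalEmbedding:
    """Average-pool residue embeddings into a fixed-length global vector."""
    if residue_embeddings.matrix.shape[0] == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    return GlobalEmbedding(
        vector=residue_embeddings.matrix.mean(axis=0),
        protein_id=residue_embeddings.protein_id,
        segment_count=1,
    )


def embed_long_sequence(
    sequence: str,
    backend: EmbeddingBackend,
    max_segment_length: int | None = None,
    protein_id: str = "",
) -> GlobalEmbedding:
    """Global embedding of a sequence of any length.

    The sequence is split into consecutive non-overlapping segments of at
    most ``max_segment_length`` residues (default: the backend's context
    window); each segment is embedded and pooled, and the segment vectors
    are averaged with weights proportional to segment length.  A sequence
    that fits in a single segment returns exactly the plain pooled
    embedding.
    """
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    seg_len = max_segment_length or backend.max_length
    if seg_len < 1:
        raise ValueError("max_segment_length must be positive")
    segments = [sequence[i : i + seg_len] for i in range(0, len(sequence), seg_len)]
    if len(segments) == 1:
        pooled = pool_global(embed_residues(sequence, backend, protein_id))
        return pooled
    total = len(sequence)
    vector = np.zeros(backend.dim)
    for seg in segments:
        pooled = backend.embed(seg).mean(axis=0)
        vector += (len(seg) / total) * pooled
    return GlobalEmbedding(vector=vector, protein_id=protein_id, segment_count=len(segments))
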