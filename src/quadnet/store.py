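"""Identifier-indexed stores of fixed-length protein embeddings.

Embeddings are produced upstream by a protein language model (1024-dim
per-protein vectors in the intended use) and consumed here as an N×D
matrix keyed by protein identifier.  On disk the store is an HDF5 file
with an ``embeddings`` matrix and a parallel ``identifiers`` dataset,
plus a plain-text sidecar index (one identifier per line) so the
contents are inspectable without HDF5 tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Protocol, Sequence

import h5py
import numpy as np
from Bio import SeqIO

__all__ = ["EmbeddingStore", "SequenceEmbedder", "store_from_fasta"]


class EmbeddingStore:
    def __init__(self, identifiers: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError(f"embedding matrix must be 2-D, got shape {matrix.shape}")
        if len(identifiers) != matrix.shape[0]:
            raise ValueError(
                f"{len(identifiers)} identifiers for {matrix.shape[0]} rows"
            )
        if len(set(identifiers)) != len(identifiers):
            raise ValueError("duplicate identifiers in store")
        self.identifiers = list(identifiers)
        self.matrix = matrix
        self._index = {pid: i for i, pid in enumerate(self.identifiers)}

    def __len__(self) -> int:
        return len(self.identifiers)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, pid: str) -> np.ndarray:
        try:
            return self.matrix[self._index[pid]]
        except KeyError:
            raise KeyError(f"protein identifier not in store: {pid!r}") from None

    def rows(self, pids: Iterable[str]) -> np.ndarray:
        """Matrix of embeddings in the order of ``pids``."""
        idx = []
        for pid in pids:
            if pid not in self._index:
                raise KeyError(f"protein identifier not in store: {pid!r}")
            idx.append(self._index[pid])
        return self.matrix[np.asarray(idx, dtype=np.intp)]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("embeddings", data=self.matrix)
            f.create_dataset(
                "identifiers",
                data=np.array(self.identifiers, dtype=h5py.string_dtype()),
            )
        path.with_suffix(path.suffix + ".index.txt").write_text(
            "\n".join(self.identifiers) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingStore":
        with h5py.File(path, "r") as f:
            matrix = f["embeddings"][...]
            identifiers = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["identifiers"][...]
            ]
        return cls(identifiers, matrix)


class SequenceEmbedder(Protocol):
    """Adapter contract for an external per-protein sequence embedder.

    Implementations map amino-acid sequences to fixed-length vectors
    (e.g. a pretrained protein language model served out of process).
    """

    dim: int

    def embed(self, sequences: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(sequences), dim)."""
        ...


def store_from_fasta(fasta_path: str | Path, embedder: SequenceEmbedder) -> EmbeddingStore:
    """Embed every record of a FASTA file through the adapter."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    matrix = embedder.embed([str(r.seq) for r in records])
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != (len(records), embedder.dim):
        raise ValueError(
            f"embedder returned shape {matrix.shape}, expected ({len(records)}, {embedder.dim})"
        )
    return EmbeddingStore([r.id for r in records], matrix)
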