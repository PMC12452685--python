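"""Pairwise distance estimation (1 - percent identity) between proteins."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import global_align


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")

    def __len__(self) -> int:
        return len(self.labels)


def estimate_distances(
    records,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> DistanceMatrix:
    """All-vs-all 1 - identity distances from pairwise global alignments."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(
                records[i].residues, records[j].residues, matrix, gap_open, gap_extend
            )
            d[i, j] = d[j, i] = 1.0 - res.identity
    return DistanceMatrix(labels=[r.accession for r in records], d=d)
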