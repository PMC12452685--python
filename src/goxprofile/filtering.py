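"""Dataset-construction filters.

Three filters build the working dataset from a raw homolog search result:

1. header-keyword exclusion (partial / synthetic / hypothetical / fragment),
2. a sequence-length window (420-460 residues by default, bracketing the
   430-residue reference), and
3. a reference-anchored percent-identity band (strictly between 35% and 97%,
   so the reference itself and near-duplicates fall out at the top).

"Similarity" is implemented as percent identity from a global alignment under
a BLOSUM62 scoring model with affine gaps (open 11 / extend 1); terminal gap
columns are excluded from the identity denominator so that length differences
inside the window do not dominate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ALLOWED_RESIDUES, SequenceRecord


@dataclass
class FilterConfig:
    min_len: int = 420
    max_len: int = 460
    min_identity: float = 0.35
    max_identity: float = 0.97
    exclusion_keywords: tuple[str, ...] = ("partial", "synthetic", "hypothetical", "fragment")
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity < self.max_identity <= 1):
            raise ValueError("need 0 <= min_identity < max_identity <= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        self.exclusion_keywords = tuple(k.lower() for k in self.exclusion_keywords)


@dataclass
class PairwiseAlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # biopython convention: a gap of length L scores open + (L-1)*extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def aligned_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical positions / columns, terminal gap columns excluded."""
    n = len(aligned_a)
    if n != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    start = 0
    while start < n and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    end = n
    while end > start and (aligned_a[end - 1] == "-" or aligned_b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    same = sum(1 for i in range(start, end) if aligned_a[i] == aligned_b[i])
    return same / cols


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignmentResult:
    """Optimal global alignment of two protein sequences.

    Returns the first optimal alignment reported by the dynamic program
    (deterministic for fixed inputs) together with its score and percent
    identity.
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid characters {sorted(bad)!r}")
    a, b = a.upper(), b.upper()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    return PairwiseAlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity=aligned_identity(aligned_a, aligned_b),
    )


def exclude_by_keywords(
    records, config: FilterConfig | None = None
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Drop records whose description contains an exclusion keyword.

    Returns (kept, dropped) where each dropped entry carries the triggering
    keyword.
    """
    config = config or FilterConfig()
    kept, dropped = [], []
    for rec in records:
        desc = rec.description.lower()
        hit = next((kw for kw in config.exclusion_keywords if kw in desc), None)
        if hit is None:
            kept.append(rec)
        else:
            dropped.append((rec, hit))
    return kept, dropped


def length_filter(records, config: FilterConfig | None = None) -> list[SequenceRecord]:
    """Keep records with min_len <= length <= max_len (inclusive)."""
    config = config or FilterConfig()
    return [r for r in records if config.min_len <= len(r) <= config.max_len]


def identity_band_filter(
    records,
    reference: SequenceRecord,
    config: FilterConfig | None = None,
    return_identities: bool = False,
):
    """Keep records strictly inside the reference identity band.

    A record is kept iff ``min_identity < identity(record, reference) <
    max_identity``; in particular the reference itself (identity 1.0) is
    excluded by the upper bound.
    """
    config = config or FilterConfig()
    kept, identities = [], {}
    for rec in records:
        res = global_align(
            rec.residues, reference.residues, config.matrix, config.gap_open, config.gap_extend
        )
        identities[rec.accession] = res.identity
        if config.min_identity < res.identity < config.max_identity:
            kept.append(rec)
    if return_identities:
        return kept, identities
    return kept
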