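"""Progressive multiple sequence alignment over a UPGMA guide tree.

The aligner follows the classic progressive scheme: estimate pairwise
1 - identity distances, build a UPGMA guide tree, then merge sub-alignments
("profiles") in post-order with a profile-profile global alignment.  Column
pairs are scored by the mean pairwise substitution score between the two
columns' residue distributions (BLOSUM62 by default); gaps are affine
(open 11 / extend 1) with terminal gaps half-weighted.  Gaps, once inserted
into a profile, are never removed, so every output row ungaps back to its
input sequence exactly.

The dynamic program is the Gotoh three-state recursion.  The insertion state
is computed with a running-maximum scan (max-plus prefix), which keeps the
whole row vectorized; traceback prefers match over insertion (gap in the
second profile) over deletion, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .distances import DistanceMatrix, estimate_distances
from .phylogeny import upgma

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows with their labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("rows have unequal lengths")
        for j in range(width):
            if all(r[j] == "-" for r in self.rows):
                raise ValueError(f"all-gap column at position {j + 1}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        """Residues of 1-based column j."""
        return "".join(r[j - 1] for r in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.rows):
                fh.write(f">{label}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(labels=labels, rows=rows)


def build_guide_tree(dm: DistanceMatrix) -> TreeNode:
    """UPGMA guide tree over the distance matrix (shared with the phylogeny)."""
    return upgma(dm)


def _load_matrix(name: str) -> np.ndarray:
    sub = substitution_matrices.load(name)
    m = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            m[i, j] = sub[a, b]
    return m


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 21) residue frequency matrix; gap rows contribute zero weight."""
    arr = np.zeros((len(rows[0]), len(_ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                arr[j, _AA_INDEX[ch]] += 1.0
    return arr / len(rows)


_M, _X, _Y = 0, 1, 2  # match, gap-in-B (consume A), gap-in-A (consume B)


def _profile_align(
    rows_a: list[str], rows_b: list[str], sub: np.ndarray, go: float, ge: float
) -> tuple[list[str], list[str]]:
    """Globally align two profiles; returns gap-expanded rows of each side."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    S = _profile(rows_a) @ sub @ _profile(rows_b).T  # (la, lb) column scores
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)
    Y = np.full((la + 1, lb + 1), neg)
    M[0, 0] = 0.0
    i_idx = np.arange(1, la + 1)
    j_idx = np.arange(1, lb + 1)
    X[1:, 0] = -(go / 2 + (i_idx - 1) * ge / 2)  # leading gap in B, half-weighted
    Y[0, 1:] = -(go / 2 + (j_idx - 1) * ge / 2)  # leading gap in A, half-weighted
    for i in range(1, la + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = S[i - 1] + np.maximum.reduce(
            [prevM[:-1], prevX[:-1], prevY[:-1]]
        )
        X[i, :] = np.maximum.reduce([prevM - go, prevX - ge, prevY - go])
        X[i, 0] = -(go / 2 + (i - 1) * ge / 2)
        # terminal column: the gap in B runs to the end, charge half weight
        X[i, lb] = max(prevM[lb] - go / 2, prevX[lb] - ge / 2, prevY[lb] - go / 2)
        go_row = go / 2 if i == la else go
        ge_row = ge / 2 if i == la else ge
        # Y[i, j] = max_{k<j} (max(M[i,k], X[i,k]) - go - (j-1-k) ge): prefix scan
        Z = np.maximum(M[i], X[i]) - go_row + np.arange(lb + 1) * ge_row
        run = np.maximum.accumulate(Z)
        Y[i, 1:] = run[:-1] - (j_idx - 1) * ge_row
    # traceback
    pairs: list[tuple[int | None, int | None]] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # pref M > X > Y on ties
    tol = 1e-6

    def pick(cand, target):
        for s in (_M, _X, _Y):
            if abs(cand[s] - target) <= tol:
                return s
        return int(np.argmax(cand))

    while i > 0 or j > 0:
        if j == 0:  # only a leading gap in B remains
            pairs.extend((k, None) for k in range(i - 1, -1, -1))
            break
        if i == 0:  # only a leading gap in A remains
            pairs.extend((None, k) for k in range(j - 1, -1, -1))
            break
        if state == _M:
            pairs.append((i - 1, j - 1))
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = pick(cand, target)
        elif state == _X:
            pairs.append((i - 1, None))
            gox, gex = (go / 2, ge / 2) if j == lb else (go, ge)
            cand = (M[i - 1, j] - gox, X[i - 1, j] - gex, Y[i - 1, j] - gox)
            target = X[i, j]
            i = i - 1
            state = pick(cand, target)
        else:
            pairs.append((None, j - 1))
            goy, gey = (go / 2, ge / 2) if i == la else (go, ge)
            cand = (M[i, j - 1] - goy, X[i, j - 1] - goy, Y[i, j - 1] - gey)
            target = Y[i, j]
            j = j - 1
            state = pick(cand, target)
    pairs.reverse()
    out_a = ["".join(row[p] if p is not None else "-" for p, _ in pairs) for row in rows_a]
    out_b = ["".join(row[q] if q is not None else "-" for _, q in pairs) for row in rows_b]
    return out_a, out_b


def progressive_align(
    records,
    guide: TreeNode | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Align records progressively along the guide tree (UPGMA by default)."""
    records = list(records)
    by_acc = {r.accession: r for r in records}
    if guide is None:
        guide = build_guide_tree(estimate_distances(records, matrix, gap_open, gap_extend))
    tip_names = {t.name for t in guide.tips()} if guide.children else {guide.name}
    if tip_names != set(by_acc):
        raise ValueError("guide tree leaves do not match record accessions")
    sub = _load_matrix(matrix)

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [by_acc[node.name].residues]
        labels, rows = merge(node.children[0])
        for child in node.children[1:]:
            labels_b, rows_b = merge(child)
            rows, rows_b = _profile_align(rows, rows_b, sub, gap_open, gap_extend)
            labels = labels + labels_b
            rows = rows + rows_b
        return labels, rows

    labels, rows = merge(guide)
    order = {acc: k for k, acc in enumerate(labels)}
    out_labels = [r.accession for r in records]
    out_rows = [rows[order[r.accession]] for r in records]
    return MultipleAlignment(labels=out_labels, rows=out_rows)
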