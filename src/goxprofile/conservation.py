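"""Per-column physicochemical conservation scoring of an alignment.

Each alignment column receives an integer score on a 0-11 scale in the AMAS
tradition: 11 means absolute conservation (a single residue type and no
gaps); otherwise the score counts the physicochemical properties (out of the
ten in the packaged table: hydrophobic, polar, small, tiny, aliphatic,
aromatic, positive, negative, charged, proline) whose presence or absence is
uniform across the column's residues, capped at 10 — so 10 means the
residues vary but share every property profile.  Residue types below a small
minority frequency (3% of non-gap rows by default) are ignored when checking
uniformity, as a sprinkle of substitutions in an otherwise fixed column
should not erase its property signal; columns that are more than 20% gaps
lose one point.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .msa import MultipleAlignment

#: Gap penalty threshold: columns gappier than this lose one score point.
GAP_FRACTION_PENALTY = 0.2


def load_property_table(path=None) -> dict[str, set[str]]:
    """Property -> residue-set table (the single source for scoring)."""
    if path is None:
        path = importlib.resources.files("goxprofile.data").joinpath("property_table.tsv")
    df = pd.read_csv(path, sep="\t")
    return {str(r.property): set(str(r.residues)) for r in df.itertuples(index=False)}


def uniform_property_count(residues: set[str], props: dict[str, set[str]]) -> int:
    """Number of properties shared (all present or all absent) by `residues`."""
    count = 0
    for members in props.values():
        flags = {r in members for r in residues}
        if len(flags) == 1:
            count += 1
    return count


@dataclass
class ColumnProfile:
    """Statistics of one alignment column (1-based index)."""

    index: int
    counts: dict[str, int]
    gap_count: int
    n_rows: int
    score: int
    modal_residues: list[str] = field(default_factory=list)

    @property
    def top_freq(self) -> float:
        """Frequency of the modal residue (gap rows in the denominator)."""
        if not self.modal_residues:
            return 0.0
        return self.counts[self.modal_residues[0]] / self.n_rows

    @property
    def top2_freq(self) -> float:
        """Joint frequency of the two most frequent residues."""
        top = self.modal_residues[:2]
        return sum(self.counts[r] for r in top) / self.n_rows

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.n_rows

    def frequency(self, residue: str) -> float:
        return self.counts.get(residue, 0) / self.n_rows


def score_column(residues: str, props: dict[str, set[str]], minority_threshold: float = 0.03) -> int:
    """Conservation score of a raw column string (gaps as '-')."""
    n = len(residues)
    non_gap = [r for r in residues if r != "-"]
    gap_count = n - len(non_gap)
    types = set(non_gap)
    if not types:
        return 0
    if len(types) == 1 and gap_count == 0:
        return 11
    counts: dict[str, int] = {}
    for r in non_gap:
        counts[r] = counts.get(r, 0) + 1
    considered = {r for r, c in counts.items() if c / len(non_gap) > minority_threshold}
    if not considered:
        considered = {max(counts, key=lambda r: (counts[r], r))}
    score = min(uniform_property_count(considered, props), 10)
    if gap_count / n > GAP_FRACTION_PENALTY:
        score = max(score - 1, 0)
    return score


@dataclass
class ConsensusTrack:
    """Ordered column profiles plus a consensus symbol per column."""

    columns: list[ColumnProfile]
    consensus: str

    def __len__(self) -> int:
        return len(self.columns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": [c.index for c in self.columns],
                "consensus": list(self.consensus),
                "score": [c.score for c in self.columns],
                "top_freq": [c.top_freq for c in self.columns],
                "gap_frac": [c.gap_fraction for c in self.columns],
            }
        )


def profile_columns(
    msa: MultipleAlignment,
    props: dict[str, set[str]] | None = None,
    minority_threshold: float = 0.03,
) -> ConsensusTrack:
    """Compute per-column counts, frequencies and conservation scores."""
    if props is None:
        props = load_property_table()
    columns = []
    consensus_chars = []
    n = msa.n_rows
    for j in range(1, msa.column_count + 1):
        col = msa.column(j)
        counts: dict[str, int] = {}
        gap_count = 0
        for ch in col:
            if ch == "-":
                gap_count += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        modal = sorted(counts, key=lambda r: (-counts[r], r))
        columns.append(
            ColumnProfile(
                index=j,
                counts=counts,
                gap_count=gap_count,
                n_rows=n,
                score=score_column(col, props, minority_threshold),
                modal_residues=modal,
            )
        )
        if gap_count > n / 2 or not modal:
            consensus_chars.append("-")
        else:
            consensus_chars.append(modal[0])
    return ConsensusTrack(columns=columns, consensus="".join(consensus_chars))
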