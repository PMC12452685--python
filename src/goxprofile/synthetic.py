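"""Synthetic protein-family generation with planted ground truth.

Every pipeline stage is testable offline against families produced here: the
generator emits annotated FASTA (accession, protein-name label, bracketed
organism at a mixed taxonomic rank), region-annotation TSV rows, and a truth
table recording exactly what was planted — clade membership, divergence,
header fields, motif columns, architecture labels.

Defaults mirror the study conditions the pipeline targets: sequences of
420-460 residues around a ~440-residue root, protein-name labels drawn with
the printed per-ontology proportions, taxonomy annotated at mixed ranks with
the printed rank proportions (0.3% domain, 2.8% phylum, 10.7% class, 7.8%
order, 7.6% family, 32.8% genus, 38% species), and clade structure imposed as
a balanced split with between-clade divergence well above within-clade
divergence.  Background residues are i.i.d. uniform over the 20 amino acids
unless an empirical frequency vector is supplied; indels never touch planted
motif spans, mirroring conserved blocks flanked by gappy regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ARCHITECTURE_LABELS, DEFAULT_RULES, RegionAnnotation
from .motifs import AMINO_ACIDS, MotifPattern, load_known_patterns
from .msa import MultipleAlignment
from .seqio import SequenceRecord, TaxonomyTable, normalize_ontology, load_ontology_counts

#: Printed dataset rank-annotation proportions (deepest populated rank).
RANK_PROPORTIONS = {
    "domain": 0.003,
    "phylum": 0.028,
    "class": 0.107,
    "order": 0.078,
    "family": 0.076,
    "genus": 0.328,
    "species": 0.380,
}


def _random_residues(rng: np.random.Generator, n: int, freqs: np.ndarray | None = None) -> str:
    if freqs is None:
        idx = rng.integers(0, 20, size=n)
    else:
        idx = rng.choice(20, size=n, p=freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _realized_positions(pattern: MotifPattern) -> list:
    """Flatten tokens to one position each, variable wildcards at min length."""
    out = []
    for tok in pattern.tokens:
        if tok.is_wild:
            out.extend([None] * tok.min_len)
        else:
            out.append(tok.residues)  # members, planted-majority first
    return out


def planted_alignment(
    patterns: list[MotifPattern],
    n_rows: int = 200,
    n_cols: int = 400,
    conservation: float = 0.95,
    min_separation: int = 10,
    seed: int = 0,
    class_majority: float = 0.6,
) -> tuple[MultipleAlignment, list[dict]]:
    """Gapless alignment of uniform background with motifs planted in order.

    Each pattern occupies a contiguous column span; at anchor columns each row
    carries the token residue with probability `conservation` (class members
    split `class_majority` / remainder in listed order) and a uniform random
    residue otherwise.  Spans are separated by at least `min_separation`
    background columns.  Returns the alignment and the per-motif truth
    (name, rendering, 1-based start/end columns).
    """
    rng = np.random.default_rng(seed)
    flat = [_realized_positions(p) for p in patterns]
    total = sum(len(f) for f in flat)
    slack = n_cols - total
    gap = slack // (len(patterns) + 1)
    if gap < min_separation:
        raise ValueError(
            f"cannot fit {len(patterns)} patterns ({total} columns) in {n_cols} "
            f"columns with separation {min_separation}"
        )
    grid = np.array(
        [list(_random_residues(rng, n_cols)) for _ in range(n_rows)], dtype="<U1"
    )
    truth = []
    cursor = gap
    for pattern, positions in zip(patterns, flat):
        for k, members in enumerate(positions):
            if members is None:
                continue
            col = cursor + k
            conserved = rng.random(n_rows) < conservation
            if len(members) == 1:
                grid[conserved, col] = members
            else:
                probs = np.full(len(members), (1 - class_majority) / (len(members) - 1))
                probs[0] = class_majority
                draws = rng.choice(len(members), size=n_rows, p=probs)
                rows = np.where(conserved)[0]
                grid[rows, col] = np.array(list(members))[draws[rows]]
        truth.append(
            {
                "name": pattern.name,
                "pattern": pattern.render(),
                "start_column": cursor + 1,
                "end_column": cursor + len(positions),
            }
        )
        cursor += len(positions) + gap
    rows = ["".join(row) for row in grid]
    labels = [f"ROW{i:04d}" for i in range(n_rows)]
    return MultipleAlignment(labels=labels, rows=rows), truth


@dataclass
class SimulationConfig:
    """Knobs of the family simulator; defaults are the study conditions."""

    n_sequences: int = 60
    length_range: tuple[int, int] = (420, 460)
    n_clades: int = 2
    clade_separation: float = 0.4  # substitution fraction root -> clade ancestor
    within_divergence: float = 0.05  # substitution fraction ancestor -> sequence
    planted_motifs: list[tuple[MotifPattern, int, float]] = field(default_factory=list)
    background_freqs: np.ndarray | None = None
    keyword_fraction: float = 0.0
    annotate_regions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid length range")
        for _, offset, level in self.planted_motifs:
            if not (0.0 <= level <= 1.0):
                raise ValueError("conservation level outside [0, 1]")
            if offset < 1:
                raise ValueError("motif offsets are 1-based")


@dataclass
class SimulatedFamily:
    records: list[SequenceRecord]
    regions: pd.DataFrame
    truth: pd.DataFrame
    motif_truth: list[dict]
    taxonomy: TaxonomyTable

    def write(self, fasta_path, regions_path=None, truth_path=None) -> None:
        from .seqio import write_fasta

        write_fasta(self.records, fasta_path)
        if regions_path is not None:
            self.regions.to_csv(regions_path, sep="\t", index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _mutate(seq: list[str], fraction: float, rng, protected: set[int]) -> tuple[list[str], int]:
    """Substitute ~fraction of unprotected positions; returns (seq, count)."""
    free = [i for i in range(len(seq)) if i not in protected]
    k = int(round(fraction * len(free)))
    if k == 0:
        return seq, 0
    sites = rng.choice(len(free), size=k, replace=False)
    out = list(seq)
    for s in sites:
        i = free[s]
        old = out[i]
        choices = AMINO_ACIDS.replace(old, "")
        out[i] = choices[rng.integers(len(choices))]
    return out, k


_ARCH_REGIONS = {
    "1a": [],
    "1b": [("transmembrane", "TMhelix", 5, 22)],
    "1c": [("non_cytoplasmic", "-", 30, 400)],
    "1d": [("cytoplasmic", "-", 1, 40), ("non_cytoplasmic", "-", 60, 400)],
    "1e": [("transmembrane", "TMhelix", 5, 22), ("non_cytoplasmic", "-", 30, 400)],
    "1f": [
        ("transmembrane", "TMhelix", 5, 22),
        ("cytoplasmic", "-", 30, 60),
        ("non_cytoplasmic", "-", 80, 400),
    ],
    "2a": [("SIGNAL_PEPTIDE", "-", 1, 22)],
    "2b": [("SIGNAL_PEPTIDE", "-", 1, 22), ("non_cytoplasmic", "-", 30, 400)],
    "2c": [
        ("SignalP_noTM", "-", 1, 22),
        ("cytoplasmic", "-", 30, 60),
        ("non_cytoplasmic", "-", 80, 400),
    ],
    "2d": [
        ("SIGNAL_PEPTIDE", "-", 1, 22),
        ("TMhelix", "TMhelix", 25, 45),
        ("cytoplasmic", "-", 50, 80),
        ("non_cytoplasmic", "-", 100, 400),
    ],
}


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate an annotated protein family with full ground truth.

    A root sequence is mutated into clade ancestors (clade separation) and
    then into per-sequence variants (within-clade divergence); indels adjust
    each sequence's length within the configured window, never inside planted
    motif spans.  Headers carry sampled protein-name labels (printed-table
    proportions) and organisms at sampled ranks; optional exclusion keywords
    are planted in a recorded fraction of descriptions.  Deterministic for a
    fixed config.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    root_len = (lo + hi) // 2
    protected: set[int] = set()
    for pattern, offset, _ in config.planted_motifs:
        span = len(_realized_positions(pattern))
        if offset - 1 + span > root_len:
            raise ValueError(f"motif {pattern.name or pattern.render()} exceeds root length")
        protected.update(range(offset - 1, offset - 1 + span))
    root = list(_random_residues(rng, root_len, config.background_freqs))

    ancestors = []
    for _ in range(config.n_clades):
        anc, _ = _mutate(root, config.clade_separation, rng, protected)
        ancestors.append(anc)

    counts = load_ontology_counts()
    labels = counts["label"].tolist()
    label_p = (counts["count"] / counts["count"].sum()).to_numpy()
    taxonomy = TaxonomyTable.synthetic_default()
    by_rank: dict[str, list[str]] = {}
    for org, (rank, _) in taxonomy.entries.items():
        by_rank.setdefault(rank, []).append(org)
    rank_names = list(RANK_PROPORTIONS)
    rank_p = np.array(list(RANK_PROPORTIONS.values()))
    rank_p = rank_p / rank_p.sum()

    records: list[SequenceRecord] = []
    truth_rows = []
    region_rows = []
    n = config.n_sequences
    for i in range(n):
        clade = i * config.n_clades // n
        seq, nsub = _mutate(ancestors[clade], config.within_divergence, rng, protected)
        # plant motifs per conservation level
        for pattern, offset, level in config.planted_motifs:
            for k, members in enumerate(_realized_positions(pattern)):
                if members is None:
                    continue
                if rng.random() < level:
                    if len(members) == 1:
                        seq[offset - 1 + k] = members
                    else:
                        seq[offset - 1 + k] = members[0 if rng.random() < 0.6 else 1]
        # indels adjust length to a sampled target; to keep planted offsets
        # valid they happen strictly after the last protected position
        target = int(rng.integers(lo, hi + 1))
        seq = list(seq)
        boundary = (max(protected) + 1) if protected else 0
        if boundary < len(seq):
            while len(seq) < target:
                at = int(rng.integers(boundary, len(seq) + 1))
                seq.insert(at, AMINO_ACIDS[rng.integers(20)])
            while len(seq) > target and len(seq) > boundary + 1:
                at = int(rng.integers(boundary, len(seq)))
                del seq[at]
        residues = "".join(seq)

        accession = f"SYN{i:05d}.1"
        ontology = labels[rng.choice(len(labels), p=label_p)]
        rank = rank_names[rng.choice(len(rank_names), p=rank_p)]
        pool = by_rank.get(rank) or sum(by_rank.values(), [])
        organism = sorted(pool)[rng.integers(len(pool))]
        has_keyword = bool(rng.random() < config.keyword_fraction)
        shown_ontology = "hypothetical protein" if has_keyword else ontology
        description = f"{accession} {shown_ontology} [{organism}]"
        rec = SequenceRecord(
            accession=accession,
            description=description,
            residues=residues,
            ontology_raw=shown_ontology,
            ontology_grouped=normalize_ontology(shown_ontology),
            organism=organism,
            taxonomy=taxonomy.lookup(organism),
        )
        records.append(rec)
        arch_label = ARCHITECTURE_LABELS[rng.integers(len(ARCHITECTURE_LABELS))]
        if config.annotate_regions:
            for rtype, rname, start, end in _ARCH_REGIONS[arch_label]:
                region_rows.append(
                    {
                        "accession": accession,
                        "type": rtype,
                        "name": rname,
                        "start": start,
                        "end": min(end, len(residues)),
                        "source": "SYNTHETIC",
                    }
                )
        truth_rows.append(
            {
                "accession": accession,
                "clade": clade + 1,
                "ontology_raw": shown_ontology,
                "ontology_grouped": normalize_ontology(shown_ontology),
                "organism": organism,
                "best_rank": rank,
                "length": len(residues),
                "n_substitutions": nsub,
                "has_keyword": has_keyword,
                "architecture": arch_label if config.annotate_regions else "",
            }
        )
    motif_truth = [
        {
            "name": p.name,
            "pattern": p.render(),
            "start": offset,
            "end": offset + len(_realized_positions(p)) - 1,
            "conservation": level,
        }
        for p, offset, level in config.planted_motifs
    ]
    return SimulatedFamily(
        records=records,
        regions=pd.DataFrame(
            region_rows, columns=["accession", "type", "name", "start", "end", "source"]
        ),
        truth=pd.DataFrame(truth_rows),
        motif_truth=motif_truth,
        taxonomy=taxonomy,
    )


def planted_cluster_matrix(
    n_clades: int = 10,
    leaves_per_clade: int = 3,
    within: float = 0.1,
    between_group: float = 0.4,
    across: tuple[float, float] = (0.8, 1.2),
    groups: dict[int, str] | None = None,
):
    """Ultrametric distance matrix with planted clades and supergroups.

    Default layout mirrors a 10-cluster tree whose unrooted view shows four
    groups: A = clades 1-4, B = 5-6, C = 7-8, D = 9-10, with groups (A, B)
    and (C, D) each merging before the root.  Returns (DistanceMatrix, truth
    DataFrame with clade and group per leaf).
    """
    from .distances import DistanceMatrix

    if groups is None:
        groups = {1: "A", 2: "A", 3: "A", 4: "A", 5: "B", 6: "B",
                  7: "C", 8: "C", 9: "D", 10: "D"}
    side = {"A": 0, "B": 0, "C": 1, "D": 1}  # which half of the root split
    labels, clade_of = [], {}
    for c in range(1, n_clades + 1):
        for i in range(leaves_per_clade):
            name = f"C{c:02d}_{i}"
            labels.append(name)
            clade_of[name] = c
    n = len(labels)
    d = np.zeros((n, n))
    near, far = across
    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = clade_of[labels[a]], clade_of[labels[b]]
            if ca == cb:
                dist = within
            elif groups[ca] == groups[cb]:
                dist = between_group
            elif side[groups[ca]] == side[groups[cb]]:
                dist = near
            else:
                dist = far
            d[a, b] = d[b, a] = dist
    truth = pd.DataFrame(
        {
            "leaf": labels,
            "clade": [clade_of[x] for x in labels],
            "group": [groups[clade_of[x]] for x in labels],
        }
    )
    return DistanceMatrix(labels=labels, d=d), truth


def plant_paper_fixtures(seed: int = 0) -> dict:
    """Fixture bundle exercising the printed worked examples.

    Contains (i) a 200-row alignment with the eight named motifs and the
    proline-rich composite planted in printed order, (ii) the packaged
    transcriptions of the printed ontology/class count tables, and (iii) a
    planted 10-clade, 4-supergroup distance matrix.
    """
    from .seqio import load_class_counts

    known = load_known_patterns()
    motif_names = [f"M{i}" for i in range(1, 9)]
    patterns = [known[name] for name in motif_names] + [known["prm_composite"]]
    alignment, motif_truth = planted_alignment(
        patterns, n_rows=200, n_cols=400, conservation=0.95, seed=seed
    )
    dm, tree_truth = planted_cluster_matrix()
    return {
        "alignment": alignment,
        "motif_truth": motif_truth,
        "ontology_counts": load_ontology_counts(),
        "class_counts": load_class_counts(),
        "cluster_matrix": dm,
        "cluster_truth": tree_truth,
    }
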