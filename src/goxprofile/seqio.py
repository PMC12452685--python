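"""FASTA I/O and header annotation.

Headers of NCBI-style protein FASTA files carry three pieces of metadata this
package relies on: the accession (first whitespace-delimited token), the
protein-name label — called the "ontology" throughout, as is common in this
corner of the literature, not to be confused with a formal GO term — and the
source organism inside the last balanced ``[...]`` span.  This module parses
those fields, normalizes and groups ontology labels, attaches taxonomy from a
packaged lookup table (never a network call), and produces the dataset-level
aggregation reports (ontology counts, taxonomy rank/class counts).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = set(AMINO_ACIDS + "X")

#: Taxonomic ranks from shallowest to deepest.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_ORGANISM_RE = re.compile(r"\[([^\[\]]*)\]\s*$")


def _data_path(name: str):
    return importlib.resources.files("goxprofile.data").joinpath(name)


def canonical_key(label: str) -> str:
    """Case-insensitive key with runs of spaces/underscores/hyphens collapsed."""
    return re.sub(r"[\s_\-]+", " ", label.strip().lower()).strip()


@dataclass
class OntologyGroupingRules:
    """Two-stage label normalization: spelling synonyms, then activity groups.

    Both maps are keyed by :func:`canonical_key` of the raw label, so matching
    ignores case and punctuation runs.  Applying the rules is idempotent: every
    output label is a fixed point of the rules.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.synonym_map = {canonical_key(k): v for k, v in self.synonym_map.items()}
        self.group_map = {canonical_key(k): v for k, v in self.group_map.items()}

    @classmethod
    def from_yaml(cls, path) -> "OntologyGroupingRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(synonym_map=raw.get("synonym_map", {}), group_map=raw.get("group_map", {}))

    @classmethod
    def default(cls) -> "OntologyGroupingRules":
        return cls.from_yaml(_data_path("ontology_rules.yaml"))


def normalize_ontology(label: str, rules: OntologyGroupingRules | None = None) -> str:
    """Map a raw protein-name label to its grouped subtype label.

    Synonyms are resolved first, then activity grouping; labels unknown to both
    maps are returned unchanged, so the function is total and idempotent.
    """
    if rules is None:
        rules = OntologyGroupingRules.default()
    label = rules.synonym_map.get(canonical_key(label), label)
    return rules.group_map.get(canonical_key(label), label)


@dataclass
class TaxonomyTable:
    """Organism name -> (deepest rank, lineage) lookup loaded from a TSV.

    The TSV has columns ``organism``, ``rank``, ``lineage`` where lineage is a
    semicolon-separated prefix of (domain, phylum, class, order, family, genus,
    species) ending at ``rank``.  Unknown organisms resolve to an empty map.
    """

    entries: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        entries = {}
        for row in df.itertuples(index=False):
            entries[str(row.organism)] = (str(row.rank), str(row.lineage).split(";"))
        return cls(entries)

    @classmethod
    def synthetic_default(cls) -> "TaxonomyTable":
        """The packaged synthetic stand-in table (no NCBI access)."""
        return cls.from_tsv(_data_path("synthetic_taxonomy.tsv"))

    def lookup(self, organism: str) -> dict[str, str]:
        if organism not in self.entries:
            return {}
        rank, lineage = self.entries[organism]
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r} for organism {organism!r}")
        depth = RANKS.index(rank) + 1
        return dict(zip(RANKS[:depth], lineage[:depth]))


@dataclass
class SequenceRecord:
    """One annotated protein sequence."""

    accession: str
    description: str
    residues: str
    ontology_raw: str = ""
    ontology_grouped: str = ""
    organism: str = ""
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)!r}"
            )

    @property
    def best_rank(self) -> str | None:
        """Deepest populated taxonomy rank, or None."""
        best = None
        for rank in RANKS:
            if self.taxonomy.get(rank):
                best = rank
        return best

    def __len__(self) -> int:
        return len(self.residues)


def parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA description line into (accession, ontology_raw, organism).

    The accession is the first whitespace token, the organism the last balanced
    bracketed span, and the ontology the trimmed text between them.
    """
    header = header.strip()
    if not header:
        raise ValueError("empty FASTA header")
    parts = header.split(None, 1)
    accession = parts[0]
    rest = parts[1] if len(parts) > 1 else ""
    m = _ORGANISM_RE.search(rest)
    if m:
        organism = m.group(1).strip()
        ontology = rest[: m.start()].strip()
    else:
        organism = ""
        ontology = rest.strip()
    return accession, ontology, organism


def _check_fasta_syntax(path) -> None:
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                seen_header = True
            elif not seen_header:
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
        if not seen_header:
            raise ValueError(f"{path}: no FASTA records found")


def read_annotated_fasta(
    path,
    taxonomy: TaxonomyTable | None = None,
    rules: OntologyGroupingRules | None = None,
) -> list[SequenceRecord]:
    """Read a protein FASTA and populate header-derived annotation.

    Raises on malformed FASTA (naming the offending line) and on duplicate
    accessions (listing them).
    """
    _check_fasta_syntax(path)
    if rules is None:
        rules = OntologyGroupingRules.default()
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, ontology, organism = parse_header(rec.description)
        tax = taxonomy.lookup(organism) if (taxonomy and organism) else {}
        records.append(
            SequenceRecord(
                accession=accession,
                description=rec.description,
                residues=str(rec.seq),
                ontology_raw=ontology,
                ontology_grouped=normalize_ontology(ontology, rules) if ontology else "",
                organism=organism,
                taxonomy=tax,
            )
        )
    seen: dict[str, int] = {}
    for r in records:
        seen[r.accession] = seen.get(r.accession, 0) + 1
    dupes = sorted(a for a, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate accessions: {', '.join(dupes)}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA, sequence lines wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Aggregation reports
# ---------------------------------------------------------------------------


def ontology_report(
    records=None,
    counts: pd.DataFrame | None = None,
    rules: OntologyGroupingRules | None = None,
) -> pd.DataFrame:
    """Per-subtype (grouped label) count/fraction table.

    Accepts either parsed records or a ``(label, count)`` DataFrame of raw
    label tallies (e.g. the packaged printed-table transcription).
    """
    if rules is None:
        rules = OntologyGroupingRules.default()
    tallies: dict[str, int] = {}
    if counts is not None:
        if counts.empty:
            raise ValueError("empty ontology count table")
        for row in counts.itertuples(index=False):
            sub = normalize_ontology(str(row.label), rules)
            tallies[sub] = tallies.get(sub, 0) + int(row.count)
    else:
        if not records:
            raise ValueError("no records given")
        for rec in records:
            sub = rec.ontology_grouped or normalize_ontology(rec.ontology_raw, rules)
            tallies[sub] = tallies.get(sub, 0) + 1
    total = sum(tallies.values())
    df = pd.DataFrame(
        {"subtype": list(tallies), "count": list(tallies.values())}
    ).sort_values(["count", "subtype"], ascending=[False, True], ignore_index=True)
    df["fraction"] = df["count"] / total
    return df


def taxonomy_report(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(rank-level, class-level) count tables.

    Each record contributes once to its deepest populated rank, so rank
    fractions sum to 1; class counts cover records annotated at class depth or
    deeper, with the remainder reported as "Undefined".
    """
    n = len(records)
    rank_counts = {rank: 0 for rank in RANKS}
    rank_counts["none"] = 0
    class_counts: dict[str, int] = {}
    for rec in records:
        rank_counts[rec.best_rank or "none"] += 1
        class_counts.setdefault(rec.taxonomy.get("class", "Undefined"), 0)
        class_counts[rec.taxonomy.get("class", "Undefined")] += 1
    rank_df = pd.DataFrame(
        {"rank": list(rank_counts), "count": list(rank_counts.values())}
    )
    rank_df["fraction"] = rank_df["count"] / n if n else 0.0
    class_df = pd.DataFrame(
        {"class": list(class_counts), "count": list(class_counts.values())}
    ).sort_values(["count", "class"], ascending=[False, True], ignore_index=True)
    return rank_df, class_df


def load_ontology_counts() -> pd.DataFrame:
    """Packaged transcription of the printed per-ontology count table."""
    return pd.read_csv(_data_path("ontology_counts.tsv"), sep="\t")


def load_class_counts() -> pd.DataFrame:
    """Packaged transcription of the printed per-phylum/class count table."""
    return pd.read_csv(_data_path("class_counts.tsv"), sep="\t")


def phylum_totals(class_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum class-level counts up to phylum level."""
    return (
        class_counts.groupby("phylum", as_index=False)["count"]
        .sum()
        .sort_values(["count", "phylum"], ascending=[False, True], ignore_index=True)
    )
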