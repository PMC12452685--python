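"""Domain-architecture classification from per-sequence region annotations.

Region annotations (signal peptide, transmembrane, cytoplasmic and
non-cytoplasmic spans, plus named domains such as DadA or FAD-dep_OxRdtase)
are consumed from TSV tables standing in for InterPro/CDD/Phobius output —
nothing is predicted de novo here.  Synonymous labels from different source
databases are merged (SIGNAL_PEPTIDE and SignalP_noTM are one "signal
peptide" region; TMhelix and TRANSMEMBRANE are one "transmembrane" region).

Architectures split into two groups on the signal-peptide indicator alone:
group 1 lacks it, group 2 has it.  Subcategories are defined by the presence
pattern of transmembrane / cytoplasmic / non-cytoplasmic regions, ordered by
increasing combination complexity; the default rule table covers every
pattern and is editable, since the subcategory boundaries are depicted
graphically rather than stated — named domains do not affect the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REGION_TYPES = (
    "signal_peptide",
    "transmembrane",
    "cytoplasmic",
    "non_cytoplasmic",
    "named_domain",
)

_LABEL_MERGE = {
    "signal_peptide": "signal_peptide",
    "signal peptide": "signal_peptide",
    "signal-peptide": "signal_peptide",
    "signalp_notm": "signal_peptide",
    "tmhelix": "transmembrane",
    "transmembrane": "transmembrane",
    "cytoplasmic": "cytoplasmic",
    "non_cytoplasmic": "non_cytoplasmic",
    "non-cytoplasmic": "non_cytoplasmic",
    "noncytoplasmic": "non_cytoplasmic",
    "non cytoplasmic": "non_cytoplasmic",
}


def merge_labels(raw: str) -> str:
    """Map a raw region-type string to the merged closed type set.

    Case-insensitive; unknown labels are treated as named domains.
    """
    return _LABEL_MERGE.get(raw.strip().lower(), "named_domain")


@dataclass
class RegionAnnotation:
    accession: str
    region_type: str
    name: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise ValueError(f"unknown region type {self.region_type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.accession}: invalid region coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def load_regions(path, records=None) -> list[RegionAnnotation]:
    """Load region annotations from TSV (accession, type, name, start, end, source).

    When records are given, coordinates are validated against sequence lengths
    and out-of-range rows raise with accession and row number.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "type", "name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region TSV missing columns: {sorted(missing)}")
    lengths = {r.accession: len(r) for r in records} if records else {}
    out = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        acc = str(row.accession)
        if end < start or start < 1:
            raise ValueError(f"row {rownum} ({acc}): invalid coordinates {start}..{end}")
        if acc in lengths and end > lengths[acc]:
            raise ValueError(
                f"row {rownum} ({acc}): region end {end} exceeds sequence length {lengths[acc]}"
            )
        out.append(
            RegionAnnotation(
                accession=acc,
                region_type=merge_labels(str(row.type)),
                name="" if pd.isna(row.name) else str(row.name),
                start=start,
                end=end,
                source=str(getattr(row, "source", "")),
            )
        )
    return out


#: Default subcategory rules: (signal peptide present, frozen presence set of
#: transmembrane/cytoplasmic/non_cytoplasmic) -> architecture label.  Ordered
#: by increasing region-combination complexity within each group.
DEFAULT_RULES: dict[tuple[bool, frozenset], str] = {
    (False, frozenset()): "1a",
    (False, frozenset({"transmembrane"})): "1b",
    (False, frozenset({"non_cytoplasmic"})): "1c",
    (False, frozenset({"cytoplasmic"})): "1c",
    (False, frozenset({"cytoplasmic", "non_cytoplasmic"})): "1d",
    (False, frozenset({"transmembrane", "non_cytoplasmic"})): "1e",
    (False, frozenset({"transmembrane", "cytoplasmic"})): "1e",
    (False, frozenset({"transmembrane", "cytoplasmic", "non_cytoplasmic"})): "1f",
    (True, frozenset()): "2a",
    (True, frozenset({"transmembrane"})): "2b",
    (True, frozenset({"non_cytoplasmic"})): "2b",
    (True, frozenset({"cytoplasmic"})): "2b",
    (True, frozenset({"cytoplasmic", "non_cytoplasmic"})): "2c",
    (True, frozenset({"transmembrane", "non_cytoplasmic"})): "2c",
    (True, frozenset({"transmembrane", "cytoplasmic"})): "2c",
    (True, frozenset({"transmembrane", "cytoplasmic", "non_cytoplasmic"})): "2d",
}

ARCHITECTURE_LABELS = ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c", "2d")


def classify_architecture(
    regions: list[RegionAnnotation],
    rules: dict[tuple[bool, frozenset], str] | None = None,
) -> str:
    """Architecture group label for one sequence's regions.

    Group 1 iff no signal peptide, group 2 otherwise; the subcategory follows
    the presence pattern of transmembrane / cytoplasmic / non-cytoplasmic
    regions.  A sequence with no predicted regions at all is 1a.
    """
    rules = rules or DEFAULT_RULES
    types = {r.region_type for r in regions}
    sp = "signal_peptide" in types
    pattern = frozenset(types & {"transmembrane", "cytoplasmic", "non_cytoplasmic"})
    key = (sp, pattern)
    if key not in rules:
        raise ValueError(f"no architecture rule for pattern {key!r}")
    return rules[key]


def classify_all(
    regions: list[RegionAnnotation],
    records,
    rules: dict[tuple[bool, frozenset], str] | None = None,
) -> dict[str, str]:
    """Classify every record; records without annotations fall into 1a."""
    by_acc: dict[str, list[RegionAnnotation]] = {r.accession: [] for r in records}
    for region in regions:
        if region.accession not in by_acc:
            raise ValueError(f"region for unknown accession {region.accession!r}")
        by_acc[region.accession].append(region)
    return {acc: classify_architecture(regs, rules) for acc, regs in by_acc.items()}


def architecture_distributions(
    groups: dict[str, str],
    assignment=None,
    records=None,
) -> dict[str, pd.DataFrame]:
    """Group-by-cluster and group-by-phylum count and presence tables."""
    rows = []
    tax = {r.accession: r.taxonomy.get("phylum", "Undefined") for r in records} if records else {}
    for acc, label in groups.items():
        rows.append(
            {
                "accession": acc,
                "group": label,
                "cluster": assignment.assignment.get(acc) if assignment else None,
                "phylum": tax.get(acc, "Undefined"),
            }
        )
    df = pd.DataFrame(rows)
    out: dict[str, pd.DataFrame] = {}
    if assignment is not None:
        counts = pd.crosstab(df["group"], df["cluster"])
        out["group_by_cluster_counts"] = counts
        out["group_by_cluster"] = counts > 0
    if records is not None:
        counts = pd.crosstab(df["group"], df["phylum"])
        out["group_by_phylum_counts"] = counts
        out["group_by_phylum"] = counts > 0
    return out
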