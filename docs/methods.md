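# Methods

This note records the models, parameter choices and numerical conventions
behind `goxprofile`, and what the synthetic benchmarks do and do not show.

## Dataset construction

Headers are parsed under the NCBI FASTA convention: the accession is the
first whitespace-delimited token, the organism is the last balanced `[...]`
span, and the protein-name label ("ontology" — a header phrase, not a GO
term) is the trimmed text between them. Ontology normalization is a
two-stage map: spelling synonyms first (matched case-insensitively with
runs of spaces/underscores/hyphens collapsed, since the same label appears
with several punctuations in practice), then activity grouping that
collapses, e.g., all D-amino acid dehydrogenase variants into one
"(D-) amino acid dehydrogenase" subtype. Both maps ship as an editable YAML
config; applying them twice equals applying them once, and unknown labels
pass through unchanged. Taxonomy comes from a packaged lookup table keyed
by organism name (the shipped default is a synthetic stand-in covering the
lineages the simulator emits) — never a network call — and each record is
counted once at its deepest populated rank, so rank fractions sum to 1.

Three filters build the working set, and they commute:

- **keywords** — drop any record whose description contains one of
  `partial`, `synthetic`, `hypothetical`, `fragment` (case-insensitive);
  the first three are the standard exclusions for this kind of homolog
  sweep, `fragment` is added because truncated entries otherwise survive
  the length window.
- **length** — keep 420–460 residues inclusive, bracketing the 430-residue
  reference.
- **identity band** — keep records whose percent identity to the reference
  lies strictly between 0.35 and 0.97. "Similarity" is implemented as
  percent identity from a global alignment (BLOSUM62, affine gap open 11 /
  extend 1, via `Bio.Align.PairwiseAligner`): identity is the conservative,
  reproducible reading, and the metric is configurable. The denominator
  excludes terminal gap columns so length differences inside the window do
  not dominate; the strict upper bound removes the reference itself and
  near-duplicates.

## Progressive alignment

Pairwise distances are 1 − identity. The guide tree is UPGMA; profiles are
merged in post-order. Column pairs score as the inner product of the two
columns' residue-frequency vectors through the substitution matrix (i.e.
the mean pairwise substitution score between the column distributions, with
gap rows contributing zero weight, which softly discourages aligning
against gappy columns). Gaps are affine (open 11 / extend 1) with terminal
gaps half-weighted; the insertion state of the Gotoh recursion is computed
with a running-maximum (max-plus prefix) scan so each DP row stays
vectorized. Traceback ties prefer match over insertion over deletion,
deterministically. There is no iterative refinement: the downstream motif
thresholds are frequency-based and tolerant of small alignment differences,
and single-pass progressive alignment keeps the pipeline deterministic.
Gaps once inserted are never removed, which guarantees every output row
ungaps to its input exactly.

## UPGMA phylogeny and clusters

UPGMA merges the closest pair under arithmetic-mean linkage at height d/2;
among equally close pairs the one whose smallest original leaf index is
lowest merges first, so ties produce deterministic trees. The output is
exactly ultrametric and reproduces ultrametric inputs' cophenetic matrices
to machine precision (and matches scipy's average-linkage cophenetics on
tie-free inputs — scipy serves as the cross-check, not the implementation,
because the tie rule and the tree/cut machinery live here). Cutting removes
the k−1 highest internal nodes; the surviving subtrees are the k
monophyletic clusters, numbered by first appearance in tip order. The same
construction with only the g−1 highest nodes yields the g "supergroups"
visible in the unrooted view; defaults k = 10 and g = 4 are config values,
not constants. By default the tree reuses the 1 − identity distances of
the guide tree. Heights are reported as such: no rooting-based claims about
ancientness are made by the code.

Cluster composition tables are plain crosstabs; the focus-subtype summary
reports each cluster's fraction and the median over all clusters including
zeros. Representative selection is greedy coverage (reference first, then
one per cluster and one per subtype, then proportional-to-cluster-size
fill) under a seeded generator, so a selection is reproducible from
(records, assignment, n, seed).

## Conservation score and motif extraction

Each column gets an integer 0–11. A column with exactly one residue type
and no gaps scores 11 (absolute conservation). Otherwise the score counts
the physicochemical properties — ten in the packaged table: hydrophobic,
polar, small, tiny, aliphatic, aromatic, positive, negative, charged,
proline — whose presence or absence is uniform across the column's residue
types, capped at 10; a column more than 20% gaps loses one point. Two
refinements matter:

- **Minority exclusion.** Residue types below 3% of the column's non-gap
  rows are ignored when checking property uniformity. A sprinkle of
  substitutions in an otherwise fixed column should not erase its property
  signal — this mirrors how alignment-annotation tools in practice ignore
  infrequent residues — and without it no realistic column (e.g. 95%
  conserved) could ever reach the score-9 threshold. The threshold is a
  parameter of `profile_columns`.
- **Property table.** The sets follow the classical amino-acid Venn
  diagram, with one deliberate edit: valine is excluded from "small", so
  that the canonical hydrophobic triple {V, I, L} is uniform across all
  ten properties and scores 10. The packaged TSV is the single source for
  scoring.

A column is *conserved* iff score ≥ 9 and its modal frequency — or the
joint frequency of its top two residues — is ≥ 0.80, with gap rows in the
denominator (a gappy column cannot be 80% conserved). Conserved columns
render as a fixed residue (modal frequency ≥ 0.80) or a two-residue class
ordered by descending frequency, ties alphabetical. Maximal blocks of
conserved columns are joined across interior wildcard runs of ≤ 3 (printed
motifs contain at most `x-x-x` interior runs) and kept if they span ≥ 6
columns with ≥ 3 anchors. The proline-rich region is handled by its own
detector because its spacings exceed that run length: columns with proline
frequency ≥ 0.80 inside a 60-column window are collected, consecutive
spacings of 3 and 2 report as P-x-x-x-P and P-x-x-P, and the composite
rendering (explicit `x` runs up to 3, `(x)k` beyond) regenerates the
spacing exactly.

Pattern matching enumerates wildcard-length assignments. Subsumption
(every string matching B also matches A) is decided exactly: for each
concrete assignment of B, the alphabet at every position is quotiented into
membership-equivalence classes against A's same-length assignments, and
one representative per class is enumerated — coverage depends only on the
membership vector, so this agrees with brute-force string enumeration at a
tiny fraction of the cost.

## Domain architectures

Region types merge across source databases (SIGNAL_PEPTIDE and
SignalP_noTM → signal peptide; TMhelix and TRANSMEMBRANE → transmembrane);
unknown labels are named domains and never affect grouping. Group 1 vs 2 is
exactly the signal-peptide indicator. The subcategory mapping from the
presence pattern of {transmembrane, cytoplasmic, non-cytoplasmic} is an
editable rule table; the shipped default orders subcategories by increasing
combination complexity (1a = nothing, 1b = transmembrane only — the
reference's architecture — up to 1f = all three; 2a = signal peptide only
up to 2d = all three) and covers every pattern, since the source
classification is depicted rather than enumerated. Region overlap is
allowed. Empty groups are legal (2a is typically empty).

## Synthetic families

The simulator mutates a root sequence (~440 aa) into clade ancestors and
then into per-sequence variants; defaults are 40% between-clade and 5%
within-clade substitution, which puts between-clade identity far below
within-clade identity so clade recovery is well-posed. Indels adjust each
sequence's length within 420–460 and occur only outside (after) planted
motif spans, so planted offsets stay valid — mirroring conserved blocks
flanked by variable regions. Planted motif columns carry their token
residue with the configured conservation level (class members split
60/40 in listed order, which reproduces frequency-ordered class rendering);
background residues are i.i.d. uniform over the 20 amino acids unless an
empirical frequency vector is supplied. Headers sample ontology labels with
the packaged table's proportions and organisms at ranks drawn with the
dataset's printed rank proportions. Everything is deterministic under the
config seed, and a truth table records every planted fact.

The planted-alignment benchmark (200 rows × 400 columns, eight motifs at
95% per-column conservation, ≥ 10 background columns between motifs) is
deliberately idealized: uniform background, no alignment error, no gap
columns, independence across rows. Passing it shows the thresholding and
block-joining logic recover exactly the planted tokens under realistic
conservation levels; it does not show robustness to misalignment,
compositional bias or phylogenetic correlation between rows, which real
alignments have. Likewise the planted cluster matrix (10 clades, 4
supergroups, within-clade 0.1 / between 0.4–1.2) tests the cutting
machinery, not distance estimation on hard families.

## Problem sizes and determinism

The shipped tests and the acceptance script use scaled-down problem sizes —
families of 16–40 sequences for end-to-end runs, 200-row alignments for
motif benchmarks, 20 seeded replicates for stochastic checks — chosen so
the full suite completes in well under a minute while still exercising
every code path at realistic per-column statistics. All randomness flows
from explicit seeds (`numpy.random.default_rng`); reruns are byte-identical,
and the pipeline manifest checksums every stage output to make that
verifiable.

## Known limitations

- Percent identity stands in for whatever "similarity" the original
  retrieval used; the band bounds are strict inequalities by reading of
  "more than 35%" / "less than 97%".
- The conservation score is a reconstruction of the alignment-annotation
  scale it emulates, pinned here (property table, minority exclusion, gap
  penalty) rather than copied from any tool's source; scores from other
  software may differ by a point on edge cases.
- The architecture subcategory boundaries beyond the group-1/group-2 gate
  are a documented reconstruction and should be re-mapped via the rule
  table if an authoritative definition is available.
- Cluster numbering matches any published numbering only up to relabeling,
  since it derives from tip order of the tree at hand.
- O(n²) pairwise alignment and O(n³) UPGMA are fine for thousands of
  sequences but not tens of thousands; k-mer pre-screening for distance
  estimation is the natural extension and is not implemented.
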