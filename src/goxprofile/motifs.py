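"""PROSITE-style motif patterns: extraction, matching, subsumption, PRM.

A motif pattern is an ordered list of tokens in the field's dash notation:

* a fixed residue, e.g. ``G``;
* a residue class, e.g. ``[V/I]`` (any listed residue, most frequent first);
* a wildcard run: ``x`` (one arbitrary residue), ``x(m,n)`` (between m and n
  residues, also accepted in the printed forms ``x1-2``/``x1–2``), or
  ``(x)k`` (exactly k residues).

Patterns are extracted from a conservation track by thresholding columns
(score >= 9 and modal — or top-two — frequency >= 80% by default), joining
conserved columns across short interior wildcard runs, and keeping blocks
that are long enough and anchored enough.  Matching enumerates wildcard
length assignments; subsumption (does every string matching pattern B also
match pattern A?) is decided exactly by quotienting the alphabet at each
position into membership-equivalence classes, so it agrees with brute-force
string enumeration while staying cheap.

The proline-rich-motif (PRM) detector is separate because its spacings are
longer than the wildcard runs the block extractor will bridge: it collects
high-frequency proline columns inside a window and reports their P-x-x-x-P /
P-x-x-P spacings and the composite spacing pattern.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import pandas as pd

from .conservation import ConsensusTrack

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CLASS_RE = re.compile(r"^\[([A-Z](?:/[A-Z])+)\]$")
_WILD_RANGE_RE = re.compile(r"^x\((\d+),(\d+)\)$")
_WILD_COMPACT_RE = re.compile(r"^x(\d+)[-–](\d+)$")
_WILD_REPEAT_RE = re.compile(r"^\(x\)(\d+)$")


@dataclass(frozen=True)
class MotifToken:
    kind: str  # "fixed" | "class" | "wild"
    residues: str = ""  # fixed/class members, most frequent first
    min_len: int = 1
    max_len: int = 1

    def render(self) -> str:
        if self.kind == "fixed":
            return self.residues
        if self.kind == "class":
            return "[" + "/".join(self.residues) + "]"
        if (self.min_len, self.max_len) == (1, 1):
            return "x"
        if self.min_len == self.max_len:
            return f"(x){self.min_len}"
        return f"x({self.min_len},{self.max_len})"

    @property
    def is_wild(self) -> bool:
        return self.kind == "wild"


def _parse_token(tok: str) -> MotifToken:
    tok = tok.strip()
    if re.fullmatch(r"[A-Z]", tok):
        return MotifToken("fixed", tok)
    m = _CLASS_RE.match(tok)
    if m:
        return MotifToken("class", m.group(1).replace("/", ""))
    if tok == "x":
        return MotifToken("wild")
    for rx in (_WILD_RANGE_RE, _WILD_COMPACT_RE):
        m = rx.match(tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if not (1 <= lo <= hi):
                raise ValueError(f"bad wildcard bounds in token {tok!r}")
            return MotifToken("wild", min_len=lo, max_len=hi)
    m = _WILD_REPEAT_RE.match(tok)
    if m:
        k = int(m.group(1))
        if k < 1:
            raise ValueError(f"bad wildcard repeat in token {tok!r}")
        return MotifToken("wild", min_len=k, max_len=k)
    raise ValueError(f"unparseable motif token {tok!r}")


@dataclass
class MotifPattern:
    """Ordered motif tokens with a canonical dash-separated rendering."""

    tokens: list[MotifToken]
    name: str = ""
    start_column: int | None = None
    end_column: int | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty pattern")
        if self.tokens[0].is_wild or self.tokens[-1].is_wild:
            raise ValueError("first and last pattern tokens must not be wildcards")

    @classmethod
    def parse(cls, text: str, name: str = "") -> "MotifPattern":
        # normalize the printed compact range form (x1-2 / x1–2) before
        # splitting on dashes
        text = re.sub(r"x(\d+)[-–](\d+)", r"x(\1,\2)", text.strip())
        tokens = [_parse_token(t) for t in text.split("-") if t.strip()]
        return cls(tokens=tokens, name=name)

    def render(self) -> str:
        return "-".join(t.render() for t in self.tokens)

    def __str__(self) -> str:
        return self.render()

    @property
    def anchor_count(self) -> int:
        return sum(1 for t in self.tokens if not t.is_wild)

    def length_range(self) -> tuple[int, int]:
        lo = sum(t.min_len for t in self.tokens)
        hi = sum(t.max_len for t in self.tokens)
        return lo, hi

    def _assignments(self):
        """Yield concrete position-sets; None marks a wildcard (any residue)."""
        var = [
            (i, t.min_len, t.max_len)
            for i, t in enumerate(self.tokens)
            if t.is_wild and t.min_len != t.max_len
        ]

        def expand(lengths: dict[int, int]):
            sets: list[frozenset[str] | None] = []
            for i, t in enumerate(self.tokens):
                if t.is_wild:
                    k = lengths.get(i, t.min_len)
                    sets.extend([None] * k)
                else:
                    sets.append(frozenset(t.residues))
            return sets

        def rec(idx, lengths):
            if idx == len(var):
                yield expand(lengths)
                return
            i, lo, hi = var[idx]
            for k in range(lo, hi + 1):
                yield from rec(idx + 1, {**lengths, i: k})

        yield from rec(0, {})


@dataclass
class MotifHit:
    start: int  # 1-based inclusive
    end: int
    matched: str


def match_pattern(pattern: MotifPattern, seq: str) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of the pattern in a sequence.

    Variable-length wildcards are enumerated, so a single start position can
    yield hits of several lengths; identical (start, end) spans are reported
    once.
    """
    seq = seq.upper()
    spans: set[tuple[int, int]] = set()
    for sets in pattern._assignments():
        L = len(sets)
        for s in range(len(seq) - L + 1):
            if all(sets[k] is None or seq[s + k] in sets[k] for k in range(L)):
                spans.add((s + 1, s + L))
    return [MotifHit(a, b, seq[a - 1 : b]) for a, b in sorted(spans)]


def pattern_subsumes(
    general: MotifPattern, specific: MotifPattern, alphabet: str = AMINO_ACIDS
) -> bool:
    """True iff every string matching `specific` also matches `general`.

    Whether a string is matched by a concrete assignment depends only on each
    character's membership in the assignment's position sets, so it suffices
    to test one representative character per membership-equivalence class at
    every position.
    """
    alpha = set(alphabet)
    general_by_len: dict[int, list[list[frozenset[str]]]] = {}
    for sets in general._assignments():
        gsets = [frozenset(alpha) if s is None else frozenset(s & alpha) for s in sets]
        general_by_len.setdefault(len(gsets), []).append(gsets)
    for sets in specific._assignments():
        L = len(sets)
        boxes = general_by_len.get(L)
        if not boxes:
            return False
        reps_per_pos: list[list[str]] = []
        for p in range(L):
            sp = alpha if sets[p] is None else sets[p] & alpha
            if not sp:
                break  # position unsatisfiable over this alphabet
            classes: dict[tuple[bool, ...], str] = {}
            for ch in sorted(sp):
                key = tuple(ch in box[p] for box in boxes)
                classes.setdefault(key, ch)
            reps_per_pos.append(sorted(classes.values()))
        else:
            def covered(prefix: list[str], p: int, alive: list[int]) -> bool:
                if p == L:
                    return bool(alive)
                for ch in reps_per_pos[p]:
                    nxt = [b for b in alive if ch in boxes[b][p]]
                    if not nxt:
                        return False
                    if not covered(prefix + [ch], p + 1, nxt):
                        return False
                return True

            if not covered([], 0, list(range(len(boxes)))):
                return False
            continue
        continue  # unsatisfiable assignment matches nothing: vacuously subsumed
    return True


# ---------------------------------------------------------------------------
# Motif extraction from a conservation track
# ---------------------------------------------------------------------------


def _column_token(col, min_freq: float) -> MotifToken:
    if col.top_freq >= min_freq:
        return MotifToken("fixed", col.modal_residues[0])
    return MotifToken("class", "".join(col.modal_residues[:2]))


def extract_motifs(
    track: ConsensusTrack,
    min_score: int = 9,
    min_freq: float = 0.80,
    max_wildcard_run: int = 3,
    min_length: int = 6,
    min_anchors: int = 3,
) -> list[MotifPattern]:
    """Threshold-based motif extraction from a profiled alignment.

    A column is conserved iff its score is at least `min_score` and its modal
    (or joint top-two) frequency is at least `min_freq`.  Conserved columns
    render as a fixed residue (modal frequency >= `min_freq`) or a two-residue
    class; maximal blocks of conserved columns are joined across interior
    runs of at most `max_wildcard_run` non-conserved columns, and blocks are
    kept iff they span at least `min_length` columns with at least
    `min_anchors` conserved ones.  Blocks are named M1, M2, ... by start
    column.
    """
    conserved = [
        c.index
        for c in track.columns
        if c.score >= min_score and (c.top_freq >= min_freq or c.top2_freq >= min_freq)
    ]
    if not conserved:
        return []
    blocks: list[list[int]] = [[conserved[0]]]
    for idx in conserved[1:]:
        if idx - blocks[-1][-1] - 1 <= max_wildcard_run:
            blocks[-1].append(idx)
        else:
            blocks.append([idx])
    cols = {c.index: c for c in track.columns}
    out = []
    for block in blocks:
        span = block[-1] - block[0] + 1
        if span < min_length or len(block) < min_anchors:
            continue
        tokens = []
        anchor_set = set(block)
        for j in range(block[0], block[-1] + 1):
            if j in anchor_set:
                tokens.append(_column_token(cols[j], min_freq))
            else:
                tokens.append(MotifToken("wild"))
        out.append(
            MotifPattern(tokens=tokens, start_column=block[0], end_column=block[-1])
        )
    out.sort(key=lambda p: p.start_column)
    for i, p in enumerate(out, start=1):
        p.name = f"M{i}"
    return out


# ---------------------------------------------------------------------------
# Proline-rich motif detection
# ---------------------------------------------------------------------------


@dataclass
class PRMReport:
    proline_columns: list[int]
    submotifs: list[dict] = field(default_factory=list)
    composite: str = ""
    frequencies: dict[int, float] = field(default_factory=dict)

    @property
    def n_prolines(self) -> int:
        return len(self.proline_columns)


def render_spacing(positions: list[int]) -> str:
    """Dash-notation composite for proline positions.

    Gaps of up to three columns print as explicit ``x`` runs, longer gaps as
    ``(x)k``, mirroring the conventional rendering of proline-rich regions.
    """
    if not positions:
        return ""
    parts = ["P"]
    for prev, cur in zip(positions, positions[1:]):
        gap = cur - prev - 1
        if gap <= 3:
            parts.extend(["x"] * gap)
        else:
            parts.append(f"(x){gap}")
        parts.append("P")
    return "-".join(parts)


def positions_from_composite(composite: str) -> list[int]:
    """Invert :func:`render_spacing`: proline positions implied by a composite."""
    pattern = MotifPattern.parse(composite)
    pos = []
    cursor = 0
    for tok in pattern.tokens:
        if tok.is_wild:
            if tok.min_len != tok.max_len:
                raise ValueError("composite has variable-length wildcards")
            cursor += tok.min_len
        else:
            cursor += 1
            if "P" in tok.residues:
                pos.append(cursor)
    return pos


def detect_prm(
    source: ConsensusTrack | str,
    min_freq: float = 0.80,
    window: int = 60,
) -> PRMReport:
    """Detect a proline-rich region in a consensus track or plain consensus.

    Collects columns whose proline frequency is at least `min_freq`, keeps the
    densest run fitting in `window` columns, and reports P-x-x-x-P / P-x-x-P
    spacings among consecutive prolines plus the composite spacing pattern.
    """
    if isinstance(source, str):
        freqs = {i + 1: (1.0 if ch == "P" else 0.0) for i, ch in enumerate(source)}
    else:
        freqs = {c.index: c.frequency("P") for c in source.columns}
    candidates = [i for i in sorted(freqs) if freqs[i] >= min_freq]
    if not candidates:
        return PRMReport(proline_columns=[])
    best: list[int] = []
    for k, start in enumerate(candidates):
        run = [p for p in candidates[k:] if p - start + 1 <= window]
        if len(run) > len(best):
            best = run
    submotifs = []
    for prev, cur in zip(best, best[1:]):
        gap = cur - prev - 1
        if gap == 3:
            submotifs.append({"kind": "PxxxP", "start": prev, "end": cur})
        elif gap == 2:
            submotifs.append({"kind": "PxxP", "start": prev, "end": cur})
    return PRMReport(
        proline_columns=best,
        submotifs=submotifs,
        composite=render_spacing(best),
        frequencies={p: freqs[p] for p in best},
    )


def load_known_patterns() -> dict[str, MotifPattern]:
    """The packaged library of named patterns (M1-M8, Rossmann-fold, PRM)."""
    path = importlib.resources.files("goxprofile.data").joinpath("known_patterns.tsv")
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.name): MotifPattern.parse(str(r.pattern), name=str(r.name))
        for r in df.itertuples(index=False)
    }
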