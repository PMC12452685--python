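"""Motif pattern parsing, matching, subsumption, extraction and the PRM."""

import itertools

import numpy as np
import pytest

from goxprofile.conservation import profile_columns
from goxprofile.motifs import (
    MotifPattern,
    MotifToken,
    detect_prm,
    extract_motifs,
    match_pattern,
    pattern_subsumes,
    positions_from_composite,
    render_spacing,
)
from goxprofile.synthetic import planted_alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


from _oracles import oracle_match, oracle_subsumes, random_pattern

# --- parsing -----------------------------------------------------------------


class TestPatternParsing:
    @pytest.mark.parametrize(
        "text",
        [
            "[V/I]-[I/V]-G-A-G-x-[V/I]-G-x-x-x-A",
            "P-x-x-x-P-(x)6-P-(x)5-P-x-x-P-(x)8-P-x-x-x-P",
            "[V/I]-x-G-x(1,2)-G-x-x-G-x-x-x-[G/A]",
            "W-x-x-x-[F/Y]",
        ],
    )
    def test_render_parse_round_trip(self, text):
        pattern = MotifPattern.parse(text)
        assert MotifPattern.parse(pattern.render()).render() == pattern.render()

    def test_printed_wildcard_range_form(self):
        # "x1-2" is the printed form of x(1,2)
        p = MotifPattern.parse("G-x1-2-G")
        assert p.render() == "G-x(1,2)-G"

    def test_unparseable_token_named(self):
        with pytest.raises(ValueError, match="qq"):
            MotifPattern.parse("A-qq-B")

    def test_wildcard_ends_rejected(self):
        with pytest.raises(ValueError, match="wildcard"):
            MotifPattern.parse("x-A-B")

    def test_random_round_trips(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            p = random_pattern(rng, alphabet=AA[:6])
            assert MotifPattern.parse(p.render()).render() == p.render()


# --- matching ----------------------------------------------------------------


class TestMatchPattern:
    def test_pxxxp_simple_hit(self):
        hits = match_pattern(MotifPattern.parse("P-x-x-x-P"), "PAAAP")
        assert [(h.start, h.end) for h in hits] == [(1, 5)]
        assert hits[0].matched == "PAAAP"

    def test_rossmann_spans_instantiated_example(self, known_patterns):
        hits = match_pattern(known_patterns["rossmann_extended"], "VIGAGSVGLLLA")
        assert [(h.start, h.end) for h in hits] == [(1, 12)]

    def test_overlapping_hits_all_reported(self):
        hits = match_pattern(MotifPattern.parse("P-x-x-P"), "PAAPAAP")
        assert [(h.start, h.end) for h in hits] == [(1, 4), (4, 7)]

    def test_matches_exhaustive_oracle(self):
        """200 random (pattern, 60-mer) cases agree with brute force."""
        rng = np.random.default_rng(33)
        for _ in range(200):
            pattern = random_pattern(rng, alphabet="ABC", max_tokens=4)
            seq = "".join("ABC"[int(rng.integers(3))] for _ in range(60))
            got = {(h.start, h.end) for h in match_pattern(pattern, seq)}
            assert got == oracle_match(pattern, seq)


class TestPatternSubsumes:
    def test_extended_rossmann_subsumes_m1(self, known_patterns):
        assert pattern_subsumes(known_patterns["rossmann_extended"], known_patterns["M1"])

    def test_m1_does_not_subsume_rossmann(self, known_patterns):
        assert not pattern_subsumes(known_patterns["M1"], known_patterns["rossmann_extended"])

    def test_length_mismatch_unsatisfiable(self):
        general = MotifPattern.parse("P-x-x-x-P")
        specific = MotifPattern.parse("P-x-x-P")
        assert not pattern_subsumes(general, specific)

    def test_agrees_with_string_enumeration_oracle(self):
        rng = np.random.default_rng(34)
        checked = 0
        for _ in range(120):
            general = random_pattern(rng, alphabet="ABC", max_tokens=4)
            specific = random_pattern(rng, alphabet="ABC", max_tokens=4)
            if specific.length_range()[1] > 8:
                continue
            got = pattern_subsumes(general, specific, alphabet="ABC")
            want = oracle_subsumes(general, specific, "ABC")
            assert got == want, (general.render(), specific.render())
            checked += 1
        assert checked > 60


# --- extraction --------------------------------------------------------------


class TestExtractMotifs:
    def test_fully_conserved_alignment_is_one_motif(self, make_record):
        from goxprofile.msa import MultipleAlignment

        row = "VIGAGSVGLLLAWCHWCHWC"
        msa = MultipleAlignment(labels=[f"r{i}" for i in range(5)], rows=[row] * 5)
        found = extract_motifs(profile_columns(msa))
        assert len(found) == 1
        assert found[0].start_column == 1 and found[0].end_column == 20
        assert all(t.kind == "fixed" for t in found[0].tokens)

    def test_planted_patterns_recovered_token_equal(self, known_patterns):
        patterns = [known_patterns[f"M{i}"] for i in range(1, 9)]
        aln, truth = planted_alignment(patterns, n_rows=200, n_cols=400,
                                       conservation=0.95, seed=5)
        found = extract_motifs(profile_columns(aln))
        assert [p.render() for p in found] == [t["pattern"] for t in truth]
        assert [p.start_column for p in found] == [t["start_column"] for t in truth]

    def test_uniform_background_yields_no_motifs(self):
        rng = np.random.default_rng(36)
        from goxprofile.msa import MultipleAlignment

        for seed in range(3):
            rows = [
                "".join(AA[int(k)] for k in rng.integers(0, 20, 150)) for _ in range(200)
            ]
            msa = MultipleAlignment(labels=[f"r{i}" for i in range(200)], rows=rows)
            assert extract_motifs(profile_columns(msa)) == []

    def test_blocks_disjoint_and_ordered(self, known_patterns):
        patterns = [known_patterns[f"M{i}"] for i in range(1, 9)]
        aln, _ = planted_alignment(patterns, conservation=0.95, seed=6)
        found = extract_motifs(profile_columns(aln))
        for a, b in zip(found, found[1:]):
            assert a.end_column < b.start_column


# --- proline-rich motif ------------------------------------------------------


class TestDetectPrm:
    def test_printed_worked_example(self):
        report = detect_prm("PAAAPAAAAAAPAAAAAPAAPAAAAAAAAPAAAP")
        assert report.n_prolines == 7
        assert report.composite == "P-x-x-x-P-(x)6-P-(x)5-P-x-x-P-(x)8-P-x-x-x-P"
        kinds = [s["kind"] for s in report.submotifs]
        assert kinds.count("PxxxP") == 2 and kinds.count("PxxP") == 1

    def test_proline_free_consensus_is_empty(self):
        report = detect_prm("AAAAAGGGGG")
        assert report.n_prolines == 0 and report.composite == ""

    def test_composite_regenerates_planted_spacing(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            pos, cursor = [], 1
            for _ in range(int(rng.integers(2, 7))):
                pos.append(cursor)
                cursor += int(rng.integers(3, 10))
            consensus = "".join(
                "P" if (i + 1) in pos else "A" for i in range(max(pos))
            )
            report = detect_prm(consensus)
            assert report.proline_columns == pos
            assert positions_from_composite(report.composite) == [
                p - pos[0] + 1 for p in pos
            ]

    def test_track_input_uses_proline_frequency(self, known_patterns):
        aln, truth = planted_alignment(
            [known_patterns["prm_composite"]], n_rows=200, n_cols=80,
            conservation=0.95, seed=8,
        )
        report = detect_prm(profile_columns(aln))
        start = truth[0]["start_column"]
        assert report.proline_columns == [start + p - 1 for p in positions_from_composite(
            known_patterns["prm_composite"].render())]
        assert all(f >= 0.8 for f in report.frequencies.values())

    def test_render_spacing_round_trip(self):
        pos = [1, 5, 12, 18, 21, 30, 34]
        assert positions_from_composite(render_spacing(pos)) == pos
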