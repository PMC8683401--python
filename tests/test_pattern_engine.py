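"""Pattern parsing, scanning semantics, and the bundled PTM patterns."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from famscreen.pattern_engine import (
    ElementKind,
    Match,
    MotifPattern,
    PatternElement,
    PatternParseError,
    count_matches,
    parse_pattern,
    ptm_patterns,
    ptm_scan,
    read_pattern_file,
    scan,
    write_pattern_file,
)

from oracles import oracle_count, oracle_match_ends, random_pattern, random_sequence


class TestParsing:
    def test_simple_three_elements(self):
        p = parse_pattern("A-X-C")
        kinds = [e.kind for e in p.elements]
        assert kinds == [ElementKind.FIXED, ElementKind.WILDCARD, ElementKind.FIXED]
        assert p.elements[0].residues == {"A"}
        assert (p.min_span, p.max_span) == (3, 3)

    def test_bracketed_single_residue_equals_plain(self):
        assert parse_pattern("[L]-W").elements == parse_pattern("L-W").elements

    def test_mixed_dashes_and_whitespace(self):
        p = parse_pattern("[ST] – X (2)—[DE]")
        assert p.elements == parse_pattern("[ST]-X(2)-[DE]").elements

    def test_count_list_token_reads_min_max(self):
        el = parse_pattern("A-X(0,1,2)").elements[1]
        assert (el.min_repeat, el.max_repeat) == (0, 2)

    def test_zero_span_pattern_is_invalid(self):
        with pytest.raises(PatternParseError):
            parse_pattern("X(0,2)")  # could only ever match emptiness

    def test_exclusion_and_class(self):
        p = parse_pattern("N-{P}-[ST]-{P}")
        assert p.elements[1].kind is ElementKind.EXCLUDED
        assert p.elements[2].kind is ElementKind.CLASS
        assert p.elements[2].residues == {"S", "T"}

    def test_anchors(self):
        p = parse_pattern("<M-X(3)>")
        assert p.anchored_start and p.anchored_end

    def test_consensus_key_has_22_elements(self, consensus_key):
        assert len(consensus_key.elements) == 22

    def test_consensus_key_spans_are_sums_of_element_bounds(self, consensus_key):
        # arithmetic oracle: spans must equal the per-element bound sums
        assert consensus_key.min_span == sum(e.min_repeat for e in consensus_key.elements)
        assert consensus_key.max_span == sum(e.max_repeat for e in consensus_key.elements)
        assert consensus_key.min_span == 39
        assert consensus_key.max_span == 53

    def test_outer_wrapper_bracket_stripped_but_class_kept(self):
        wrapped = parse_pattern("[[L]-X(2)-[G]]")
        assert len(wrapped.elements) == 3
        bare_class = parse_pattern("[ST]")
        assert len(bare_class.elements) == 1
        assert bare_class.elements[0].kind is ElementKind.CLASS

    @pytest.mark.parametrize(
        "bad",
        ["", "A--C", "A-X(3,1)", "A-[]-C", "A-J-C", "A-X(2-C", "{P}(0)", "[AX]"],
    )
    def test_malformed_patterns_raise_naming_token(self, bad):
        with pytest.raises(PatternParseError):
            parse_pattern(bad)


@st.composite
def element_lists(draw):
    n = draw(st.integers(1, 6))
    out = []
    for _ in range(n):
        kind = draw(st.sampled_from(list(ElementKind)))
        if kind is ElementKind.WILDCARD:
            lo = draw(st.integers(0, 3))
            hi = draw(st.integers(lo, lo + 3))
            out.append(PatternElement(kind, frozenset(), lo, hi))
        else:
            # classes of size 1 intentionally collapse to fixed residues on
            # serialization ([L] == L), so draw genuine multi-residue classes
            k = 1 if kind is ElementKind.FIXED else draw(st.integers(2, 5))
            residues = frozenset(draw(st.permutations(sorted("ACDEFGHIKLMNPQRSTVWY")))[:k])
            lo = draw(st.integers(1, 3))
            hi = draw(st.integers(lo, lo + 2))
            out.append(PatternElement(kind, residues, lo, hi))
    return out


class TestRoundTrip:
    @settings(max_examples=150, derandomize=True)
    @given(element_lists())
    def test_serialize_parse_identity_on_elements(self, elements):
        try:
            pattern = MotifPattern(tuple(elements))
        except PatternParseError:
            return  # zero-span degenerate list: not a valid pattern
        again = parse_pattern(pattern.to_string())
        assert again.elements == pattern.elements

    def test_pattern_file_round_trip(self, tmp_path, consensus_key):
        path = tmp_path / "patterns.tsv"
        write_pattern_file([consensus_key], path)
        (loaded,) = read_pattern_file(path)
        assert loaded.elements == consensus_key.elements
        assert loaded.name == consensus_key.name


class TestScanning:
    def test_single_match(self):
        assert scan(parse_pattern("A-X-C"), "AAC") == [Match(0, 3, "AAC")]

    def test_overlapping_starts_all_reported(self):
        p = parse_pattern("[ST]-X(2)-[DE]")
        assert [(m.start, m.end) for m in scan(p, "STTEDE")] == [(0, 4), (1, 5), (2, 6)]
        assert count_matches(p, "STTEDE") == 3

    def test_empty_sequence_yields_no_matches(self):
        assert scan(parse_pattern("A-X-C"), "") == []
        assert count_matches(parse_pattern("[ST]-X(2)-[DE]"), "") == 0

    def test_shortest_expansion_at_a_start(self):
        # X(1,3) could swallow 1..3 residues; the reported span is minimal
        p = parse_pattern("A-X(1,3)-C")
        m = scan(p, "ABCCC")[0]
        assert (m.start, m.end) == (0, 3)

    def test_case_insensitive(self):
        assert count_matches(parse_pattern("A-X-C"), "aac") == 1

    def test_unknown_letters_match_wildcards_only(self):
        assert count_matches(parse_pattern("A-X-C"), "AXC") == 1
        assert count_matches(parse_pattern("[AC]-C"), "XC") == 0
        assert count_matches(parse_pattern("A-C"), "BC") == 0  # B is ambiguous
        # excluded classes are classes too: ambiguity codes never satisfy them
        assert count_matches(parse_pattern("{P}"), "X") == 0

    def test_anchored_scan(self):
        assert count_matches(parse_pattern("<M-X"), "MA") == 1
        assert count_matches(parse_pattern("<M-X"), "AMA") == 0
        assert count_matches(parse_pattern("A-X>"), "AAA") == 1

    @settings(max_examples=250, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agreement_with_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        pattern = random_pattern(rng)
        seq = random_sequence(rng)
        matches = scan(pattern, seq)
        assert len(matches) == oracle_count(pattern, seq)
        for m in matches:
            ends = oracle_match_ends(pattern, seq.upper(), m.start)
            assert m.end == min(ends)  # shortest satisfying expansion

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fixed_length_pattern_match_count_bound(self, seed):
        rng = random.Random(seed)
        pattern = random_pattern(rng)
        seq = random_sequence(rng)
        if pattern.min_span == pattern.max_span and not pattern.anchored_start:
            bound = max(0, len(seq) - pattern.min_span + 1)
            assert count_matches(pattern, seq) <= bound


class TestPTM:
    def test_bundle_loads_all_site_classes(self):
        names = {p.name for p in ptm_patterns()}
        assert {
            "N-glycosylation", "cAMP/cGMP-kinase", "protein-kinase-C",
            "casein-kinase-II", "tyrosine-kinase", "N-myristoylation",
            "amidation", "P-loop-ATP/GTP-A", "leucine-zipper",
        } <= names

    def test_n_glycosylation_hand_check(self):
        # N-{P}-[ST]-{P}: NGSA qualifies, NPSA (proline after N) does not
        table = ptm_scan("NGSA").set_index("site_class")
        assert table.loc["N-glycosylation", "count"] == 1
        assert table.loc["N-glycosylation", "positions"] == [1]
        assert ptm_scan("NPSA").set_index("site_class").loc["N-glycosylation", "count"] == 0

    def test_all_zero_on_polyproline(self):
        assert (ptm_scan("PPPP")["count"] == 0).all()

    def test_leucine_zipper_periodicity(self):
        seq = "L" + ("AAAAAA" + "L") * 3
        table = ptm_scan(seq).set_index("site_class")
        assert table.loc["leucine-zipper", "count"] == 1
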