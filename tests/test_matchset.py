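"""Match parsing, the internal exact matcher, and the e-value filter."""

import io

import numpy as np
import pytest

from ggdist.genome_io import genome_from_sequences, reverse_complement
from ggdist.matchset import (
    DirectedMatchSet,
    Match,
    filter_by_evalue,
    find_exact_matches,
    parse_blast_tabular,
    parse_mummer_mums,
    read_match_tsv,
    write_match_tsv,
)

from conftest import brute_force_mems, random_sequence, mutate


def _genome(name, length, rng=None, seq=None):
    if seq is None:
        seq = random_sequence(rng, length)
    return genome_from_sequences(name, [(name + "_chr", seq)])


@pytest.fixture
def pair(rng):
    q = genome_from_sequences("gq", [("q", random_sequence(rng, 1000))])
    s = genome_from_sequences("gs", [("s", random_sequence(rng, 1000))])
    return q, s


class TestBlastTabular:
    def test_plus_strand_conversion(self, pair):
        line = "q\ts\t90.00\t200\t20\t0\t101\t300\t1\t200\t1e-50\t370\n"
        ms = parse_blast_tabular(io.StringIO(line), *pair)
        (m,) = ms.matches
        assert (m.q_start, m.q_end) == (100, 300)
        assert (m.s_start, m.s_end) == (0, 200)
        assert m.strand == "+"
        assert m.length == 200
        assert m.identities == 180  # round(0.90 * 200)
        assert m.score == 370.0
        assert m.evalue == 1e-50

    def test_minus_strand_stored_forward(self, pair):
        line = "q\ts\t95.00\t100\t5\t0\t1\t100\t500\t401\t1e-10\t150\n"
        ms = parse_blast_tabular(io.StringIO(line), *pair)
        (m,) = ms.matches
        assert m.strand == "-"
        assert (m.s_start, m.s_end) == (400, 500)

    def test_empty_stream_and_comments(self, pair):
        ms = parse_blast_tabular(io.StringIO("# comment\n\n"), *pair)
        assert len(ms) == 0

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("q\ts\t90.0\t200\n", "expected 12 columns"),
            ("q\ts\tx\t200\t20\t0\t1\t200\t1\t200\t1e-50\t370\n", "non-numeric"),
            ("other\ts\t90.0\t200\t20\t0\t1\t200\t1\t200\t1e-50\t370\n",
             "not in genome"),
        ],
    )
    def test_malformed_input_rejected(self, pair, line, msg):
        with pytest.raises(ValueError, match=msg):
            parse_blast_tabular(io.StringIO(line), *pair)

    def test_error_reports_line_number(self, pair):
        text = (
            "q\ts\t90.0\t200\t20\t0\t1\t200\t1\t200\t1e-50\t370\n"
            "q\ts\tbroken\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_blast_tabular(io.StringIO(text), *pair)

    def test_out_of_bounds_interval_rejected(self, pair):
        line = "q\ts\t90.0\t200\t20\t0\t901\t1100\t1\t200\t1e-50\t370\n"
        with pytest.raises(ValueError, match="exceeds"):
            parse_blast_tabular(io.StringIO(line), *pair)


class TestMummer:
    def test_forward_match(self, pair):
        text = "> q\n  101  51  40\n"
        ms = parse_mummer_mums(io.StringIO(text), *pair)
        (m,) = ms.matches
        # first column = subject (reference) position, second = query
        assert (m.s_start, m.s_end) == (100, 140)
        assert (m.q_start, m.q_end) == (50, 90)
        assert m.strand == "+"
        assert m.identities == m.length == 40
        assert m.score == 40.0
        assert m.evalue is None

    def test_reverse_match_reflected_to_forward(self, pair):
        # query replicon is 1000 bp; reversed position 801 means the match
        # ends at forward position 200: interval [170, 200)
        text = "> q Reverse\n  11  801  30\n"
        ms = parse_mummer_mums(io.StringIO(text), *pair)
        (m,) = ms.matches
        assert (m.q_start, m.q_end) == (170, 200)
        assert m.strand == "-"
        assert (m.s_start, m.s_end) == (10, 40)

    def test_four_column_names_subject_replicon(self, rng):
        q = genome_from_sequences("gq", [("q", random_sequence(rng, 500))])
        s = genome_from_sequences(
            "gs",
            [("s1", random_sequence(rng, 500)), ("s2", random_sequence(rng, 500))],
        )
        text = "> q\ns2  1  1  20\n"
        ms = parse_mummer_mums(io.StringIO(text), q, s)
        assert ms.matches[0].s_replicon == "s2"

    def test_empty_stream(self, pair):
        assert len(parse_mummer_mums(io.StringIO(""), *pair)) == 0

    def test_nonpositive_length_rejected(self, pair):
        with pytest.raises(ValueError, match="length must be > 0"):
            parse_mummer_mums(io.StringIO("> q\n1 1 0\n"), *pair)


class TestExactMatcher:
    def test_shared_substring_found(self):
        a = _genome("A", 0, seq="AAACCCGGGTTT")
        b = _genome("B", 0, seq="CCCGGGTTTAAA")
        ms = find_exact_matches(a, b, 9)
        forward = [m for m in ms.matches if m.strand == "+"]
        (m,) = forward
        assert (m.q_start, m.q_end, m.s_start, m.s_end) == (3, 12, 0, 9)
        assert m.identities == m.length == 9
        # full agreement with the brute-force oracle, reverse hits included
        oracle = brute_force_mems("AAACCCGGGTTT", "CCCGGGTTTAAA", 9)
        got = sorted(
            (m.q_start, m.q_end, m.s_start, m.s_end, m.strand)
            for m in ms.matches
        )
        assert got == oracle

    def test_reverse_complement_identity(self, rng):
        seq = random_sequence(rng, 120)
        a = _genome("A", 0, seq=seq)
        b = _genome("B", 0, seq=reverse_complement(seq))
        ms = find_exact_matches(a, b, len(seq))
        (m,) = ms.matches
        assert m.strand == "-"
        assert (m.q_start, m.q_end) == (0, 120)
        assert (m.s_start, m.s_end) == (0, 120)

    def test_independent_sequences_share_nothing(self, rng):
        for _ in range(3):
            a = _genome("A", 10_000, rng)
            b = _genome("B", 10_000, rng)
            assert len(find_exact_matches(a, b, 30)) == 0

    def test_n_never_matches(self):
        a = _genome("A", 0, seq="ACGTACGTNNNNNNNNNNACGTACGT")
        b = _genome("B", 0, seq="ACGTACGTNNNNNNNNNNACGTACGT")
        ms = find_exact_matches(a, b, 8)
        assert all(
            "N" not in a.replicons[0].sequence[m.q_start:m.q_end]
            for m in ms.matches
        )

    def test_min_length_floor(self, pair):
        with pytest.raises(ValueError, match="min_length"):
            find_exact_matches(*pair, 7)

    def test_deterministic_sorted_output(self, rng):
        base = random_sequence(rng, 800)
        a = _genome("A", 0, seq=base)
        b = _genome("B", 0, seq=mutate(rng, base, 0.03))
        ms = find_exact_matches(a, b, 12)
        keys = [m.sort_key() for m in ms.matches]
        assert keys == sorted(keys)
        ms2 = find_exact_matches(a, b, 12)
        assert ms.matches == ms2.matches


class TestEvalueFilter:
    def test_threshold_applied(self, pair):
        mk = lambda ev: Match("q", "s", 0, 10, 0, 10, "+", 10, 10, 20.0, ev)
        ms = DirectedMatchSet("gq", "gs", [mk(1e-50), mk(0.5)], 1000, 1000)
        kept = filter_by_evalue(ms, 1e-2)
        assert [m.evalue for m in kept.matches] == [1e-50]

    def test_mums_pass_unchanged(self, pair):
        mums = [Match("q", "s", 0, 10, 0, 10, "+", 10, 10, 10.0, None)]
        ms = DirectedMatchSet("gq", "gs", mums, 1000, 1000)
        assert filter_by_evalue(ms).matches == mums

    def test_empty_set(self):
        ms = DirectedMatchSet("a", "b", [], 10, 10)
        assert len(filter_by_evalue(ms)) == 0


def test_match_tsv_roundtrip(rng):
    base = random_sequence(rng, 600)
    a = _genome("A", 0, seq=base)
    b = _genome("B", 0, seq=mutate(rng, base, 0.05))
    ms = find_exact_matches(a, b, 10)
    assert len(ms) > 0
    buf = io.StringIO()
    write_match_tsv(ms, buf)
    back = read_match_tsv(io.StringIO(buf.getvalue()), a, b)
    assert back.matches == ms.matches
    assert back.query_genome_id == ms.query_genome_id


def test_match_invariants_enforced():
    with pytest.raises(ValueError):
        Match("q", "s", 10, 10, 0, 5, "+", 5, 5, 1.0)  # empty query interval
    with pytest.raises(ValueError):
        Match("q", "s", 0, 5, 0, 5, "+", 5, 6, 1.0)  # identities > length
    with pytest.raises(ValueError):
        Match("q", "s", 0, 5, 0, 5, "*", 5, 5, 1.0)  # bad strand
    with pytest.raises(ValueError):
        Match("q", "s", 0, 5, 0, 5, "+", 5, 5, 0.0)  # score must be positive
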