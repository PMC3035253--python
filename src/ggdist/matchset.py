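"""Intergenomic match sets: HSPs and exact matches (MUM-style).

A :class:`Match` is one local alignment segment between a query and a subject
genome — an HSP from a similarity-search program, or an exact match.  All
intervals are 0-based half-open on the forward strand of their replicon;
``strand`` records the orientation of the subject segment relative to the
query.  Reverse-strand coordinates from external programs are reflected to
forward-strand intervals at parse time, so downstream overlap bookkeeping is
strand-agnostic.

The built-in :func:`find_exact_matches` finder makes the whole distance
pipeline testable without external aligner binaries.  It enumerates maximal
exact matches on both strands (no uniqueness filter, i.e. the semantics of
MUMmer's ``-maxmatch``); the greedy trimming step downstream is what deals
with repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from .genome_io import Genome, PathOrHandle, _open_maybe, reverse_complement

__all__ = [
    "Match",
    "DirectedMatchSet",
    "parse_blast_tabular",
    "parse_mummer_mums",
    "find_exact_matches",
    "filter_by_evalue",
    "write_match_tsv",
    "read_match_tsv",
]

DEFAULT_EVALUE_THRESHOLD = 1e-2
MIN_SEED_LENGTH = 8


@dataclass(frozen=True)
class Match:
    """One HSP or exact match between two genomes.

    ``length`` counts alignment columns (BLAST column 4), which for gapped
    alignments may exceed either genomic span; for exact matches it equals
    both spans.  ``identities`` counts identical aligned columns.  ``score``
    is the aligner's score; for exact matches the match length stands in for
    the score.  ``evalue`` is absent (None) for exact matches.
    """

    q_replicon: str
    s_replicon: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    length: int
    identities: int
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"invalid query interval [{self.q_start}, {self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"invalid subject interval [{self.s_start}, {self.s_end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.identities <= self.length:
            raise ValueError(
                f"identities {self.identities} outside [0, length={self.length}]"
            )
        if not self.score > 0:
            raise ValueError("score must be > 0")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start

    def sort_key(self) -> tuple:
        return (
            self.q_replicon, self.q_start, self.q_end,
            self.s_replicon, self.s_start, self.strand,
        )


@dataclass
class DirectedMatchSet:
    """All matches from one query genome against one subject genome.

    Directional: the x→y and y→x sets are distinct objects, and the H/I
    totals entering the distance formulas are accumulated per direction.
    """

    query_genome_id: str
    subject_genome_id: str
    matches: list[Match]
    query_length: int
    subject_length: int

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self) -> Iterator[Match]:
        return iter(self.matches)

    def total_h(self) -> int:
        """Total match length in bp (the H component of this direction)."""
        return sum(m.length for m in self.matches)

    def total_i(self) -> int:
        """Total identical base pairs (the I component of this direction)."""
        return sum(m.identities for m in self.matches)

    @classmethod
    def validated(
        cls,
        query_genome: Genome,
        subject_genome: Genome,
        matches: Iterable[Match],
    ) -> "DirectedMatchSet":
        """Build a set, checking every interval against replicon bounds."""
        qlens = query_genome.replicon_lengths
        slens = subject_genome.replicon_lengths
        out: list[Match] = []
        for m in matches:
            if m.q_replicon not in qlens:
                raise ValueError(
                    f"query replicon {m.q_replicon!r} not in genome "
                    f"{query_genome.genome_id!r}"
                )
            if m.s_replicon not in slens:
                raise ValueError(
                    f"subject replicon {m.s_replicon!r} not in genome "
                    f"{subject_genome.genome_id!r}"
                )
            if m.q_end > qlens[m.q_replicon]:
                raise ValueError(
                    f"query interval [{m.q_start}, {m.q_end}) exceeds "
                    f"replicon {m.q_replicon!r} length {qlens[m.q_replicon]}"
                )
            if m.s_end > slens[m.s_replicon]:
                raise ValueError(
                    f"subject interval [{m.s_start}, {m.s_end}) exceeds "
                    f"replicon {m.s_replicon!r} length {slens[m.s_replicon]}"
                )
            out.append(m)
        return cls(
            query_genome.genome_id,
            subject_genome.genome_id,
            out,
            query_genome.total_length,
            subject_genome.total_length,
        )


# ---------------------------------------------------------------------------
# BLAST tabular parsing


def parse_blast_tabular(
    source: PathOrHandle, query_genome: Genome, subject_genome: Genome
) -> DirectedMatchSet:
    """Parse 12-column BLAST tabular output (outfmt 6/7) into a match set.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  1-based inclusive coordinates become 0-based
    half-open; ``sstart > send`` marks a minus-strand HSP, whose subject
    interval is stored on the forward strand.  Identities are reconstructed
    as ``round(pident × length / 100)`` because the tabular format carries a
    percentage, not a count.
    """
    handle, close = _open_maybe(source, "r")
    try:
        matches: list[Match] = []
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"line {line_no}: expected 12 columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {line_no}: non-numeric field") from exc
            if qstart > qend:
                raise ValueError(
                    f"line {line_no}: qstart > qend (nucleotide query "
                    "coordinates must be ascending)"
                )
            if sstart <= send:
                strand = "+"
                s_lo, s_hi = sstart - 1, send
            else:
                strand = "-"
                s_lo, s_hi = send - 1, sstart
            identities = round(pident * length / 100.0)
            try:
                matches.append(
                    Match(
                        q_replicon=qseqid,
                        s_replicon=sseqid,
                        q_start=qstart - 1,
                        q_end=qend,
                        s_start=s_lo,
                        s_end=s_hi,
                        strand=strand,
                        length=length,
                        identities=identities,
                        score=bitscore,
                        evalue=evalue,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return DirectedMatchSet.validated(query_genome, subject_genome, matches)


# ---------------------------------------------------------------------------
# MUMmer `mummer` match-list parsing


def parse_mummer_mums(
    source: PathOrHandle, query_genome: Genome, subject_genome: Genome
) -> DirectedMatchSet:
    """Parse classic ``mummer`` match-list output into a match set.

    Sections start with ``> query_id`` headers; a trailing ``Reverse`` marks
    matches of the reversed query strand.  Data lines carry 3 columns
    (subject position, query position, length; single-replicon subject) or 4
    (subject replicon name first).  Positions are 1-based; reverse-section
    query positions index the reversed query sequence and are reflected back
    to forward-strand half-open intervals here.  Exact matches carry
    ``identities = length = score`` and no e-value.
    """
    qlens = query_genome.replicon_lengths
    handle, close = _open_maybe(source, "r")
    try:
        matches: list[Match] = []
        current_query: str | None = None
        reverse = False
        if len(query_genome.replicons) == 1:
            current_query = query_genome.replicons[0].replicon_id
        single_subject = (
            subject_genome.replicons[0].replicon_id
            if len(subject_genome.replicons) == 1
            else None
        )
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()
                if not header:
                    raise ValueError(f"line {line_no}: empty section header")
                reverse = header[-1].lower() == "reverse"
                current_query = header[0]
                continue
            fields = line.split()
            if len(fields) == 3:
                if single_subject is None:
                    raise ValueError(
                        f"line {line_no}: 3-column match line but subject "
                        "genome has multiple replicons"
                    )
                s_rep = single_subject
                s_pos, q_pos, length = fields
            elif len(fields) == 4:
                s_rep, s_pos, q_pos, length = fields
            else:
                raise ValueError(
                    f"line {line_no}: expected 3 or 4 columns, got {len(fields)}"
                )
            try:
                s_pos_i, q_pos_i, length_i = int(s_pos), int(q_pos), int(length)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: non-numeric field") from exc
            if length_i <= 0:
                raise ValueError(f"line {line_no}: match length must be > 0")
            if current_query is None:
                raise ValueError(
                    f"line {line_no}: match line before any '>' header and "
                    "query genome has multiple replicons"
                )
            if current_query not in qlens:
                raise ValueError(
                    f"line {line_no}: query replicon {current_query!r} not in "
                    f"genome {query_genome.genome_id!r}"
                )
            if reverse:
                # q_pos indexes the reversed query: reversed position p
                # (1-based) is forward position L - p (0-based); the match
                # extends downstream in reversed coordinates, i.e. upstream
                # on the forward strand.
                L = qlens[current_query]
                q_hi = L - (q_pos_i - 1)
                q_lo = q_hi - length_i
                strand = "-"
            else:
                q_lo = q_pos_i - 1
                q_hi = q_lo + length_i
                strand = "+"
            matches.append(
                Match(
                    q_replicon=current_query,
                    s_replicon=s_rep,
                    q_start=q_lo,
                    q_end=q_hi,
                    s_start=s_pos_i - 1,
                    s_end=s_pos_i - 1 + length_i,
                    strand=strand,
                    length=length_i,
                    identities=length_i,
                    score=float(length_i),
                    evalue=None,
                )
            )
    finally:
        if close:
            handle.close()
    return DirectedMatchSet.validated(query_genome, subject_genome, matches)


# ---------------------------------------------------------------------------
# Internal exact matcher


def _maximal_matches_one_strand(
    qseq: str, sseq: str, min_length: int
) -> list[tuple[int, int, int]]:
    """All maximal exact matches (q_start, s_start, length) on '+' vs sseq.

    k-mer anchoring with k = min_length, then bidirectional extension; a
    per-diagonal high-water mark deduplicates seeds falling inside an
    already-emitted run.  N never matches anything, including N, so runs are
    N-free by construction.
    """
    k = min_length
    index: dict[str, list[int]] = {}
    for j in range(len(sseq) - k + 1):
        kmer = sseq[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    out: list[tuple[int, int, int]] = []
    # furthest query end already covered, per diagonal (q_start - s_start)
    covered: dict[int, int] = {}
    nq, ns = len(qseq), len(sseq)
    for i in range(nq - k + 1):
        kmer = qseq[i:i + k]
        if "N" in kmer:
            continue
        hits = index.get(kmer)
        if not hits:
            continue
        for j in hits:
            d = i - j
            if covered.get(d, -1) >= i + k:
                continue  # seed inside an already-extended run
            lo_q, lo_s = i, j
            while lo_q > 0 and lo_s > 0 and qseq[lo_q - 1] == sseq[lo_s - 1] \
                    and qseq[lo_q - 1] != "N":
                lo_q -= 1
                lo_s -= 1
            hi_q, hi_s = i + k, j + k
            while hi_q < nq and hi_s < ns and qseq[hi_q] == sseq[hi_s] \
                    and qseq[hi_q] != "N":
                hi_q += 1
                hi_s += 1
            covered[d] = hi_q
            out.append((lo_q, lo_s, hi_q - lo_q))
    return out


def find_exact_matches(
    query_genome: Genome, subject_genome: Genome, min_length: int
) -> DirectedMatchSet:
    """Find all maximal exact matches of length >= ``min_length``, both strands.

    The finder reports every maximal run (repeats included; no uniqueness
    filter — greedy trimming downstream handles repeats).  Output order is
    deterministic: sorted by query interval, then subject interval, then
    strand.  Seeding uses k-mers of length ``min_length``; values below 8
    make seeding unreliable and are rejected.
    """
    if min_length < MIN_SEED_LENGTH:
        raise ValueError(f"min_length must be >= {MIN_SEED_LENGTH}")
    matches: list[Match] = []
    for q_rep in query_genome.replicons:
        for s_rep in subject_genome.replicons:
            for q0, s0, length in _maximal_matches_one_strand(
                q_rep.sequence, s_rep.sequence, min_length
            ):
                matches.append(
                    Match(
                        q_replicon=q_rep.replicon_id,
                        s_replicon=s_rep.replicon_id,
                        q_start=q0,
                        q_end=q0 + length,
                        s_start=s0,
                        s_end=s0 + length,
                        strand="+",
                        length=length,
                        identities=length,
                        score=float(length),
                    )
                )
            s_rc = reverse_complement(s_rep.sequence)
            S = s_rep.length
            for q0, s0_rc, length in _maximal_matches_one_strand(
                q_rep.sequence, s_rc, min_length
            ):
                matches.append(
                    Match(
                        q_replicon=q_rep.replicon_id,
                        s_replicon=s_rep.replicon_id,
                        q_start=q0,
                        q_end=q0 + length,
                        s_start=S - (s0_rc + length),
                        s_end=S - s0_rc,
                        strand="-",
                        length=length,
                        identities=length,
                        score=float(length),
                    )
                )
    matches.sort(key=Match.sort_key)
    return DirectedMatchSet.validated(query_genome, subject_genome, matches)


# ---------------------------------------------------------------------------
# e-value filter


def filter_by_evalue(
    match_set: DirectedMatchSet,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> DirectedMatchSet:
    """Drop matches with e-value above ``threshold`` (default 1e-2).

    Matches lacking an e-value (exact matches / MUMs) pass unchanged: the
    filter is vacuous for them.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    kept = [
        m for m in match_set.matches
        if m.evalue is None or m.evalue <= threshold
    ]
    return DirectedMatchSet(
        match_set.query_genome_id,
        match_set.subject_genome_id,
        kept,
        match_set.query_length,
        match_set.subject_length,
    )


# ---------------------------------------------------------------------------
# TSV serialisation (documented interchange format for internal matches)

_TSV_HEADER = (
    "q_replicon\ts_replicon\tq_start\tq_end\ts_start\ts_end\t"
    "strand\tlength\tidentities\tscore\tevalue"
)


def write_match_tsv(match_set: DirectedMatchSet, target: PathOrHandle) -> None:
    """Write one Match per line, 0-based half-open, explicit strand column."""
    handle, close = _open_maybe(target, "w")
    try:
        handle.write(f"# query={match_set.query_genome_id}"
                     f" subject={match_set.subject_genome_id}"
                     f" query_length={match_set.query_length}"
                     f" subject_length={match_set.subject_length}\n")
        handle.write(_TSV_HEADER + "\n")
        for m in match_set.matches:
            ev = "" if m.evalue is None else repr(m.evalue)
            handle.write(
                f"{m.q_replicon}\t{m.s_replicon}\t{m.q_start}\t{m.q_end}\t"
                f"{m.s_start}\t{m.s_end}\t{m.strand}\t{m.length}\t"
                f"{m.identities}\t{m.score!r}\t{ev}\n"
            )
    finally:
        if close:
            handle.close()


def read_match_tsv(
    source: PathOrHandle,
    query_genome: Genome | None = None,
    subject_genome: Genome | None = None,
) -> DirectedMatchSet:
    """Read the TSV written by :func:`write_match_tsv`.

    When the genomes are supplied, intervals are validated against replicon
    bounds; otherwise the metadata header line supplies ids and lengths.
    """
    handle, close = _open_maybe(source, "r")
    try:
        meta: dict[str, str] = {}
        matches: list[Match] = []
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, val = token.split("=", 1)
                        meta[key] = val
                continue
            if line.startswith("q_replicon\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValueError(
                    f"line {line_no}: expected 11 columns, got {len(fields)}"
                )
            try:
                matches.append(
                    Match(
                        q_replicon=fields[0],
                        s_replicon=fields[1],
                        q_start=int(fields[2]),
                        q_end=int(fields[3]),
                        s_start=int(fields[4]),
                        s_end=int(fields[5]),
                        strand=fields[6],
                        length=int(fields[7]),
                        identities=int(fields[8]),
                        score=float(fields[9]),
                        evalue=float(fields[10]) if fields[10] else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from exc
    finally:
        if close:
            handle.close()
    if query_genome is not None and subject_genome is not None:
        return DirectedMatchSet.validated(query_genome, subject_genome, matches)
    return DirectedMatchSet(
        meta.get("query", "query"),
        meta.get("subject", "subject"),
        matches,
        int(meta.get("query_length", 0)),
        int(meta.get("subject_length", 0)),
    )
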