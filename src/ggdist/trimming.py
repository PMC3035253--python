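"""Overlap removal for match sets: greedy-with-trimming and coverage.

Repeats make raw H/I sums misleading: a segment present once in the query
but five times in the subject produces five HSPs whose lengths would all be
counted.  Greedy-with-trimming processes matches in descending score order
and clips each candidate against the union of intervals already accepted on
*either* genome, so every genomic position contributes at most once per
side.  The coverage variant skips the greedy pass and instead measures the
footprint union of all matches directly.

Bookkeeping is per replicon and strand-agnostic: all intervals are
forward-strand, 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

from .matchset import DirectedMatchSet, Match

__all__ = ["TrimmedMatchSet", "TrimProvenance", "greedy_trim", "coverage_reduce"]


class _UnionByReplicon:
    """Accepted-interval unions, one interval tree per replicon."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, replicon: str, start: int, end: int) -> None:
        tree = self._trees.setdefault(replicon, IntervalTree())
        tree.addi(start, end)
        tree.merge_overlaps(strict=False)

    def total_length(self) -> int:
        return sum(
            iv.end - iv.begin for tree in self._trees.values() for iv in tree
        )

    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {
            rep: sorted((iv.begin, iv.end) for iv in tree)
            for rep, tree in self._trees.items()
        }

    def remaining(
        self, replicon: str, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Fragments of [start, end) not covered by the union."""
        tree = self._trees.get(replicon)
        if tree is None:
            return [(start, end)]
        hits = sorted(tree.overlap(start, end))
        frags: list[tuple[int, int]] = []
        cursor = start
        for iv in hits:
            if iv.begin > cursor:
                frags.append((cursor, iv.begin))
            cursor = max(cursor, iv.end)
        if cursor < end:
            frags.append((cursor, end))
        return frags


@dataclass(frozen=True)
class TrimProvenance:
    """Where an output match came from and what was cut off.

    ``result`` is None for candidates dropped entirely (fully covered by
    previously accepted matches, or collapsed by clipping).  Trim amounts
    are bp removed from each end of the source interval, per genome side.
    """

    source: Match
    result: Match | None
    q_trim: tuple[int, int] = (0, 0)
    s_trim: tuple[int, int] = (0, 0)

    @property
    def dropped(self) -> bool:
        return self.result is None


@dataclass
class TrimmedMatchSet:
    """A match set reduced to non-overlapping parts, with provenance.

    Greedy output guarantees zero pairwise overlap on both genome sides.
    Coverage-mode results keep the original matches but override the H/I
    totals with footprint-union bookkeeping (``h_total``/``i_total``).
    """

    query_genome_id: str
    subject_genome_id: str
    matches: list[Match]
    provenance: list[TrimProvenance] = field(default_factory=list)
    query_length: int = 0
    subject_length: int = 0
    h_total_override: float | None = None
    i_total_override: float | None = None

    def total_h(self) -> float:
        if self.h_total_override is not None:
            return self.h_total_override
        return sum(m.length for m in self.matches)

    def total_i(self) -> float:
        if self.i_total_override is not None:
            return self.i_total_override
        return sum(m.identities for m in self.matches)

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)


def _clip(match: Match, side: str, frag: tuple[int, int]) -> Match | None:
    """Clip ``match`` so the given side's interval becomes ``frag``.

    The opposite side's interval is shifted/shrunk proportionally to the
    positional cut (respecting strand), alignment length is scaled by the
    retained fraction, and identities are scaled and rounded down.  Returns
    None when the mapped interval collapses to zero width.
    """
    if side == "q":
        lo, hi = match.q_start, match.q_end
        o_lo, o_hi = match.s_start, match.s_end
    else:
        lo, hi = match.s_start, match.s_end
        o_lo, o_hi = match.q_start, match.q_end
    a, b = frag
    span = hi - lo
    o_span = o_hi - o_lo
    left_frac = (a - lo) / span
    right_frac = (hi - b) / span
    retained = (b - a) / span
    if match.strand == "+":
        o_a = o_lo + round(left_frac * o_span)
        o_b = o_hi - round(right_frac * o_span)
    else:
        # reverse orientation: a cut at this side's left end removes the
        # other side's right end
        o_a = o_lo + round(right_frac * o_span)
        o_b = o_hi - round(left_frac * o_span)
    if o_a >= o_b:
        return None
    new_length = max(1, round(match.length * retained))
    new_identities = min(math.floor(match.identities * retained), new_length)
    if side == "q":
        q_lo, q_hi, s_lo, s_hi = a, b, o_a, o_b
    else:
        q_lo, q_hi, s_lo, s_hi = o_a, o_b, a, b
    return Match(
        q_replicon=match.q_replicon,
        s_replicon=match.s_replicon,
        q_start=q_lo,
        q_end=q_hi,
        s_start=s_lo,
        s_end=s_hi,
        strand=match.strand,
        length=new_length,
        identities=new_identities,
        score=match.score,
        evalue=match.evalue,
    )


def _longest_fragment(frags: list[tuple[int, int]]) -> tuple[int, int]:
    # tie broken toward the leftmost fragment
    return max(frags, key=lambda f: (f[1] - f[0], -f[0]))


def greedy_trim(match_set: DirectedMatchSet) -> TrimmedMatchSet:
    """Reduce a match set to non-overlapping parts, best matches first.

    Matches are processed in descending score order (ties: longer first,
    then lexicographic coordinates).  Each candidate is clipped against the
    union of already-accepted query intervals and accepted subject intervals;
    when an accepted interval splits a candidate internally, the longest
    remaining fragment is kept.  Fully covered candidates are dropped.  The
    output carries no pairwise overlap on either genome side.
    """
    q_union = _UnionByReplicon()
    s_union = _UnionByReplicon()
    out: list[Match] = []
    prov: list[TrimProvenance] = []
    order = sorted(
        match_set.matches,
        key=lambda m: (-m.score, -m.length) + m.sort_key(),
    )
    for src in order:
        cur: Match | None = src
        # clip query side, then subject side, re-checking until stable;
        # clipping always yields sub-intervals on both sides, so this
        # reaches a fixed point in <= 2 passes (the loop bound is a guard)
        for _ in range(4):
            changed = False
            assert cur is not None
            frags = q_union.remaining(cur.q_replicon, cur.q_start, cur.q_end)
            if not frags:
                cur = None
                break
            frag = _longest_fragment(frags)
            if frag != (cur.q_start, cur.q_end):
                cur = _clip(cur, "q", frag)
                changed = True
                if cur is None:
                    break
            frags = s_union.remaining(cur.s_replicon, cur.s_start, cur.s_end)
            if not frags:
                cur = None
                break
            frag = _longest_fragment(frags)
            if frag != (cur.s_start, cur.s_end):
                cur = _clip(cur, "s", frag)
                changed = True
                if cur is None:
                    break
            if not changed:
                break
        if cur is not None:
            # invariant guard: the final intervals must be fully outside
            # both accepted unions
            if (
                q_union.remaining(cur.q_replicon, cur.q_start, cur.q_end)
                != [(cur.q_start, cur.q_end)]
                or s_union.remaining(cur.s_replicon, cur.s_start, cur.s_end)
                != [(cur.s_start, cur.s_end)]
            ):
                cur = None
        if cur is None:
            prov.append(TrimProvenance(source=src, result=None))
            continue
        q_union.add(cur.q_replicon, cur.q_start, cur.q_end)
        s_union.add(cur.s_replicon, cur.s_start, cur.s_end)
        out.append(cur)
        prov.append(
            TrimProvenance(
                source=src,
                result=cur,
                q_trim=(cur.q_start - src.q_start, src.q_end - cur.q_end),
                s_trim=(cur.s_start - src.s_start, src.s_end - cur.s_end),
            )
        )
    out.sort(key=Match.sort_key)
    return TrimmedMatchSet(
        query_genome_id=match_set.query_genome_id,
        subject_genome_id=match_set.subject_genome_id,
        matches=out,
        provenance=prov,
        query_length=match_set.query_length,
        subject_length=match_set.subject_length,
    )


def coverage_reduce(
    match_set: DirectedMatchSet, mode: str = "union"
) -> TrimmedMatchSet:
    """No-trimming reduction: measure match footprints instead of clipping.

    ``mode="union"`` (default): raw H and I sums are scaled by the ratio of
    the footprint-union lengths (query side + subject side) to the raw span
    sums, so each genomic position counts once per side, the identity
    fraction I/H is preserved, and overlap-free inputs pass through with
    totals identical to :func:`greedy_trim`'s.  ``mode="raw"`` keeps plain
    sums (overlaps multi-counted).
    """
    if mode not in ("union", "raw"):
        raise ValueError("mode must be 'union' or 'raw'")
    matches = list(match_set.matches)
    raw_h = sum(m.length for m in matches)
    raw_i = sum(m.identities for m in matches)
    if mode == "raw" or not matches:
        return TrimmedMatchSet(
            query_genome_id=match_set.query_genome_id,
            subject_genome_id=match_set.subject_genome_id,
            matches=matches,
            query_length=match_set.query_length,
            subject_length=match_set.subject_length,
            h_total_override=float(raw_h),
            i_total_override=float(raw_i),
        )
    q_union = _UnionByReplicon()
    s_union = _UnionByReplicon()
    for m in matches:
        q_union.add(m.q_replicon, m.q_start, m.q_end)
        s_union.add(m.s_replicon, m.s_start, m.s_end)
    u_q = q_union.total_length()
    u_s = s_union.total_length()
    span_sum = sum(m.q_span + m.s_span for m in matches)
    scale = min((u_q + u_s) / span_sum, 1.0) if span_sum > 0 else 0.0
    h_total = raw_h * scale
    i_total = raw_i * scale
    return TrimmedMatchSet(
        query_genome_id=match_set.query_genome_id,
        subject_genome_id=match_set.subject_genome_id,
        matches=matches,
        query_length=match_set.query_length,
        subject_length=match_set.subject_length,
        h_total_override=h_total,
        i_total_override=i_total,
    )
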