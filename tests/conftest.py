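"""Shared fixtures and independent reference oracles.

The oracles here deliberately use the slowest, most transparent approach —
full diagonal scans, O(n^2) pair counting, per-column loops — so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ggdist.genome_io import reverse_complement
from ggdist.matchset import DirectedMatchSet, Match

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# maximal exact match oracle: full per-diagonal scan, both strands


def _diagonal_runs(q: str, s: str, min_length: int):
    """All maximal equal runs (q_start, s_start, length), one strand.

    Scans every diagonal of the full comparison plane; N matches nothing.
    """
    qa = np.frombuffer(q.encode(), dtype="S1")
    sa = np.frombuffer(s.encode(), dtype="S1")
    q_valid = np.isin(qa, np.frombuffer(b"ACGT", dtype="S1"))
    s_valid = np.isin(sa, np.frombuffer(b"ACGT", dtype="S1"))
    nq, ns = len(qa), len(sa)
    for d in range(-(ns - 1), nq):
        i0 = max(0, d)
        j0 = i0 - d
        L = min(nq - i0, ns - j0)
        eq = (qa[i0:i0 + L] == sa[j0:j0 + L]) \
            & q_valid[i0:i0 + L] & s_valid[j0:j0 + L]
        edges = np.diff(np.concatenate(([0], eq.astype(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for st, en in zip(starts, ends):
            if en - st >= min_length:
                yield (i0 + int(st), j0 + int(st), int(en - st))


def brute_force_mems(q_seq: str, s_seq: str, min_length: int):
    """Maximal exact matches as (q_start, q_end, s_start, s_end, strand)."""
    out = []
    for q0, s0, L in _diagonal_runs(q_seq, s_seq, min_length):
        out.append((q0, q0 + L, s0, s0 + L, "+"))
    s_rc = reverse_complement(s_seq)
    S = len(s_seq)
    for q0, s0, L in _diagonal_runs(q_seq, s_rc, min_length):
        out.append((q0, q0 + L, S - (s0 + L), S - s0, "-"))
    return sorted(out)


# ---------------------------------------------------------------------------
# pairwise-overlap oracle for trimmed sets: exhaustive O(k^2) intersection


def overlapping_pairs(matches, side: str):
    """All index pairs whose intervals on the given genome side intersect."""
    bad = []
    for i in range(len(matches)):
        for j in range(i + 1, len(matches)):
            a, b = matches[i], matches[j]
            if side == "q":
                rep_a, rep_b = a.q_replicon, b.q_replicon
                lo_a, hi_a, lo_b, hi_b = a.q_start, a.q_end, b.q_start, b.q_end
            else:
                rep_a, rep_b = a.s_replicon, b.s_replicon
                lo_a, hi_a, lo_b, hi_b = a.s_start, a.s_end, b.s_start, b.s_end
            if rep_a == rep_b and lo_a < hi_b and lo_b < hi_a:
                bad.append((i, j))
    return bad


def random_match_set(rng: np.random.Generator, max_matches: int = 50):
    """A random, possibly heavily overlapping directed match set."""
    k = int(rng.integers(1, max_matches + 1))
    n_rep = int(rng.integers(1, 3))
    matches = []
    for _ in range(k):
        q_rep = f"q{rng.integers(0, n_rep)}"
        s_rep = f"s{rng.integers(0, n_rep)}"
        q_span = int(rng.integers(10, 200))
        q_start = int(rng.integers(0, 2000 - q_span))
        s_span = max(1, q_span + int(rng.integers(-5, 6)))
        s_start = int(rng.integers(0, 2000 - s_span))
        length = max(q_span, s_span) + int(rng.integers(0, 10))
        identities = int(rng.integers(length // 2, length + 1))
        matches.append(
            Match(
                q_replicon=q_rep,
                s_replicon=s_rep,
                q_start=q_start,
                q_end=q_start + q_span,
                s_start=s_start,
                s_end=s_start + s_span,
                strand="+" if rng.random() < 0.5 else "-",
                length=length,
                identities=identities,
                score=float(rng.integers(1, 1000)),
                evalue=float(10.0 ** rng.uniform(-60, 1)),
            )
        )
    return DirectedMatchSet("gx", "gy", matches, 2000 * n_rep, 2000 * n_rep)


# ---------------------------------------------------------------------------
# correlation oracles


def naive_kendall_tau_b(a, b) -> float:
    """Tau-b by explicit O(n^2) concordant/discordant/tie counting."""
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (concordant - discordant) / denom


def naive_pearson(a, b) -> float:
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def naive_p_distance(seq_a: str, seq_b: str) -> float:
    valid = mism = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        x = "T" if x == "U" else x
        y = "T" if y == "U" else y
        if x in BASES and y in BASES:
            valid += 1
            if x != y:
                mism += 1
    return mism / valid if valid else float("nan")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
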