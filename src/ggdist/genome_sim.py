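"""Synthetic genomes and Lander-Waterman incomplete-sequencing simulation.

Two generators live here.  :func:`generate_genome_pair` emulates a pair of
closely related bacterial strains: genome B derives from genome A through
iid point substitutions, optional segment deletions and optional extra
copies of a repeat segment, so every pipeline stage can be exercised
without downloading real genomes.

:func:`simulate_incomplete` emulates an unfinished shotgun sequencing
project.  Given a target retained proportion p and a fixed read length L
(700 bp by default, a realistic single read), the number of reads N needed
per replicon of length G follows the Lander-Waterman expectation for the
covered fraction, 1 − e^(−NL/G) = p.  Read start positions are drawn
uniformly (with replacement) per replicon, positions covered by no read are
removed, and the surviving runs become disjoint contigs.  Replicons are
linear: reads truncate at the sequence end rather than wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genome_io import Genome, Replicon

__all__ = [
    "ShredConfig",
    "SyntheticPairConfig",
    "lw_read_count",
    "simulate_incomplete",
    "simulate_replicates",
    "generate_genome_pair",
    "random_genome",
    "PairReport",
]

DEFAULT_READ_LENGTH = 700

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ShredConfig:
    """Parameters of one incomplete-sequencing simulation."""

    proportion: float
    read_length: int = DEFAULT_READ_LENGTH
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("proportion must lie strictly in (0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class SyntheticPairConfig:
    """Parameters of a synthetic related-genome pair.

    ``substitution_rate`` is the per-site probability that genome B carries
    a different base than genome A at that position.  Deletions remove
    ``n_segment_deletions`` disjoint segments of ``deletion_length`` bp from
    B; ``repeat_copies`` extra copies of a ``repeat_length`` bp segment of A
    are inserted into B at random positions.
    """

    genome_length: int
    substitution_rate: float = 0.01
    n_segment_deletions: int = 0
    deletion_length: int = 0
    repeat_copies: int = 0
    repeat_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if self.n_segment_deletions < 0 or self.deletion_length < 0:
            raise ValueError("deletion parameters must be >= 0")
        if self.repeat_copies < 0 or self.repeat_length < 0:
            raise ValueError("repeat parameters must be >= 0")
        if self.n_segment_deletions * self.deletion_length >= self.genome_length:
            raise ValueError("deletions would remove the whole genome")
        if 0 < self.repeat_length > self.genome_length:
            raise ValueError("repeat segment longer than the genome")


@dataclass(frozen=True)
class PairReport:
    """Realised divergence of a generated genome pair."""

    substitutions: int
    deleted_bp: int
    deleted_segments: tuple[tuple[int, int], ...]
    repeat_insertions: int
    repeat_source: tuple[int, int] | None


def lw_read_count(
    genome_length: int, proportion: float, read_length: int = DEFAULT_READ_LENGTH
) -> int:
    """Reads needed so the expected covered fraction equals ``proportion``.

    Solves 1 − e^(−NL/G) = p for N and rounds up:
    N = ceil(G · (−ln(1 − p)) / L).
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must lie strictly in (0, 1)")
    if genome_length < 1 or read_length < 1:
        raise ValueError("genome_length and read_length must be >= 1")
    return math.ceil(genome_length * (-math.log(1.0 - proportion)) / read_length)


def _shred_replicon(
    sequence: str, read_length: int, n_reads: int, rng: np.random.Generator
) -> list[str]:
    """Mark read footprints on a position array; return covered runs."""
    G = len(sequence)
    starts = rng.integers(0, G, size=n_reads)
    ends = np.minimum(starts + read_length, G)  # linear: truncate at the end
    diff = np.zeros(G + 1, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    covered = np.cumsum(diff[:-1]) > 0
    if not covered.any():
        return []
    boundaries = np.flatnonzero(np.diff(covered.astype(np.int8)))
    edges = np.concatenate(([0], boundaries + 1, [G]))
    contigs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if covered[lo]:
            contigs.append(sequence[lo:hi])
    return contigs


def simulate_incomplete(
    genome: Genome,
    config: ShredConfig,
    rng: np.random.Generator | None = None,
) -> Genome:
    """One incomplete-sequencing replicate of ``genome``.

    Applied independently per replicon with that replicon's real length;
    contigs are named ``<replicon_id>_ctg<k>`` and are exact substrings of
    the input.  Deterministic given ``config.seed`` (or the supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    replicons: list[Replicon] = []
    for rep in genome.replicons:
        n_reads = lw_read_count(rep.length, config.proportion, config.read_length)
        contigs = _shred_replicon(rep.sequence, config.read_length, n_reads, rng)
        for k, contig in enumerate(contigs, start=1):
            replicons.append(Replicon(f"{rep.replicon_id}_ctg{k}", contig))
    if not replicons:
        raise ValueError(
            "simulation retained no positions at all; proportion too small "
            "for this replicon length"
        )
    return Genome(f"{genome.genome_id}_p{config.proportion:g}", tuple(replicons))


def simulate_replicates(
    genome: Genome, config: ShredConfig
) -> Iterator[Genome]:
    """Yield ``config.replicates`` independent shreds; replicate r uses
    seed ``config.seed + r`` so individual replicates are reproducible."""
    for r in range(config.replicates):
        rng = np.random.default_rng(config.seed + r)
        yield simulate_incomplete(genome, config, rng=rng)


def random_genome(
    genome_id: str, length: int, rng: np.random.Generator
) -> Genome:
    """Uniform iid {A,C,G,T} genome with a single replicon."""
    arr = _BASES[rng.integers(0, 4, size=length)]
    return Genome(genome_id, (Replicon(f"{genome_id}_chr", arr.tobytes().decode()),))


def generate_genome_pair(
    config: SyntheticPairConfig,
) -> tuple[Genome, Genome, PairReport]:
    """A pair of related synthetic genomes plus its realised divergence.

    Genome A is uniform over {A,C,G,T}; genome B applies, in order: iid
    substitutions (to a uniformly chosen different base), insertion of
    extra repeat copies, then segment deletions.
    """
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    a_codes = rng.integers(0, 4, size=G, dtype=np.int8)
    b_codes = a_codes.copy()

    sub_mask = rng.random(G) < config.substitution_rate
    n_sub = int(sub_mask.sum())
    if n_sub:
        shifts = rng.integers(1, 4, size=n_sub, dtype=np.int8)
        b_codes[sub_mask] = (b_codes[sub_mask] + shifts) % 4

    repeat_source: tuple[int, int] | None = None
    segments: list[np.ndarray] = [b_codes]
    if config.repeat_copies > 0 and config.repeat_length > 0:
        start = int(rng.integers(0, G - config.repeat_length + 1))
        repeat_source = (start, start + config.repeat_length)
        repeat = a_codes[start:start + config.repeat_length]
        merged = b_codes
        for _ in range(config.repeat_copies):
            pos = int(rng.integers(0, len(merged) + 1))
            merged = np.concatenate([merged[:pos], repeat, merged[pos:]])
        segments = [merged]

    b_merged = segments[0]
    deleted: list[tuple[int, int]] = []
    if config.n_segment_deletions > 0 and config.deletion_length > 0:
        keep = np.ones(len(b_merged), dtype=bool)
        attempts = 0
        while len(deleted) < config.n_segment_deletions:
            attempts += 1
            if attempts > 1000 * config.n_segment_deletions:
                raise ValueError("could not place disjoint deletion segments")
            lo = int(rng.integers(0, len(b_merged) - config.deletion_length + 1))
            hi = lo + config.deletion_length
            if keep[lo:hi].all():
                keep[lo:hi] = False
                deleted.append((lo, hi))
        b_merged = b_merged[keep]
        if len(b_merged) == 0:
            raise ValueError("deletions removed the whole genome")

    a_seq = _BASES[a_codes].tobytes().decode()
    b_seq = _BASES[b_merged].tobytes().decode()
    genome_a = Genome("A", (Replicon("A_chr", a_seq),))
    genome_b = Genome("B", (Replicon("B_chr", b_seq),))
    report = PairReport(
        substitutions=n_sub,
        deleted_bp=sum(hi - lo for lo, hi in deleted),
        deleted_segments=tuple(sorted(deleted)),
        repeat_insertions=config.repeat_copies if repeat_source else 0,
        repeat_source=repeat_source,
    )
    return genome_a, genome_b, report
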