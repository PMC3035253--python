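"""Genome sequence and calibration-table input/output.

Every coordinate in this package is 0-based and half-open (``[start, end)``),
expressed on the forward strand of a single replicon.  All parsers convert
into this convention at the boundary, so interval arithmetic downstream never
has to special-case coordinate systems.

A :class:`Genome` is an ordered collection of replicons (chromosome plus any
plasmids or draft contigs).  The genome length that enters the normalising
denominator of the length-dependent distance formulas is the total over all
replicons present in the input file; callers wanting chromosome-only
comparisons filter records before loading.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PathOrHandle = Union[str, Path, IO[str]]


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str, context: str = "") -> str:
    """Uppercase a nucleotide string and map IUPAC ambiguity codes to N.

    Draft genomes routinely contain ambiguity codes (R, Y, S, ...); these are
    normalised to N with a logged warning rather than rejected.  N never
    participates in exact matching downstream.
    """
    seq = sequence.upper()
    if not set(seq) <= VALID_BASES:
        n_bad = sum(c not in VALID_BASES for c in seq)
        logger.warning(
            "%s: %d character(s) outside {A,C,G,T,N} normalized to N",
            context or "sequence", n_bad,
        )
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


@dataclass(frozen=True)
class Replicon:
    """One chromosome, plasmid or contig."""

    replicon_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """Named, ordered set of replicon sequences.

    Invariants: replicon ids unique, sequences non-empty and restricted to
    the {A,C,G,T,N} alphabet (enforced at construction).
    """

    genome_id: str
    replicons: tuple[Replicon, ...]

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"genome {self.genome_id!r} has no replicons")
        seen: set[str] = set()
        for rep in self.replicons:
            if rep.replicon_id in seen:
                raise ValueError(
                    f"duplicate replicon id {rep.replicon_id!r} in genome "
                    f"{self.genome_id!r}"
                )
            seen.add(rep.replicon_id)
            if not rep.sequence:
                raise ValueError(
                    f"empty sequence for replicon {rep.replicon_id!r} in "
                    f"genome {self.genome_id!r}"
                )
            if not set(rep.sequence) <= VALID_BASES:
                raise ValueError(
                    f"replicon {rep.replicon_id!r}: sequence contains "
                    "characters outside {A,C,G,T,N}; normalize first"
                )

    @property
    def total_length(self) -> int:
        """Sum of replicon lengths in bp (the λ input)."""
        return sum(rep.length for rep in self.replicons)

    @property
    def replicon_lengths(self) -> dict[str, int]:
        return {rep.replicon_id: rep.length for rep in self.replicons}

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(
            f"replicon {replicon_id!r} not in genome {self.genome_id!r}"
        )

    def __iter__(self) -> Iterator[Replicon]:
        return iter(self.replicons)


def genome_from_sequences(
    genome_id: str, sequences: Sequence[tuple[str, str]]
) -> Genome:
    """Build a Genome from ``(replicon_id, sequence)`` pairs, normalising."""
    reps = tuple(
        Replicon(rid, normalize_sequence(seq, context=f"{genome_id}/{rid}"))
        for rid, seq in sequences
    )
    return Genome(genome_id, reps)


def _open_maybe(source: PathOrHandle, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fasta(source: PathOrHandle, genome_id: str | None = None) -> Genome:
    """Read a (possibly multi-record) FASTA file into a Genome.

    Replicons keep file order; sequences are uppercased and ambiguity codes
    normalised to N.  ``genome_id`` defaults to the file stem, or to the
    first record id when reading from a stream.
    """
    handle, close = _open_maybe(source, "r")
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError(f"no FASTA records in {source!r}")
    if genome_id is None:
        if isinstance(source, (str, Path)):
            genome_id = Path(source).stem
        else:
            genome_id = records[0].id
    pairs = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        pairs.append((rec.id, seq))
    ids = [rid for rid, _ in pairs]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate record id in {source!r}")
    return genome_from_sequences(genome_id, pairs)


def write_fasta(
    genome: Genome, target: PathOrHandle, line_width: int = 70
) -> None:
    """Write a Genome as FASTA, wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    records = [
        SeqRecord(Seq(rep.sequence), id=rep.replicon_id, description="")
        for rep in genome.replicons
    ]
    handle, close = _open_maybe(target, "w")
    try:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(records)
    finally:
        if close:
            handle.close()


@dataclass(frozen=True)
class CalibrationRecord:
    """One genome pair with its in-silico distance and wet-lab DDH value."""

    pair_id: str
    ggd: float
    ddh: float

    def __post_init__(self) -> None:
        if not (self.ggd >= 0.0 and self.ggd == self.ggd):
            raise ValueError(f"pair {self.pair_id!r}: ggd must be finite >= 0")
        if not 0.0 <= self.ddh <= 100.0:
            raise ValueError(
                f"pair {self.pair_id!r}: ddh {self.ddh} outside [0, 100]"
            )


def read_calibration_table(source: PathOrHandle) -> list[CalibrationRecord]:
    """Read a delimited calibration table (columns pair_id, ggd, ddh).

    Tab- or comma-separated, header required.  Rows with non-numeric or
    out-of-range values are rejected with their (1-based, header = line 1)
    row number.
    """
    handle, close = _open_maybe(source, "r")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = {"pair_id", "ggd", "ddh"} - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing column(s): {sorted(missing)}")
    records: list[CalibrationRecord] = []
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            ggd = float(row["ggd"])
            ddh = float(row["ddh"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"calibration table row {line_no}: non-numeric ggd/ddh"
            ) from exc
        try:
            records.append(CalibrationRecord(str(row["pair_id"]), ggd, ddh))
        except ValueError as exc:
            raise ValueError(f"calibration table row {line_no}: {exc}") from exc
    return records


def write_calibration_table(
    records: Sequence[CalibrationRecord], target: PathOrHandle
) -> None:
    df = pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in records],
            "ggd": [r.ggd for r in records],
            "ddh": [r.ddh for r in records],
        }
    )
    handle, close = _open_maybe(target, "w")
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()
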