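"""Genome I/O and coordinate arithmetic.

Reads reference genomes from FASTA, sanitizes ambiguity codes, and provides
strand-aware, topology-aware sequence extraction.  Coordinates are 0-based,
half-open throughout: a region ``(start, length)`` covers offsets
``start .. start+length-1``, wrapping past the contig end when the genome is
circular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (empty records, duplicate names)."""


@dataclass(frozen=True)
class Genome:
    """An ordered collection of contigs with a linear-or-circular topology flag.

    Topology is a user-supplied property of the whole genome: FASTA carries no
    topology metadata, so it is never inferred from the file.
    """

    contigs: tuple[tuple[str, str], ...]
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        names = [name for name, _ in self.contigs]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise FastaFormatError(f"duplicate contig name: {dup!r}")
        for name, seq in self.contigs:
            if not seq:
                raise FastaFormatError(f"contig {name!r} has empty sequence")
            if not set(seq) <= VALID_BASES:
                bad = next(c for c in seq if c not in VALID_BASES)
                raise ValueError(f"contig {name!r} contains non-ACGT character {bad!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.contigs]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def sequence(self, contig: str) -> str:
        for name, seq in self.contigs:
            if name == contig:
                return seq
        raise KeyError(f"no contig named {contig!r}")


@dataclass(frozen=True)
class ReadRegion:
    """A sampled genomic span: contig, 0-based start, length and strand."""

    contig: str
    start: int
    length: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length <= 0:
            raise ValueError(f"region length must be positive, got {self.length}")
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")


def sanitize_sequence(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Uppercase ``seq`` and replace every non-ACGT character with a uniform
    random base drawn from ``rng``.

    Returns the sanitized sequence and the number of substituted positions.
    Ambiguity codes (N and the other IUPAC letters) are randomized rather than
    rejected because the pore model is defined only on A/C/G/T; seeding makes
    the substitution reproducible.
    """
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    valid = np.frombuffer(b"ACGT", dtype=np.uint8)
    bad = ~np.isin(arr, valid)
    n_bad = int(bad.sum())
    arr[bad] = rng.choice(valid, size=n_bad)
    return arr.tobytes().decode("ascii"), n_bad


def read_fasta(path: str | Path, topology: str = "linear",
               rng: np.random.Generator | None = None) -> Genome:
    """Load a (multi-record) FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; characters outside A/C/G/T are replaced by
    a random base drawn from ``rng`` (default: fresh generator seeded 0), and
    the substitution count is logged at WARNING.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    contigs: list[tuple[str, str]] = []
    total_sub = 0
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        clean, n_sub = sanitize_sequence(seq, rng)
        if n_sub:
            logger.warning("sanitized %d non-ACGT characters in contig %r", n_sub, rec.id)
        total_sub += n_sub
        contigs.append((rec.id, clean))
    if total_sub:
        logger.warning("sanitized %d non-ACGT characters in total", total_sub)
    return Genome(contigs=tuple(contigs), topology=topology)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    if not set(seq) <= VALID_BASES:
        bad = next(c for c in seq if c not in VALID_BASES)
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(genome: Genome, region: ReadRegion) -> str:
    """Extract the sequence of a :class:`ReadRegion` from a genome.

    On a circular genome the span may wrap past the contig end (equivalent to
    substring extraction on the doubled sequence).  Minus-strand regions
    return the reverse complement of the plus-strand span.
    """
    seq = genome.sequence(region.contig)
    n = len(seq)
    if region.start >= n:
        raise IndexError(
            f"region start {region.start} beyond contig {region.contig!r} length {n}")
    if genome.topology == "circular":
        if region.length > n:
            raise IndexError(
                f"circular region length {region.length} exceeds contig length {n}")
        end = region.start + region.length
        span = seq[region.start:end] if end <= n else seq[region.start:] + seq[:end - n]
    else:
        if region.start + region.length > n:
            raise IndexError(
                f"linear region [{region.start}, {region.start + region.length}) "
                f"runs off contig {region.contig!r} of length {n}")
        span = seq[region.start:region.start + region.length]
    return reverse_complement(span) if region.strand == "-" else span


def write_reads_fasta(reads: Iterable[tuple[str, ReadRegion, str]], path: str | Path) -> int:
    """Write ground-truth reads as FASTA.

    Each item is ``(read_id, region, sequence)``; the header records the
    sampled coordinates as ``name=<id> contig=<c> start=<s> length=<l>
    strand=<+/->`` so the truth can be parsed back without sidecar files.
    Returns the number of records written.
    """
    records = []
    for read_id, region, seq in reads:
        desc = (f"contig={region.contig} start={region.start} "
                f"length={region.length} strand={region.strand}")
        records.append(SeqRecord(Seq(seq), id=f"name={read_id}", description=desc))
    n = SeqIO.write(records, str(path), "fasta")
    return n


def parse_read_header(header: str) -> dict[str, str]:
    """Parse a ground-truth FASTA header back into its key=value fields."""
    fields = {}
    for token in header.split():
        if "=" in token:
            key, _, value = token.partition("=")
            fields[key] = value
    return fields
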