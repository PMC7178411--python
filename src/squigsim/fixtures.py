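"""Deterministic synthetic genomes and pore tables.

Everything the simulator needs can be generated from a seed, so the full
pipeline (and its test suite) runs with zero downloads.  Synthetic pore
tables mimic the layout and value ranges of the officially released 6-mer
statistics (level means in the tens-of-pA band, small positive stdvs) but
are random: they are stand-ins for testing the machinery, not emulations of
a real pore's chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import Genome
from .pore_model import PoreModelTable, all_kmers


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic genome + pore-table pair."""

    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_contigs: int = 1
    seed: int = 0
    k: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction must lie in [0, 1], got {self.gc_fraction}")
        if self.genome_length < self.n_contigs:
            raise ValueError("genome_length must allow at least 1 base per contig")
        if not (3 <= self.k <= 8):
            raise ValueError(f"k must lie in [3, 8], got {self.k}")


def synth_genome(spec: FixtureSpec, topology: str = "linear") -> Genome:
    """i.i.d. random genome with P(G)+P(C) = gc_fraction, split into contigs."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=spec.genome_length, p=probs)
    bounds = np.linspace(0, spec.genome_length, spec.n_contigs + 1).astype(int)
    contigs = tuple(
        (f"contig_{i}", seq[bounds[i]:bounds[i + 1]].tobytes().decode("ascii"))
        for i in range(spec.n_contigs))
    return Genome(contigs=contigs, topology=topology)


def synth_pore_table(spec: FixtureSpec) -> PoreModelTable:
    """Complete 4^k table: means uniform in [60, 120] pA, stdvs in [1, 3] pA."""
    rng = np.random.default_rng(spec.seed)
    kmers = all_kmers(spec.k)
    means = rng.uniform(60.0, 120.0, size=len(kmers))
    stdvs = rng.uniform(1.0, 3.0, size=len(kmers))
    levels = {km: (float(m), float(s)) for km, m, s in zip(kmers, means, stdvs)}
    return PoreModelTable(k=spec.k, levels=levels)


def write_fixtures(spec: FixtureSpec, out_dir: str | Path,
                   topology: str = "linear") -> tuple[Path, Path]:
    """Write genome FASTA + pore-table TSV; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = synth_genome(spec, topology=topology)
    fasta = out_dir / "genome.fasta"
    with open(fasta, "w") as fh:
        for name, seq in genome.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    table_path = out_dir / f"pore_table_k{spec.k}.tsv"
    synth_pore_table(spec).write_tsv(table_path)
    return fasta, table_path
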