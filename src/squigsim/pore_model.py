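"""The context-independent k-mer pore model.

Maps a read sequence to its expected current-level sequence by exact lookup
in a complete k-mer statistics table (the layout of the officially released
6-mer tables: tab-separated, header, columns ``kmer  level_mean
level_stdv``).  "Context-independent" means each k-mer's expected level
depends only on the k-mer itself — no state carries across positions, which
is what makes this model dramatically faster than a recurrent
context-dependent one.

The model surface is pluggable (:class:`PoreModel`): a context-dependent
neural model can be slotted in behind the same ``expected_levels`` call
without touching the signal pipeline.
"""

from __future__ import annotations

import itertools
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"


class PoreTableError(ValueError):
    """Raised when a pore-model table violates its completeness/validity invariants."""


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers over ACGT in lexicographic order."""
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


@dataclass(frozen=True)
class PoreModelTable:
    """A complete map from every k-mer to (level mean pA, level stdv pA)."""

    k: int
    levels: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        expected = 4 ** self.k
        if len(self.levels) != expected:
            missing = next((km for km in all_kmers(self.k) if km not in self.levels), None)
            raise PoreTableError(
                f"table has {len(self.levels)} entries, expected 4^{self.k} = {expected}"
                + (f"; first missing k-mer: {missing}" if missing else ""))
        for kmer, (mean, stdv) in self.levels.items():
            if len(kmer) != self.k:
                raise PoreTableError(f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}")
            if stdv <= 0:
                raise PoreTableError(f"k-mer {kmer} has non-positive level_stdv {stdv}")

    def level_mean(self, kmer: str) -> float:
        return self.levels[kmer][0]

    def level_stdv(self, kmer: str) -> float:
        return self.levels[kmer][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [(km, m, s) for km, (m, s) in sorted(self.levels.items())]
        return pd.DataFrame(rows, columns=["kmer", "level_mean", "level_stdv"])

    def write_tsv(self, path: str | Path) -> None:
        # %.17g keeps the table exactly round-trippable through text
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class EventTrack:
    """Per-position events of one read: k-mer, expected level, and dwell.

    There are ``len(seq) - k + 1`` events (one per overlapping window);
    ``dwells`` is filled later by the signal pipeline.
    """

    kmers: list[str]
    expected_levels: np.ndarray
    dwells: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def total_samples(self) -> int:
        if self.dwells is None:
            raise ValueError("dwells are not set on this track")
        return int(self.dwells.sum())


def kmerize(seq: str, k: int) -> list[str]:
    """The ``len(seq) - k + 1`` overlapping k-windows of ``seq``, in order."""
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


class PoreModel(ABC):
    """Anything that can turn a sequence into expected current levels."""

    @property
    @abstractmethod
    def k(self) -> int: ...

    @abstractmethod
    def expected_levels(self, seq: str) -> EventTrack: ...


class TablePoreModel(PoreModel):
    """The shipped implementation: exact per-k-mer table lookup."""

    def __init__(self, table: PoreModelTable):
        self.table = table

    @property
    def k(self) -> int:
        return self.table.k

    def expected_levels(self, seq: str) -> EventTrack:
        kmers = kmerize(seq, self.table.k)
        levels = np.array([self.table.levels[km][0] for km in kmers], dtype=np.float64)
        return EventTrack(kmers=kmers, expected_levels=levels)

    def level_stdvs(self, track: EventTrack) -> np.ndarray:
        return np.array([self.table.levels[km][1] for km in track.kmers], dtype=np.float64)


def expected_levels(seq: str, table: PoreModelTable) -> EventTrack:
    """Functional form of :meth:`TablePoreModel.expected_levels`."""
    return TablePoreModel(table).expected_levels(seq)


def load_table(path: str | Path) -> PoreModelTable:
    """Load and validate a pore-model table from tab-separated text.

    The file must have a header naming at least ``kmer``, ``level_mean`` and
    ``level_stdv`` columns; extra columns are ignored.  k is inferred from
    the k-mer length, and the table must be complete (all 4^k k-mers, no
    duplicates) with strictly positive stdvs.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"kmer", "level_mean", "level_stdv"}
    if not required <= set(df.columns):
        raise PoreTableError(
            f"{path}: pore table must have columns {sorted(required)}; "
            f"found {list(df.columns)}")
    kmers = df["kmer"].astype(str)
    klens = kmers.str.len().unique()
    if len(klens) != 1:
        raise PoreTableError(f"{path}: inconsistent k-mer lengths {sorted(klens)}")
    k = int(klens[0])
    if kmers.duplicated().any():
        dup = kmers[kmers.duplicated()].iloc[0]
        raise PoreTableError(f"{path}: duplicate k-mer {dup}")
    levels = {row.kmer: (float(row.level_mean), float(row.level_stdv))
              for row in df.itertuples()}
    return PoreModelTable(k=k, levels=levels)
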