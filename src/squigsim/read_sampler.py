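"""Read sampling: how many reads, how long, and where from.

This is the "sequence generator" stage of the simulator.  It draws read
lengths from one of several parametric families shaped like real Nanopore
run length profiles, rescales them to a requested mean, and places reads on
the genome with contig choice proportional to contig length, uniform start
and uniform strand.

Length families
---------------
``expansion_tail``
    A right-skewed two-component gamma mixture — the long-tail shape typical
    of a modern Nanopore run (a body of moderate reads plus a heavy tail of
    ultra-long ones).  This is the default.
``exponential``
    Memoryless fragmentation; the classic single-parameter profile.
``beta_like``
    A beta draw scaled to a maximum length — bounded-support profiles.
``fixed``
    Every read has exactly the target length (degenerate; mainly for tests).

When ``target_mean`` is set, draws are rescaled multiplicatively
(``x -> x * target_mean / family_mean``) so the expectation matches while the
distribution's shape is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome, ReadRegion

logger = logging.getLogger(__name__)

LENGTH_FAMILIES = ("expansion_tail", "exponential", "beta_like", "fixed")

#: Default parameters for each family, collected in one place so they can be
#: refit against a real run without touching sampling code.  Units: bases.
FAMILY_DEFAULTS: dict[str, dict[str, float]] = {
    # mixture weight of the short-read component, then (shape, scale) per component
    "expansion_tail": {"w_body": 0.7, "shape_body": 2.0, "scale_body": 2000.0,
                       "shape_tail": 3.0, "scale_tail": 6000.0},
    "exponential": {"scale": 8000.0},
    "beta_like": {"a": 2.0, "b": 5.0, "max_length": 50000.0},
    "fixed": {},
}


@dataclass(frozen=True)
class LengthDistSpec:
    """Read-length distribution choice, parameters, and optional target mean."""

    family: str = "expansion_tail"
    params: dict = field(default_factory=dict)
    target_mean: float | None = None
    min_length: int = 100

    def __post_init__(self) -> None:
        if self.family not in LENGTH_FAMILIES:
            raise ValueError(
                f"unknown length family {self.family!r}; choose from {LENGTH_FAMILIES}")
        if self.target_mean is not None and self.target_mean <= 0:
            raise ValueError("target_mean must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.family == "fixed" and self.target_mean is None:
            raise ValueError("family 'fixed' requires target_mean")

    @property
    def effective_params(self) -> dict[str, float]:
        merged = dict(FAMILY_DEFAULTS[self.family])
        merged.update(self.params)
        return merged

    def family_mean(self) -> float:
        """Analytic mean of the un-rescaled family with the effective params."""
        p = self.effective_params
        if self.family == "expansion_tail":
            w = p["w_body"]
            return (w * p["shape_body"] * p["scale_body"]
                    + (1.0 - w) * p["shape_tail"] * p["scale_tail"])
        if self.family == "exponential":
            return p["scale"]
        if self.family == "beta_like":
            return p["a"] / (p["a"] + p["b"]) * p["max_length"]
        return float(self.target_mean)  # fixed

    @property
    def mean_length(self) -> float:
        """The mean the sampler will actually target."""
        return float(self.target_mean) if self.target_mean is not None else self.family_mean()


@dataclass(frozen=True)
class SamplingPlan:
    """How many reads to draw and in which mode.

    ``pass_through`` emits every input contig exactly once, uncut — useful to
    simulate the signal of known sequences rather than a shotgun run.
    """

    n_reads: int
    mode: str = "sample"  # "sample" | "pass_through"
    length_spec: LengthDistSpec = field(default_factory=LengthDistSpec)

    def __post_init__(self) -> None:
        if self.mode not in ("sample", "pass_through"):
            raise ValueError(f"mode must be 'sample' or 'pass_through', got {self.mode!r}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def reads_for_coverage(genome_length: int, coverage: float, mean_length: float) -> int:
    """Number of reads needed for ``coverage``-fold redundancy: ceil(G*C/L), min 1."""
    if genome_length <= 0 or coverage <= 0 or mean_length <= 0:
        raise ValueError("genome_length, coverage and mean_length must all be positive")
    return max(1, math.ceil(genome_length * coverage / mean_length))


def sample_lengths(spec: LengthDistSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer read lengths from ``spec``.

    Draws are rescaled to ``target_mean`` (shape-preserving), rounded, and
    truncated below at ``min_length``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = spec.effective_params
    if spec.family == "fixed":
        return np.full(n, int(round(spec.target_mean)), dtype=np.int64)
    if spec.family == "expansion_tail":
        is_body = rng.random(n) < p["w_body"]
        draws = np.where(
            is_body,
            rng.gamma(p["shape_body"], p["scale_body"], size=n),
            rng.gamma(p["shape_tail"], p["scale_tail"], size=n),
        )
    elif spec.family == "exponential":
        draws = rng.exponential(p["scale"], size=n)
    else:  # beta_like
        draws = rng.beta(p["a"], p["b"], size=n) * p["max_length"]
    if spec.target_mean is not None:
        draws = draws * (spec.target_mean / spec.family_mean())
    lengths = np.maximum(np.rint(draws).astype(np.int64), spec.min_length)
    return lengths


def sample_length(spec: LengthDistSpec, rng: np.random.Generator) -> int:
    """Draw a single read length (see :func:`sample_lengths`)."""
    return int(sample_lengths(spec, 1, rng)[0])


def _contig_probs(genome: Genome, min_len: int) -> np.ndarray:
    lengths = np.asarray(genome.lengths, dtype=np.float64)
    if genome.topology == "circular":
        probs = lengths
    else:
        if not any(L >= min_len for L in genome.lengths):
            raise ValueError(
                f"no contig reaches the minimum read length {min_len}; "
                "no valid linear placement exists")
        probs = np.where(lengths >= min_len, lengths, 0.0)
    return probs / probs.sum()


def _place_reads(genome: Genome, raw_lengths: np.ndarray, min_len: int,
                 rng: np.random.Generator) -> tuple[list[ReadRegion], int]:
    """Place reads of the given lengths; returns (regions, n_clipped)."""
    probs = _contig_probs(genome, min_len)
    circular = genome.topology == "circular"
    n = len(raw_lengths)
    contig_idx = rng.choice(len(genome.contigs), size=n, p=probs)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    regions: list[ReadRegion] = []
    n_clipped = 0
    for i in range(n):
        name, seq = genome.contigs[int(contig_idx[i])]
        clen = len(seq)
        length = int(raw_lengths[i])
        if circular:
            start = int(rng.integers(0, clen))
            if length > clen:
                length = clen
                n_clipped += 1
        else:
            # any start that leaves room for a minimum-length read is valid
            start = int(rng.integers(0, clen - min_len + 1))
            if start + length > clen:
                length = clen - start
                n_clipped += 1
        regions.append(ReadRegion(contig=name, start=start, length=length,
                                  strand=str(strands[i])))
    return regions, n_clipped


def sample_regions_for_coverage(genome: Genome, coverage: float,
                                length_spec: LengthDistSpec,
                                rng: np.random.Generator) -> list[ReadRegion]:
    """Draw reads until the cumulative base count reaches ``coverage``-fold.

    Unlike converting coverage to a fixed read count up front (which leaves
    the achieved coverage with O(cv/sqrt(n)) error under heavy-tailed length
    distributions), stopping on cumulative bases bounds the overshoot by a
    single read length, so the requested redundancy is met tightly for any
    family.  :func:`reads_for_coverage` still provides the expected count.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    target = genome.total_length * coverage
    regions: list[ReadRegion] = []
    total = 0
    n_clipped = 0
    while total < target:
        remaining = target - total
        est = max(8, math.ceil(remaining / length_spec.mean_length))
        lengths = sample_lengths(length_spec, est, rng)
        batch, clipped = _place_reads(genome, lengths, length_spec.min_length, rng)
        n_clipped += clipped
        for region in batch:
            regions.append(region)
            total += region.length
            if total >= target:
                break
    if n_clipped:
        logger.warning("clipped %d read lengths at contig boundaries", n_clipped)
    return regions


def sample_regions(genome: Genome, plan: SamplingPlan,
                   rng: np.random.Generator) -> list[ReadRegion]:
    """Place ``plan.n_reads`` reads on the genome.

    Contigs are chosen with probability proportional to their length, starts
    uniformly over valid positions, strands uniformly.  Lengths beyond what
    the topology allows are clipped: circular reads clip at the contig
    length, linear reads at ``contig_length - start``.  Clipping counts are
    logged so a user simulating long reads from short contigs can see it.

    In ``pass_through`` mode every contig is emitted once, full-length and
    plus-strand, in input order.
    """
    if plan.mode == "pass_through":
        return [ReadRegion(contig=name, start=0, length=len(seq), strand="+")
                for name, seq in genome.contigs]

    raw_lengths = sample_lengths(plan.length_spec, plan.n_reads, rng)
    regions, n_clipped = _place_reads(genome, raw_lengths,
                                      plan.length_spec.min_length, rng)
    if n_clipped:
        logger.warning("clipped %d of %d read lengths at contig boundaries",
                       n_clipped, plan.n_reads)
    return regions
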