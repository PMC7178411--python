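"""End-to-end pipeline driver: config, seeding, scheduling, basecaller hook.

Reproducibility contract
------------------------
Every byte of output is a pure function of (input FASTA, pore table, config,
master seed).  Each read gets a *child seed* derived deterministically from
(master seed, read index) via ``numpy.random.SeedSequence([master_seed,
read_index])``, so the per-read random streams are independent of execution
order and thread count.  Region sampling uses its own stream seeded directly
with the master seed before any parallel work begins.

Memory contract
---------------
Signals stream to disk per read: reads are processed in small batches and
nothing proportional to the total output is held in memory — peak usage is
bounded by the longest single read's signal times the batch size.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import Genome, ReadRegion, extract_region, read_fasta
from .outputs import MANIFEST_COLUMNS, write_alignment, write_fast5
from .pore_model import PoreModelTable, TablePoreModel, load_table
from .read_sampler import (LengthDistSpec, SamplingPlan, sample_regions,
                           sample_regions_for_coverage)
from .signal_pipeline import (ChannelParams, NoiseFilterSpec, digitize,
                              simulate_signal)
from .fixtures import FixtureSpec, synth_pore_table

logger = logging.getLogger(__name__)


class ReadSimulationError(RuntimeError):
    """A hard error while simulating one read, annotated with its id."""


@dataclass(frozen=True)
class SimulationConfig:
    """Fully serializable description of one simulation run."""

    input_fasta: str | None = None
    pore_table: str | None = None          # None -> deterministic synthetic k=6 table
    out_dir: str = "squigsim_out"
    topology: str = "linear"
    mode: str = "sample"                   # "sample" | "pass_through"
    n_reads: int | None = None
    coverage: float | None = None
    length_family: str = "expansion_tail"
    length_mean: float | None = None
    length_min: int = 100
    cutoff_fraction: float = 0.08
    filter_order: int = 2
    noise_sigma: float = 1.5
    dwell_mean: float = 9.0
    dwell_spread: float = 4.0
    sampling_rate: float = 4000.0
    level_jitter: bool = False
    master_seed: int = 0
    threads: int = 1
    basecaller_cmd: str | None = None
    skip_bad_reads: bool = False
    keep_intermediate: bool = False

    def __post_init__(self) -> None:
        if self.n_reads is not None and self.coverage is not None:
            raise ValueError("n_reads and coverage are mutually exclusive")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    def length_spec(self) -> LengthDistSpec:
        return LengthDistSpec(family=self.length_family,
                              target_mean=self.length_mean,
                              min_length=self.length_min)

    def noise_filter_spec(self) -> NoiseFilterSpec:
        return NoiseFilterSpec(cutoff_fraction=self.cutoff_fraction,
                               filter_order=self.filter_order,
                               noise_sigma_pA=self.noise_sigma,
                               dwell_mean=self.dwell_mean,
                               dwell_spread=self.dwell_spread,
                               level_jitter=self.level_jitter)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"squigsim_version": __version__, "config": self.to_dict()},
                           fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["config"] if "config" in doc else doc)


def child_seed(master_seed: int, read_index: int) -> int:
    """Stable per-read seed: first word of SeedSequence([master_seed, read_index]).

    Documented so other implementations can reproduce the streams exactly.
    """
    return int(np.random.SeedSequence([master_seed, read_index]).generate_state(1)[0])


def _resolve_pore_model(config: SimulationConfig) -> TablePoreModel:
    if config.pore_table is not None:
        table = load_table(config.pore_table)
    else:
        logger.info("no pore table supplied; using deterministic synthetic k=6 table")
        table = synth_pore_table(FixtureSpec(seed=config.master_seed, k=6))
    return TablePoreModel(table)


def _simulate_one(index: int, region: ReadRegion, genome: Genome,
                  model: TablePoreModel, spec: NoiseFilterSpec,
                  channel: ChannelParams, config: SimulationConfig):
    """Compute one read end to end (no I/O).  Returns None for dropped reads."""
    read_id = f"read_{index:06d}"
    seq = extract_region(genome, region)
    if len(seq) < model.k:
        logger.warning("read %s: sequence length %d < k=%d; dropping",
                       read_id, len(seq), model.k)
        return None
    rng = np.random.default_rng(child_seed(config.master_seed, index))
    track = model.expected_levels(seq)
    stdvs = model.level_stdvs(track) if spec.level_jitter else None
    signal, alignment = simulate_signal(track, spec, rng,
                                        sampling_rate=config.sampling_rate,
                                        level_stdvs=stdvs)
    dac = digitize(signal, channel)
    row = (read_id, region.contig, region.start, region.length, region.strand,
           len(alignment), len(dac), child_seed(config.master_seed, index))
    return read_id, seq, alignment, dac, signal, row


def run(config: SimulationConfig, genome: Genome | None = None,
        pore_table: PoreModelTable | None = None,
        channel: ChannelParams | None = None) -> pd.DataFrame:
    """Execute the full simulation described by ``config``; return the manifest.

    ``genome``/``pore_table`` may be passed in-memory (tests, library use);
    otherwise they are loaded from the configured paths.  Outputs land under
    ``config.out_dir``: ``fast5/`` (one file per read), ``reads.fasta``
    (strand-resolved ground truth), ``alignments/*.align.tsv``,
    ``manifest.tsv`` and ``config.yaml``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fast5_dir = out_dir / "fast5"
    fast5_dir.mkdir(exist_ok=True)
    align_dir = out_dir / "alignments"
    align_dir.mkdir(exist_ok=True)

    master_rng = np.random.default_rng(config.master_seed)
    if genome is None:
        if config.input_fasta is None:
            raise ValueError("config.input_fasta is required when no genome is passed")
        genome = read_fasta(config.input_fasta, topology=config.topology, rng=master_rng)
    model = TablePoreModel(pore_table) if pore_table is not None else _resolve_pore_model(config)
    channel = channel or ChannelParams()
    spec = config.noise_filter_spec()
    length_spec = config.length_spec()

    if config.mode == "pass_through":
        plan = SamplingPlan(n_reads=len(genome.contigs), mode="pass_through",
                            length_spec=length_spec)
        regions = sample_regions(genome, plan, master_rng)
    elif config.coverage is not None:
        # stop on cumulative bases so the achieved coverage is tight even
        # for heavy-tailed length families
        regions = sample_regions_for_coverage(genome, config.coverage,
                                              length_spec, master_rng)
    elif config.n_reads is not None:
        plan = SamplingPlan(n_reads=config.n_reads, length_spec=length_spec)
        regions = sample_regions(genome, plan, master_rng)
    else:
        raise ValueError("one of n_reads or coverage must be set in sample mode")

    rows: list[tuple] = []
    fasta_path = out_dir / "reads.fasta"
    batch = max(4 * config.threads, 8)

    def worker(i: int):
        try:
            return _simulate_one(i, regions[i], genome, model, spec, channel, config)
        except Exception as exc:  # noqa: BLE001 - aggregated below
            if config.skip_bad_reads:
                logger.warning("read %d failed and was skipped: %s", i, exc)
                return None
            raise ReadSimulationError(f"read_{i:06d}: {exc}") from exc

    with open(fasta_path, "w") as fasta_fh:
        for lo in range(0, len(regions), batch):
            indices = range(lo, min(lo + batch, len(regions)))
            if config.threads > 1:
                with ThreadPoolExecutor(max_workers=config.threads) as pool:
                    results = list(pool.map(worker, indices))
            else:
                results = [worker(i) for i in indices]
            for i, result in zip(indices, results):
                if result is None:
                    continue
                read_id, seq, alignment, dac, signal, row = result
                region = regions[i]
                fasta_fh.write(
                    f">name={read_id} contig={region.contig} start={region.start} "
                    f"length={region.length} strand={region.strand}\n")
                for j in range(0, len(seq), 80):
                    fasta_fh.write(seq[j:j + 80] + "\n")
                write_fast5(read_id, dac, channel, config.sampling_rate,
                            fast5_dir / f"{read_id}.fast5", read_number=i)
                write_alignment(alignment, align_dir / f"{read_id}.align.tsv")
                if config.keep_intermediate:
                    inter_dir = out_dir / "intermediate"
                    inter_dir.mkdir(exist_ok=True)
                    np.savetxt(inter_dir / f"{read_id}.signal_pa.tsv",
                               signal.samples, fmt="%.4f")
                rows.append(row)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "config.yaml")

    status = None
    if config.basecaller_cmd:
        status, bc_out = call_external_basecaller(config.basecaller_cmd,
                                                  fast5_dir, out_dir / "basecalls")
        (out_dir / "basecaller_status.txt").write_text(
            f"cmd: {config.basecaller_cmd}\nexit_status: {status}\noutput_dir: {bc_out}\n")
    else:
        (out_dir / "basecaller_status.txt").write_text("no basecaller\n")
    return manifest


def call_external_basecaller(cmd_template: str, input_dir: str | Path,
                             output_dir: str | Path) -> tuple[int, Path]:
    """Run an external basecaller over the FAST5 directory.

    ``{input_dir}`` and ``{output_dir}`` in the template are substituted and
    the command executed; the exit status is returned and recorded, never
    masked.  The basecaller's output is treated as opaque — nothing is
    parsed or post-processed.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    cmd = cmd_template.format(input_dir=str(input_dir), output_dir=str(output_dir))
    logger.info("running external basecaller: %s", cmd)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    if proc.returncode != 0:
        logger.error("basecaller exited with status %d: %s", proc.returncode,
                     proc.stderr.strip()[:500])
    return proc.returncode, output_dir
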