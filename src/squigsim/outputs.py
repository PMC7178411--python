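"""Persist simulated reads, signals, truth and the run manifest.

FAST5 files use the conventional single-read layout (one HDF5 file per
read): the 16-bit DAC trace under ``Raw/Reads/Read_<n>/Signal`` and channel
calibration attributes (digitisation, range, offset, sampling_rate) under
``UniqueGlobalKey/channel_id``.  Datasets are written with HDF5 timestamp
tracking disabled so identical simulations produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genome_io import ReadRegion, write_reads_fasta
from .signal_pipeline import ChannelParams, GroundTruthAlignment

MANIFEST_COLUMNS = ["read_id", "contig", "start", "length", "strand",
                    "n_events", "n_samples", "child_seed"]


@dataclass
class SimulatedRead:
    """Everything the pipeline produced for one read."""

    read_id: str
    region: ReadRegion
    sequence: str
    alignment: GroundTruthAlignment
    dac: np.ndarray
    child_seed: int


def write_fast5(read_id: str, signal: np.ndarray, channel: ChannelParams,
                sampling_rate: float, path: str | Path, read_number: int = 0) -> Path:
    """Write one single-read FAST5-layout HDF5 file and return its path."""
    signal = np.asarray(signal)
    if signal.size == 0:
        raise ValueError(f"refusing to write empty signal for read {read_id!r}")
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        read_grp = f.create_group(f"Raw/Reads/Read_{read_number}")
        read_grp.attrs["read_id"] = read_id
        read_grp.attrs["read_number"] = read_number
        ds = read_grp.create_dataset("Signal", data=signal.astype(np.int16),
                                     dtype=np.int16, track_times=False)
        ds.attrs["sampling_rate"] = float(sampling_rate)
        ch = f.create_group("UniqueGlobalKey/channel_id")
        ch.attrs["digitisation"] = float(channel.digitisation)
        ch.attrs["range"] = float(channel.range_pA)
        ch.attrs["offset"] = float(channel.offset)
        ch.attrs["sampling_rate"] = float(sampling_rate)
    return path


def read_fast5(path: str | Path) -> tuple[str, np.ndarray, ChannelParams, float]:
    """Read back (read_id, signal, channel, sampling_rate) from a single-read file."""
    with h5py.File(path, "r") as f:
        reads = f["Raw/Reads"]
        (read_name,) = list(reads.keys())
        grp = reads[read_name]
        read_id = grp.attrs["read_id"]
        if isinstance(read_id, bytes):
            read_id = read_id.decode()
        signal = grp["Signal"][:]
        ch = f["UniqueGlobalKey/channel_id"].attrs
        channel = ChannelParams(digitisation=float(ch["digitisation"]),
                                range_pA=float(ch["range"]),
                                offset=float(ch["offset"]))
        sampling_rate = float(ch["sampling_rate"])
    return str(read_id), signal, channel, sampling_rate


def alignment_frame(alignment: GroundTruthAlignment) -> pd.DataFrame:
    return pd.DataFrame({
        "event_index": alignment.event_index,
        "base_offset": alignment.base_offset,
        "signal_start": alignment.signal_start,
        "signal_end": alignment.signal_end,
    })


def write_alignment(alignment: GroundTruthAlignment, path: str | Path) -> None:
    """Per-read ground-truth alignment TSV: event_index base_offset signal_start signal_end."""
    alignment_frame(alignment).to_csv(path, sep="\t", index=False)


def manifest_frame(reads: list[SimulatedRead]) -> pd.DataFrame:
    rows = [(r.read_id, r.region.contig, r.region.start, r.region.length,
             r.region.strand, len(r.alignment), len(r.dac), r.child_seed)
            for r in reads]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_truth(reads: list[SimulatedRead], out_dir: str | Path) -> pd.DataFrame:
    """Write ground-truth FASTA, per-read alignment TSVs, and the manifest TSV.

    Sequences are written as extracted (already strand-resolved).  Returns
    the manifest frame.  Collection consistency (one alignment and one
    signal per read) is enforced by construction of SimulatedRead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    align_dir = out_dir / "alignments"
    align_dir.mkdir(exist_ok=True)
    write_reads_fasta([(r.read_id, r.region, r.sequence) for r in reads],
                      out_dir / "reads.fasta")
    for r in reads:
        write_alignment(r.alignment, align_dir / f"{r.read_id}.align.tsv")
    manifest = manifest_frame(reads)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
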