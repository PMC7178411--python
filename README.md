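# squigsim

A simulator for Oxford Nanopore sequencing that produces both the raw
electrical current traces ("squiggles") and the underlying reads, with full
base-to-signal ground truth.

Nanopore devices read DNA by measuring the ionic current while a strand
translocates through a protein pore; at any instant the current level is
determined (to first order) by the k-mer occupying the pore. Tools that work
on raw signals — basecallers, event segmenters, modification callers, signal
aligners — need test data where the true sequence and the exact
signal-to-base correspondence are known. Real runs never provide that;
a simulator does.

## What it does

Given a reference genome (FASTA) and a k-mer pore-model table, `squigsim`:

1. **samples reads** — contigs chosen proportional to length, uniform starts
   and strands, read lengths drawn from one of four families
   (`expansion_tail`, a right-skewed gamma mixture and the default;
   `exponential`; `beta_like`, a bounded scaled beta; `fixed`), rescalable to
   any target mean. Circular genomes wrap around the origin; a pass-through
   mode emits each input sequence whole. Read count may be given directly or
   via target coverage (reads are drawn until the requested fold-redundancy
   is reached).
2. **computes expected levels** — a context-independent pore model: each of
   the `len(read) − k + 1` overlapping k-mers is looked up in a complete
   4^k table of (mean pA, stdv pA). The model interface is pluggable, so a
   context-dependent model can be slotted in.
3. **builds the signal** — each event's level is repeated for a random dwell
   (discretized gamma, default mean 9 samples at 4 kHz ≈ 450 bases/s),
   giving a square wave; a zero-phase low-pass filter (cascaded real-pole
   sections, default normalized cutoff 0.08) removes the artificial sharp
   transitions; i.i.d. Gaussian noise (default σ = 1.5 pA) is added last.
   Filter cutoff and noise σ together control output signal quality.
4. **writes outputs** — one single-read FAST5 (HDF5) file per read with the
   16-bit DAC trace and channel calibration, a strand-resolved ground-truth
   FASTA, a per-read event-to-signal alignment TSV, and a run manifest.
   Every byte is a pure function of (inputs, config, master seed); per-read
   child seeds make results independent of the thread count.

## Worked example

Everything below runs offline; `make-fixtures` writes a deterministic
synthetic genome and pore table.

```bash
squigsim make-fixtures -o fx --genome-length 50000 --k 6 --circular
# wrote fx/genome.fasta and fx/pore_table_k6.tsv

squigsim simulate -i fx/genome.fasta --pore-table fx/pore_table_k6.tsv \
    -o sim --coverage 2 --mean-len 1500 --circular --seed 42
# simulated 69 reads (897695 signal samples) -> sim
```

69 reads of mean target 1500 bases cover the 50 kb genome just over 2-fold
(coverage is a floor: sampling stops when cumulative bases reach
genome_length × coverage). `sim/` now contains `fast5/` (69 raw-signal
files), `reads.fasta`, `alignments/`, `manifest.tsv` and `config.yaml`.
The manifest starts:

```
read_id      contig    start  length  strand  n_events  n_samples  child_seed
read_000000  contig_0  42556  3575    -       3570      32210      3444837047
read_000001  contig_0  22439  416     -       411       3756       3329053876
```

`read_000000` is a 3575-base fragment from the minus strand starting at
0-based offset 42556; its 3570 events (3575 − 6 + 1) dwelt for 32 210
samples, ≈ 9.0 samples/base. The alignment TSV for the read maps each event
(and hence each base) to its half-open sample interval, and the child seed
lets that single read be regenerated in isolation.

Re-running with the same `--seed` reproduces every output file byte for
byte, at any `--threads` value. An external basecaller can be hooked in with
`--basecaller-cmd 'guppy_basecaller -i {input_dir} -s {output_dir}'`; its
exit status is recorded and its output left untouched.

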