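# Methods

## Model overview

`squigsim` simulates a Nanopore sequencing run in three stages that mirror
the physical process: fragment sampling (which DNA segments enter pores),
signal generation (what current trace each segment produces), and an
optional external basecaller hook (what reads come back out). The signal
model is a *context-independent pore model*: the expected current while a
k-mer occupies the pore depends on that k-mer alone, via a complete 4^k
lookup table of (level mean, level stdv) in pA. This is a deliberate
trade-off — a context-dependent (recurrent) model can capture longer-range
sequence effects but costs orders of magnitude more compute; the table
model makes large-scale and metagenomic simulation cheap. The
`PoreModel` interface keeps the context-dependent variant pluggable.

A simulated read is produced as

```
region → sequence → k-mer events → expected levels → dwell expansion
       → low-pass filter → Gaussian noise → 16-bit DAC quantization
```

with ground truth (region coordinates, strand-resolved sequence, and the
half-open sample interval of every event) recorded alongside.

## Read sampling

Contigs are chosen with probability proportional to length, starts
uniformly over valid positions, strands uniformly. Circular topology allows
wraparound (extraction is equivalent to substring extraction on the doubled
sequence, and is tested against that oracle). Coordinates are 0-based,
half-open.

Length families (all rescalable to a target mean by multiplying draws by
`target_mean / family_mean`, which preserves shape):

| family | form | default parameters | emulates |
|---|---|---|---|
| `expansion_tail` | 0.7·Gamma(2, 2000) + 0.3·Gamma(3, 6000) | mean 8200 b, cv ≈ 1.1 | long-tailed modern runs (default) |
| `exponential` | Exp(scale) | scale 8000 b | memoryless fragmentation |
| `beta_like` | Beta(2, 5) · max | max 50 000 b | bounded-support profiles |
| `fixed` | point mass | — | controlled experiments |

Draws are rounded and truncated below at `length.min` (default 100 bases;
negligible bias at realistic means). Lengths that a placement cannot
accommodate are clipped (circular: at contig length; linear: at
`contig_length − start`) and counted in the log, avoiding the bias a
rejection scheme would introduce on short contigs. The exact parametric
forms fitted to real runs are not published for this chemistry generation;
these families reproduce the qualitative shapes and are collected in one
config block (`FAMILY_DEFAULTS`) so they can be refit.

**Coverage control.** `reads_for_coverage(G, C, L) = ceil(G·C/L)` gives the
expected read count, but for heavy-tailed families a fixed count leaves the
achieved coverage with relative error ~cv/√n (several percent at C = 20 on
100 kb). When coverage is the requested target the sampler therefore draws
reads until cumulative bases reach `G·C`: the overshoot is bounded by one
read length, so requested redundancy is met tightly for every family. The
acceptance run measures this at C = 20 on a 100 kb circular fixture with
the default family at mean 2000 bases — a mean chosen so that ~1000 reads
contribute to the estimate while staying in a realistic range.

Non-ACGT reference characters (N and other IUPAC codes) are replaced at
load time by uniform random bases under the run seed, with a logged count:
the pore table is defined only on A/C/G/T, and randomization keeps real
genomes usable without making the run irreproducible.

## Dwell model

Each event's dwell (samples during which its k-mer occupies the pore) is an
independent draw from a gamma distribution parameterized by mean and spread
(`shape = (mean/spread)²`, `scale = spread²/mean`), rounded to integers and
truncated at 1. Defaults: mean 9, spread 4 samples. At the default 4 kHz
sampling rate a mean of 9 samples/base corresponds to ≈ 450 bases/s, the
nominal translocation speed of the targeted chemistry. The gamma is a
stand-in for the empirical dwell pattern of real runs: right-skewed,
strictly positive, two interpretable parameters. Stalls, skips and
recaptures are not modeled.

## Low-pass filter

The ideal square wave has instantaneous level transitions whose
high-frequency content real pore/amplifier physics cannot produce; the
filter removes it. Design: `filter_order` (default 2) identical first-order
sections — the bilinear transform of the analog one-pole `ωc/(s+ωc)` —
each applied forward and backward (`filtfilt`, even-reflection padding).

Why real poles rather than a standard Butterworth biquad: a second-order
Butterworth has complex poles and overshoots on steps (~4%, doubled by
zero-phase application), which would place spurious current levels at every
event boundary that belong to no k-mer. The critically damped cascade has a
provably monotone step response (its impulse response is nonnegative), exact
unity DC gain, and an exact zero at Nyquist. Zero-phase application keeps
transitions centred on the ground-truth boundaries so the alignment stays
valid after filtering. The default normalized cutoff of 0.08 of the
sampling rate (320 Hz at 4 kHz) sits well above the per-base event rate
(~450 Hz / 9 ≈ 50 level changes per 1000 samples) while strongly attenuating
the transition edges; cutoff and order are fully exposed in config.
Even-reflection padding is used because odd reflection amplifies
high-frequency content at the edges (measured: a Nyquist tone retains ~99%
amplitude at the boundary under odd padding, 1% under even).

Numerical notes: constant signals are exact fixed points; signals too short
to pad (≤ 6 samples) pass through unchanged with a warning; filtering never
changes sample count. `cutoff_fraction = 0.5` with `filter_order = 0` is
the documented clean mode (exact bypass).

## Noise and quantization

After filtering, i.i.d. zero-mean Gaussian noise with `noise_sigma_pA`
(default 1.5 pA) is added per sample; it is deliberately not smoothed, since
measurement noise in real traces is broadband. An optional pre-expansion
stage (`level_jitter`, default off) perturbs each event's level once using
the table's per-k-mer stdv, modeling event-to-event level variability as
distinct from per-sample noise; by default the table means are emitted and
all stochasticity lives in the explicit noise stage, keeping clean mode
exactly invertible.

The pA trace is stored as 16-bit DAC integers,
`dac = round(pA · digitisation / range − offset)` with defaults
digitisation 8192, range 1467.61 pA, offset 0 — the conventional raw-FAST5
calibration, invertible to within half a DAC step (~0.09 pA). Out-of-range
values abort with the offending extreme rather than wrapping.

## Reproducibility and resource behavior

All randomness flows from one master seed. Region sampling uses a stream
seeded directly with it; each read then receives a child seed — the first
output word of `numpy.random.SeedSequence([master_seed, read_index])` — so
per-read streams are independent of scheduling. Outputs are byte-identical
across runs and across `--threads` values (HDF5 timestamp tracking is
disabled to make FAST5 files content-deterministic). Reads are processed in
batches of `4 × threads`; signals stream to disk per read, so peak memory
is proportional to the longest read's signal times the batch size, not the
total output (measured ≈ 230 MB peak for 1000 reads × 8000 bases ≈ 68 M
samples). Workers only compute; all HDF5 I/O happens on the main thread.

## Synthetic fixtures

Tests and the acceptance script run entirely on generated inputs: i.i.d.
random genomes with a chosen GC fraction, and complete pore tables with
means uniform in [60, 120] pA and stdvs in [1, 3] pA — matching the layout
and value ranges of released 6-mer tables but not any real pore's
chemistry. Consequently the tests demonstrate the *machinery* (exact
lookup, invertibility, distributional recovery, determinism, container
round-trips), not signal realism against real sequencing data: real genomes
have repeat structure and composition bias, and real pore tables have
strong k-mer correlations, none of which affect the code paths exercised.
k = 3 tables (64 rows) are used in unit tests for readable failures, k = 6
in integration tests.

## Known limitations

- No stall/adapter prefix, skips, recaptures, or event-rate drift.
- RNA and base-modification simulation are out of scope.
- Basecalling is an opaque external command hook; nothing is parsed back.
- Single-read FAST5 only (no multi-read FAST5, POD5 or SLOW5 containers).
- The length and dwell families are qualitative stand-ins exposed as
  config, not fits to a specific published run.
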