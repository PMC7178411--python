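"""From events to raw signal: dwells, square waves, filtering, noise, DAC.

The pipeline mirrors what a nanopore device does to the ideal level
sequence.  Each event (k-mer occupancy) persists for a random dwell of
samples; repeating each expected level for its dwell yields a square wave;
a zero-phase low-pass filter rounds off the physically implausible sharp
transitions; Gaussian noise models the thermal/electronic measurement
noise; finally the pA trace is digitized to the 16-bit DAC integers that
raw FAST5 files store.

Pipeline order is expand -> filter -> noise: the filter removes the
high-frequency content of the square wave, and the noise added afterwards
is deliberately *not* smoothed.  Together the filter cutoff and the noise
sigma control output signal quality.

Ground truth: because the filter is zero-phase and length-preserving, the
per-event signal intervals recorded before filtering remain valid, so every
sample can be attributed to the k-mer (and hence base) that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseFilterSpec:
    """Tunables of the signal pipeline.

    cutoff_fraction : normalized low-pass cutoff as a fraction of the
        sampling rate, in (0, 0.5].  0.5 disables filtering (Nyquist).
    filter_order : number of cascaded first-order sections; 0 disables
        filtering.
    noise_sigma_pA : standard deviation of the per-sample Gaussian noise.
    dwell_mean, dwell_spread : mean and spread (sd) in samples of the
        discretized-gamma dwell distribution; the default mean of 9 samples
        at 4 kHz corresponds to the nominal ~450 bases/s translocation speed.
    dwell_min : hard lower truncation of dwells (every event emits at least
        this many samples).
    level_jitter : when True, each event's level is perturbed once (before
        expansion) by a Gaussian with the pore table's per-k-mer stdv.
    """

    cutoff_fraction: float = 0.08
    filter_order: int = 2
    noise_sigma_pA: float = 1.5
    dwell_mean: float = 9.0
    dwell_spread: float = 4.0
    dwell_min: int = 1
    level_jitter: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff_fraction <= 0.5):
            raise ValueError(f"cutoff_fraction must lie in (0, 0.5], got {self.cutoff_fraction}")
        if self.filter_order < 0:
            raise ValueError("filter_order must be >= 0")
        if self.noise_sigma_pA < 0:
            raise ValueError("noise_sigma_pA must be >= 0")
        if self.dwell_mean <= 0 or self.dwell_spread < 0:
            raise ValueError("dwell_mean must be > 0 and dwell_spread >= 0")
        if self.dwell_min < 1:
            raise ValueError("dwell_min must be >= 1")

    @property
    def filter_enabled(self) -> bool:
        return self.filter_order > 0 and self.cutoff_fraction < 0.5

    @classmethod
    def clean(cls) -> "NoiseFilterSpec":
        """Noise off, filter bypassed: the pipeline is the identity on the
        square wave, so the simulator is exactly invertible to its truth."""
        return cls(cutoff_fraction=0.5, filter_order=0, noise_sigma_pA=0.0)


@dataclass(frozen=True)
class ChannelParams:
    """FAST5 channel calibration: pA = (dac + offset) * range_pA / digitisation."""

    digitisation: float = 8192.0
    range_pA: float = 1467.61
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.digitisation <= 0 or self.range_pA <= 0:
            raise ValueError("digitisation and range_pA must be positive")

    @property
    def pa_per_step(self) -> float:
        return self.range_pA / self.digitisation


@dataclass(frozen=True)
class RawSignal:
    """A current trace in pA at a stated sampling rate."""

    samples: np.ndarray
    sampling_rate: float = 4000.0

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "RawSignal":
        return RawSignal(samples=samples, sampling_rate=self.sampling_rate)


@dataclass(frozen=True)
class GroundTruthAlignment:
    """Half-open per-event signal intervals tiling [0, total_samples).

    ``base_offset`` is the 0-based read position where the event's k-mer
    starts (stride-1 windows, so it equals the event index).
    """

    event_index: np.ndarray
    base_offset: np.ndarray
    signal_start: np.ndarray
    signal_end: np.ndarray

    def __len__(self) -> int:
        return len(self.event_index)

    @property
    def total_samples(self) -> int:
        return int(self.signal_end[-1]) if len(self.signal_end) else 0


def sample_dwells(n_events: int, spec: NoiseFilterSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw per-event dwells (samples) from a discretized gamma.

    Shape/scale are derived from (dwell_mean, dwell_spread); draws are
    rounded and truncated below at dwell_min.  A zero spread degenerates to
    the constant round(dwell_mean).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if spec.dwell_spread == 0:
        return np.full(n_events, max(spec.dwell_min, int(round(spec.dwell_mean))),
                       dtype=np.int64)
    shape = (spec.dwell_mean / spec.dwell_spread) ** 2
    scale = spec.dwell_spread ** 2 / spec.dwell_mean
    draws = rng.gamma(shape, scale, size=n_events)
    return np.maximum(np.rint(draws).astype(np.int64), spec.dwell_min)


def expand_square_wave(track, sampling_rate: float = 4000.0) -> RawSignal:
    """Repeat event i's expected level dwell[i] times, concatenated in order."""
    if track.dwells is None:
        raise ValueError("track has no dwells; call sample_dwells first")
    if np.any(track.dwells < 1):
        raise ValueError("all dwells must be >= 1")
    samples = np.repeat(np.asarray(track.expected_levels, dtype=np.float64),
                        track.dwells)
    return RawSignal(samples=samples, sampling_rate=sampling_rate)


def _one_pole_coeffs(cutoff_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    # bilinear transform of the analog one-pole wc/(s+wc); unity DC gain,
    # zero at Nyquist, single real pole in (0,1)
    wc = np.tan(np.pi * cutoff_fraction)
    p = (1.0 - wc) / (1.0 + wc)
    g = (1.0 - p) / 2.0
    b = np.array([g, g])
    a = np.array([1.0, -p])
    return b, a


def low_pass(signal: RawSignal, spec: NoiseFilterSpec) -> RawSignal:
    """Zero-phase low-pass filtering of the square wave.

    The design is a cascade of ``filter_order`` identical first-order
    (real-pole) sections, each applied forward-and-backward (``filtfilt``).
    Real poles make the step response monotone — level transitions are
    smoothed without ringing, so no spurious intermediate levels appear —
    while the zero-phase application keeps transitions centred on the
    ground-truth event boundaries.  DC gain is exactly 1 (constant signals
    are fixed points) and the gain at Nyquist is exactly 0.

    Signals too short to pad for filtering pass through unchanged with a
    warning.  Length is always preserved.
    """
    if not (0.0 < spec.cutoff_fraction <= 0.5):
        raise ValueError(f"cutoff_fraction must lie in (0, 0.5], got {spec.cutoff_fraction}")
    if not spec.filter_enabled:
        return signal
    b, a = _one_pole_coeffs(spec.cutoff_fraction)
    padlen = 3 * max(len(a), len(b))
    if len(signal) <= max(padlen, 3 * spec.filter_order):
        logger.warning("signal of %d samples too short to filter; passing through",
                       len(signal))
        return signal
    x = np.asarray(signal.samples, dtype=np.float64)
    for _ in range(spec.filter_order):
        # even (reflection) padding keeps constants exact and avoids the
        # edge blow-up that odd extension produces on high-frequency content
        x = filtfilt(b, a, x, padlen=padlen, padtype="even")
    return signal.with_samples(x)


def add_noise(signal: RawSignal, sigma_pA: float, rng: np.random.Generator) -> RawSignal:
    """Independent zero-mean Gaussian perturbation per sample."""
    if sigma_pA < 0:
        raise ValueError("sigma_pA must be >= 0")
    if sigma_pA == 0:
        return signal
    noisy = signal.samples + rng.normal(0.0, sigma_pA, size=len(signal))
    return signal.with_samples(noisy)


def jitter_levels(track, stdvs: np.ndarray, rng: np.random.Generator):
    """Optionally perturb each event's level once with its table stdv.

    Models per-event level variability (as opposed to per-sample noise);
    applied before square-wave expansion so the whole dwell shares the
    jittered level.  Returns a new track.
    """
    from .pore_model import EventTrack
    jittered = track.expected_levels + rng.normal(0.0, stdvs)
    return EventTrack(kmers=track.kmers, expected_levels=jittered, dwells=track.dwells)


def digitize(signal: RawSignal, channel: ChannelParams) -> np.ndarray:
    """Quantize a pA trace to the 16-bit DAC integers stored in raw FAST5.

    dac = round(pA * digitisation / range_pA - offset).  Values outside the
    int16 range abort with the offending extreme, rather than silently
    wrapping.
    """
    dac = np.rint(np.asarray(signal.samples, dtype=np.float64)
                  * channel.digitisation / channel.range_pA - channel.offset)
    lo, hi = np.iinfo(np.int16).min, np.iinfo(np.int16).max
    if dac.min() < lo or dac.max() > hi:
        extreme = dac.min() if dac.min() < lo else dac.max()
        pa = (extreme + channel.offset) * channel.range_pA / channel.digitisation
        raise OverflowError(
            f"DAC value {extreme:.0f} (~{pa:.1f} pA) outside 16-bit range "
            f"[{lo}, {hi}]; adjust channel digitisation/range")
    return dac.astype(np.int16)


def dedigitize(dac: np.ndarray, channel: ChannelParams) -> np.ndarray:
    """Inverse of :func:`digitize` up to quantization (half a DAC step)."""
    return (dac.astype(np.float64) + channel.offset) * channel.range_pA / channel.digitisation


def build_alignment(track) -> GroundTruthAlignment:
    """Cumulative-sum tiling of dwells into half-open signal intervals."""
    if track.dwells is None:
        raise ValueError("track has no dwells; call sample_dwells first")
    ends = np.cumsum(track.dwells)
    starts = ends - track.dwells
    idx = np.arange(len(track.dwells), dtype=np.int64)
    return GroundTruthAlignment(event_index=idx, base_offset=idx.copy(),
                                signal_start=starts.astype(np.int64),
                                signal_end=ends.astype(np.int64))


def simulate_signal(track, spec: NoiseFilterSpec, rng: np.random.Generator,
                    sampling_rate: float = 4000.0,
                    level_stdvs: np.ndarray | None = None,
                    ) -> tuple[RawSignal, GroundTruthAlignment]:
    """Run the full pipeline on one event track.

    Fills dwells, optionally jitters levels, expands, filters, adds noise,
    and returns the pA signal plus its ground-truth alignment.
    """
    dwells = sample_dwells(len(track), spec, rng)
    track.dwells = dwells
    work = track
    if spec.level_jitter:
        if level_stdvs is None:
            raise ValueError("level_jitter requires per-event level_stdvs")
        work = jitter_levels(track, level_stdvs, rng)
    alignment = build_alignment(work)
    signal = expand_square_wave(work, sampling_rate=sampling_rate)
    signal = low_pass(signal, spec)
    signal = add_noise(signal, spec.noise_sigma_pA, rng)
    return signal, alignment
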