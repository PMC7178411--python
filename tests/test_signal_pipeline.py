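import numpy as np
import pytest

from squigsim.pore_model import EventTrack
from squigsim.signal_pipeline import (ChannelParams, NoiseFilterSpec, RawSignal,
                                      add_noise, build_alignment, dedigitize,
                                      digitize, expand_square_wave, low_pass,
                                      sample_dwells, simulate_signal)


def make_track(levels, dwells=None):
    levels = np.asarray(levels, dtype=float)
    return EventTrack(kmers=["NNN"] * len(levels), expected_levels=levels,
                      dwells=None if dwells is None else np.asarray(dwells))


def random_track(rng, n_events=50):
    levels = rng.uniform(60, 120, size=n_events)
    dwells = rng.integers(1, 15, size=n_events)
    return make_track(levels, dwells)


class TestSampleDwells:
    def test_degenerate_zero_spread(self, rng):
        spec = NoiseFilterSpec(dwell_mean=1, dwell_spread=0)
        assert sample_dwells(5, spec, rng).tolist() == [1, 1, 1, 1, 1]

    def test_long_run_mean(self, rng):
        spec = NoiseFilterSpec(dwell_mean=9, dwell_spread=4)
        dwells = sample_dwells(10_000, spec, rng)
        assert abs(dwells.mean() / 9 - 1) < 0.05

    def test_minimum_respected_even_for_short_mean(self, rng):
        spec = NoiseFilterSpec(dwell_mean=1.2, dwell_spread=3)
        assert (sample_dwells(5000, spec, rng) >= 1).all()

    def test_invalid_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_dwells(0, NoiseFilterSpec(), rng)


class TestExpandSquareWave:
    def test_hand_expansion(self):
        sig = expand_square_wave(make_track([1.0, 2.0], [3, 2]))
        assert sig.samples.tolist() == [1, 1, 1, 2, 2]

    def test_single_event_identity(self):
        sig = expand_square_wave(make_track([80.0], [1]))
        assert len(sig) == 1 and sig.samples[0] == 80.0

    def test_unset_dwells_rejected(self):
        with pytest.raises(ValueError, match="dwells"):
            expand_square_wave(make_track([1.0]))

    def test_segment_means_equal_levels_exactly(self, rng):
        track = random_track(rng)
        sig = expand_square_wave(track)
        aln = build_alignment(track)
        for i in range(len(track)):
            seg = sig.samples[aln.signal_start[i]:aln.signal_end[i]]
            assert (seg == track.expected_levels[i]).all()


class TestLowPass:
    def test_dc_gain_unity(self):
        out = low_pass(RawSignal(np.full(2000, 80.0)), NoiseFilterSpec())
        assert np.abs(out.samples / 80.0 - 1).max() < 1e-6
        assert len(out) == 2000

    def test_nyquist_tone_attenuated(self):
        tone = np.where(np.arange(2000) % 2 == 0, 1.0, -1.0)
        out = low_pass(RawSignal(tone), NoiseFilterSpec())
        assert np.abs(out.samples).max() <= 0.1

    def test_step_response_monotone(self):
        step = np.concatenate([np.zeros(300), np.ones(300)])
        out = low_pass(RawSignal(step), NoiseFilterSpec())
        assert (np.diff(out.samples) >= -1e-12).all()

    def test_clean_mode_is_bypass(self):
        sig = RawSignal(np.array([1.0, 5.0, 2.0, 8.0] * 10))
        out = low_pass(sig, NoiseFilterSpec.clean())
        assert out.samples is sig.samples

    def test_short_signal_passes_through(self):
        sig = RawSignal(np.array([1.0, 2.0, 3.0]))
        out = low_pass(sig, NoiseFilterSpec())
        assert np.array_equal(out.samples, sig.samples)

    @pytest.mark.parametrize("cutoff", [0.0, -0.1, 0.6])
    def test_invalid_cutoff_rejected(self, cutoff):
        with pytest.raises(ValueError):
            NoiseFilterSpec(cutoff_fraction=cutoff)


class TestAddNoise:
    def test_sigma_zero_identity(self, rng):
        sig = RawSignal(np.arange(100, dtype=float))
        assert add_noise(sig, 0.0, rng).samples is sig.samples

    def test_empirical_sigma_and_mean(self, rng):
        sig = RawSignal(np.full(1_000_000, 80.0))
        out = add_noise(sig, 1.5, rng)
        resid = out.samples - 80.0
        assert abs(resid.std() / 1.5 - 1) < 0.01
        assert abs(resid.mean()) < 3 * 1.5 / 1000  # 3 standard errors of 0

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            add_noise(RawSignal(np.zeros(10)), -1.0, rng)


class TestDigitize:
    def test_zero_maps_to_zero(self):
        dac = digitize(RawSignal(np.zeros(4)), ChannelParams())
        assert (dac == 0).all() and dac.dtype == np.int16

    def test_round_trip_within_half_step(self, rng):
        ch = ChannelParams()
        pa = rng.uniform(0, 200, size=5000)
        back = dedigitize(digitize(RawSignal(pa), ch), ch)
        assert np.abs(pa - back).max() <= ch.pa_per_step / 2 + 1e-12

    def test_overflow_rejected(self):
        with pytest.raises(OverflowError, match="DAC"):
            digitize(RawSignal(np.array([1e6])), ChannelParams())


class TestBuildAlignment:
    def test_cumulative_sum_by_hand(self):
        aln = build_alignment(make_track([1.0, 2.0], [3, 2]))
        assert aln.signal_start.tolist() == [0, 3]
        assert aln.signal_end.tolist() == [3, 5]
        assert aln.total_samples == 5

    def test_tiling_no_gaps_no_overlaps_random_tracks(self, rng):
        for _ in range(100):
            track = random_track(rng, n_events=int(rng.integers(1, 80)))
            aln = build_alignment(track)
            assert aln.signal_start[0] == 0
            assert (aln.signal_start[1:] == aln.signal_end[:-1]).all()
            assert (aln.signal_end - aln.signal_start == track.dwells).all()
            assert aln.total_samples == track.dwells.sum()
            assert (aln.base_offset == aln.event_index).all()


class TestFullSignalSimulation:
    def test_clean_mode_invertible_to_truth(self, k3_model, rng):
        """Noise off + filter bypassed: segment values equal table means."""
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=200))
        track = k3_model.expected_levels(seq)
        sig, aln = simulate_signal(track, NoiseFilterSpec.clean(), rng)
        for i in range(len(track)):
            seg = sig.samples[aln.signal_start[i]:aln.signal_end[i]]
            assert (seg == track.expected_levels[i]).all()

    def test_length_conservation_through_pipeline(self, k3_model, rng):
        seq = "".join(np.random.default_rng(4).choice(list("ACGT"), size=300))
        track = k3_model.expected_levels(seq)
        sig, aln = simulate_signal(track, NoiseFilterSpec(), rng)
        assert len(sig) == aln.total_samples == track.dwells.sum()

    def test_level_jitter_requires_stdvs(self, k3_model, rng):
        track = k3_model.expected_levels("ACGTACGT")
        spec = NoiseFilterSpec(level_jitter=True)
        with pytest.raises(ValueError, match="stdvs"):
            simulate_signal(track, spec, rng)

    def test_quality_degrades_with_noise_sigma(self, k3_model):
        """Mean absolute per-event error is nondecreasing in noise sigma."""
        errors = []
        for sigma in (0.0, 1.5, 5.0):
            rng_seq = np.random.default_rng(21)
            total_err = []
            for r in range(20):
                seq = "".join(rng_seq.choice(list("ACGT"), size=150))
                track = k3_model.expected_levels(seq)
                sig, aln = simulate_signal(
                    track, NoiseFilterSpec(noise_sigma_pA=sigma),
                    np.random.default_rng(1000 + r))
                seg_means = np.array([
                    sig.samples[aln.signal_start[i]:aln.signal_end[i]].mean()
                    for i in range(len(track))])
                total_err.append(np.abs(seg_means - track.expected_levels).mean())
            errors.append(np.mean(total_err))
        assert errors[0] <= errors[1] <= errors[2]
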