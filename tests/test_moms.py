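import numpy as np
import pytest

import momentropy as mt
from momentropy.moms import DEFAULT_BANDS, DetectionError

ALPHA = DEFAULT_BANDS[2]
DELTA = DEFAULT_BANDS[0]
BETA = DEFAULT_BANDS[3]


def band(name):
    return {b.name: b for b in DEFAULT_BANDS}[name]


class TestBandpass:
    def test_passband_identity(self, make_tone):
        sig = make_tone(10.0)
        out = mt.bandpass_fft(sig, ALPHA)
        inner = slice(500, -500)
        c = np.corrcoef(out.values[0, inner], sig.values[0, inner])[0, 1]
        assert c > 0.99

    def test_stopband_rejection(self, make_tone):
        sig = make_tone(10.0)
        out = mt.bandpass_fft(sig, BETA)
        assert np.sqrt((out.values**2).mean()) < 0.01 * np.sqrt(
            (sig.values**2).mean()
        )

    def test_mixture_recovers_component(self, make_tone):
        slow = make_tone(2.0)
        fast = make_tone(10.0)
        mixed = mt.SignalSet(
            values=slow.values + fast.values, sampling_rate=slow.sampling_rate
        )
        out = mt.bandpass_fft(mixed, DELTA)
        inner = slice(500, -500)
        c = np.corrcoef(out.values[0, inner], slow.values[0, inner])[0, 1]
        assert c > 0.99

    def test_dc_removed(self, make_tone):
        sig = make_tone(2.0)
        sig.values += 5.0
        out = mt.bandpass_fft(sig, DELTA)
        assert abs(out.values.mean()) < 1e-9

    def test_band_above_nyquist_rejected(self, make_tone):
        sig = make_tone(10.0, fs=50.0)
        with pytest.raises(DetectionError, match="Nyquist"):
            mt.bandpass_fft(sig, BETA)  # 30 Hz > 25 Hz


class TestHilbertEnvelope:
    def test_constant_tone_amplitude(self, make_tone):
        sig = make_tone(10.0, amplitude=2.0)
        env = mt.hilbert_envelope(sig)
        inner = env[0, 500:-500]
        assert np.allclose(inner, 2.0, rtol=0.01)

    def test_zero_signal(self):
        env = mt.hilbert_envelope(np.zeros((3, 1000)))
        assert np.all(env == 0)

    def test_tracks_amplitude_ramp(self):
        fs, T = 500.0, 5000
        t = np.arange(T) / fs
        ramp = 1.0 + t  # amplitude 1 -> 11 over 10 s
        x = (ramp * np.sin(2 * np.pi * 10 * t))[None, :]
        env = mt.hilbert_envelope(x)
        inner = slice(1000, -1000)  # the ramp's broadband trend leaks near edges
        assert np.allclose(env[0, inner], ramp[inner], rtol=0.02)

    def test_non_finite_rejected(self):
        bad = np.zeros((2, 100))
        bad[0, 50] = np.nan
        with pytest.raises(DetectionError):
            mt.hilbert_envelope(bad)


@pytest.fixture(scope="module")
def params():
    return mt.SimulationParams(K=5.0, mean_delay=0.003, duration=4.0, seed=11)


class TestBaseline:
    def test_threshold_is_mean_plus_nstd_sd(self, params, small_connectome):
        base = mt.compute_baseline(params, small_connectome, DEFAULT_BANDS, 5.0)
        assert np.allclose(base.thresholds, base.mean_amp + 5.0 * base.std_amp)
        assert np.all(base.std_amp > 0)

    def test_sd_only_variant(self, params, small_connectome):
        base = mt.compute_baseline(
            params, small_connectome, DEFAULT_BANDS, 5.0, threshold_formula="sd_only"
        )
        assert np.allclose(base.thresholds, 5.0 * base.std_amp)

    def test_baseline_ignores_main_run_delay(self, params, small_connectome):
        # identical baseline whatever the main run's mean delay
        from dataclasses import replace

        base1 = mt.compute_baseline(params, small_connectome)
        base2 = mt.compute_baseline(
            replace(params, mean_delay=0.01), small_connectome
        )
        assert np.array_equal(base1.thresholds, base2.thresholds)

    def test_seed_stability_of_thresholds(self):
        # two independent noise realizations give similar 40 s baselines
        conn = mt.generate_synthetic_connectome(30, 0.3, seed=1)
        params = mt.SimulationParams(K=10.0, duration=40.0, seed=1)
        a = mt.compute_baseline(params, conn, baseline_seed=1)
        b = mt.compute_baseline(params, conn, baseline_seed=2)
        assert not np.array_equal(a.thresholds, b.thresholds)
        rel = np.abs(a.thresholds - b.thresholds) / a.thresholds
        assert np.median(rel) < 0.10
        assert rel.max() < 0.30


def stats_for_threshold(thr, n_bands=1, n_nodes=6):
    """BaselineStats whose thresholds are all ``thr``."""
    mean = np.full((n_bands, n_nodes), thr - 0.5)
    std = np.full((n_bands, n_nodes), 0.1)
    return mt.BaselineStats(
        bands=DEFAULT_BANDS[:n_bands], mean_amp=mean, std_amp=std, n_std=5.0
    )


class TestCoalitionCounts:
    def test_direct_count(self):
        base = stats_for_threshold(1.0)
        env = np.array([[1.2], [1.3], [0.5], [0.9], [1.1], [1.4]]).reshape(1, 6, 1)
        series = mt.coalition_counts(env, base, 500.0)
        assert series.counts[0, 0] == 4
        assert series.total[0] == 4

    def test_all_below(self):
        base = stats_for_threshold(1.0)
        env = np.zeros((1, 6, 10))
        series = mt.coalition_counts(env, base, 500.0)
        assert np.all(series.counts == 0)

    def test_upper_bound_everyone_active(self):
        base = stats_for_threshold(1.0, n_nodes=90)
        env = np.full((1, 90, 5), 2.0)
        series = mt.coalition_counts(env, base, 500.0)
        assert np.all(series.counts == 90)

    def test_total_is_band_sum(self):
        rng = np.random.default_rng(0)
        base = stats_for_threshold(1.0, n_bands=4)
        env = rng.uniform(0, 2, size=(4, 6, 200))
        series = mt.coalition_counts(env, base, 500.0)
        assert np.array_equal(series.total, series.counts.sum(axis=0))

    def test_shape_mismatch_rejected(self):
        base = stats_for_threshold(1.0)
        with pytest.raises(DetectionError, match="shape"):
            mt.coalition_counts(np.zeros((2, 6, 10)), base, 500.0)

    def test_raising_nstd_never_raises_counts(self):
        rng = np.random.default_rng(1)
        env = rng.uniform(0, 2, size=(1, 6, 500))
        lo = stats_for_threshold(1.0)
        hi = mt.BaselineStats(
            bands=DEFAULT_BANDS[:1],
            mean_amp=lo.mean_amp,
            std_amp=lo.std_amp,
            n_std=8.0,
        )
        counts_lo = mt.coalition_counts(env, lo, 500.0).counts
        counts_hi = mt.coalition_counts(env, hi, 500.0).counts
        assert np.all(counts_hi <= counts_lo)


def series_from_counts(counts, fs=500.0):
    counts = np.asarray(counts, dtype=np.int64)[None, :]
    n_nodes = max(int(counts.max()), 1)
    above = np.zeros((1, n_nodes, counts.shape[1]), dtype=bool)
    for t in range(counts.shape[1]):
        above[0, : counts[0, t], t] = True
    return mt.CoalitionSeries(
        bands=DEFAULT_BANDS[:1],
        counts=counts,
        total=counts.sum(axis=0),
        above=above,
        sampling_rate=fs,
    )


class TestEventDetection:
    def test_single_run_duration_and_peak(self):
        series = series_from_counts([0, 0, 6, 7, 6, 0])
        events = mt.detect_mom_events(series, 5)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == pytest.approx(3 / 500.0)  # 6 ms
        assert ev.peak_size == 7
        assert ev.start == pytest.approx(2 / 500.0)
        assert len(ev.node_set) == 7

    def test_subthreshold_peak_yields_no_event(self):
        series = series_from_counts([0, 4, 4, 4, 0])
        assert mt.detect_mom_events(series, 5) == []

    def test_min_one_counts_boundary_runs(self):
        series = series_from_counts([1, 0, 1])
        events = mt.detect_mom_events(series, 1)
        assert len(events) == 2
        assert all(ev.duration == pytest.approx(1 / 500.0) for ev in events)

    def test_peak_tie_takes_earliest(self):
        series = series_from_counts([0, 6, 6, 6, 0])
        ev = mt.detect_mom_events(series, 5)[0]
        assert ev.start == pytest.approx(1 / 500.0)
        assert ev.peak_size == 6

    def test_raising_min_coalition_shrinks_event_coverage(self):
        # a higher minimum can split one run into several events, but the
        # total time covered by events can only shrink, and every stricter
        # event must lie inside some laxer one
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=120)
        series = series_from_counts(counts)
        lo = mt.detect_mom_events(series, 3)
        hi = mt.detect_mom_events(series, 6)
        assert sum(e.duration for e in hi) <= sum(e.duration for e in lo)
        for ev in hi:
            assert any(
                o.start <= ev.start
                and ev.start + ev.duration <= o.start + o.duration + 1e-12
                for o in lo
            )

    def test_invalid_min_coalition(self):
        series = series_from_counts([0, 1])
        with pytest.raises(DetectionError):
            mt.detect_mom_events(series, 0)
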