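"""MEA chain: filtering, noise, spikes, surprise, bursts, network bursts."""

import math

import numpy as np
import pytest

from pannpc import synth
from pannpc.mea import (
    RawRecording,
    SpikeTrain,
    bandpass,
    detect_bursts,
    detect_network_bursts,
    detect_spikes,
    firing_timecourse,
    is_active,
    noise_sd,
    poisson_surprise,
    read_recording_h5,
    write_recording_h5,
)
from pannpc.presets import get_preset

FS = 12500.0


def sinusoid(freq, duration=2.0, fs=FS, amp=10.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_below_band_attenuated(self):
        rec = RawRecording(sinusoid(1.0), FS)
        out = bandpass(rec)
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        assert np.abs(out.voltage[0, mid]).max() < 0.1 * 10.0

    def test_in_band_preserved(self):
        rec = RawRecording(sinusoid(100.0), FS)
        out = bandpass(rec)
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        assert np.abs(out.voltage[0, mid]).max() == pytest.approx(10.0, rel=0.05)

    def test_white_noise_band_fraction(self, rng):
        x = rng.normal(0, 1, int(8 * FS))
        out = bandpass(RawRecording(x, FS))
        # spectral-integral oracle: white noise through the zero-phase
        # filter has variance equal to the mean squared power response
        # (|H|^4: forward-backward filtering squares the magnitude)
        from scipy import signal

        sos = signal.butter(3, [10.0, 2500.0], btype="bandpass", fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=65536, fs=FS)
        frac = float(np.mean(np.abs(h) ** 4))
        assert out.voltage[0].var() == pytest.approx(frac, rel=0.10)
        # and the passband covers most of the ideal 10-2500 Hz rectangle
        assert 0.7 * (2490.0 / (FS / 2)) < frac < 2490.0 / (FS / 2)

    def test_insufficient_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass(RawRecording(np.zeros(100), 4000.0))


class TestNoiseSd:
    def test_consistent_on_gaussian(self, rng):
        x = rng.normal(0, 3.0, 200000)
        assert noise_sd(x) == pytest.approx(3.0, rel=0.05)

    def test_robust_to_spike_contamination(self, rng):
        x = rng.normal(0, 3.0, 100000)
        idx = rng.choice(len(x), 1000, replace=False)
        x[idx] = 30.0
        assert noise_sd(x) == pytest.approx(3.0, rel=0.10)
        assert x.std() > 1.15 * 3.0  # naive SD is inflated

    def test_zero_trace(self):
        assert noise_sd(np.zeros(1000)) == 0.0


class TestDetectSpikes:
    def test_recall_and_timing_at_8_sigma(self, rng):
        rec, truth = synth.gen_mea_recording(
            rate=5.0, duration=60.0, n_electrodes=1, noise_sd=3.0,
            spike_amplitude=24.0, seed=11,
        )
        filt = bandpass(rec)
        train = detect_spikes(filt.voltage[0], FS)
        gt = truth.trains[0].spike_times
        det = train.spike_times
        matched = sum(np.min(np.abs(det - t)) <= 1e-3 for t in gt)
        assert matched / len(gt) >= 0.95
        assert sum(np.min(np.abs(gt - t)) <= 1e-3 for t in det) / len(det) >= 0.95

    def test_threshold_rule_boundary(self, rng):
        # one deflection just below and one just above 5.5 sigma
        noise = rng.normal(0, 1.0, int(10 * FS))
        sd = noise_sd(noise)
        for mult, expected in ((5.4, 0), (5.6, 1)):
            x = noise.copy()
            x[int(5 * FS)] = math.copysign(mult * sd, -1)
            train = detect_spikes(x, FS, k=5.5)
            near = np.abs(train.spike_times - 5.0) < 2e-3
            assert near.sum() == expected

    def test_false_positive_rate_on_pure_noise(self, rng):
        x = rng.normal(0, 1.0, int(60 * FS))
        train = detect_spikes(x, FS, k=5.5)
        from scipy.stats import norm

        expected = 2 * norm.sf(5.5) * len(x)
        assert len(train.spike_times) <= max(2.0, 2 * expected)

    def test_dead_time_merges_doublets(self):
        x = np.zeros(int(1 * FS))
        x[1000] = -50.0
        x[1003] = -40.0  # within 1 ms of the first
        train = detect_spikes(x + 0.5, FS)  # offset avoids zero noise SD
        assert len(train.spike_times) <= 1 or (
            np.diff(train.spike_times).min() >= 1e-3
        )


class TestActiveCriterion:
    @pytest.mark.parametrize(
        "n,duration,expected",
        [(5, 60.0, True), (4, 60.0, False), (9, 120.0, False), (10, 120.0, True)],
    )
    def test_rate_threshold(self, n, duration, expected):
        times = np.linspace(1.0, duration - 1.0, n)
        assert is_active(SpikeTrain("E1", times, duration)) is expected


def surprise_series_oracle(n, rt):
    """Direct tail sum of the Poisson pmf in log space."""
    total = 0.0
    for k in range(n, n + 600):
        total += math.exp(k * math.log(rt) - rt - math.lgamma(k + 1))
    return -math.log(total)


class TestPoissonSurprise:
    def test_zero_spikes(self):
        assert poisson_surprise(0, 1.0, 2.0) == 0.0

    def test_against_series_oracle_grid(self):
        for n in range(1, 21):
            for rt in (0.1, 0.5, 1.0, 2.0, 5.0):
                s = poisson_surprise(n, 1.0, rt)
                oracle = surprise_series_oracle(n, rt)
                assert s == pytest.approx(oracle, rel=1e-6)

    def test_monotone_in_count(self):
        vals = [poisson_surprise(n, 1.0, 0.5) for n in range(1, 15)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_surprise(3, 1.0, 0.0)


def burst_oracle(train, s_min=10.0, min_spikes=5):
    """Exhaustive max-surprise window over all O(n^2) spike windows."""
    t = train.spike_times
    n = len(t)
    if n < min_spikes:
        return None
    rate = n / train.duration
    best = None
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            s = surprise_series_oracle(j - i + 1, rate * (t[j] - t[i]))
            if best is None or s > best[0]:
                best = (s, i, j)
    if best is None or best[0] < s_min:
        return None
    return best


class TestDetectBursts:
    def test_planted_burst_recovered(self, rng):
        bg = np.sort(rng.uniform(0, 60, 30))
        planted = 30.0 + np.arange(10) * 0.005
        times = np.unique(np.concatenate([bg, planted]))
        train = SpikeTrain("E1", times, 60.0)
        bursts = detect_bursts(train)
        assert len(bursts) >= 1
        top = max(bursts, key=lambda b: b.surprise)
        assert top.start <= planted[0] + 1e-9 and top.end >= planted[-1] - 1e-9
        assert top.surprise >= 10.0

    def test_homogeneous_poisson_rarely_bursts(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            times = np.unique(np.sort(rng.uniform(0, 60, rng.poisson(60))))
            if len(times) < 5:
                continue
            if detect_bursts(SpikeTrain("E1", times, 60.0)):
                hits += 1
        assert hits <= 2  # >= 95% of null recordings yield no burst

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle_small_trains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        if rng.random() < 0.5:
            times = np.sort(rng.uniform(0, 30, n))
        else:  # half the cases contain a dense cluster
            cluster = rng.uniform(5, 20) + np.sort(rng.uniform(0, 0.2, n // 2))
            rest = rng.uniform(0, 30, n - n // 2)
            times = np.sort(np.concatenate([cluster, rest]))
        times = np.unique(times)
        train = SpikeTrain("E1", times, 30.0)
        got = detect_bursts(train)
        oracle = burst_oracle(train)
        if oracle is None:
            assert got == []
        else:
            s, i, j = oracle
            top = max(got, key=lambda b: b.surprise)
            assert top.start == pytest.approx(times[i])
            assert top.end == pytest.approx(times[j])
            assert top.surprise == pytest.approx(s, rel=1e-6)

    def test_bursts_disjoint_and_within_range(self, rng):
        times = np.unique(
            np.sort(
                np.concatenate(
                    [rng.uniform(0, 120, 100), 50 + np.arange(20) * 0.004, 80 + np.arange(15) * 0.003]
                )
            )
        )
        train = SpikeTrain("E1", times, 120.0)
        bursts = detect_bursts(train)
        assert len(bursts) >= 2
        for b in bursts:
            assert 0 <= b.start < b.end <= 120.0
        for a, b in zip(bursts, bursts[1:]):
            assert a.end < b.start


class TestNetworkBursts:
    def _two_electrode_run(self, n, isi, t0=10.0, duration=600.0):
        times = t0 + np.arange(n) * isi
        return [
            SpikeTrain("E1", times[::2], duration),
            SpikeTrain("E2", times[1::2], duration),
        ]

    def test_twelve_spikes_at_90ms(self):
        trains = self._two_electrode_run(12, 0.09)
        nbs = detect_network_bursts(trains, require_active=False)
        assert len(nbs) == 1
        assert nbs[0].n_spikes == 12
        assert set(nbs[0].electrodes) == {"E1", "E2"}

    def test_one_long_gap_breaks_run(self):
        times = np.concatenate([np.arange(5) * 0.05, 0.301 + np.arange(5) * 0.05])
        # gap of 101 ms between spike 5 and 6
        trains = [
            SpikeTrain("E1", 10 + times[::2], 600.0),
            SpikeTrain("E2", 10 + times[1::2], 600.0),
        ]
        assert detect_network_bursts(trains, require_active=False) == []

    def test_nine_spikes_insufficient(self):
        trains = self._two_electrode_run(9, 0.05)
        assert detect_network_bursts(trains, require_active=False) == []

    def test_pooled_isi_condition_verifiable_post_hoc(self, rng):
        trains = [
            SpikeTrain("E1", np.sort(rng.uniform(0, 600, 600)), 600.0),
            SpikeTrain("E2", np.sort(rng.uniform(0, 600, 600)), 600.0),
        ]
        nbs = detect_network_bursts(trains)
        pooled = np.sort(np.concatenate([t.spike_times for t in trains]))
        for nb in nbs:
            inside = pooled[(pooled >= nb.start) & (pooled <= nb.end)]
            assert len(inside) == nb.n_spikes >= 10
            assert np.diff(inside).max() <= 0.100 + 1e-12


class TestTimecourse:
    def test_single_week_normalizes_to_one(self):
        trains = synth.gen_spike_trains(get_preset("human"), week=6, seed=0)
        df = firing_timecourse(
            [{"line": "h1", "species": "human", "week": 6, "trains": trains}]
        )
        assert df["rate_normalized"].iloc[0] == pytest.approx(1.0)

    def test_zero_active_electrodes_flagged(self):
        trains = [SpikeTrain("E1", np.array([1.0]), 600.0)]
        df = firing_timecourse(
            [{"line": "h1", "species": "human", "week": 1, "trains": trains}]
        )
        assert df["rate_hz"].iloc[0] == 0.0
        assert df["flag"].iloc[0] == "no_active_electrodes"

    def test_species_curves_cross_between_weeks_4_and_5(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            for sp in ("human", "chimpanzee"):
                preset = get_preset(sp)
                for line in range(2):
                    for wk in (1, 2, 3, 4, 5, 6):
                        rows.append(
                            {
                                "line": f"{sp}{line}",
                                "species": sp,
                                "week": wk,
                                "trains": synth.gen_spike_trains(
                                    preset, wk, n_electrodes=16, duration=600.0,
                                    seed=rng.integers(2**31),
                                ),
                            }
                        )
            df = firing_timecourse(rows)
            mean = df.groupby(["species", "week"])["rate_normalized"].mean()
            chimp_ahead_4 = mean["chimpanzee", 4] > mean["human", 4]
            human_ahead_5 = mean["human", 5] > mean["chimpanzee", 5]
            early = mean["chimpanzee", 2] > mean["human", 2]
            if chimp_ahead_4 and human_ahead_5 and early:
                ok += 1
        assert ok >= 18  # >= 90% of seeds


class TestRecordingIO:
    def test_h5_round_trip(self, tmp_path, rng):
        rec = RawRecording(rng.normal(0, 3, (4, 2000)), FS, well="B2")
        p = tmp_path / "rec.h5"
        write_recording_h5(rec, p)
        back = read_recording_h5(p)
        np.testing.assert_allclose(back.voltage, rec.voltage)
        assert back.sampling_rate == FS
        assert back.electrodes == rec.electrodes
        assert back.well == "B2"
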