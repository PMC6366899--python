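"""Synthetic MEA recordings with known spikes, bursts and network bursts.

Voltage traces are Gaussian noise plus stereotyped biphasic spike
waveforms (a derivative-of-Gaussian transient about 1 ms wide) at times
drawn from a Poisson process whose rate follows the preset's firing
trajectory for the requested differentiation week.  Bursts and
well-wide network bursts can be planted explicitly, and every planted
event is returned as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..mea import RawRecording, SpikeTrain
from ..presets import SpeciesPreset

__all__ = ["MeaTruth", "gen_spike_times", "gen_spike_trains", "gen_mea_recording"]

_MIN_SEPARATION = 3e-3  # s; keeps planted spikes resolvable by a 1 ms dead time


@dataclass
class MeaTruth:
    """Ground truth for one generated recording."""

    trains: list[SpikeTrain]
    bursts: list[tuple[str, float, float, int]] = field(default_factory=list)
    network_bursts: list[tuple[float, float, int]] = field(default_factory=list)


def _thin(times: np.ndarray, min_sep: float = _MIN_SEPARATION) -> np.ndarray:
    """Enforce a minimum separation, keeping the earlier spike of a clash."""
    if len(times) == 0:
        return times
    out = [times[0]]
    for t in times[1:]:
        if t - out[-1] >= min_sep:
            out.append(t)
    return np.asarray(out)


def gen_spike_times(
    rate: float, duration: float, rng: np.random.Generator, min_sep: float = _MIN_SEPARATION
) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration), thinned to *min_sep*."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    n = rng.poisson(rate * duration)
    return _thin(np.sort(rng.uniform(0.0, duration, n)), min_sep)


def gen_spike_trains(
    preset: SpeciesPreset,
    week: float,
    n_electrodes: int = 16,
    duration: float = 600.0,
    seed: int | np.random.Generator = 0,
    rate: float | None = None,
) -> list[SpikeTrain]:
    """Poisson spike trains at the preset's firing rate for *week*.

    Lightweight path for timecourse studies where the voltage traces
    themselves are not needed (default duration 600 s, the 10-min
    recording window).
    """
    rng = np.random.default_rng(seed)
    r = preset.firing_rate(week) if rate is None else rate
    return [
        SpikeTrain(f"E{i+1}", gen_spike_times(r, duration, rng), duration)
        for i in range(n_electrodes)
    ]


def _spike_waveform(sampling_rate: float, amplitude: float, width_s: float = 4e-4):
    """Biphasic transient (negative-leading derivative of Gaussian)."""
    half = int(round(3 * width_s * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    w = -t * np.exp(-(t**2) / (2 * width_s**2))
    w = w / np.abs(w).max() * amplitude
    return w, half


def gen_mea_recording(
    preset: SpeciesPreset | None = None,
    week: float = 2.0,
    n_electrodes: int = 8,
    duration: float = 60.0,
    sampling_rate: float = 12500.0,
    noise_sd: float = 3.0,
    spike_amplitude: float = 24.0,
    burst_structure: dict | None = None,
    rate: float | None = None,
    seed: int | np.random.Generator = 0,
    well: str = "A1",
) -> tuple[RawRecording, MeaTruth]:
    """Generate one well's voltage traces plus ground-truth events.

    *burst_structure* may contain:

    ``bursts``
        list of ``(electrode_index, t0, n_spikes, isi)`` dense spike
        clusters planted on one electrode;
    ``network_bursts``
        list of ``(t0, n_spikes, isi)`` pooled runs distributed
        round-robin over all electrodes.

    Background spikes come from a Poisson process at the preset's rate
    for *week* (or explicit *rate*).  Returns the raw (unfiltered)
    recording and the ground truth.
    """
    if spike_amplitude <= 0:
        raise ValueError("spike_amplitude must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if rate is None:
        rate = preset.firing_rate(week) if preset is not None else 0.0
    if rate < 0:
        raise ValueError("firing rate must be >= 0")
    burst_structure = burst_structure or {}

    spike_lists: list[np.ndarray] = [
        gen_spike_times(rate, duration, rng) for _ in range(n_electrodes)
    ]
    truth_bursts: list[tuple[str, float, float, int]] = []
    for elec_idx, t0, n_spk, isi in burst_structure.get("bursts", []):
        planted = t0 + np.arange(n_spk) * isi
        spike_lists[elec_idx] = _thin(
            np.sort(np.concatenate([spike_lists[elec_idx], planted]))
        )
        truth_bursts.append((f"E{elec_idx+1}", float(planted[0]), float(planted[-1]), n_spk))
    truth_nb: list[tuple[float, float, int]] = []
    for t0, n_spk, isi in burst_structure.get("network_bursts", []):
        planted = t0 + np.arange(n_spk) * isi
        for j, t in enumerate(planted):
            e = j % n_electrodes
            spike_lists[e] = _thin(np.sort(np.concatenate([spike_lists[e], [t]])))
        truth_nb.append((float(planted[0]), float(planted[-1]), n_spk))

    n_samples = int(round(duration * sampling_rate))
    voltage = rng.normal(0.0, noise_sd, (n_electrodes, n_samples))
    wave, half = _spike_waveform(sampling_rate, spike_amplitude)
    trains = []
    for e, times in enumerate(spike_lists):
        times = times[(times > half / sampling_rate) & (times < duration - half / sampling_rate)]
        for t in times:
            c = int(round(t * sampling_rate))
            voltage[e, c - half : c + half + 1] += wave
        trains.append(SpikeTrain(f"E{e+1}", times, duration))

    rec = RawRecording(voltage, sampling_rate, [f"E{i+1}" for i in range(n_electrodes)], well)
    return rec, MeaTruth(trains=trains, bursts=truth_bursts, network_bursts=truth_nb)
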