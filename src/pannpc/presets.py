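"""Species presets parameterizing the synthetic-data generators.

A :class:`SpeciesPreset` bundles everything the generators need to emulate
one species' neural-progenitor phenotype: the slow/rapid migration speed
mixture, the directional bias toward a scratch, the heterochronic
dendritic-growth parameters, and the developmental firing-rate trajectory.
Shipped defaults live in ``data/presets.yaml`` and are calibrated against
the published species contrasts (see the package methods note); they can
be edited or replaced wholesale without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = ["SpeciesPreset", "load_presets", "get_preset"]


@dataclass(frozen=True)
class SpeciesPreset:
    """Generator parameters for one species.

    Parameters
    ----------
    name
        Species label carried into every generated record.
    slow_speed_range, rapid_speed_range
        Per-step speed intervals (um/min) of the two mixture components.
    rapid_fraction
        Probability that a step is drawn from the rapid component.
    drift_bias
        von Mises concentration (dimensionless, >= 0) of step directions
        about the direction toward the scratch; 0 means an unbiased walk.
    morpho_onset_weeks
        Week at which dendritic growth starts (heterochronic onset).
    elongation_rate
        Mean dendritic elongation per growing tip per week (um/week).
    branch_prob
        Per-tip per-week probability of branching.
    spine_rate
        Spine accrual rate (spines per um of dendrite per week).
    initial_trees, initial_neurite_um
        Minimal tree present before growth onset.
    firing_trajectory
        Map of differentiation week -> mean firing rate per active
        electrode (spikes/s); intermediate weeks are linearly
        interpolated, and the trajectory is clamped at its end knots.
    """

    name: str
    slow_speed_range: tuple[float, float]
    rapid_speed_range: tuple[float, float]
    rapid_fraction: float
    drift_bias: float
    morpho_onset_weeks: float
    elongation_rate: float
    branch_prob: float
    spine_rate: float
    initial_trees: int = 3
    initial_neurite_um: float = 15.0
    firing_trajectory: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rng in (self.slow_speed_range, self.rapid_speed_range):
            lo, hi = rng
            if lo < 0 or hi < lo:
                raise ValueError(f"speed range must be ordered and non-negative, got {rng}")
        if not 0.0 <= self.rapid_fraction <= 1.0:
            raise ValueError("rapid_fraction must lie in [0, 1]")
        if self.drift_bias < 0:
            raise ValueError("drift_bias must be >= 0")
        if any(r < 0 for r in self.firing_trajectory.values()):
            raise ValueError("firing_trajectory rates must be non-negative")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")

    def firing_rate(self, week: float) -> float:
        """Interpolated firing rate (spikes/s per active electrode) at *week*."""
        if not self.firing_trajectory:
            raise ValueError(f"preset {self.name!r} has no firing trajectory")
        weeks = np.array(sorted(self.firing_trajectory))
        rates = np.array([self.firing_trajectory[w] for w in weeks])
        return float(np.interp(week, weeks, rates))

    def replace(self, **kwargs) -> "SpeciesPreset":
        """Return a copy with selected fields overridden."""
        from dataclasses import asdict

        d = asdict(self)
        d.update(kwargs)
        return SpeciesPreset(**d)


def _coerce(name: str, raw: dict) -> SpeciesPreset:
    raw = dict(raw)
    traj = {float(k): float(v) for k, v in raw.pop("firing_trajectory", {}).items()}
    raw["slow_speed_range"] = tuple(raw["slow_speed_range"])
    raw["rapid_speed_range"] = tuple(raw["rapid_speed_range"])
    return SpeciesPreset(name=name, firing_trajectory=traj, **raw)


def load_presets(path=None) -> dict[str, SpeciesPreset]:
    """Load species presets from a YAML file (shipped defaults if *path* is None)."""
    if path is None:
        text = resources.files("pannpc").joinpath("data/presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _coerce(name, cfg) for name, cfg in raw.items()}


def get_preset(name: str, path=None) -> SpeciesPreset:
    """Fetch one named preset; raises ``KeyError`` with the known names."""
    presets = load_presets(path)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None
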