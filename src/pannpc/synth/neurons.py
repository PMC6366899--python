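"""Stochastic heterochronic dendrite growth for synthetic morphologies.

Discrete-week, segment-level growth from a soma: before the preset's
onset week the neuron carries only a minimal tree (``initial_trees``
straight neurites of ``initial_neurite_um``); after onset, every growing
tip elongates by a Gamma-distributed increment with mean
``elongation_rate`` per week and branches with probability
``branch_prob`` per week.  Spines accrue as counts per segment at
``spine_rate`` spines per um of standing dendrite per week.

The model admits closed-form expectations used by recovery tests:
with n0 initial tips and branch probability p, the expected tip count
after j weeks is ``n0 (1+p)^j``, so

    E[TDL after w weeks] = L0 + rate * n0 * sum_{j=0}^{w-1} (1+p)^j
    E[DSN after w weeks] = spine_rate * sum_{k=1}^{w} E[TDL after k weeks]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..morphometry import (
    DENDRITE_TYPE,
    SOMA_TYPE,
    NeuronMorphology,
    Node,
    segment_decomposition,
)
from ..presets import SpeciesPreset

__all__ = ["MorphoTruth", "gen_morphology", "expected_tdl", "expected_dsn"]

_ELONGATION_SHAPE = 4.0  # Gamma shape of weekly tip elongation (mean preserved)


@dataclass
class MorphoTruth:
    """Closed-form expectations for one generated neuron."""

    expected_tdl: float
    expected_dsn: float
    growth_weeks: int


def _growth_weeks(preset: SpeciesPreset, week: float) -> int:
    return max(0, int(np.floor(week - preset.morpho_onset_weeks)))


def expected_tdl(preset: SpeciesPreset, week: float) -> float:
    """Expected total dendritic length (um) at *week* under the growth model."""
    w = _growth_weeks(preset, week)
    n0 = preset.initial_trees
    l0 = n0 * preset.initial_neurite_um
    p = preset.branch_prob
    growth = sum((1.0 + p) ** j for j in range(w))
    return l0 + preset.elongation_rate * n0 * growth


def expected_dsn(preset: SpeciesPreset, week: float) -> float:
    """Expected total spine count at *week* under the growth model."""
    w = _growth_weeks(preset, week)
    onset = preset.morpho_onset_weeks
    return preset.spine_rate * sum(expected_tdl(preset, onset + k) for k in range(1, w + 1))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _wiggle(direction: np.ndarray, sd_rad: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, sd_rad, 3))


def gen_morphology(
    preset: SpeciesPreset,
    week: float,
    seed: int | np.random.Generator = 0,
    soma_radius: float = 7.0,
    wiggle_sd: float = 0.25,
) -> tuple[NeuronMorphology, dict[int, int], MorphoTruth]:
    """Grow one synthetic neuron to *week*; returns (tree, spines, truth).

    The spine sidecar maps segment ids (as assigned by
    :func:`pannpc.morphometry.segment_decomposition`) to counts.
    """
    if week < 0:
        raise ValueError("week must be >= 0")
    rng = np.random.default_rng(seed)
    nodes: list[Node] = [Node(1, SOMA_TYPE, 0.0, 0.0, 0.0, soma_radius, -1)]
    position = {1: np.zeros(3)}
    next_id = 2
    tips: list[tuple[int, np.ndarray]] = []  # (node id, outward unit direction)

    # minimal tree: initial neurites at roughly even angles around the soma;
    # path lengths are measured from the soma node, so the first node sits
    # exactly initial_neurite_um away
    base = rng.uniform(0.0, 2 * np.pi)
    for i in range(preset.initial_trees):
        ang = base + 2 * np.pi * i / preset.initial_trees
        direction = _unit(np.array([np.cos(ang), np.sin(ang), rng.normal(0, 0.1)]))
        end = direction * preset.initial_neurite_um
        nodes.append(Node(next_id, DENDRITE_TYPE, *end, 0.6, 1))
        position[next_id] = end
        tips.append((next_id, direction))
        next_id += 1

    tdl_history = []  # TDL standing at the end of each growth week
    tdl = preset.initial_trees * preset.initial_neurite_um
    for _ in range(_growth_weeks(preset, week)):
        new_tips: list[tuple[int, np.ndarray]] = []
        for tip_id, direction in tips:
            length = rng.gamma(_ELONGATION_SHAPE, preset.elongation_rate / _ELONGATION_SHAPE)
            direction = _wiggle(direction, wiggle_sd, rng)
            end = position[tip_id] + direction * length
            nodes.append(Node(next_id, DENDRITE_TYPE, *end, 0.5, tip_id))
            position[next_id] = end
            grown_id = next_id
            next_id += 1
            tdl += length
            if rng.random() < preset.branch_prob:
                # the grown tip becomes a branch point with two short daughters
                for sign in (+1.0, -1.0):
                    d2 = _wiggle(direction + sign * 0.6 * _orthogonal(direction, rng), 0.05, rng)
                    stub = end + d2 * 0.5
                    nodes.append(Node(next_id, DENDRITE_TYPE, *stub, 0.4, grown_id))
                    position[next_id] = stub
                    new_tips.append((next_id, d2))
                    next_id += 1
                    tdl += 0.5
            else:
                new_tips.append((grown_id, direction))
        tips = new_tips
        tdl_history.append(tdl)

    morph = NeuronMorphology(
        nodes=nodes,
        soma_area=float(np.pi * soma_radius**2),
        species=preset.name,
        weeks_pst=float(week),
        cell_id=f"{preset.name}_wk{week:g}",
    )
    segments = segment_decomposition(morph)
    total_spines = rng.poisson(preset.spine_rate * sum(tdl_history)) if tdl_history else 0
    spines = {s.segment_id: 0 for s in segments}
    if total_spines > 0 and segments:
        lengths = np.array([s.length for s in segments])
        alloc = rng.multinomial(total_spines, lengths / lengths.sum())
        for s, k in zip(segments, alloc):
            spines[s.segment_id] = int(k)
    truth = MorphoTruth(
        expected_tdl=expected_tdl(preset, week),
        expected_dsn=expected_dsn(preset, week),
        growth_weeks=_growth_weeks(preset, week),
    )
    return morph, spines, truth


def _orthogonal(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(0.0, 1.0, 3)
    v -= v.dot(direction) * direction
    return _unit(v)
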