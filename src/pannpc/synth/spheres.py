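"""Synthetic neurosphere nucleus fields with known radial outgrowth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..neurosphere import NucleusField

__all__ = ["SphereTruth", "gen_neurosphere_field"]


@dataclass
class SphereTruth:
    """Ground truth for a generated field."""

    center: tuple[float, float]
    core_radius: float
    sector_outgrowth: tuple[float, float, float, float]

    @property
    def outgrowth(self) -> float:
        return float(np.mean(self.sector_outgrowth))


def gen_neurosphere_field(
    core_radius: float = 100.0,
    outgrowth_mean: float = 330.0,
    outgrowth_sd: float = 60.0,
    anisotropy: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    n_core: int = 600,
    n_migrating: int = 300,
    center: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> tuple[NucleusField, SphereTruth]:
    """Dense nucleus disc plus radially migrated nuclei.

    Core nuclei are uniform over a disc of *core_radius*; migrating
    nuclei sit at radius ``core_radius + d`` where ``d`` is a truncated
    (at zero) normal with per-sector mean ``outgrowth_mean * anisotropy[s]``
    and SD *outgrowth_sd*, the sector being the quadrant of the nucleus'
    angle.  Ground truth records the per-sector mean outgrowth.
    """
    if core_radius <= 0 or outgrowth_mean <= 0:
        raise ValueError("core_radius and outgrowth_mean must be positive")
    if outgrowth_sd < 0 or n_core < 0 or n_migrating < 0:
        raise ValueError("negative geometry or counts")
    rng = np.random.default_rng(seed)
    cx, cy = center
    # uniform disc via sqrt radial transform
    r_core = core_radius * np.sqrt(rng.random(n_core))
    th_core = rng.uniform(0.0, 2 * np.pi, n_core)
    core = np.column_stack([cx + r_core * np.cos(th_core), cy + r_core * np.sin(th_core)])

    th_mig = rng.uniform(0.0, 2 * np.pi, n_migrating)
    sector = (th_mig // (np.pi / 2)).astype(int)
    mult = np.asarray(anisotropy, dtype=float)[sector]
    if outgrowth_sd == 0:
        d = outgrowth_mean * mult
    else:
        d = rng.normal(outgrowth_mean * mult, outgrowth_sd)
        while np.any(d < 0):  # redraw below-zero distances (truncation at 0)
            bad = d < 0
            d[bad] = rng.normal(outgrowth_mean * mult[bad], outgrowth_sd)
    r_mig = core_radius + d
    mig = np.column_stack([cx + r_mig * np.cos(th_mig), cy + r_mig * np.sin(th_mig)])

    truth = SphereTruth(
        center=(float(cx), float(cy)),
        core_radius=float(core_radius),
        sector_outgrowth=tuple(float(outgrowth_mean * m) for m in anisotropy),
    )
    return NucleusField(np.vstack([core, mig])), truth
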