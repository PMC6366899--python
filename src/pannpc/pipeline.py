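"""End-to-end study runner: every assay on synthetic or manifest inputs.

`run_pipeline` executes the requested assay stages, writes tidy CSVs and
a JSON summary with every species contrast (raw and Bonferroni-adjusted
p values), and logs seeds and versions.  A stage failure is recorded in
the log and the report; the other stages still run, and the process
exit status (via the CLI) is non-zero if any stage failed.

Synthetic-study sample sizes default to desk-scale versions of the
study design (see the methods note); all are overridable from the YAML
config.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mea, migration, morphometry, neurosphere
from . import synth, transcriptomics
from .presets import load_presets
from .stats import bonferroni_adjust, mann_whitney_u, welch_t

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_ASSAYS = ("migration", "sphere", "morpho", "mea", "reads", "cells")

# per-species neurosphere outgrowth means (um) used by the synthetic study;
# spread across spheres is large relative to the species contrast
SPHERE_OUTGROWTH_UM = {"human": 331.7, "chimpanzee": 392.7, "bonobo": 404.3}
SPHERE_BETWEEN_SD_UM = 150.0

DEFAULT_SIZES = {
    "tracks_per_species": 80,
    "track_frames": 145,
    "null_cells": 2000,
    "spheres_per_species": 40,
    "neurons_per_timepoint": 8,
    "morpho_weeks": [1, 2, 4, 6, 8],
    "mea_weeks": [1, 1.5, 2, 3, 4, 5, 6],
    "mea_lines_per_species": 2,
    "mea_electrodes": 16,
    "mea_duration_s": 600.0,
    "n_reads": 10000,
    "n_single_cells": 2000,
}


@dataclass
class PipelineConfig:
    assays: list[str] = dc_field(default_factory=lambda: list(ALL_ASSAYS))
    species: list[str] = dc_field(default_factory=lambda: ["human", "chimpanzee", "bonobo"])
    seed: int = 0
    out_dir: str = "pannpc_out"
    alpha: float = 0.05
    sizes: dict = dc_field(default_factory=dict)
    presets_path: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.assays) - set(ALL_ASSAYS)
        if unknown:
            raise ValueError(f"unknown assays: {sorted(unknown)}")
        self.sizes = {**DEFAULT_SIZES, **self.sizes}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _contrast_pairs(species: list[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(species) for b in species[i + 1 :]]


def _stage_migration(cfg, presets, rng, out):
    sizes = cfg.sizes
    per_species = {}
    for sp in cfg.species:
        ts = synth.gen_tracks(
            presets[sp],
            n_cells=sizes["tracks_per_species"],
            n_frames=sizes["track_frames"],
            seed=rng.integers(2**31),
        )
        summaries = migration.summarize_tracks(ts.tracks, ts.fieldgeom)
        per_species[sp] = [s for s in summaries if s.included]
    rows = [
        {
            "species": sp,
            "cell_id": s.cell_id,
            "cdt_um": s.cdt,
            "dd_um": s.dd,
            "mean_speed_um_min": s.mean_speed,
            "regression_speed_um_min": s.regression_speed,
        }
        for sp, ss in per_species.items()
        for s in ss
    ]
    pd.DataFrame(rows).to_csv(out / "migration_cells.csv", index=False)
    null_dd, null_frac = migration.simulate_null_dd(
        n_cells=sizes["null_cells"], seed=rng.integers(2**31)
    )
    comparisons = []
    for a, b in _contrast_pairs(cfg.species):
        res = mann_whitney_u(
            [s.mean_speed for s in per_species[a]],
            [s.mean_speed for s in per_species[b]],
            contrast=f"migration_speed:{a}-vs-{b}",
        )
        comparisons.append(res)
    bonferroni_adjust(comparisons)
    summary = {
        "mean_speed_um_min": {
            sp: float(np.mean([s.mean_speed for s in ss])) for sp, ss in per_species.items()
        },
        "toward_fraction": {
            sp: migration.toward_fraction(ss) for sp, ss in per_species.items()
        },
        "null_dd_mean_um": float(null_dd.mean()),
        "null_toward_fraction": null_frac,
        "comparisons": [c.to_dict() for c in comparisons],
    }
    return summary


def _stage_sphere(cfg, presets, rng, out):
    sizes = cfg.sizes
    measurements: dict[str, list] = {}
    rows = []
    for sp in cfg.species:
        ms = []
        for i in range(sizes["spheres_per_species"]):
            mean = max(
                50.0, rng.normal(SPHERE_OUTGROWTH_UM.get(sp, 350.0), SPHERE_BETWEEN_SD_UM)
            )
            ffield, truth = synth.gen_neurosphere_field(
                outgrowth_mean=mean, seed=rng.integers(2**31)
            )
            m = neurosphere.measure_sphere(ffield)
            ms.append(m)
            rows.append(
                {
                    "species": sp,
                    "sphere": i,
                    "outgrowth_um": m.outgrowth,
                    "truth_um": truth.outgrowth,
                    "core_radius_um": m.core_radius,
                }
            )
        measurements[sp] = ms
    pd.DataFrame(rows).to_csv(out / "sphere_measurements.csv", index=False)
    comparisons = []
    for a, b in _contrast_pairs(cfg.species):
        comparisons.append(
            neurosphere.compare_outgrowth(
                measurements[a], measurements[b], contrast=f"outgrowth:{a}-vs-{b}"
            )
        )
    bonferroni_adjust(comparisons)
    return {
        "mean_outgrowth_um": {
            sp: float(np.mean([m.outgrowth for m in ms])) for sp, ms in measurements.items()
        },
        "comparisons": [c.to_dict() for c in comparisons],
    }


def _stage_morpho(cfg, presets, rng, out):
    sizes = cfg.sizes
    species = cfg.species[:2]  # morphometric study compares two species
    records = []
    for sp in species:
        for wk in sizes["morpho_weeks"]:
            for _ in range(sizes["neurons_per_timepoint"]):
                m, spines, _ = synth.gen_morphology(
                    presets[sp], week=wk, seed=rng.integers(2**31)
                )
                records.append(morphometry.compute_metrics(m, spines))
    df = morphometry.records_frame(records)
    df.to_csv(out / "morpho_metrics.csv", index=False)
    result = {"regressions": {}, "comparisons": {}}
    for var in ("TDL", "MSL", "DSN", "DSD"):
        result["regressions"][var] = {
            sp: morphometry.timecourse_regression(df[df["species"] == sp], var).to_dict()
            for sp in species
        }
        tests = morphometry.crosssection_tests(df, var, species_pair=tuple(species))
        result["comparisons"][var] = [t.to_dict() for t in tests]
    return result


def _stage_mea(cfg, presets, rng, out):
    sizes = cfg.sizes
    wells = []
    for sp in cfg.species:
        for line in range(sizes["mea_lines_per_species"]):
            for wk in sizes["mea_weeks"]:
                trains = synth.gen_spike_trains(
                    presets[sp],
                    week=wk,
                    n_electrodes=sizes["mea_electrodes"],
                    duration=sizes["mea_duration_s"],
                    seed=rng.integers(2**31),
                )
                wells.append(
                    {
                        "line": f"{sp}_{line+1}",
                        "species": sp,
                        "week": wk,
                        "well": f"{sp[:1]}{line+1}w{wk:g}",
                        "trains": trains,
                    }
                )
    tc = mea.firing_timecourse(wells)
    tc.to_csv(out / "mea_timecourse.csv", index=False)
    comparisons = []
    sp_a, sp_b = cfg.species[0], cfg.species[1]
    for wk in sizes["mea_weeks"]:
        a = tc[(tc.species == sp_a) & (tc.week == wk)]["rate_hz"]
        b = tc[(tc.species == sp_b) & (tc.week == wk)]["rate_hz"]
        if len(a) >= 2 and len(b) >= 2:
            from .stats import student_t

            comparisons.append(student_t(a, b, contrast=f"rate:{sp_a}-vs-{sp_b}@wk{wk:g}"))
    bonferroni_adjust(comparisons)
    return {
        "mean_rate_hz": {
            sp: {
                f"{wk:g}": float(tc[(tc.species == sp) & (tc.week == wk)]["rate_hz"].mean())
                for wk in sizes["mea_weeks"]
            }
            for sp in cfg.species
        },
        "comparisons": [c.to_dict() for c in comparisons],
    }


def _stage_reads(cfg, presets, rng, out):
    model = synth.MismatchModel()
    multimap = 0.05
    records, labels = synth.gen_alignment_pairs(
        cfg.sizes["n_reads"], model, multimap_prob=multimap, seed=rng.integers(2**31)
    )
    kept = transcriptomics.filter_cross_species(records)
    with open(out / "kept_reads.txt", "w") as fh:
        fh.write("\n".join(kept) + ("\n" if kept else ""))
    return {
        "n_reads": len(records),
        "kept_fraction": len(kept) / len(records),
        "expected_kept_fraction": synth.expected_keep_fraction(model, multimap),
        "truth_agreement": float(
            np.mean([(r.read_id in set(kept)) == lbl for r, lbl in zip(records, labels)])
        ),
    }


def _stage_cells(cfg, presets, rng, out):
    panels, aliases = transcriptomics.load_marker_panels()
    props = [0.3, 0.2, 0.3, 0.2]
    expr, truth = synth.gen_expression_matrix(
        cfg.sizes["n_single_cells"],
        panels=panels,
        planted_proportions=props,
        dropout=0.2,
        seed=rng.integers(2**31),
    )
    scores, proportions = transcriptomics.panel_membership(expr, panels, aliases=aliases)
    scores.to_csv(out / "cell_panel_scores.csv")
    gated_truth = truth[truth["sox2_positive"]].set_index("cell")["panel"]
    acc = float((scores["assigned"] == gated_truth.loc[scores.index]).mean())
    return {
        "planted_proportions": dict(zip([p.name for p in panels], props)),
        "recovered_proportions": {k: float(v) for k, v in proportions.items()},
        "assignment_accuracy": acc,
        "n_gated_cells": int(len(scores)),
    }


_STAGES = {
    "migration": _stage_migration,
    "sphere": _stage_sphere,
    "morpho": _stage_morpho,
    "mea": _stage_mea,
    "reads": _stage_reads,
    "cells": _stage_cells,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured assay stages; returns (and writes) the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = load_presets(cfg.presets_path)
    log_lines = [f"pannpc {__version__}", f"seed {cfg.seed}", f"assays {cfg.assays}"]
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "species": cfg.species,
        "alpha": cfg.alpha,
        "stages": {},
        "errors": {},
    }
    for assay in cfg.assays:
        rng = np.random.default_rng([cfg.seed, ALL_ASSAYS.index(assay)])
        try:
            report["stages"][assay] = _STAGES[assay](cfg, presets, rng, out)
            log_lines.append(f"stage {assay}: ok")
        except Exception as exc:  # isolate stage failures
            report["errors"][assay] = f"{type(exc).__name__}: {exc}"
            log_lines.append(f"stage {assay}: FAILED {exc!r}")
            log_lines.append(traceback.format_exc())
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
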