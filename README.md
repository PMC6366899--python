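# pannpc

Cross-species comparison of neural-progenitor and neuronal phenotypes
between human and *Pan* (chimpanzee, bonobo) iPSC-derived cells.

Human neural progenitor cells (NPCs) migrate more slowly than their
chimpanzee and bonobo counterparts, and human neurons mature later but
eventually overtake — a heterochronic shift visible in migration
assays, dendritic morphometry and network electrophysiology. `pannpc`
implements the quantitative pipelines needed to measure these
contrasts, and ships synthetic-data generators with known ground truth
so every estimator can be validated end to end without access to raw
recordings.

## What it computes

**Scratch-assay migration** — per-cell cumulative distance travelled
(CDT = Σ‖Δx‖), the signed net displacement toward the scratch
(DD = (x_end − x_start)·û_toward, path independent, mean-zero under an
isotropic walk), migration speed (CDT/Δt, cross-checked against the
OLS slope of cumulative distance on time), a CDT ≥ width/4 inclusion
filter, the toward-fraction P(DD > 0), and a random-walk null with
random scratch offsets for testing directionality.

**Neurosphere outgrowth** — density-based core detection on
DAPI-style nucleus fields, then the mean over four quadrant sectors of
(95th-percentile radial extent − core radius).

**Graft spread** — per-cell distance from the injection site and the
convex-hull area covered by each species' grafted cells.

**Dendritic morphometry** — on SWC reconstructions with spine-count
sidecars: SOMA, TDL, TREE, DSC, MSL = TDL/DSC, DSN, DSD = DSN/TDL,
centrifugal branch orders; per-species regressions on weeks post
transplantation (Pearson test) and per-time-point unpaired t tests
with Bonferroni adjustment.

**MEA analysis** — 10 Hz–2.5 kHz zero-phase band-pass, robust noise SD,
5.5 σ spike detection with 1 ms dead time, the 5 spikes/min
active-electrode criterion, Poisson-surprise burst detection
(S = −ln P(X ≥ n | rate·T), S ≥ 10), pooled network bursts (≥ 10
spikes, ISIs ≤ 100 ms), and per-line max-normalized firing
timecourses.

**Transcriptomic filters** — the dual-reference read filter (keep iff
uniquely mapped to both references with ≤ 3 mismatches to the origin
species and ≤ 5 to the alternate, from SAM NM tags) and SOX2-gated
marker-panel membership scoring for cortical layer identity.

**Statistics** — Mann-Whitney U (exact by enumeration at small n),
Welch and Student t, Pearson regression, one-way ANOVA, Bonferroni —
all returning a uniform result record with raw and adjusted p.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

Generate synthetic scratch-assay tracks for two species and compare
migration:

```python
import numpy as np
from pannpc import synth, migration
from pannpc.presets import get_preset
from pannpc.stats import mann_whitney_u

for sp in ("human", "chimpanzee"):
    ts = synth.gen_tracks(get_preset(sp), n_cells=150, n_frames=145, seed=0)
    summ = [s for s in migration.summarize_tracks(ts.tracks, ts.fieldgeom)
            if s.included]
    print(f"{sp}: n={len(summ)}  "
          f"mean speed={np.mean([s.mean_speed for s in summ]):.3f} um/min  "
          f"toward={migration.toward_fraction(summ):.2f}")

dd, frac = migration.simulate_null_dd(n_cells=2000, seed=0)
print(f"null: mean DD={dd.mean():.2f} um  toward={frac:.3f}")
```

prints

```
human: n=150  mean speed=0.459 um/min  toward=0.87
chimpanzee: n=150  mean speed=0.696 um/min  toward=0.77
null: mean DD=-0.50 um  toward=0.493
```

Human cells move at ~0.46 µm/min against ~0.70 µm/min for chimpanzee
(a Mann-Whitney test on the two speed samples gives U = 0,
p ≈ 1e-50 — complete separation at this sample size), and both species
move predominantly toward the scratch (87% and 77% of cells), while
the unbiased-walk null sits at a toward-fraction of 0.49 with mean DD
indistinguishable from zero — the directed migration is real, not a
random-walk artifact.

The same study runs end to end from the command line:

```sh
pannpc run --seed 1 --out study_out     # all assays, synthetic presets
pannpc synth tracks --preset bonobo --seed 2 --out tracks_out
pannpc migrate analyze --tracks tracks_out/tracks.csv --out report.json
pannpc mea detect --in recording.h5 --out well.json
pannpc reads xfilter --origin human.sam --alt pantro.sam --out keep.txt
```

`pannpc run` writes `report.json` with every species contrast (raw and
Bonferroni-adjusted p values), tidy per-assay CSVs, and a `run.log`
recording seeds and versions.

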