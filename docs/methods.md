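# Methods

`pannpc` quantifies species differences between human and *Pan*
(chimpanzee, bonobo) iPSC-derived neural cells across five assays, each
implemented as an independent module with a synthetic-data generator
that carries known ground truth. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not establish.

## Scratch-assay migration

A tracked cell is a sequence of calibrated positions (µm) at fixed
frame intervals (default 10 min). Per cell we compute:

- **CDT** (cumulative distance travelled): the sum of Euclidean step
  lengths. Cells with CDT below a quarter of the viewing-field extent
  are excluded to avoid diluting the statistics with non-migrating
  cells. The extent defaults to the field width (the scratch-normal
  direction); `height` and `diagonal` are available. A length
  threshold is used rather than an area because CDT is a length.
- **DD** (distance difference): the net start-to-end displacement
  projected onto the unit vector pointing from the start position
  toward the scratch line. Positive values mean net movement toward
  the scratch. This statistic is path independent, coincides with the
  drop in perpendicular distance to the line whenever the cell does not
  cross the scratch, ranges over the whole real line, and — unlike the
  raw difference of point-to-line distances, which is biased negative
  by convexity — has mean exactly zero under any isotropic random
  walk. That zero-mean property is what makes the random-walk null
  interpretable.
- **Migration speed**: CDT divided by elapsed time, or equivalently the
  OLS slope of cumulative distance against time. The two are identical
  on constant-speed tracks and agree within ~10% on essentially all
  24 h tracks; the slope form is retained as a cross-check.
- **Toward fraction**: the share of included cells with DD > 0; DD = 0
  counts as not-toward (affects only degenerate inputs).

The null for directionality simulates unbiased walks (per-step speeds
resampled from a supplied pool, or uniform over the slow 0–1 µm/min
band) with the scratch offset redrawn uniformly per cell; the observed
toward fraction is tested against the null toward probability with a
binomial tail.

The scratch is modelled as an infinite line. Graft spread uses the
same geometry: per-cell Euclidean (point site) or perpendicular (line
site) distance, and the convex-hull area of each species' cell cloud
(SciPy Qhull; at least three non-collinear cells required).

## Neurosphere outgrowth

Nucleus centroids are binned at 5 µm, smoothed with a 12 µm Gaussian,
and the core is the connected component above half the peak density
containing the peak; its radius is the component's maximal radial
extent from the density-weighted centre. A field with no dense core
(the peak component holding under 10% of nuclei) is rejected rather
than measured. The field is then split into four quadrant sectors
about the centre; per sector the outer circumference is the 95th
percentile of radial nucleus distance, and the sector outgrowth is
(outer − core radius), floored at zero. The per-sphere outgrowth is
the mean over the four sectors, mirroring the four averaged manual
measurements the assay uses.

The 95th percentile resists stray nuclei but sits roughly one
within-front standard deviation outside the mean migration distance,
so absolute outgrowth carries a small constant positive offset; this
cancels in species contrasts and leaves the estimate-vs-truth
regression slope at unity (the recovery criterion used in the tests).

## Dendritic morphometry

Neurons are 7-column SWC trees (soma type 1, dendrite type 3, 1-based
ids, parents preceding children) with spine counts in a sidecar table
per segment, since SWC has no spine concept and tracing practice
records counts, not spine geometry. A **segment** is a maximal
unbranched path between the soma, branch points and terminals; its
length includes the edge from its anchoring node, so segment lengths
sum exactly to the total dendritic length. Centrifugal orders start at
1 for soma-adjacent segments and increment after every branch point.

The seven variables: SOMA (projected soma area, taken from metadata as
in tracing practice), TDL (Σ segment lengths), TREE (number of order-1
segments), DSC (number of segments), MSL = TDL/DSC (identical to the
mean of per-segment lengths), DSN (Σ spine counts) and DSD = DSN/TDL
(defined as 0 when both are 0; spines on a zero-length arbor are an
error). The identities MSL·DSC = TDL and DSD·TDL = DSN hold to 1e-9
for every valid tree and are enforced by property tests. Neurons
flagged truncated in a cohort manifest are excluded from analysis.

Longitudinal analysis: per species, OLS of each variable on weeks post
transplantation with the two-sided Pearson correlation test; per
time point, unpaired t tests between species, plus adjacent-time-point
tests within species, Bonferroni-adjusted over each variable's family
of comparisons. Time points with fewer than two neurons in a group are
skipped with a flag. Regressions pool clones within species; a group
column is exposed for users who prefer clone-level modelling.

## MEA analysis

The chain: zero-phase 3rd-order Butterworth band-pass (10 Hz–2.5 kHz;
forward–backward filtering squares the magnitude response), robust
per-electrode noise SD (median absolute deviation / 0.6745, insensitive
to spike contamination), two-sided threshold crossing at 5.5× the noise
SD with a 1 ms dead time and event times at the excursion extremum, and
the 5 spikes/min active-electrode criterion.

**Bursts** use the Poisson surprise S = −ln P(X ≥ n | baseline rate ×
window), computed from the Poisson log-survival function (stable for
S ≫ 1). The baseline is the electrode's whole-recording mean rate —
the adaptive element: equal spike density is more surprising on a quiet
electrode. Detection maximizes S exactly over all contiguous spike
windows with at least `min_spikes` spikes and accepts non-overlapping
windows with S ≥ 10 greedily by surprise; at MEA spike counts the exact
search is tractable and equals the exhaustive oracle by construction.
`min_spikes` defaults to 5: because a window's span is conditioned on
its endpoint spikes, dense 3-spike triplets reach S ≥ 10 by chance in
a nontrivial share of homogeneous Poisson trains, whereas the 5-spike
floor keeps null recordings quiet (≤ ~5% of seeds) while recovering
every planted burst in testing. Both thresholds are configurable.

**Network bursts** are non-adaptive: all active-electrode spikes in a
well are pooled and sorted, and every maximal run whose consecutive
pooled inter-spike intervals are ≤ 100 ms counts if it has ≥ 10 spikes
from ≥ 2 distinct electrodes (the electrode minimum is configurable;
the ISI criterion applies to the pooled train, the standard reading).

**Timecourses**: per well and week, the mean firing rate over active
electrodes (zero with a flag when none are active) and the
network-burst rate per minute. Because absolute rates differ between
lines, each line's rates are normalized by that line's maximum across
weeks; raw rates are always reported alongside, and normalization can
be disabled.

## Transcriptomic filters

The dual-reference filter keeps a read iff it maps uniquely to both the
origin-species and the alternate-species reference with at most 3
mismatches to the origin and 5 to the alternate. "Uniquely" means a
primary alignment with no secondary or supplementary records for that
read name (supplementary records break uniqueness); mismatches come
from the SAM NM tag, so indels count per their edit contribution. The
filter is monotone in both caps.

Marker-panel scoring restricts to the SOX2-positive population
(count > 0; threshold configurable), scores each cell per panel as the
number of panel genes detected, and assigns the arg-max panel, with
ties — including all-zero cells — left unassigned, so proportions sum
to at most one. Panels ship in an editable YAML with a symbol-alias
map (DARPP32 → PPP1R1B, DIAP3 → DIAPH3) applied before matching;
legacy symbols without an HGNC equivalent (ECPN, IGH6, SVETL) are
matched as written.

## Statistical kernel

Mann-Whitney U uses full permutation enumeration when the pooled sample
is ≤ 12 (exact even with ties) and the tie-corrected normal
approximation otherwise; effect sizes are rank-biserial. Welch and
Student t tests report the mean difference; samples that are both
constant give t = 0, p = 1 when equal and a flagged infinite statistic
with p → 0 when not. Pearson regression flags a constant response
instead of reporting an undefined correlation. All tests are two-sided
by default. Bonferroni adjustment multiplies by the family size,
capped at 1; the family is all tests for one variable across time
points (configurable), and raw p values are always reported next to
adjusted ones. Type-I error for every test is verified at 10,000 null
replicates to lie in [0.04, 0.06] at α = 0.05.

## Synthetic-data generators

Every generator takes an explicit seed (no global state) and returns
ground truth sufficient for recovery tests; equal seed and
configuration give byte-identical serialized output. Preset numbers
live in one editable YAML file.

- **Tracks**: per-step speeds from a two-component mixture — a slow
  band below 1 µm/min for every species and a rapid 1.25–2.5 µm/min
  band only in the *Pan* presets — with mixture weights calibrated so
  per-cell mean speeds land at 0.46 (human), 0.70 (chimpanzee) and
  0.72 µm/min (bonobo). Step directions are von Mises about the
  toward-scratch direction; concentrations (0.15/0.12/0.11) reproduce
  toward fractions near 84/76/72% on 24 h tracks. The bias re-centres
  on the current position, so cells that cross the scratch are pulled
  back — a deliberate feature of gap-filling behaviour.
- **Spheres**: a uniform nucleus disc plus migrating nuclei at
  core-radius + d, d truncated-normal with per-sector anisotropy
  multipliers; sector ground truth is the per-sector mean.
- **Neurons**: discrete-week tip growth. Before the preset onset week
  only the minimal tree exists (3 neurites × 15 µm); afterwards each
  tip elongates by a Gamma increment (shape 4, mean `elongation_rate`)
  and branches with probability p per week, and spines accrue as
  Poisson counts at `spine_rate` × standing TDL per week, distributed
  over segments by length. Expected TDL and DSN have closed forms
  (tip count grows as (1+p)^weeks) used by the recovery tests. The
  human preset (onset 4 wk, 85 µm/wk, p = 0.40) starts later but grows
  faster than the chimpanzee preset (onset 1 wk, 30 µm/wk, p = 0.25),
  so cohorts show chimpanzee > human TDL at week 2 and human >
  chimpanzee at week 8 — the heterochronic pattern. Because tip growth
  is exponential, presets are not meant for weeks ≫ 8.
- **MEA**: Gaussian noise (3 µV SD) plus biphasic derivative-of-Gaussian
  spike waveforms (~1 ms, default 24 µV = 8× noise) at homogeneous
  Poisson times from the preset's firing trajectory, with optional
  planted bursts and well-wide network bursts. The human trajectory
  ramps late (0.05 → 4.0 spikes/s over weeks 1–6) while the *Pan*
  trajectories peak early and decay, so species mean curves cross
  between weeks 4 and 5 in both raw and max-normalized units.
- **Reads**: origin mismatches Poisson(0.5); alternate mismatches add
  an independent Poisson(1.2) cross-species excess; unique/multi/
  unmapped status per reference with configured probabilities. The
  expected kept fraction has a closed form used for calibration.
- **Cells**: each cell expresses its planted panel's genes minus
  dropout, is SOX2-positive with rate 0.9, and carries its planted
  label as truth.

What the generators do **not** emulate: imaging artifacts, tracking
errors and z-flattening; nucleus segmentation noise and overlapping
spheres; tortuosity-realistic dendrite geometry or spine positions;
electrode cross-talk, LFP, bursting beyond planted structure; sequence
content (mismatch counts are drawn, not aligned); ambient RNA and
doublets. Passing tests therefore establish that the estimators
recover known structure of the right statistical shape at the study's
scale — not that they are robust to every artifact of real microscopy
or electrophysiology.

## Problem sizes and runtime choices

Synthetic studies default to desk-scale versions of the study design:
80–300 tracks/species at 145 frames, 40–50 spheres/group, 8–10
neurons/species/time point over weeks 1–8, 2 lines/species × 16
electrodes × 10 min recordings for timecourses, 10,000 reads, and
2,000 cells. Voltage-level simulation is used where waveform handling
is under test (detection operating points); timecourse studies draw
spike trains directly. All sizes are config-overridable.

## Known limitations

- The motion coefficient reported alongside speed distributions is
  exposed as an alias of migration speed; its original definition is
  not fully specified, and the alias is flagged in the API docs.
- The four sector directions are fixed to quadrants; manual
  measurements may choose other directions, which the rotation
  tolerance (<2%) covers only for roughly isotropic fields.
- Whether toward-fractions should be computed before or after the CDT
  filter is ambiguous; we compute after filtering.
- Burst-detection parameters mimic a proprietary analysis whose exact
  algorithm is unpublished; all thresholds are exposed in config so
  sensitivity can be assessed.
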