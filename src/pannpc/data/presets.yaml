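# Species presets for the synthetic-data generators.
#
# All preset numbers live here, never in code.  Speed ranges are um/min;
# the slow/rapid mixture reproduces the reported per-step speed structure
# (slow excursions below 1 um/min for every species, a rapid 1.25-2.5
# um/min component only in the Pan species).  rapid_fraction values are
# calibrated so the mixture means match the reported per-cell migration
# speeds (human 0.46, chimpanzee 0.70, bonobo 0.72 um/min).
# drift_bias is the von Mises concentration of step directions toward the
# scratch; values are calibrated to give toward-fractions in the 70-85%
# band at the default 145-frame (24 h) track length.
#
# Morphology: heterochronic growth.  The human preset starts dendritic
# growth later (onset_weeks) but elongates faster, so synthetic cohorts
# show chimpanzee > human early and human > chimpanzee late, with a TDL
# crossover around week 7-8.
#
# firing_trajectory maps differentiation week -> mean firing rate per
# active electrode (spikes/s); linear interpolation between knots.  The
# Pan presets peak early and decay, the human preset ramps late, so raw
# and max-normalized mean curves cross between weeks 4 and 5.

human:
  slow_speed_range: [0.0, 0.92]
  rapid_speed_range: [1.25, 2.5]
  rapid_fraction: 0.0
  drift_bias: 0.15
  morpho_onset_weeks: 4.0
  elongation_rate: 85.0
  branch_prob: 0.40
  spine_rate: 0.020
  initial_trees: 3
  initial_neurite_um: 15.0
  firing_trajectory:
    1.0: 0.05
    1.5: 0.10
    2.0: 0.30
    3.0: 1.00
    4.0: 1.80
    5.0: 3.20
    6.0: 4.00

chimpanzee:
  slow_speed_range: [0.0, 1.0]
  rapid_speed_range: [1.25, 2.5]
  rapid_fraction: 0.145
  drift_bias: 0.12
  morpho_onset_weeks: 1.0
  elongation_rate: 30.0
  branch_prob: 0.25
  spine_rate: 0.012
  initial_trees: 3
  initial_neurite_um: 15.0
  firing_trajectory:
    1.0: 0.50
    1.5: 1.30
    2.0: 1.90
    3.0: 2.20
    4.0: 2.00
    5.0: 1.70
    6.0: 1.50

bonobo:
  slow_speed_range: [0.0, 1.0]
  rapid_speed_range: [1.25, 2.5]
  rapid_fraction: 0.16
  drift_bias: 0.11
  morpho_onset_weeks: 1.0
  elongation_rate: 28.0
  branch_prob: 0.25
  spine_rate: 0.012
  initial_trees: 3
  initial_neurite_um: 15.0
  firing_trajectory:
    1.0: 0.45
    1.5: 1.20
    2.0: 1.80
    3.0: 2.10
    4.0: 1.90
    5.0: 1.60
    6.0: 1.40
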