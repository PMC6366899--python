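# Cortical layer / region marker panels used for single-cell region
# membership scoring, and the symbol-alias map applied before matching.
# DARPP32 and SVETL are legacy aliases: DARPP32 is HGNC PPP1R1B; SVETL
# (Svet1-like) has no HGNC equivalent and is matched as written.
panels:
  layer_Vb: [FOXO1, ECPN, LIX1, SYT9, S100A10, OMA1, LDB2, CRIM1, PCP4, RAC3, DIAP3]
  layer_VI: [LXN, FOXP2, DARPP32, IGH6]
  layer_II_III: [RORB, CYP39A1, LHX2, UNC5D, GPR6, MEF2C, DTX4, CUX1, CUX2, KITL, SVETL]
  hindbrain: [EN2, PAX2, EN1, ISL1, LHX3]
aliases:
  DARPP32: PPP1R1B
  DIAP3: DIAPH3
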