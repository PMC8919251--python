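# Named motif presets, one per exemplar decoding strategy.
# Units: relative abundance for thresholds, per-hour for rates, hours for delays.
version: 1
presets:
  SESN1-like:        # post-transcriptional cFFL; protein induced under rising only
    mechanism: cffl_posttranscriptional
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.9, kp_prot: 1.0, kd_prot: 0.5, tdel: 0.0}
    ffl:
      topology: coherent
      level: posttranscriptional
      y_production: 0.5
      y_degradation: 0.05
      y_delay: 0.5
      y_threshold: 1.6
      y_hill_n: 24.0
      x_half: 1.4
      x_hill_n: 8.0
  RAD51C-like:       # transcriptional cFFL; mRNA and protein induced under rising only
    mechanism: cffl_transcriptional
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.5, kp_prot: 1.0, kd_prot: 0.5, tdel: 0.0}
    ffl:
      topology: coherent
      level: transcriptional
      y_production: 0.5
      y_degradation: 0.05
      y_delay: 0.5
      y_threshold: 1.0
      y_hill_n: 8.0
      x_half: 1.4
      x_hill_n: 8.0
  HSPG2-like:        # iFFL; protein induced under oscillatory only
    mechanism: iffl
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.9, kp_prot: 1.0, kd_prot: 0.7, tdel: 2.0}
    ffl:
      topology: incoherent
      y_production: 3.0
      y_degradation: 0.6
      y_delay: 0.0
      y_threshold: 1.5
      y_hill_n: 8.0
      x_half: 1.25
      x_hill_n: 8.0
      repression: 150.0
      target: translation
  HOXC13-like:       # medium translational activation threshold; rising-only protein
    mechanism: threshold
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.25, kp_prot: 1.0, kd_prot: 0.5, tdel: 0.0}
    threshold: {theta: medium, hill_n: 8.0, level: translational}
  FDXR-like:         # low threshold; protein induced under both regimes
    mechanism: threshold
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.25, kp_prot: 1.0, kd_prot: 0.5, tdel: 0.0}
    threshold: {theta: 0.0, hill_n: 8.0, level: translational}
  BAX-like:          # high threshold; protein induced under neither regime
    mechanism: threshold
    kinetics: {kp_mrna: 1.0, kd_mrna: 0.25, kp_prot: 1.0, kd_prot: 0.5, tdel: 0.0}
    threshold: {theta: high, hill_n: 8.0, level: translational}
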