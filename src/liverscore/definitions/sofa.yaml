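# Sequential Organ Failure Assessment: six organ systems, 0-4 points each,
# total 0-24. PaO2/FiO2 edges are in kPa (13.3/26.7/40/53.3 kPa ~
# 100/200/300/400 mmHg); ventilation status is not collected, so the
# respiratory 3-4 point bands are assigned on the ratio alone.
# Band convention: left-closed intervals, i.e. [edge_i, edge_{i+1}).
name: SOFA
kind: band_sum
source: "six-organ SOFA band tables"
bounds: [0, 24]
components:
  - field: pf_ratio          # respiration
    edges: [13.3, 26.7, 40.0, 53.3]
    points: [4, 3, 2, 1, 0]
  - field: platelets         # coagulation, 1e9/L
    edges: [20, 50, 100, 150]
    points: [4, 3, 2, 1, 0]
  - field: bilirubin         # liver, umol/L
    edges: [20, 33, 102, 205]
    points: [0, 1, 2, 3, 4]
  - rule: sofa_cardiovascular
  - field: gcs               # central nervous system
    edges: [6, 10, 13, 15]
    points: [4, 3, 2, 1, 0]
  - field: creatinine        # renal, umol/L
    edges: [110, 171, 300, 441]
    points: [0, 1, 2, 3, 4]
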