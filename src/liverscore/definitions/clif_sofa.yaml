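# Chronic Liver Failure - SOFA: the SOFA variant adapted to cirrhosis.
# Coagulation is scored on INR instead of platelets and the cerebral
# component on the West Haven encephalopathy grade (grade = points), with a
# GCS fallback for cohorts without pre-intubation grades. Creatinine edges
# are the mg/dL thresholds 1.2/2.0/3.5/5.0 converted to umol/L.
name: CLIF-SOFA
kind: band_sum
source: "CLIF-SOFA band tables (cirrhosis-adapted SOFA)"
bounds: [0, 24]
components:
  - field: pf_ratio          # lungs
    edges: [13.3, 26.7, 40.0, 53.3]
    points: [4, 3, 2, 1, 0]
  - field: pt_ratio          # coagulation, INR bands
    edges: [1.1, 1.25, 1.5, 2.5]
    points: [0, 1, 2, 3, 4]
  - field: bilirubin         # liver, umol/L
    edges: [20, 34, 102, 205]
    points: [0, 1, 2, 3, 4]
  - rule: sofa_cardiovascular
  - rule: clif_cerebral
  - field: creatinine        # kidney, umol/L
    edges: [106, 177, 309, 442]
    points: [0, 1, 2, 3, 4]
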