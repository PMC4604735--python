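# Model for End-stage Liver Disease (unscaled, continuous).
# Inputs are floored at 1.0 before the natural log and creatinine is capped
# at 4.0 mg/dL, per the standard (UNOS-style) definition.
name: MELD
kind: linear_predictor
source: "MELD log-linear predictor on bilirubin, INR and creatinine"
intercept: 6.43
components:
  - field: bilirubin
    unit: mg/dL
    floor: 1.0
    transform: log
    coefficient: 3.78
  - field: pt_ratio
    floor: 1.0
    transform: log
    coefficient: 11.2
  - field: creatinine
    unit: mg/dL
    floor: 1.0
    cap: 4.0
    transform: log
    coefficient: 9.57
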