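# United Kingdom Model for End-stage Liver Disease.
# Log-linear in INR, creatinine (umol/L), bilirubin (umol/L) and sodium
# (mmol/L); hyponatraemia raises the score via the negative sodium term.
name: UKELD
kind: linear_predictor
source: "UKELD log-linear predictor (UK transplant listing score)"
intercept: 435.0
components:
  - field: pt_ratio
    floor: 0.1
    transform: log
    coefficient: 5.395
  - field: creatinine
    transform: log
    coefficient: 1.485
  - field: bilirubin
    transform: log
    coefficient: 3.13
  - field: sodium
    transform: log
    coefficient: -81.565
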