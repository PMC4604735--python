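# Royal Free Hospital-style prognostic predictor -- SYNTHETIC definition.
# The published RFH score is a continuous linear predictor for critically
# ill cirrhosis patients whose inputs include arterial lactate, bilirubin,
# urea and a separately computed count of failing organ systems. The input
# structure here follows that design, but the COEFFICIENTS ARE SYNTHETIC
# placeholders (provisional: true): they are chosen to give a continuous,
# roughly zero-centred predictor of plausible magnitude, not transcribed
# from the primary publication. Replace this file with transcribed
# coefficients before any use beyond pipeline exercise on synthetic data.
name: RFH
kind: linear_predictor
provisional: true
source: "synthetic stand-in for the Royal Free Hospital score (lactate, bilirubin, urea, organ-failure count)"
intercept: -3.6
components:
  - rule: organ_failure_count
    coefficient: 0.66
  - field: lactate
    transform: log
    coefficient: 0.45
  - field: bilirubin
    transform: log
    coefficient: 0.38
  - field: urea
    floor: 0.1
    transform: log
    coefficient: 0.41
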