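# APACHE II restricted to the first-available admission variables collected
# here. Physiology components that are not collected at all (temperature,
# heart rate, respiratory rate, haematocrit, arterial pH) are omitted, and
# collected physiology that is missing for a given patient scores its normal
# (zero-point) band, per the usual APACHE convention of treating unmeasured
# physiology as normal. The fixed constant is the chronic-health element:
# all patients have cirrhosis (severe organ insufficiency) and nonoperative
# emergency admission, worth 5 points. Oxygenation uses PaO2 in kPa with
# FiO2 assumed < 0.5 (edges ~ 55/60/70 mmHg).
name: APACHE II
kind: band_sum
source: "APACHE II acute-physiology + age + chronic-health points"
constant: 5
components:
  - field: map
    right_closed: true
    edges: [49, 69, 109, 129, 159]
    points: [4, 2, 0, 2, 3, 4]
    normal_if_missing: true
  - field: sodium
    right_closed: true
    edges: [110, 119, 129, 149, 154, 159, 179]
    points: [4, 3, 2, 0, 1, 2, 3, 4]
    normal_if_missing: true
  - field: potassium
    edges: [2.5, 3.0, 3.5, 5.5, 6.0, 7.0]
    points: [4, 2, 1, 0, 1, 3, 4]
    normal_if_missing: true
  - field: creatinine        # umol/L (mg/dL bands 0.6/1.5/2.0/3.5)
    edges: [53, 124, 168, 309]
    points: [2, 0, 2, 3, 4]
    normal_if_missing: true
  - field: wcc
    edges: [1, 3, 15, 20, 40]
    points: [4, 2, 0, 1, 2, 4]
    normal_if_missing: true
  - field: pao2              # kPa
    edges: [7.3, 8.05, 9.35]
    points: [4, 3, 1, 0]
    normal_if_missing: true
  - field: gcs               # points = 15 - GCS
    mapping: {3: 12, 4: 11, 5: 10, 6: 9, 7: 8, 8: 7, 9: 6, 10: 5,
              11: 4, 12: 3, 13: 2, 14: 1, 15: 0}
    normal_if_missing: true
  - field: age
    edges: [45, 55, 65, 75]
    points: [0, 2, 3, 5, 6]
    normal_if_missing: true
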