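# NEWS — Royal College of Physicians National Early Warning Score (2012).
# Published integer cut-offs rendered as half-open real intervals
# (e.g. RR "9-11 -> 1" becomes [9, 12)). Checksum: maximum 20.
name: NEWS
declared_max: 20
oxygen_points: 2
loc_rule:
  avpu_points: {A: 0, V: 3, P: 3, U: 3}
  agitation_points: 0
  combination: max
scales:
  - parameter: sbp
    bands:
      - {lower: null, upper: 91, points: 3}
      - {lower: 91, upper: 101, points: 2}
      - {lower: 101, upper: 111, points: 1}
      - {lower: 111, upper: 220, points: 0}
      - {lower: 220, upper: null, points: 3}
  - parameter: hr
    bands:
      - {lower: null, upper: 41, points: 3}
      - {lower: 41, upper: 51, points: 1}
      - {lower: 51, upper: 91, points: 0}
      - {lower: 91, upper: 111, points: 1}
      - {lower: 111, upper: 131, points: 2}
      - {lower: 131, upper: null, points: 3}
  - parameter: temp
    bands:
      - {lower: null, upper: 35.1, points: 3}
      - {lower: 35.1, upper: 36.1, points: 1}
      - {lower: 36.1, upper: 38.1, points: 0}
      - {lower: 38.1, upper: 39.1, points: 1}
      - {lower: 39.1, upper: null, points: 2}
  - parameter: rr
    bands:
      - {lower: null, upper: 9, points: 3}
      - {lower: 9, upper: 12, points: 1}
      - {lower: 12, upper: 21, points: 0}
      - {lower: 21, upper: 25, points: 2}
      - {lower: 25, upper: null, points: 3}
  - parameter: spo2
    bands:
      - {lower: null, upper: 92, points: 3}
      - {lower: 92, upper: 94, points: 2}
      - {lower: 94, upper: 96, points: 1}
      - {lower: 96, upper: null, points: 0}
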