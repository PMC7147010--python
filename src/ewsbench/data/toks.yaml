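# TOKS — regional six-component early warning score.
# Bands are half-open [lower, upper); null encodes -inf/+inf.
# Interior column placement of the one-sided extreme bands is a transcription
# choice; validate_score_system enforces the published maximum (18) as a checksum.
name: TOKS
declared_max: 18
oxygen_points: 0
loc_rule:
  avpu_points: {A: 0, V: 1, P: 2, U: 3}
  agitation_points: 1
  combination: max
scales:
  - parameter: sbp
    bands:
      - {lower: null, upper: 70, points: 3}
      - {lower: 70, upper: 80, points: 2}
      - {lower: 80, upper: 100, points: 1}
      - {lower: 100, upper: 200, points: 0}
      - {lower: 200, upper: null, points: 2}
  - parameter: hr
    bands:
      - {lower: null, upper: 40, points: 3}
      - {lower: 40, upper: 50, points: 1}
      - {lower: 50, upper: 90, points: 0}
      - {lower: 90, upper: 110, points: 1}
      - {lower: 110, upper: 130, points: 2}
      - {lower: 130, upper: null, points: 3}
  - parameter: temp
    bands:
      - {lower: null, upper: 34, points: 3}
      - {lower: 34, upper: 36, points: 1}
      - {lower: 36, upper: 38, points: 0}
      - {lower: 38, upper: 39, points: 1}
      - {lower: 39, upper: 40, points: 2}
      - {lower: 40, upper: null, points: 3}
  - parameter: rr
    bands:
      - {lower: null, upper: 9, points: 3}
      - {lower: 9, upper: 12, points: 1}
      - {lower: 12, upper: 21, points: 0}
      - {lower: 21, upper: 25, points: 2}
      - {lower: 25, upper: null, points: 3}
  - parameter: spo2
    bands:
      - {lower: null, upper: 85, points: 3}
      - {lower: 85, upper: 90, points: 2}
      - {lower: 90, upper: 93, points: 1}
      - {lower: 93, upper: null, points: 0}
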