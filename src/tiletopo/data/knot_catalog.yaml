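# The prime knots reachable by sealed tile complexes, with a rational
# (4-plat) construction for a reference minimal diagram and the knot
# determinant as a load-time checksum.  All invariants are computed from
# the construction at load time.
knots:
  "3_1": {cf: [3], det: 3}
  "4_1": {cf: [2, 2], det: 5}
  "5_1": {cf: [5], det: 5}
  "5_2": {cf: [2, 3], det: 7}
  "6_1": {cf: [2, 4], det: 9}
  "6_2": {cf: [2, 1, 3], det: 11}
  "6_3": {cf: [2, 1, 1, 1, 1], det: 13}
  "7_6": {cf: [2, 1, 2, 2], det: 19}
  "7_7": {cf: [2, 1, 1, 1, 2], det: 21}
  "8_12": {cf: [2, 2, 2, 2], det: 29}
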