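# Default whisker-pad layout for the rat face, used by the arrangement
# shuffle test and the synthetic generator.
#
# Grid coordinates are (row, column) on a schematic pad: row 0 holds the
# two supra-orbital whiskers (lSO, sSO), rows 1-4 hold the straddlers
# (alpha..delta, at column 0) together with mystacial rows A-D (arcs 1-4),
# and row 5 holds the E row.  The caudal-most arc is column 1; straddlers
# sit caudal of arc 1 at column 0.
positions:
  lSO: [0, 0]
  sSO: [0, 1]
  alpha: [1, 0]
  A1: [1, 1]
  A2: [1, 2]
  A3: [1, 3]
  A4: [1, 4]
  beta: [2, 0]
  B1: [2, 1]
  B2: [2, 2]
  B3: [2, 3]
  B4: [2, 4]
  gamma: [3, 0]
  C1: [3, 1]
  C2: [3, 2]
  C3: [3, 3]
  C4: [3, 4]
  delta: [4, 0]
  D1: [4, 1]
  D2: [4, 2]
  D3: [4, 3]
  D4: [4, 4]
  E1: [5, 1]
  E2: [5, 2]
  E3: [5, 3]
  E4: [5, 4]

# The six spatial arrangements tested against the shuffle null.  Each is a
# rule over grid coordinates; group labels are derived integers.
schemes:
  arcs:
    rule: by_column
  rows:
    rule: by_row
  semicircles_A1:
    rule: chebyshev_from
    anchor: A1
  oblique45_A1:
    rule: diagonal_sum      # bands of constant row+col, i.e. 45 deg from A1 corner
  oblique135_A4:
    rule: diagonal_diff     # bands of constant row-col, i.e. 135 deg from A4 corner
  opposite_semicircle_E4:
    rule: chebyshev_from
    anchor: E4
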