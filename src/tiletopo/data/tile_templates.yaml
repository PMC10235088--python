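# Crossing templates of the five base tiles.
#
# Encoding (see tiletopo.templates): each strand lists its crossing
# passages in order as [crossing, in_side, layer]; in_side is S/E/N/W for
# an axis-aligned crossing or SW/SE/NE/NW for a diagonal one (sides in
# counterclockwise order), layer is o (over) / u (under).  Strand "main"
# runs W -> E; strand "west" runs SW -> NW; strand "east" runs SE -> NE.
#
# The five shapes: alpha is an open trefoil and beta an open figure-eight
# (1-string tiles); delta, epsilon and gamma are a hook clasped through a
# loop carrying 0, 1 and 2 extra twists.  Layer choices are frozen by the
# gate that the engine must reproduce the published cross-products table
# and basic sealing classes (see tests/test_acceptance.py).
tiles:
  alpha:
    arity: 1
    strands:
      main: [[k1, NE, u], [k2, NW, o], [k3, NE, u], [k1, NW, o], [k2, NE, u], [k3, NW, o]]
  beta:
    arity: 1
    strands:
      main: [[L1, NW, o], [L2, NW, u], [L4, NE, o], [L1, NE, u], [L3, NW, o], [L4, NW, u], [L2, NE, o], [L3, NE, u]]
  delta:
    arity: 2
    strands:
      west: [[c1, S, o], [c2, S, u]]
      east: [[c1, E, u], [c2, W, o]]
  epsilon:
    arity: 2
    strands:
      west: [[c1, S, u], [c2, S, o]]
      east: [[cE, S, o], [c2, E, u], [c1, W, o], [cE, W, u]]
  gamma:
    arity: 2
    strands:
      west: [[t1, SW, u], [t0, SE, o]]
      east: [[t3, SE, o], [t2, NE, u], [t1, SE, o], [t0, SW, u], [t2, NW, o], [t3, SW, u]]
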