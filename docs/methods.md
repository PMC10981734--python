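# Methods

## Scope and model

`tautopo` quantifies the three-dimensional shape of amyloid filament
backbones — above all the tau filament folds seen in neurodegenerative
disease — with measures from open-curve knot theory. A protein chain is
reduced to the open, oriented polygonal curve through its consecutive
C-alpha atoms (N- to C-terminus). On such curves the package computes:

* **Gauss linking integral** `Lk(l1, l2)`: the double integral
  `1/(4π) ∮∮ ((γ̇1 × γ̇2) · (γ1 − γ2)) / |γ1 − γ2|³ dt ds`,
  a real-valued measure of interwinding of two open curves. It equals the
  average over all projection directions of half the signed crossing count
  between the two projected curves.
* **Writhe** `Wr(l)`: the same integral of one curve with itself (off-
  diagonal domain, `1/(2π)` normalization), equal to the average signed
  self-crossing count over projections. Its sign is a handedness indicator.
* **Second Vassiliev measure** `v2(l)`: the sphere average of a per-diagram
  quantity — half the sum, over pairs of interleaved crossings whose four
  points alternate over/under along the curve, of the product of the two
  crossing signs. For a closed curve every generic diagram gives the same
  integer (the second Vassiliev invariant, e.g. 1 for the trefoil, 2 for
  5₂); for an open curve the value is direction-dependent and its average
  measures knotoid content. Open ends are left free (knotoid convention);
  no closure segment is ever added.

Crossing signs follow the right-handed convention (over-strand along +x,
under-strand along +y, viewed from +z, is +1). The sign can equivalently be
computed symmetrically as `sign((t1 × t2) · (p1 − p2))`, which is what the
projection-sampled estimators use.

## Numerical choices

* `Lk` and `Wr` are computed **exactly** as finite sums of per-segment-pair
  signed solid angles (the arcsin form of the quadrilateral solid angle,
  with the sign from the triple product). Coplanar pairs contribute exactly
  zero, so planar configurations give `Lk = Wr = 0` identically. Projection
  sampling for these two quantities exists in the package only as an
  independent cross-check (`mc_linking`, `mc_writhe`).
* `v2` is estimated by Monte Carlo over directions drawn uniformly on the
  sphere from a seeded generator (antipodes not deduplicated); the result
  carries its standard error, seed and projection count. Degenerate
  projections — projected edges parallel within 1e-12 of machine scale,
  crossings at edge endpoints, depth ties, overlapping collinear images —
  are rejected and the direction resampled (and counted). Collinear but
  disjoint projected edges are *not* degenerate; they can never cross.
* Whole linking matrices reuse a 2-D prefix sum over the pairwise edge
  Gauss matrix, so the full residue-by-residue matrix costs little more
  than one writhe evaluation.
* Fragment conventions: the fragment `p_{i,j}` includes both residues i and
  j; the preceding part ends at i−1 and the following part starts at j+1.
  Matrix entries whose defining fragment has fewer than two vertices are ND.
* A linking value of exactly 0.0 maps to ND in sign tuples (only + and −
  are meaningful signs); tuple distances count ND-vs-sign as a difference
  and ND-vs-ND as equal.

## Repeat annotation

The microtubule-binding repeats are annotated from a configurable boundary
table defaulting to R1 244–274, R2 275–305, R3 306–336, R4 337–368 and C
369 onward (author numbering, inclusive). Only fragments of these
boundaries appear in the source captions, so the table is a config default,
overridable per run. Per filament the annotation is the intersection with
the resolved residues: a repeat absent from the ordered core is ND, and
resolved residues before R1 are flagged `pre-R1` so the annotation is
total. The Pick's-disease fold's N-terminal segment 254–274 falls inside
the default R1 interval and is therefore annotated R1, which is what
enables its extra (R1,R3)/(R1,R4)/(R1,C) sign triple.

## Side-chain push-off

The push-off curve takes, per residue, the R-group heavy atom farthest from
that residue's CA (`atom_rank` selects the k-th farthest for robustness
re-analysis; conclusions should only be drawn from features stable across
ranks). Glycines have no R-group heavy atom: their push-off vertex is
interpolated linearly between the flanking residues' push-off vertices, and
terminal glycines copy the CA nudged toward the chain interior — this keeps
one vertex per residue without coincident points that would make the
linking integral singular. Backbone+push-off bound an open ribbon; with
`Tw = Lk − Wr` and the flat folds' tiny writhe, the reported linking is an
approximation of the ribbon twist, i.e. of the total turning of side chains
about the backbone. Per-region values are normalized both by the region's
residue count (the default reading) and by the filament length; the source
table caption supports either reading, so both are reported.

## Stacked filaments

Each deposited chain is treated as one protofilament rung. Rungs are
neighbors when their minimal CA–CA distance is below 6 Å (capturing the
~4.7 Å cross-β stacking but not next-nearest rungs at ~9.4 Å; the cutoff is
configurable). `Lk_s` of a rung is the mean Gauss linking with its
neighbors, reported per-residue as `Lk_s/N`. How many rungs a deposition
contains and which chain is "the" filament are not fixed by the source;
both are config-exposed and recorded in the output provenance. N is always
the number of CA vertices of the analyzed curve.

## Classification

Global features are `(Wr/N, Lk_s/N, |v2|)`. Level 1 of the classification
is the writhe sign (negative = left-handed, positive = right-handed, zero
ND); level 2 subdivides by identical repeat-pair sign tuples. K-means
(10 seeded restarts) groups the feature vectors; features are **z-scored by
default** because the three metrics, though all of order 1e-3 for tau
filaments, have very different spreads — without standardization the
writhe axis dominates the objective and the published 5-cluster structure
of the reference dataset is not recoverable, while z-scored features
reproduce it exactly. Cluster quality is reported as the silhouette score
and labelled as such; the quality number attached to the published cluster
figure uses an unnamed metric, and no attempt is made to reproduce it.

## Synthetic data

The generator module produces every fixture the test-suite needs:

* helices with chosen turns/radius/pitch/handedness (writhe ground truth
  via the projection oracle);
* closed polygonal knots — trefoil and figure-8 from trigonometric
  parametrizations, 5₂ as the closure of the braid word σ₁³σ₂σ₁⁻¹σ₂ built
  by a generic braid-closure constructor. Generators self-verify the knot
  type through the projection-invariance (and value) of the per-diagram
  second Vassiliev quantity;
* the K2₁ knotoid as a 7-vertex open curve whose +z projection is the
  standard two-crossing diagram (one interleaved alternating pair of
  equal-sign crossings, per-diagram value exactly 0.5);
* synthetic fibrils written as PDB files: rungs of a fold curve (default a
  flat C-shaped fold with 3.8 Å CA spacing) stacked with 4.7 Å rise and a
  default −1°/rung twist (canonical cross-β geometry; the twist default is
  a plausible emulation, not a fitted value), with two side-chain
  pseudo-atoms per residue placed by a configurable rule. The
  `sidechain_turns_rule` rotates the side-chain direction a known integer
  number of turns along the chain, giving construction-level ground truth
  for push-off linking.

What the synthetic fibrils do **not** emulate: real side-chain rotamers and
sequence, interface geometry of paired protofilaments, coordinate noise of
cryo-EM models, or the specific fold topologies of the disease filaments.
Tests passing on synthetic fibrils therefore validate the operations and
their invariances, not agreement with any particular deposited structure.

## Verification strategy and problem sizes

Every operation is validated against an independent route: segment-pair
solid angles against direct numerical quadrature of the Gauss integrand;
whole-curve `Lk`/`Wr` against projection-sampled signed crossing counts
(1e5 directions in the acceptance checks, 4e4 in unit tests); per-diagram
v2 of closed knots against a Polyak–Viro-style basepoint count on the same
diagrams and against the table invariants 1, −1, 2, 0; fragment prefix-sum
linking against direct evaluations. Monte-Carlo `v2` runs in tests use
10²–10³ directions (the estimator is exact for closed curves, where every
projection yields the same integer); production-scale runs default to 1e5
directions in the CLI.

## Reproducing published worked examples

The deposited cryo-EM coordinates (PDB 5o3t, 5o3l, 7nrq, 6nwp, 6nwq, 6gx5,
6tjo, 6tjx, 7p6d, 7p6e, 7p65, 7p66–7p68, 7p6a–7p6c, and 2etl for the
worked examples) are **not** bundled; computing the published per-structure
values requires fetching them (`tautopo.structure_io.fetch_structure`) into
a local cache on a networked machine. The corresponding acceptance test
(`test_deposited_structure_values_reproduced`) runs the full computation
when `data/pdb/` holds the entries and otherwise fails with a pointer to
this section. Two caveats apply when comparing with printed values: the
analyzed chain is chosen as the alphabetically first chain with the widest
resolved span (the original chain choice is unstated), and values that
depend on chain selection are then expected to agree in sign and order of
magnitude rather than digit-for-digit. The published global-metric table
itself ships as typed-in reference data (`tautopo.reference`) and drives
the clustering and classification-report examples offline.

## Known limitations

* Knotoid detection is v2-based only; no full knotoid-type classification
  or knot polynomials.
* No symmetry expansion: only chains deposited in the file are analyzed.
* `v2` of strongly entangled open curves converges slowly in the number of
  projections; the standard error is reported and should be respected.
* Band patterns in fingerprints are rendered, not auto-detected.
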