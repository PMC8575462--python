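# Methods

## The recruitment model

PP2A/B55α engages substrates like p107 in two places at once: a basic
anchor residue (p107 Arg-621) docks against Asp-197 in the groove on top
of the B55α β-propeller, while the phosphoacceptor (p107 pSer-615, here
represented by its Glu phosphomimetic) sits in the di-Mn²⁺ active site of
the catalytic subunit. The consensus motif

```
p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R
```

encodes this bipartite geometry as sequence: a Ser/Thr-Pro phosphosite, a
variable spacer, and the anchor block. Because the two docking points are
~27.5 Å apart, the spacer must adopt a highly extended conformation; the
structural half of the package asks which experimentally observed peptide
conformations can bridge that distance, and how well their Glu/Arg
termini superpose onto the two anchor points.

## Motif grammar and scanning

Patterns are dash-separated tokens: fixed residue, residue class
`[ABC]`, wildcard `x`, gap `x(m,n)`; a leading `p` on exactly one
letter/class (restricted to S/T/Y) marks the phosphoacceptor. The anchor
element is identified structurally as the first R/K-only element after
the first gap. Parsing is strict (inverted gap bounds, duplicate
phospho markers, empty classes and stray tokens are errors naming the
token) and formatting round-trips.

Scanning enumerates every start position and gap-length assignment and
checks each element literally. **Hit identity** is one hit per distinct
(phosphoacceptor position, anchor position) pair: multiple gap
realizations landing on the same pair collapse. This is deterministic
and matches common motif-scanner behaviour; since published hit counts
for this motif family do not state an overlap convention, counts produced
under a different convention are not directly comparable. The
alternative — one hit per phosphoacceptor — is available via
`hit_identity="phospho"`.

Ambiguity letters: X/B/Z/U never satisfy a fixed residue or class; X
(unknown residue) satisfies wildcard and gap positions, B/Z/U do not.
Sequences are uppercased on read; `-`/`*` are stripped with a warning.
Coordinates are 1-based inclusive; an `offset` maps local positions to
author numbering (offset 611 puts the 15-mer fragment at p107 612–626).

**Enrichment** uses the one-sided Fisher exact (hypergeometric tail)
test, with a protein counted positive iff it has ≥ 1 hit anywhere. The
tail direction follows the observed fraction (enriched: P(X ≥ k);
depleted: P(X ≤ k); equal fractions: p = 1). The source analysis reports
only fractions; an exact test makes the comparison usable, and its
conservativeness is verified empirically (type-I error ≤ α over 2,000
null simulations).

## Fragment mining

Fragments are excised from coordinate files wherever a fixed-length
wildcard pattern (e.g. `xHPRVx`) matches the chain sequence. A fragment
must be contiguous (consecutive CA–CA ≤ 4.5 Å, a standard break
heuristic), carry all four backbone atoms at every position, and contain
no nonstandard residues (selenomethionine reads as Met). Wildcard flanks
are part of the pattern, so a motif at a chain terminus is not a match.
Alternate conformations are reduced at read time to the
highest-occupancy altloc (ties toward 'A'). Side-chain OE1/OE2 of the
pattern Glu and NH1/NH2 of the pattern Arg are role-tagged for the
placement pipeline.

Backbone torsions follow the IUPAC convention, wrapped to (−180°, 180°];
phi is undefined at the first residue, psi/omega at the last, and
degenerate (colinear) geometry yields an undefined angle with a warning
rather than an error. The conformer distance is the **maximum circular
difference** over compared residue positions and angle types — a metric
(max of circular metrics) that is property-tested for symmetry and the
triangle inequality. By default only the pattern-core residues are
compared (`core_only=True`): the published procedure computed torsions
"of each residue of the HPRV motif", which reads as core-only; flank
torsions are one bond from the fragment boundary and noisier.

Clustering is DBSCAN on the precomputed distance matrix. **eps = 60°,
min_pts = 5** by default: the source analysis does not state its
parameters, so these are chosen coarse enough to absorb thermal
variation within a secondary-structure class and strict enough to keep
helical and extended families apart (planted clusters 120° apart at 5°
noise separate perfectly at eps = 30°). Both parameters are explicit in
`ClusterConfig` and echoed by the CLI. The reference conformer is the
best-resolution member of the largest cluster; equal-size clusters break
toward the one whose best member has lower resolution, structures
without a resolution (NMR) rank last, and remaining ties fall back to
lexicographic fragment id.

The Glu–Arg end-to-end span is the **minimum** over the ≤ 4 OE×NH atom
pairs (configurable to max/mean), mirroring the "save the shortest
distance" convention of the Mn–phosphate survey; the published text does
not say which atom pair its distances used, so the full per-pair table
is also reported for scenes. The span filter retains fragments with
span ≥ 20 Å (boundary inclusive). The Mn–phosphate survey records, per
Mn²⁺ ion, the shortest distance to any phosphate oxygen (PO4 residues or
O1P–O4P/OP1–OP3 atom names) and aggregates with a **population (n
denominator) standard deviation**, stated in the output metadata because
the convention behind the published 2.38 ± 0.59 Å aggregate is not
recoverable.

## Model assembly

`superpose` is the Kabsch algorithm with the reflection branch of the
SVD corrected, so only proper rotations are returned; mirror-image point
sets fit with non-zero residual. Active-site alignment pairs the two
metals plus CA atoms of metal-coordinating residues (any atom < 2.6 Å
from a metal; metals = Mn/Fe/Zn/Mg/Ni within 5 Å of each other), pairing
residues in author order with an LCS fallback on residue names and
trying both metal orderings. This replaces "align the homologous
phosphatases" with a concrete, logged atom set.

The Arg anchor is placed deterministically instead of interactively: the
NH pair is the Asp OD pair displaced along a trial direction, scaled so
the minimum NH–OD distance equals the contact distance (default 3.0 Å)
exactly; directions are enumerated on a 10° spherical grid and the
orientation with fewest heavy-atom clashes (< 2.5 Å) wins, ties broken
toward the largest clearance. If nothing is clash-free the least-bad
orientation is returned flagged, with a warning.

Candidate fitting superposes the fragment's OE/NH atoms onto the scene
references; OE1/OE2 and NH1/NH2 labels are arbitrary in deposited files,
so both assignments per side are tried and the best kept. The
displacement score is the **sum of unsquared distances** of the fitted
anchor atoms to their references (the transform itself is the
least-squares pair-fit). With only two anchor atoms the pair-fit is
underdetermined for Kabsch; a closed-form segment fit is used whose
minimal score equals |d − s| for segment lengths d, s (verified against
a brute-force reference). Ranking is ascending by score, top 20
retained; the final model minimizes (min OE→Mn) + (min NH→OD), a
concrete reading of "minimum distances to the Mn²⁺ ions and D197", with
lexicographic id tie-breaks. Ranking happens pre-threading; threading
preserves the anchor atoms, so scores are unchanged by construction.

Threading renames the core residues to the target sequence with
coordinates untouched, drops wildcard flanks and side chains beyond CB
(anchor Glu/Arg atoms excepted), and grows terminal extensions in
extended conformation (φ = −139°, ψ = 135°, ω = 180°) by
internal-coordinate placement. Models are written as standard PDB files
with occupancy 1 and no hydrogens.

## Synthetic data

Generators are pure functions of (parameters, seed); identical calls are
byte-identical.

* **Proteomes**: each protein independently receives one planted motif
  instance with probability `plant_rate` (instance drawn uniformly from
  the pattern language, gap length uniform), overwriting background
  sequence at a uniform offset. Background composition defaults to
  uniform residue frequencies, with a human-like Swiss-Prot preset
  (`residue_frequencies="human"`). Truth records every plant and, after
  a self-scan, the chance background hits and the full positive-id set —
  so recovery tests can separate planted from incidental positives.
* **Interactor sets**: weighted sampling without replacement
  (Efraimidis–Spirakis keys), weight = enrichment factor for
  motif-positive proteins vs 1 for negatives; factor 1 is exactly the
  hypergeometric null, factor ∞ takes positives first, factor 0 errors
  if the negative pool is too small.
* **Peptide builder**: sequential internal-coordinate (NeRF) placement
  with ideal stereochemistry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å;
  angles 111.2°/116.2°/121.7°); carbonyl O, CB and full Glu/Arg
  side-chain stubs (all-anti torsions, planar carboxylate/guanidinium)
  from fixed geometry. Build→measure round-trips torsions to ≤ 1e−6°
  in memory (PDB's three-decimal coordinates limit file round-trips to
  ~0.05°).
* **Conformer libraries**: cluster center + wrapped-Gaussian angular
  noise (well-defined on circular data), random global rigid motion per
  member (torsions are invariant), and a random nominal resolution in
  1.2–3.0 Å so reference selection has a ranking to exercise.
* **Anchor scenes**: OD pair 2.2 Å apart, NH pair displaced by the
  contact distance, nearest OE exactly `span` beyond the first NH,
  metals just past the OE atoms, all under a random global rotation.
  The default span, 27.5 Å, is the published two-fragment geometry.

What the generators do **not** emulate: real proteome length/composition
structure (domains, low-complexity regions, splice isoforms), rotamer
physics or packing in built peptides, and receptor context beyond a
minimal mock (di-metal site, coordinating residues, an Asp-197 anchor
and a context shell). Passing tests therefore demonstrate correctness of
the algorithms under controlled truth, not database-level hit counts:
proteome-scale fractions depend on the sequence database release and the
hit-counting convention, and the deposited-structure anchor span (27.5 Å
reproduced within ±1.5 Å) requires fetching PDB entries 3DW8/5HPE/1G8M,
which the test suite attempts live.

## Problem sizes and numerical choices

Default test/acceptance problem sizes: 500-protein proteomes at plant
rate 0.1 for recovery; 2,000 null draws for test calibration; 1,000
random sequences for the scanner/oracle equivalence; ≤ 50 fragments for
the definitional DBSCAN oracle; 30 candidate peptides for the fitting
pipeline — sizes at which every check is exact or tightly bounded while
the whole suite runs in well under a minute. Superposition tolerances:
rigid-motion recovery ≤ 1e−8 Å RMSD, transform inverses to 1e−9;
orthonormality of rotations enforced at 1e−9. Angle comparisons use
circular differences wrapped to [0°, 180°] throughout; tie-breaks are
lexicographic everywhere a total order is needed.

## Known limitations

* No refinement: the pipeline stops at rigid placement; published
  post-refinement contact distances (3.2/4.4/5.1 Å) are out of scope.
* The Glu phosphomimetic convention is retained; phosphoserine is not
  parameterized.
* The anchor-orientation grid search ignores receptor flexibility and
  scores clashes by a hard 2.5 Å cutoff.
* Live structure-database searches are not reproduced; fragment mining
  operates on user-supplied coordinate directories, and published
  fragment-set sizes (520/217/68) are database-release dependent.
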