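# Methods

## Model

All areas are defined on *expanded spheres*: each atom's van der Waals
sphere inflated by the solvent probe radius (default 1.4 Å, an idealized
water). The SASA of an atom is the part of its expanded sphere not covered
by any other atom's expanded sphere; the contact surface area CSA(A, B) is
the part of A's expanded sphere lying inside B's, attributed with
fractional sharing when several occluders cover the same patch.

The estimator is point sampling. A fixed lattice of `n` unit directions is
shared by all atoms; a direction `u` of atom A corresponds to the surface
point `x_A + R_A u` with `R_A = r_A + r_probe`, and carries area
`(4π/n) R_A²`. Each point is tested against every overlapping neighbor's
expanded sphere (`|x − x_B| ≤ R_B`, closed inequality, so boundary points
count as buried — a stable, conservative tie-break of measure zero). The
set of neighbors containing a point is its *occluder group*. A group G with
`k` points buries a patch of area `k (4π/n) R_A²`, and contributes `1/|G|`
of that patch to CSA(A, B) for every B in G. Every lattice point therefore
carries total weight 1 — accessible, or split over its group — which makes
the conservation identity

    SASA(A) + Σ_B CSA(A, B) = 4π R_A²

exact in point-count arithmetic (tests assert it to 1e-9 relative in Å²,
the residual being only floating-point summation). The contact matrix is
asymmetric by construction: CSA(A, B) is measured on A's sphere and
CSA(B, A) on B's, and they differ whenever radii or local crowding differ.

Assumptions: rigid atoms as hard spheres; one conformation (PDB model 1,
one altloc per atom — highest occupancy, first on tie); no reentrant
(probe-rolling) surface — this is the accessible-surface convention of
Shrake-Rupley point counting, not a molecular (Connolly) surface.

## Sampling lattice

Directions come from a golden-section (Fibonacci) spiral, deterministic
for any count, with nearest-neighbor spacing uniform within a factor 2
(asserted for n ≥ 100). Two deliberate choices:

- The spiral is indexed symmetrically about the equator with the azimuth
  origin chosen so the lattice maps onto itself under a 180° rotation about
  the **x axis**. Mirror-symmetric atom arrangements (such as the
  shared-patch triple fixture) then bury exactly symmetric point sets, and
  symmetric contacts agree exactly rather than statistically.
- Oracle fixtures place atom pairs along a *generic* direction
  ((2, 3, 6)/7) rather than a coordinate axis. A cap centered on the
  lattice's symmetry axis sees boundary quantization errors in coherent
  pairs, roughly doubling the cap-count error (up to ~1.5% at 2000 points);
  in general position the measured worst-case error over the two-sphere
  grid is 0.65% at 2000 points.

Default point count is 2000 per atom (CLI `--points`). At that resolution
two-sphere SASA and CSA agree with closed-form spherical caps to better
than 1% over deep-to-moderate overlaps (buried fraction ≳ 0.15); accuracy
degrades for thin sliver contacts simply because few points fall in them
(the absolute error stays near one point weight). Mean oracle error
decreases from ~1.5% at 250 points to ~0.2% at 4000.

## Neighbor search

Candidate occluders are found with a k-d tree (`scipy.spatial.cKDTree`)
queried at `R_A + max_B R_B` and filtered to `|x_A − x_B| < R_A + R_B`;
results are returned in ascending serial order so group keys and all
downstream output are deterministic. Exactly coincident atom centers are
kept (with a warning) and occlude each other like any pair. The index is
validated against an all-pairs brute-force oracle on random systems.

## Operating modes

- **0** SASA only.
- **1** Intermolecular contacts: points are classified against *all*
  overlapping atoms (so a patch shared between a partner atom and a
  same-object neighbor is split with that neighbor), then intra-object
  entries are zeroed; BSA is the row sum over the partner's columns. This
  keeps mode 1 consistent with the conservation identity.
- **2 / 3** Intramolecular residue / atom contact maps over all pairs;
  mode 2 is exactly the residue aggregation of mode 3.
- **4** Points of each object are classified against atoms of *other*
  objects only. Contact surfaces need not be solvent accessible: a fully
  enclosed ligand retains its entire expanded-sphere area as contact
  surface (asserted exactly in the cage test), and receptor atoms stop
  sharing their buried patches with same-object neighbors. On the cage
  fixture this roughly doubles the receptor-to-ligand contact area
  relative to mode 1.

Whether the original description of these modes restricts occluders per
object in mode 1 is not decidable from its prose; the semantics above are
this package's documented choice.

## Differential-SASA comparison

`delta_sasa_csa` implements the conventional interface estimate
ΔSASA = Σ (SASA isolated − SASA in complex) for exactly two objects. With
a single occluder per interface atom it coincides with direct CSA (same
group tables, exact agreement); on the crowded fixture — one atom facing a
tightly overlapping pair — it undercounts the direct total by ~17%,
because partner-facing patches already buried within their own object are
invisible to ΔSASA. The fixture demonstrates the direction and mechanism
of the bias at desk scale; its magnitude on real complexes depends on
interface crowding.

## Radius tables

`pdb-united` (default for PDB input) is a united-atom set in the
Chothia/NACCESS tradition: tetrahedral C 1.87 Å, trigonal/aromatic C
1.76 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å, P 1.90 Å, element fallback 1.80 Å;
hydrogens are skipped by default. `mol2-typed` (default for Mol2) keys on
SYBYL atom types with explicit hydrogens (C.3 1.88, C.ar 1.77, N.* 1.64,
O.3 1.46, O.2 1.42, S 1.77, H 1.00, fallback 1.70), in the style of the
standard-radii sets used by common modelling software. Both ship as
plain-text files; `--radii <path>` substitutes a custom table in the same
format. Unknown keys fall back with a logged warning, never an error.

## Synthetic fixtures

The toy systems are geometric, not biochemical: they exercise occlusion
topology (single caps, shared patches, crowding, full burial, interleaved
cross-object-only overlaps, seeded random clusters with mixed radii drawn
from the united-atom range). Expected values are closed-form spherical-cap
areas computed independently of the engine. Passing these tests
establishes the correctness of the geometry and attribution machinery; it
does not certify radius-set fidelity on real structures, which depends on
the tabulated radii above. Test problem sizes — 40–50-atom clusters, 500-
or 2000-point lattices, a 22-geometry oracle grid — were chosen as the
smallest systems that exercise every code path and keep the full suite in
a few seconds.

## Output conventions

TSV matrices: first row column labels, first column row labels; labels are
`chain/resname resnum[icode]/atomname` (atom level) or
`chain/resname resnum[icode]` (residue level); values to 4 decimals, below
sampling noise and diff-friendly. Run parameters are echoed to a
`<prefix>.log` file and to REMARK 99 lines of PDB outputs; B-factor values
are capped at 999.99 (field width) with a warning. Identical invocations
produce byte-identical files.

## Limitations

- Sampled, not analytic: per-area relative error scales like the inverse
  of the number of points in the patch; thin slivers are noisy.
- No reentrant surface, no volumes, no free-energy or scoring layer.
- mmCIF and trajectory formats are out of scope (convert externally; batch
  runs feed one PDB per snapshot).
- Radii are tabulated heuristics; ions and exotic ligand atoms fall back
  to element-level values.
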