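# Methods

## The dimer order parameters

Each solute molecule carries, through its `MoleculeSpec`, the atom roles the
analysis needs: ring atoms (≥ 3, non-collinear) defining the aromatic plane,
an ordered pair of reference atoms defining the in-plane reference vector,
and labeled acceptor and hydrogen atoms.  For a pair of solutes:

* **r** is the minimum-image distance between ring centroids (orthorhombic
  boxes only; frames without a box are treated as non-periodic).
* **ψ** is the angle between the centroid-separation vector and the
  least-squares ring-plane normal of the *reference molecule*, chosen as the
  pair member with the lower molecule id.  The single-normal convention keeps
  ψ on the full [0, π] range (stacks on opposite faces map to 0 and π); a
  symmetrized variant averaging both members' angles is available via
  `psi_convention="symmetric"`.  The normal itself is the smallest-singular-
  value direction of the centered ring coordinates, sign-fixed by the cross
  product of the reference vector with the first ring bond so that rigid
  rotations rotate it rather than flip it.
* **θ** is the angle between the two reference vectors, in [0, π] by
  construction; θ ≈ 0 is parallel, θ ≈ π antiparallel.  The parallel/
  antiparallel polarity of stacked pairs is the sign of the reference-vector
  dot product (exact zero, a measure-zero tie, resolves to antiparallel with
  a logged warning).

Angles are computed in atan2 form (`atan2(|u×v|, u·v)`), which stays
well-conditioned at 0 and π where arccos loses half its digits — this is what
lets the rigid-motion invariance tests demand 1e-9.

Classification: *stacked* iff ψ is within π/6 of 0 or π **and** r ∈ [3.0,
5.5] Å (a window around the ~4 Å stacking distance); *coplanar* iff
|ψ − π/2| ≤ π/9 **and** the pair is hydrogen bonded (any hydrogen of one
molecule within 2.5 Å of any acceptor heavy atom of the other, both
directions, minimum image); everything else is *other*.  The 4 Å and 2.5 Å
values are physical constants of the system; the band halfwidths are
analysis choices exposed in `ClassifierThresholds`.

## Populations and maps

Dimers are all solute pairs with r ≤ 8 Å (config-exposed; the crystal motifs
of the idealized lattice live below ~6.5 Å).  A dimer is *near* the modifier
when both members have a minimum heavy-atom distance to any modifier heavy
atom ≤ 4 Å (an `either_member` rule is available); *bulk* when neither
member is within the cutoff; pairs straddling the boundary are excluded from
both populations, so near + bulk + straddling = all enumerated dimers.  The
bulk is the strict complement of the near rule — no buffer annulus is
carved out, which keeps the decomposition exact.

Histograms bin (r, θ, ψ) on half-open bins (last bin closed), r ∈ [2, 8] Å
in 0.2 Å steps and both angles in 5° steps, normalized as probability per
bin (not density).  Differential maps subtract the bulk 2D marginal from the
near marginal on identical edges (they sum to 0 by construction and are
antisymmetric under argument exchange).  Free-energy maps are −ln p in kT,
shifted so the occupied minimum is 0, with empty bins masked as NaN rather
than given a sentinel value.

## Crystal fingerprints and enrichment

The idealized lattice stacks solute copies *parallel* along z at 4.0 Å and
tiles each plane by two in-plane hydrogen-bond translations generated by the
same coplanar construction the solution generator uses, so lattice
extraction and solution generation cannot drift apart.  Extraction
enumerates all pairs under a 6.5 Å neighbor cutoff and clusters them by
greedy leader agglomeration in the tolerance-scaled max-metric
(tolerances (0.5 Å, 15°, 15°) by default, echoed into every report); each
cluster leader becomes a fingerprint with the cluster size as multiplicity.
Leader clustering guarantees closure: every lattice dimer conforms to the
fingerprint list extracted from it.

A solution dimer *conforms* when (r, θ, ψ) lies inside any selected
fingerprint box.  By default only coplanar fingerprints are selected,
because solution stacking is antiparallel while the crystal's is parallel —
the stacked fingerprint is available (`use="all"`) for sensitivity analysis.
The report gives p_near, p_bulk and their ratio (the enrichment);
modifiers are ranked by enrichment with ties broken by p_near, then name.

## Alignment, SDF, contacts

Frames are superposed on the modifier's ring atoms (rigid by construction;
side chains would flex in real data) with a proper-rotation Kabsch fit; the
per-frame post-alignment ring RMSD is reported.  The SDF is a cubic voxel
grid centered on the modifier's heavy-atom centroid; each voxel's value is
the fraction of frames in which at least one solute heavy atom falls inside
it — a dimensionless occupancy in [0, 1] matched to fraction-like isosurface
levels such as 0.4.  A density-normalized g(r)-style SDF is deliberately out
of scope.  Templating regions are 26-connected components (the most
permissive connectivity, stated explicitly) of super-threshold voxels,
reported with voxel count, bounding extents and volume.  The default voxel
edge is 0.5 Å; for isosurface-extent comparisons between modifiers a 1.5 Å
edge — comparable to the interatomic spacing — is the better choice, because
at finer resolution the occupancy of a point-atom model fragments into
per-atom islands instead of a contiguous molecular surface.

Contact frequency is, per (modifier hydrogen, solute acceptor label) cell,
the fraction of frames in which the minimum distance over all solute copies
is ≤ 2.5 Å; a per-copy-averaged variant is flag-switchable.  The conditional
split assigns a near dimer to the *contacting* set when either member has an
acceptor within the cutoff of one named modifier hydrogen (e.g. the
side-chain H13); the two sets partition the near population and feed r–θ
free-energy maps.  Hydrogen-bond mode timelines label each frame of a
tracked pair by the sorted set of (donor hydrogen, acceptor) contacts under
2.5 Å and count consecutive-frame label changes.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the chemistry producing it.  The solute is an idealized planar molecule —
six ring atoms on a 1.4 Å-circumradius hexagon, four acceptors (N3, O2, O6,
O8) at 2.4 Å, two donor hydrogens at 2.3 Å — because the analysis depends
only on planarity, a reference vector and labeled donor/acceptor sites.
Modifiers are chains of 1–4 edge-fused hexagons (in-plane extent strictly
increasing with size), two perimeter hydrogens, and an optional side-chain
hydrogen H13 reaching toward the first templating layer.

Default study conditions (`EnsembleSpec`): 30% of bulk pairs coplanar, the
rest stacked at N(4.0, 0.25) Å along the first member's normal with an 80%
antiparallel preference; angular disorder of 0.1 rad on all pair angles; a
hydrogen-bond criterion of 2.5 Å shared as one constant with the classifier.
Coplanar pairs are built by one of three in-plane hydrogen-bond modes (two
parallel modes — the ones the lattice realizes — and one antiparallel,
crystal-incongruent mode) at a 1.9 Å donor–acceptor contact; a pair whose
jittered geometry would violate the hydrogen-bond criterion or the 1.5 Å
heavy-atom overlap cutoff is resampled.  Solutes are placed as pairs whose
midpoints keep a 16 Å minimum-image exclusion (and, in templated frames, a
23 Å clearance from the modifier), so the dimers enumerated at r ≤ 8 Å are
exactly the generated pairs and recovered fractions obey clean binomial
statistics.

Templated ensembles hold one modifier per frame at the box center and one
near pair per frame whose conformer class follows the near coplanar fraction

    f_near = f_bulk + (f_max − f_bulk) · s / (1 + s),
    f_max  = f_bulk + (1 − f_bulk) · x² / (1 + x²),   x = extent / footprint,

a smooth, bounded, strictly increasing map of templating strength s and of
the modifier's in-plane extent relative to the solute footprint (4.8 Å) — a
small aromatic core cannot host two solute footprints side by side, which
caps how coplanar its first layer can become.  The class sequence over
frames is quota-sampled (a seeded permutation with exactly round(f_near·n)
coplanar frames), a variance-reduction choice that leaves per-frame
statistics exchangeable.  Near coplanar pairs lie flat 3.4 Å above the
modifier plane with the hydrogen-bond axis steered along the modifier's long
axis; near stacked pairs sit edge-on (plates perpendicular to the modifier
plane, stack axis horizontal) — the only stacked geometry for which *both*
members stay inside the 4 Å near region.  Anchors carry small positional
(0.1 Å) and yaw (0.03 rad) jitter, emulating a well-defined templating site;
conformational angles use the same 0.1 rad noise as the bulk, so at zero
strength the near ψ distribution is statistically indistinguishable from the
bulk by construction.  Frame 0 is emitted in the modifier body frame so
aligned analyses inherit its axes.  All randomness derives from one integer
seed through per-frame `SeedSequence` child streams; identical spec + seed
reproduces the ensemble bit for bit.

What the generator does **not** emulate: solvent and electrostatics, real
urate/flavin geometry, temporal correlation between frames (each frame is an
independent draw — timeline transition counts on synthetic data reflect
that), surface incorporation, and thermal breadth beyond the stated jitters.
Passing tests therefore demonstrate that the *analysis* measures what it
claims on ensembles with known structure — not that any particular real
modifier templates urate.

## Problem sizes and numerical choices

Statistical checks use 5000 bulk dimers (250 frames × 20 pairs) for fraction
recovery within 3 binomial standard errors, and 300-frame templated
ensembles per condition for enrichment orderings across templating strengths
(0, 2, 5) and modifier sizes (1, 2, 3); these sizes put the orderings
several standard errors apart while keeping any single analysis under ~15 s.
Degenerate inputs fail loudly rather than silently: collinear rings,
coincident centroids (r < 1e-9 Å), empty histograms and empty populations
all raise typed errors.  Coordinate round trips are exact to format
precision (1e-3 Å for XYZ/PDB via MDAnalysis); volumetric grids are OpenDX
with voxel-center convention, exact to 1e-6.  The proper-rotation constraint
in the Kabsch fit uses the standard determinant correction, so reflections
are never applied.

## Known limitations

Orthorhombic boxes only; one modifier per frame; binary trajectory formats
are out of scope (convert to multi-frame XYZ or multi-model PDB first).  The
packaged lattice is an idealization — fingerprints from a real crystal
structure can be substituted through the documented fingerprint file format.
The conforming-dimer enrichment compares populations within one ensemble;
comparisons across modifiers assume equal bulk conditions, which the
pipeline enforces by refusing to compare runs with inconsistent fingerprint
or selection settings.
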