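# Methods

`zernab` quantifies the shape and electrostatic character of
antibody–antigen interface surfaces with rotation-invariant 3D Zernike
descriptors (3DZD), and uses them for two analyses: classifying
antibodies by the broad type of antigen they bind (protein vs
non-protein) from their CDR surface alone, and scoring paratope–epitope
surface complementarity against size-matched decoy patches.  This note
records the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Surfaces and electrostatics

The solvent-accessible surface (SAS) is sampled Shrake–Rupley style: a
deterministic Fibonacci spiral of `points_per_atom` (default 256) test
points is placed on each atom's probe-inflated sphere (probe 1.4 Å) and
points falling inside any neighbouring inflated sphere are discarded.
The surviving points form the SAS point cloud; the surviving fraction
per atom gives its solvent-accessible surface area (SASA),

    SASA(atom) = retained/total × 4π(r + probe)²,

reported per residue in nm².  Relative SASA divides by a per-amino-acid
theoretical maximum (Tien-style reference table, configurable).  The
spiral is seedless, so surfaces are reproducible; because the spiral is
fixed in the lab frame, SASA estimates of a rotated structure agree only
to sampling noise (a few percent at 256 points/atom).

Every surface point of a residue carries one electrostatic value — the
per-residue convention used throughout.  The default potential is a
screened Coulomb sum over all partial charges, evaluated at the
residue's side-chain centroid:

    φ(R) = Σ_j q_j exp(−d_j/λ) / (ε d_j),   λ = 8 Å, ε = 80,

with distances clamped below 1 Å to avoid the self-term singularity.
This is a deliberately simple surrogate for a generalized-Born or
Poisson–Boltzmann calculation: the pipeline binarizes the potential into
positive/negative voxel channels, so only the sign pattern matters, and
the sign pattern is dominated by which charged residues are nearby —
which the screened Coulomb sum reproduces.  Users with externally
computed per-point potentials can inject them (`per_point_file` mode).
Where a residue's potential "is evaluated" is not uniquely defined;
the side-chain centroid choice is documented, not asserted as equivalent
to any particular reference implementation.

## Patches

All patch types are residue-level selections of a surface point cloud.

* **CDR patch** — one combined patch over the six hypervariable loops,
  selected by Chothia position ranges (L1 24–34, L2 50–56, L3 89–97,
  H1 26–32, H2 52–56, H3 95–102; configurable).  Insertion-coded
  residues belong to the range of their base number.  Residues present
  only as HETATM records (e.g. hapten ligands) are excluded by default.
* **Native epitope** — antigen residues whose minimum inter-atomic
  distance to any antibody atom is below a cutoff: 6 Å for the
  geometric epitope, 15 Å for the electrostatic one.
* **Pivot residue** — the patch residue with the lowest mean
  representative-atom (Cα, else first atom) distance to all patch
  residues.
* **Paratope shells** — the centerpoint *b* is the centroid of the 10
  antibody atoms closest to any antigen atom; a shell of fraction *f*
  keeps the ⌈f·N⌉ CDR surface points nearest *b*.  Shells nest
  monotonically in *f*.
* **Decoy epitopes** — each decoy starts from a pivot drawn uniformly
  among solvent-exposed residues with SASA inside a window (default
  0.48 ± ½·0.33 nm², the distribution observed for native epitope
  pivots on real antigen surfaces), grows by repeatedly adding the
  exposed residue (relative SASA > 0.2) nearest to the current patch,
  and stops at the first crossing of the native epitope's total SASA.
  Decoys overlapping the native epitope by more than 50% are rejected
  and resampled (budget 1000 attempts per decoy); generation is
  deterministic under an explicit seed.  Overlap is measured as
  |D∩N| / min(|D|, |N|), the strictest of the common conventions.
  "Similar global SASA" is operationalized as first crossing; a
  tolerance band would be an alternative reading.  Decoy pivots may
  coincide with the native pivot unless the overlap cap rejects them.

## Voxelization

A patch is mapped onto a `dim³` grid (default 128; the synthetic
experiments use 64) spanning [−1,1]³:

1. Points are translated to their **centroid** and uniformly scaled so
   the farthest point sits at radius 0.8 — keeping the support away from
   the unit-sphere boundary where the basis is truncated.  The centroid,
   not the bounding-box center, is the expansion origin: it is
   rotation-covariant, which is what makes the invariants reproducible
   when the same patch arrives in a different pose.  (A bounding-box
   center moves relative to the cloud under rotation and destroys
   invariance at the tens-of-percent level.)
2. **Shape channel**: voxel value 1 iff the voxel center lies within
   1.7 voxel-edge lengths of any surface point.  The reach is in voxel
   units deliberately — after unit-sphere normalization an Ångström
   reach would mean different things for different patch sizes, and a
   voxel-edge reach gives a resolution-consistent shell (the implied
   surface area, on-voxels × edge², is stable under grid refinement;
   the occupied volume fraction is not, since the shell thins with the
   voxel edge).
3. **Electrostatic channels**: each voxel takes the mean electrostatic
   value of the points it strictly contains (0 if none), then the mean
   is split by sign into two non-negative channels.  In the default
   `binary` mode the channels are indicators (1 where the mean is
   positive/negative); `magnitude` mode keeps the absolute values
   instead.  The two channels are disjoint by construction.  Strict
   containment (rather than the shape channel's reach neighbourhood)
   defines "enclosed"; the reach-based alternative is a documented
   possibility, not implemented.

## Zernike moments and invariants

A channel f on the unit ball is expanded in the orthonormal basis
Z_nlm = R_nl(r)·Y_lm(θ,φ) with complex spherical harmonics
(Condon–Shortley phase) and radial polynomials R_nl (n−l even, l ≤ n)
orthonormalized against weight r² on [0,1], positive leading
coefficient.  The moments are

    C_nlm = ∫_{|r|≤1} f(r) conj(Z_nlm) dr,

and the rotation invariants are the per-(n,l) norms

    D_nl = sqrt( Σ_{m=−l..l} |C_nlm|² ).

The norm includes the square root (the standard Euclidean norm of the
coefficient vector); an elementwise-squared variant would rescale
distances monotonically without changing the orderings that the
classifier and the decoy ROC consume.  At order 20 there are 121
invariants, at order 10 there are 36 (Σ_n ⌊n/2⌋+1).  Vectors are ordered
lexicographically in (n,l), so a lower-order descriptor is an exact
prefix of a higher-order one — the order sweep reuses one order-20
computation.

The production path accumulates geometric (monomial) moments of the
voxel field by separable tensor contractions — O(order·dim³) — and
combines them with a cached monomial-coefficient table of the basis.
Radial coefficients come from exact rational Gram–Schmidt (no floating
cancellation in the table itself); the angular part is the Cartesian
expansion of the solid harmonics r^l·Y_lm.  Only m ≥ 0 is computed;
m < 0 follows from conjugate symmetry of moments of a real field.
Orders above 46 are refused: beyond that the float64 monomial route
degrades.

An independent oracle (`moments_oracle`) evaluates the basis pointwise —
Jacobi-polynomial radial part, SciPy spherical harmonics — and Riemann-
sums over voxel centers inside the unit ball.  The two routes share no
coefficient code and agree elementwise to ~1e−12 on random grids; the
test suite enforces 1e−6.

Measured invariance at dim 64, order 20 (enforced in tests): rotation +
translation of the input cloud changes D_nl by < 5% relative L2
(discretization noise only; typically 1–3%); pure translation and
uniform scaling are exact by construction of the unit-sphere fit.

## Comparison metrics

Descriptor vectors are compared by cosine distance
D(x,y) = 1 − x·y/(‖x‖‖y‖).  For two patches A, B with descriptor triples
(shape, elec+, elec−):

* similarity: shape vs shape; electrostatics as the mean of the
  same-sign channel distances;
* complementarity: shape vs shape (rotation invariance makes a surface
  and its mold yield near-identical invariants); electrostatics as the
  mean of the **cross**-sign channel distances, so facing surfaces with
  opposite charge patterns score as complementary.

A patch with an empty electrostatic channel (apolar) has no defined
cosine distance; the metrics raise rather than returning NaN, with
guidance to exclude the patch.

For the decoy experiment, the distances of a paratope to its native
epitope and to each decoy are z-scored per complex over the combined
{native + decoys} population (a decoys-only reference is available as an
option) and pooled into a native-vs-decoy ROC with −z as the score; AUC
is computed by the Mann–Whitney rank identity.  Pooling across complexes
is the default aggregation; per-complex AUC averaging is available.

## Classification

For each antibody, the 5% most similar CDR surfaces (leave-one-out,
k = ⌈0.05·(N−1)⌉, distance ties broken by entry id) are its neighbour
set, and N_pb — the number of protein-binding antibodies in that set —
is the score.  Shape and electrostatic counts combine as
N̄_pb = A·N_pb^elec + (1−A)·N_pb^shape with A ∈ [0,1] (default 0.4).  An
antibody is called protein-binding when its count strictly exceeds the
label-blind expectation Ex[N_pb] = k·N_prot/N_tot; the expectation is
scaled by the neighbour-set size k so that it lives on the same scale as
the counts.  ROC AUC uses the counts directly as scores.  The weight ×
order × shell-fraction sweep truncates stored order-20 descriptors,
never recomputing moments.

## Synthetic data: what it emulates, and what it does not

The generators make every stage testable without structure downloads.

* `make_patch` builds spherical caps, ellipsoid caps, and Gaussian-bump
  height fields.  Planar positions are **scattered, not gridded**: real
  SAS point clouds do not align with the voxel lattice, and a regular
  grid aliases against it, inflating rotation-invariance noise several-
  fold.  Points group into 5-point pseudo-residues with one
  electrostatic value each, emulating the per-residue convention.
* `make_complementary_pair` produces a bumpy patch and its mold — same
  contact geometry (offset by an optional gap), inverted charges —
  re-posed by a random rigid motion so that only invariant descriptors
  can reveal the match.
* `make_classification_dataset` encodes the classical geometric prior
  that protein-binding antibodies have flat combining sites while
  small-antigen binders form concave pockets: the "protein" class is
  nearly flat (bowl radius 80 Å) with balanced dipolar charges, the
  "nonprotein" class is strongly concave (radius 8 Å at full contrast)
  with single-draw random charges.  A `curvature_contrast` dial scales
  the separation; at 0 the classes are identically distributed and the
  classifier sits at chance.
* `make_toy_complex` builds a 60-residue single-sphere-per-residue
  antigen shell (1.9 Å spheres on a 10 Å sphere, interior sealed by a
  core atom) whose residues expose ~0.35–0.55 nm² each — the exposure
  range typical of surface residues on small protein antigens, and the
  range the decoy pivot window expects — plus Chothia-numbered H/L
  chains whose CDR cap faces the antigen pole at a 5 Å gap, inside the
  6 Å epitope cutoff.

Passing the synthetic benchmarks shows that the machinery — surface →
patch → voxels → invariants → metrics — preserves and exposes the
geometric and electrostatic signal it is designed to carry.  It does not
show field performance on crystallographic antibody–antigen complexes:
the synthetic classes are far cleaner than real CDR surface variation,
the charge patterns are idealized, and pseudo-residues have no side-chain
chemistry.  Reproducing the dataset-level numbers reported for curated
antibody sets requires downloading those structures and is outside the
test surface.

## Problem sizes and defaults

The synthetic experiments run at dim 64 and order 20 (121 invariants):
the complementarity benchmark uses 30 mold pairs with 10 decoy patches
each; the classification benchmark uses 25 antibodies per class; decoy
validity is checked with 20 decoys at 3 seeds on the toy complex.  These
sizes give stable AUCs (±0.02 across seeds) while keeping a full run in
tens of seconds.  The voxel grid default for single-patch description is
128, matching the resolution commonly used for molecular surfaces.

## Known limitations

* The electrostatic surrogate reproduces sign structure, not magnitudes;
  `magnitude`-mode voxelization is only meaningful with externally
  supplied potentials.
* SASA from 256 spiral points per atom is quantized (ties across
  symmetric residues are common); increase `points_per_atom` where exact
  ranking of residue exposure matters.
* Decoy growth uses representative-atom distances between residues;
  with multi-atom residues a minimum heavy-atom rule would differ
  slightly near patch borders.
* The classifier is strictly two-class (protein vs non-protein); finer
  antigen classes are kept only as metadata.
* No docking search: complementarity is scored on given pairings only.
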