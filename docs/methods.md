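# Methods

## The model

`zpocket` scores the geometric compatibility between a small molecule and a
candidate binding region on a protein surface. The working hypothesis is
that two surfaces that fit each other share their shape, so a compact,
rotation-invariant summary of local surface shape lets ligand-pocket
compatibility be read off as a distance between summaries.

The summary is the 3D Zernike descriptor. A surface patch (a set of
attributed surface sample points) is centered on its centroid, scaled into
the unit ball, rasterized to a voxel field `f`, and expanded in the
orthonormal basis

    Z_nlm(r, θ, φ) = R_nl(r) · Y_lm(θ, φ),      0 ≤ l ≤ n,  n − l even,

with complex orthonormal spherical harmonics (Condon–Shortley phase) and
the radial polynomials

    R_nl(r) = √(2n+3) · r^l · P_k^(0, l+1/2)(2r² − 1),   k = (n−l)/2,

expressed through shifted Jacobi polynomials so that
∫₀¹ R_nl R_n'l r² dr = δ_nn'. The moments C_nlm = ∫ f · conj(Z_nlm) dV are
approximated by a Riemann sum over voxel centers inside the ball, and the
descriptors are the per-(n, l) norms over the magnetic index,

    D_nl = √( Σ_m |C_nlm|² ),

which are exactly invariant under rotation of the underlying field and, by
centroid centering, under translation of the input points. At the default
expansion order n_max = 10 there are 36 invariants. Complementarity between
two descriptor vectors is the Manhattan distance Σ |D_i − D'_i| (lower =
more compatible).

The orthonormality of the implemented basis is not taken on faith: the test
suite integrates all 286 × 286 basis inner products up to order 10 by
Gauss–Legendre quadrature (radial and polar) with a trapezoid rule in
azimuth, and requires the Gram matrix to equal the identity to 1e-6
(observed: ~1e-14).

## Pipeline

1. **Structures.** PDB files are parsed with gemmi; polymer chains merge
   into one protein entity, each remaining HETATM residue becomes a ligand
   entity. Waters and common additives (HOH, DOD, NA, CL, SO4, GOL, PEG,
   EDO — configurable) are dropped. Altloc groups keep the
   highest-occupancy conformer (ties by altloc letter).
2. **Surfaces.** Either a DMS surface file is parsed (each surface point
   resolved to its generating atom), or an internal solvent-excluded-surface
   approximation is built: sample each atom's solvent-accessible sphere
   (radius vdW + probe, probe 1.4 Å, ~3 points/Å²), discard points inside
   any other atom's inflated sphere, retract survivors by the probe radius
   onto the vdW envelope. Sampling directions live in a structure-intrinsic
   PCA frame with moment-fixed signs, so the builder is equivariant:
   rotating the structure rotates the cloud (same seed). For highly
   symmetric inputs the frame degenerates to the identity and equivariance
   is no longer guaranteed; molecular structures are generic enough in
   practice.
3. **Patches.** The binding site (BS) is the set of residues whose Cα lies
   strictly within 6 Å of any ligand atom. Decoys (BSD) are residue-centered
   regions grown at every surface-exposed Cα; the radius R* is picked from
   the 6–20 Å grid (1 Å steps) to minimize |mean region size − |BS||, ties
   to the smaller radius. Decoys centered inside the BS are excluded by
   default (`keep_overlapping` restores them). Residue-centered candidate
   pockets use a 9 Å Cα–Cα radius.
4. **Scoring.** Within one complex, the BS and all decoy patches are
   described and their ligand distances standardized to Z-scores with the
   population standard deviation over all rows. A strongly negative BS
   Z-score marks a specific interaction. Across a dataset, associations are
   called when a receptor's best-pocket distance falls strictly below the
   empirical 5% quantile (type-1, smallest order statistic, no
   interpolation) of a background of non-association distances — the
   threshold is always recomputed from the supplied background, never
   hard-coded. An optional per-residue quality gate (e.g. model-confidence
   scores, lower = better) requires the best patch's mean quality to fall
   inside a supplied first-quartile bound.

## Numerical choices

- **Voxelization.** Default grid 64³ (32³ in the fast tests and the
  benchmark), fill fraction 0.7 so the farthest point sits at radius 0.7,
  leaving headroom against truncation at the ball boundary. Two
  rasterization modes exist. `binary` marks every voxel containing ≥ 1
  point — simple, but the occupied shell's thickness depends on the
  surface's orientation relative to the lattice, and measured descriptor
  deviations under rotation reach 3–7% at 64³. `density` deposits unit
  mass per point onto the 8 neighboring voxel centers with trilinear
  weights and normalizes total mass to 1; mass is exactly conserved under
  rotation and measured deviations drop to ~0.05%. The descriptor pipeline
  therefore uses `density`; `binary` remains available and contract-tested.
- **Scaling is per patch.** Each patch and ligand is normalized to its own
  extent, so descriptors capture shape only, not absolute size. Two
  surfaces of identical shape but different size are indistinguishable;
  size-matched decoys keep this from trivializing the benchmark. A common
  scale for a patch-ligand pair can be imposed by the caller where
  size-sensitivity is wanted.
- **Order cap.** Orders above 20 trigger a warning; the double-precision
  evaluation of the high-degree radial polynomials degrades beyond that.
- **Strict inequalities** at every threshold (6 Å rule, 9 Å patches,
  association threshold), and population (N) standard deviation in the
  Z-score; at typical decoy counts (~60/complex) the N vs N−1 difference is
  immaterial, and the choice is recorded in output headers.
- **Ties.** Best-pocket ties break by patch-id order and are flagged;
  radius-grid ties break to the smaller radius; quartile boundary ties fall
  to the lower (better) stratum.

## The synthetic benchmark

`synthetic.make_toy_complex` builds what the scoring question needs and
nothing more: ~80 single-atom pseudo-residues on a spherical shell (~10.7 Å
radius, spacing ~4 Å, Gaussian positional jitter 0.3 Å), a ligand blob of
15 atoms with a ~3 Å envelope, and a pocket carved as the ligand's negative
imprint — wall residues on a sphere of radius ligand + 2 Å contact gap
around the ligand center, restricted to directions inside the protein body,
with clashing shell residues removed. The `complementarity` parameter in
[0, 1] blends the pocket wall between the perfect imprint (1) and its flat
projection onto the shell (0⁺); at exactly 0 the ligand is parked far away
and no ground truth exists. Residue names are drawn from a background
amino-acid composition so frequency analyses are exercisable. All geometry
derives from one integer seed; fixtures regenerate bit-identically.

The benchmark (50 seeded complexes, complementarity 1.0, noise 0.3 Å,
descriptors at 32³/order 10) labels the BS patch positive and the decoy
patches negative and computes the ROC over pooled ligand distances plus the
per-complex BS Z-scores. What it shows: the full pipeline — surface,
patches, decoy size-matching, descriptors, scoring — picks a geometrically
complementary pocket out of dozens of same-size convex decoys essentially
every time. What it does not show: performance on real receptor-ligand
chemistry. The toys are smooth, near-spherical, single-chain caricatures;
real pockets are shallower, lined with side chains, and separated from
decoys by far less geometric contrast, so real-data discrimination is
necessarily weaker than the near-perfect AUC on the toys.

## Known limitations

- Descriptors are size-blind under the default per-patch scaling (above).
- The internal surface builder approximates the solvent-excluded surface by
  retracted sphere sampling; it does not reproduce DMS output bit-exactly,
  and reentrant (probe-contact) surface regions are represented only by
  their atom-sphere boundaries. Descriptor-level results should be reported
  together with the surface source.
- Buried residues generate no surface points and therefore cannot anchor
  decoys; peptide-ligand-scale pockets connected to bulk solvent are
  represented poorly by a single patch.
- The quality-gate plumbing ingests per-residue scores as opaque tables; no
  model-confidence estimation is performed here.
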