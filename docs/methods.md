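# Methods

## The compliance score

The EDC (electron-density compliance) score asks a deliberately coarse
question: does a rigid pose of the mobile protein sit inside the
experimental density, ignoring atom-scale detail?  Two design elements
enforce the coarseness:

1. **Moving-average smoothing.** The map is filtered with an unweighted
   mean over a cubic window of 5 cells per axis (125 cells).  At box edges
   the mean is truncated to in-bounds cells rather than zero-padded, so a
   constant map stays constant everywhere; zero padding would darken edges
   and penalize poses near the box boundary for a reason that has nothing
   to do with density.  Smoothing is implemented with per-axis cumulative
   sums and exact in-bounds counts, and is checked cell-for-cell against a
   triple-loop oracle (agreement to 1e-12).
2. **Cα-only sampling.** The smoothed map is sampled at the mobile
   protein's Cα positions only and averaged.  Sampling is
   nearest-voxel — the value of the cell whose center is closest to the
   atom.  A trilinear mode exists behind a flag for sensitivity checks;
   after a 5-cell smoothing the two differ negligibly, which is the point
   of the smoothing.

Scoring a raw (unsmoothed) grid is a usage error, not a silent fallback:
the score is only meaningful after the filter.  Map values are never
rescaled on read, so EDC inherits the deposited map's arbitrary units.

**Out-of-bounds convention.** Cα positions outside the grid contribute 0.0
to the average and are tallied; callers get the out-of-bounds fraction
alongside the score (a pose fully outside the box scores exactly 0 with
fraction 1).  Whether the experimental setting ever produced out-of-box
atoms is unknowable from the map alone; counting them as zero density is
an assumption, and the reported fraction is what lets a user notice when a
score is meaningless for that reason.

## Grid conventions

Grids are stored in canonical Cartesian x,y,z index order regardless of
the file's MAPC/MAPR/MAPS axis permutation (gemmi performs the reorder;
reading is round-trip tested against raw struct-packed files in all axis
orders).  The physical `origin` is the center of cell (0,0,0), taken from
the ORIGIN header words when present and otherwise reconstructed as
start-index × voxel size.  Indexing is 0-based; the center of cell
(i,j,k) is `origin + (i,j,k)·voxel`.

## The common reference frame

All pairwise pose metrics presuppose one frame.  Each complex is placed by
a single rigid transform fitted on the *anchor* protein only: heavy atoms
of reference-chain residues having any heavy atom within `heme_radius`
(default 8 Å) of the reference heme Fe, paired to anchor atoms by residue
number + atom name (with a sequence-alignment remap of residue numbering
when the anchor is a homolog numbered differently).  The superposition is
unweighted Kabsch — SVD with the determinant sign correction, so
reflections are excluded — and requires ≥ 3 non-collinear pairs.  The
exact "atoms surrounding the heme" set is a parametrization, exposed as
config; the 8 Å heavy-atom rule is the default, and downstream EDC
tolerances are wide enough that reasonable radii give the same
conclusions.

Fitting on the anchor and never refitting per pair is what gives the
comparison table its meaning: after common placement, the mobile protein's
center-of-mass distance (upper triangle) and Cα RMSD (lower triangle)
between two poses measure *where the mobile protein sits*, not how its
fold differs.  Cα pairing across homologs (e.g. spinach vs poplar
plastocyanin, same length, interface-conserved) uses residue-number
correspondence when at least half the residue numbers are shared, and a
global identity-scored sequence alignment otherwise; unpaired residues are
dropped.  Centers of mass use all heavy atoms, mass-weighted by default
(an unweighted geometric-center mode exists); waters and hydrogens are
excluded from everything.

For a multi-heme anchor (a whole cytochrome *b₆f*), the Cu–Fe diagonal can
take the Fe nearest the Cu (`multi_heme="nearest"`); the default is strict
and treats multiple Fe candidates as an error listing them.

## Ensembles and trajectories

The central structure of an ensemble is the member with minimum mean Cα
RMSD to the other members, self-distance excluded (including it cannot
change the argmin, since it adds the same zero to every row); ties break
to the lowest index for determinism.  Spread is reported as the maximum
pairwise RMSD plus the max and mean RMSD from the central member to the
rest.  Trajectory frames (multi-model PDB or file lists; native MD formats
are out of scope) are each aligned to the reference and EDC-scored,
yielding a time series with a default time base of frame-index × 1 ns;
series smoothing is a centered truncated-window moving average (a
20-sample window at 1 ns sampling = 20 ns smoothing).

## The synthetic study system

The generator provides the statistical shape of the real inputs without
downloads:

* **Toy complex.** The mobile protein is a self-avoiding smoothed random
  walk of 99 Cα pseudo-atoms (the mature plastocyanin length) at the
  canonical 3.8 Å spacing, biased toward its running centroid so it stays
  globular; one Cu rides 2 Å off its first residue.  The anchor is a
  120-residue trace with a heme-like Fe 3 Å off its midpoint (so several
  anchor residues surround the Fe — enough to define the alignment frame).
  The mobile protein is placed with the Cu 8–14 Å from the Fe, inside the
  functional < 15 Å regime.
* **Simulated map.** Each atom contributes a unit-amplitude Gaussian of
  width `kernel_sigma` (default 2.0 Å — protein-shaped blobs rather than
  resolved atoms, as in a mid-resolution map); the box uses the
  experimental 0.86 Å voxel and 3σ padding; seeded Gaussian noise
  (default σ = 0.05 map units, a few percent of the density peak) is
  added.  The kernel is evaluated as an exact separable outer product.
  Deliberately absent realism: atomic form factors, B-factors, CTF,
  solvent, and the anchor protein's much larger true mass — so passing
  tests demonstrate the *machinery* (geometry, sampling, ranking), not
  quantitative agreement with experimental density values.  Synthetic EDC
  values are accordingly on a different scale (order 1) than scores on a
  deposited map.
* **Perturbed ensembles.** A pose perturbation rotates the mobile subset
  about its center of mass around a uniform random axis and translates it
  along a uniform random direction; the anchor never moves.  Ensembles
  draw per-member magnitudes as the given scale jittered ±25% (uniform),
  directions uniform — a shell-like cloud with a well-defined spread and
  the true pose at its center of symmetry.  The jittered-shell choice is
  deliberate: a magnitude distribution with mass near zero produces
  members statistically indistinguishable from the true pose, which can
  then usurp the central-structure slot by chance; a bundle with a
  characteristic spread keeps the unperturbed pose the ensemble centre
  almost surely, which is the regime central-structure selection is meant
  to be exercised (and tested) in.

All generators are pure functions of (spec, seed) with per-operation
random streams; repeated calls are bit-identical.

## Numerical choices

* Smoothing sums via per-axis cumulative sums; exact integer in-bounds
  counts; window 1 returns a copy (bit-exact identity).
* Kabsch degeneracy: < 3 pairs or centered rank < 2 (collinear) raises a
  geometry error rather than returning an arbitrary rotation.
* Rotation validity asserted on construction (orthogonality and det = +1
  to 1e-8).
* Table values are kept full precision internally; the Table-style
  formatter rounds distances to 1 decimal and EDC to 3, only at output.
* PDB round trips preserve coordinates to the format's 1e-3 Å precision;
  maps are written as 32-bit floats (the MRC mode-2 precision).

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
system: maps of roughly 70³ cells at 0.86 Å, 99-residue mobile proteins,
ensembles of up to 20 members, 50–300-seed property checks, and 200-trial
recovery experiments — sizes chosen so a full run takes seconds while
keeping every statistical check comfortably away from its threshold.

## Known limitations

* The published EDC values can only be reproduced with the deposited map
  and coordinate entries on disk (see README); the offline suite
  demonstrates the method's properties on synthetic data instead.
* The heme-surrounding fit-atom set is a radius parametrization of a set
  the original analysis defined by enumeration; alignment-sensitive
  quantities inherit that freedom (EDC is insensitive to it by
  construction; sub-Å pairwise distances are not guaranteed to be).
* Nearest-voxel sampling quantizes at the half-voxel scale; use the
  trilinear mode to check sensitivity if a map's voxel is coarse.
* No density-based docking, map sharpening, masking, FSC or correlation
  scoring — the compliance score exists precisely because correlation
  coefficients answer a different question.
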