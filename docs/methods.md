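# Methods

## The system being emulated

A WDPU nanoparticle is an amorphous assembly of block-copolymer chains.
Each chain alternates urethane-bearing hard segments with polyester soft
segments; four repeating units carry two soft-segment slots each, so a chain
holds eight soft segments filled 6:2 with PCL and PLA for the 3:1 molar
compositions shipped as `PCL75DL25` and `PCL75LL25`.  The PLA slot positions
within a chain are drawn from the seed (slot order is not constrained by the
chemistry).  The D,L- vs L-lactide distinction is represented **only** as
preset parameter differences (chain stiffness, packing targets); no
stereochemistry is modelled, and the claim that chirality *causes* the
structural differences is not re-derived here — the presets simply let each
composition be calibrated to its own reference statistics.

### Resolution and particle counts

Particles are united heavy atoms (CH, CH₂, CH₃ beads and explicit C, N, O)
plus explicit polar hydrogens on the urethane nitrogens — the minimum that
preserves masses, van der Waals radii, segment labels and
donor–hydrogen–acceptor geometry.  Soft segments are chemically explicit:
18 PCL repeats (−O(CH₂)₅CO−, 8 beads each) or 28 PLA repeats (−OCH(CH₃)CO−,
5 beads each) per segment, matching ~2,000 Da diol blocks.  The junction
chemistry between the two marker nitrogens is not public in transcribable
form, so each junction is `N–C–(pad…)–C–N` with generic CH₂-mass pad beads,
sized so the chain meets an exact particle-count target (3,070 by default:
9 junctions × 206 pads + 1,216 explicit particles).  Particle-count
arithmetic (10 chains → 30,700; 2×2×2 replication → 245,600) is therefore
exact, while the chain molar mass is only approximate — a deliberate trade.

Every soft segment is flanked by two junction nitrogens; these are the
end markers for segment and whole-chain end-to-end distances.  Hard-segment
particles inherit the block label (PCL or PLA) of the soft segment they
precede, which makes the three-way hydrogen-bond classification
(PCL–PCL / PLA–PLA / PCL–PLA) total — every donor and acceptor has a block
label.

## Chain conformations

The backbone follows a correlated random walk: step direction
`d' ∝ κ·d + u` with `u` isotropic, bond length b = 1.5 Å.  The persistence
parameter κ maps to a per-step mean cosine `c = κ/√(1+κ²)`; the exact
finite-chain law

    <R²> = N b² [ (1+c)/(1−c) − 2c(1−c^N)/(N(1−c)²) ]

interpolates from the freely-jointed value N·b² (c = 0) to the contour
length squared (c → 1) and is inverted by bisection during calibration.

Two sampling modes exist.  *Free* walks are used for the statistical-physics
checks (freely-jointed-chain law, rigid-rod limit, monotonicity in κ).
*Bridged* walks — the default when packing assemblies — add a linear drift
of at most `|ΔR|/N` per bond (≪ 0.1 Å here) so the end-to-end vector equals
a per-chain target drawn as `rms(κ)·N(1, 0.02)`.  The bridging exists
because equilibrated-nanoparticle ensembles report extremely narrow
chain-statistic spreads (fractions of an Å on ~100 Å means, since they are
time averages over one configuration), while a free walk has a ~42 %
Maxwell spread per chain; with only 10 chains × 5 replicates the free-walk
mean estimator would be dominated by sampling noise rather than by the
quantity being measured.  The 2 % per-chain spread is the generator's
stand-in for residual chain-to-chain variation.

Intra-chain excluded volume is **off by default** (a hard-sphere constraint
would bias exactly the end-to-end statistics the calibration relies on) and
available as an option that re-draws walks until non-adjacent backbone beads
clear 0.8× their summed radii.  Chain centers are kept ≥ 2 Å apart.

## Assembly packing

The target radial mass profile is a plateau to `core_radius` (50 Å default)
decaying linearly to zero at `decay_radius` (115 Å default).  Chain centers
are placed at stratified radii drawn from the pdf ∝ shape(r)·r² in random
directions, then (i) the mass-weighted mean center is zeroed and (ii) the
radii are rescaled so the mass-weighted RMS center radius equals the
profile's analytic RMS radius exactly.  This conditioning removes the
O(1/√n_chains) placement noise from assembly-level shape statistics —
mirroring the near-deterministic assembly-level error bars of an
equilibrated particle — while keeping all angular and stratified-radial
randomness.  Shape anisotropy is applied as per-axis coordinate scale
factors at the end (isotropic by default).

`core_density` (default 0.60 Da/Å³ ≈ 1 g/cm³) is used for a close-packing
feasibility check: the plateau density implied by the total mass and the
profile shape must not exceed 0.74 × the mean bead density, otherwise the
configuration is refused.  The realized plateau level follows from total
mass and profile shape (both cannot be fixed independently); the profile's
absolute units are therefore reported but validated only qualitatively.

The generator's ground truth (per-chain end-to-end values, planted
hydrogen-bond triples, the profile's analytic R_g) is bookkeeping recorded
at construction, never re-measured.

### Planted hydrogen bonds

Planting repositions chosen donor–H–acceptor triads to a controlled
geometry (d(D,A) = 2.9 Å, near-linear D–H…A by default), builds decoys that
violate exactly one criterion (distance 3.1 Å with good angle, or 2.9 Å
with ~80° deviation), and then sweeps every *other* donor–acceptor pair
beyond the distance cutoff so the planted list is the complete ground
truth.  When two planted triads collide, the offending triad is translated
rigidly.  Acceptors within two covalent bonds of a donor are never planted,
matching the detector's bonded-pair exclusion.

## Descriptors — conventions and numerics

* **Weighting**: center of mass, R_g and the inertia tensor are
  mass-weighted (a `weights="number"` option exists); with near-uniform
  bead masses the difference is far below the acceptance tolerances.
* **Eccentricity** uses the linear form 1 − I_min/I_avg (not the
  square-root variant); collinear input (I_min ≈ 0) is rejected as
  degenerate rather than reported as ≈ 1.
* **SASA**: deterministic Fibonacci point sets (960 points default) on
  probe-extended spheres; the reference sphere for `A_m/A_s` has the same
  *accessible volume*, estimated by counting regular-grid points inside the
  union of extended spheres (spacing adaptive, ≥ 0.4 Å).  The convention is
  recorded in the report metadata.
* **Radial profile**: 5 Å shells about the center of mass (configurable);
  mass is conserved exactly by construction; both mass and number density
  are emitted, mass density primary.
* **RDF**: 0.5 Å bins (all reference peak positions sit at odd multiples of
  0.25 Å, i.e. at centers of 0.5 Å bins).  Finite-cluster normalization:
  shell volume × mean pair density in the minimal enclosing sphere,
  corrected by the exact uniform-sphere pair-overlap factor
  1 − 3x/4 + x³/16 (x = r/R) so an ideal gas gives g ≈ 1 at every r.  Raw
  counts are always retained so any other normalization is recoverable.
  Peak searches ignore the cluster rim (x > 1.5) where the expected count
  vanishes and single stray pairs produce unbounded g.  Chain/segment RDFs
  use mass-weighted centroids by default; an all-atom mode exists.
* **Hydrogen bonds**: d(D,A) ≤ 3.0 Å (inclusive) and D–H…A within 30° of
  linearity, both configurable.  The "angle" is the deviation from 180° at
  the hydrogen.  Donor/acceptor identity comes from topology labels
  (urethane N–H donors; carbonyl and ester O acceptors), never from element
  inference.  Acceptors ≤ 2 covalent bonds from the donor are excluded
  (they belong to the same urethane group).  The spatial-grid search is
  exactly equivalent to the exhaustive scan (tested against a brute-force
  triple loop).
* **Ensembles**: averages are over R independent seeded replicates
  (default 5), reported mean ± sd, emulating time-window ensemble averaging.

## CVFF energy evaluation

All terms are evaluated per the consistent-valence functional form with
user-supplied parameter tables; cross terms default to zero when absent.
Non-bonded exclusions are 1–2 and 1–3, with 1–4 at full weight (the
CVFF-era convention, configurable in the exclusion builder).  The
out-of-plane coordinate is the Wilson angle, χ = arcsin(n̂·ŵ) with n̂ the
unit normal of the two in-plane bonds and ŵ the unit out-of-plane bond.
Coulomb energies use 332.0637 kcal·Å/(mol·e²), ε_r = 1 by default.  Forces
are fully analytic (verified against central finite differences to 1e-6
relative); `relax` is Armijo-backtracking steepest descent with a
monotone-non-increasing energy guarantee.  No physical parameter values are
shipped — the bundled `toy_params()` set is self-consistent but explicitly
non-physical, for tests and demos only.  No cutoff is applied by default at
desk scale.

## Calibration

`calibrate_preset("mean_end_to_end", target, cfg)` bisects the analytic
end-to-end law on the mean cosine, then verifies the result on ≥ 5 seeded
generated ensembles measured with the descriptor code (2 % default
tolerance).  `calibrate_preset("rg", target, cfg)` bisects a radial scale
factor applied to both profile radii against 5-seed ensemble means; the
lower bracket starts just above the close-packing feasibility bound and the
achievable floor (set by chain extent) is reported when a target cannot be
bracketed.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of the reference
nanoparticles — composition bookkeeping, radial profile shape, calibrated
chain statistics, planted hydrogen-bond geometries — not their physics: no
thermodynamics, no self-assembly, no solvent, no NPT equilibration, and no
emergent chirality effects.  Passing round-trip tests therefore validates
that the descriptor implementations measure what they claim with the
correct conventions and tolerances; it does not re-derive the molecular-
dynamics results themselves.  Problem sizes in the shipped tests and
acceptance runs are the 10-chain × 3,070-particle unit-cell scale (with
reduced ~400-particle chains in unit tests); the 245,600-particle
replicated model is exercised for bookkeeping, not for per-descriptor
timing.

## Known limitations

* Hard-segment chemistry is padded, so chain molar mass (~43 kDa here vs
  ~39 kDa for the real chain) is approximate; all counts are exact.
* Bridged sampling fixes end-to-end exactly; higher moments of the chain
  conformation distribution are those of the drifted walk, not of an
  equilibrated melt.
* The SASA reference sphere uses a grid volume estimate; `A_m/A_s` can dip
  ~1 % below 1 for a perfect sphere at coarse point counts.
* RDF normalization assumes an approximately spherical cluster; strongly
  anisotropic systems should rely on `raw_counts`.
* The CVFF evaluator is desk-scale (Python loops over bonded terms and
  non-bonded pairs); it is not an MD engine.
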