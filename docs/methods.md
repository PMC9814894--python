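# Methods

This note documents the models behind each `cagekit` module, the
defaults that matter, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Building-block topology assembly

A container molecule with n-fold symmetry is assembled from n copies of
one residue template. The assembler installs, in order: all intra-residue
bonds; n−1 sequence bonds (tail of residue i to head of residue i+1); one
cyclization bond (tail of the last residue to head of the first) when the
spec is cyclic; and, per cross-link rule `(from_atom, to_atom, offset)`,
one bond per eligible position — all n positions with modular wrapping
when cyclic, otherwise the n−offset positions whose partner exists. Bond
provenance is recorded so downstream tools (script emission, validation,
tests) can reason about where each edge came from. Duplicate bonds are an
error, not a silent merge: a spec that installs the same edge twice is
malformed.

Atom addressing is `(residue index, atom name)`; global indices are
residue-major in template declaration order. Validation reports
connectivity, per-atom degree against a per-element valence table, and
the residue-cycle symmetry order: the number of residue shifts
`i → (i+k) mod n` that map the name-labelled bond set onto itself (4 for
the packaged four-block host).

The packaged HC1 template is heavy-atom only. Its atom names, head/tail
designation (C1/C20), the six cross-link atoms, and the 22 cavity-lining
names are fixed by the published residue definition; the remaining
intra-residue connectivity (linker ring closure, carboxylates, methyls)
is a chemically plausible completion and is flagged as such in the
template file. No stereochemistry or geometry is implied — coordinates
always come from input files or from the synthetic-cage generator.

The build-script dialect mirrors leap-style `sequence`/`bond` statements
(1-based residues, `residue.atom` addressing, provenance as a trailing
comment). It is parsed only by this package; emission aims at
human-readable compatibility, not byte-compatibility with any external
tool. Cross-link bond statements are oriented from-atom-first so parsing
recovers each rule's offset rather than its modular complement.

## Constrained RESP fitting

The fit minimizes the squared ESP reproduction error summed over grids
(conformers), plus the hyperbolic restraint `Σ_j a_j(√(q_j²+b²) − b)`,
subject to linear equality constraints. Implementation choices:

- **Equivalences by variable sharing.** Equivalence constraints are
  merged union-find style into classes numbered by first atom occurrence;
  each class is one unknown. Equivalent atoms are therefore bitwise
  identical in the result, and equivalence across conformations is
  automatic because all conformers share the charge vector.
- **Equalities by KKT.** Total-charge, group-sum and frozen constraints
  enter as rows of a KKT system solved directly; constraint residuals are
  reported per constraint. A rank-deficient system (e.g. contradictory
  totals) raises with the rank.
- **Restraint iteration.** The hyperbolic restraint is linearized as a
  diagonal `a_j/√(q_j²+b²)` and iterated to `max|Δq| < 1e-10` (at most
  200 iterations; non-convergence raises rather than returning silently).
  Restraint strengths default to the canonical two-stage protocol values
  — stage 1 `a = 0.0005` au, stage 2 `a = 0.001` au, `b = 0.1` au,
  hydrogens unrestrained — which the source protocol defines; per-class
  strength is the sum over class members, matching per-atom restraint.
- **Canonical conformer order.** Grids are sorted by conformer id before
  stacking, so the fit is independent of input order down to
  floating-point identity. Conformers are weighted equally by default;
  per-grid weights are exposed (`EspGrid.weight`) since the original
  protocol does not state unequal weighting.
- **Units.** Structures are held in Å; design matrices convert to Bohr so
  potentials are atomic units. ESP files use the classic fixed-width
  layout (counts header, atoms as 17X,3E16.7, points as 4E16.7 with the
  potential first, all in Bohr/hartree) with a whitespace fallback.

Two-stage fitting freezes all non-group atoms at stage-1 values
(implemented as frozen equality constraints, exempt from restraint),
re-imposes the total-charge constraint, and ties each group's hydrogens
equivalent. Block-charge extraction verifies the blocking-group zero-sum
actually held before returning residue charges; with total charge and
blocking sum constrained, the extracted sum equals the fragment total
exactly.

The synthetic ESP generator lays deterministic Fibonacci-lattice points
on scaled vdW shells (default 1.4/1.6/1.8/2.0 × Bondi radii), discards
points inside any atom's current scaled surface, and evaluates the exact
Coulomb potential of the ground-truth charges. With no restraint and
noise-free grids, the fit is an exactly identifiable linear problem, so
ground-truth recovery to ~1e-8 is the expected behaviour, not a
tolerance choice.

## Cavity radius of gyration and portal spikes

Rg is mass-weighted by default (uniform weighting available); the cavity
selection is the 22 named atoms per residue, 88 for the four-block host.
The portal "open" state is operationalized as Rg > 5.70 Å — between the
closed (~5.4 Å) baseline and the open-state value (~5.9 Å) — and is
configurable. A spike is a maximal run of consecutive frames above
threshold; frequency is count divided by total simulated time. When a
trajectory carries no time metadata, 0.1 ns/frame is assumed and the
spike summary flags the assumption. Replicate summaries follow the
replicate-statistics convention: the grand mean is the mean of
per-replicate time averages and the SE is the sample SD of those means
over √k; fewer than two replicates is an error because the SE is
undefined. Spike *counts* are not monotone in the threshold (raising it
can split runs), so the monotonicity guarantee — asserted in tests — is
on the above-threshold dwell fraction. No periodic-image handling is done
inside Rg: the host is a single molecule, and imaging is a preprocessing
step for clustering.

## Conformational clustering

The metric is best-fit RMSD (Kabsch superposition with proper-rotation
determinant correction) over all carbon atoms by default, resolved by
element symbol rather than name prefix. Pairwise matrices are built with
a batched formulation — only the 3×3 cross-covariance per pair is needed,
so singular values are computed on stacked 3×3 arrays — which keeps 2000
frames well inside a two-minute budget on one core.

Agglomeration is average linkage with an ε stop (default 1.0 Å). Because
average linkage is monotone, stopping when the minimum average
inter-cluster distance exceeds ε is equivalent to cutting the dendrogram
at height ε; the merge sequence itself is delegated to scipy's
hierarchical clustering (Lance–Williams average-linkage update via the
nearest-neighbor-chain algorithm, deterministic for fixed input). An
independent O(F⁴) brute-force enumerator ships in the package for
oracle comparisons at small frame counts. Cluster ids are relabelled by
descending population (ties broken by smallest member frame index), the
representative is the medoid (member minimizing total intra-cluster
distance; assumed, since the reference tooling's default representative
definition is not documented), and average structures are coordinate
means after superposing members onto the representative, reported
without any minimization. Preprocessing centers the (selected) solute
per frame and, when a box is present, wraps each molecule — grouped by
residue id — by whole box lengths to the primary cell.

## Guest-motion classification

`average_guest_structure` superposes every frame onto the first by host
atoms and averages the guest in that frame of reference. Shape is read
from the averaged structure's gyration tensor: eigenvalues λ1 ≥ λ2 ≥ λ3,
asphericity `b = λ1 − (λ2+λ3)/2`, and relative shape anisotropy
`κ² = 3/2·Σλᵢ²/(Σλᵢ)² − 1/2 ∈ [0, 1]`.

Decision rule (all thresholds configurable, `ShapeThresholds`):

- **ball** if κ² < 0.15 *or* the averaged end-to-end length < 3.0 Å;
- otherwise **rod**, **long** if the averaged length ≥ 6.0 Å, else
  **short**.

The collapse guard exists because κ² is scale-free: when even spinning
about multiple axes has contracted the average toward a point, the
residual coordinates are sampling noise and their κ² is essentially a
random draw (the mean of N uniform rotations is a random 3×3 matrix of
norm ~N^(−1/2) whose singular-value spread is O(1)). An absolute
collapse length decides ball in that regime; κ² handles genuinely
compact-but-extended averages. The 6.0 Å long-rod cut sits between the
observed maximal dimensions of partially-free-spin guests (≤6.5 Å, which
average to ~90% of their length) and axial-spin guests (≥6.8 Å, which
keep their full length). Shape maps deterministically onto motion:
ball → free spin, short rod → partially free spin, long rod → axial spin.

The host axial axis is estimated as the smallest-moment principal axis
of the cavity-atom gyration tensor — valid because the cavity shell is
an oblate band (wider than tall); an explicit axis can be supplied when
that assumption fails. Orientation is the angle (0–90°) between the
averaged guest's leading principal axis and the axial axis; when the two
leading eigenvalues coincide (relative gap < 1e-6) the long axis is
indeterminate and the angle is flagged rather than fabricated. The
guest's maximal dimension is geometric (max pairwise distance, optional
vdW padding of the endpoint atoms); it approximates, but is not claimed
to equal, quantum-surface-derived maximal dimensions, and whether those
include vdW radii is not documented — hence both variants.

## Synthetic fixtures: what they emulate, and what they do not

The generators are kinematic, not physical: no energetics, no solvent,
no barriers. They emulate the *statistical signatures* the analyses must
detect, with defaults matching the observed host: cavity baseline 5.44 Å
with 0.02 Å Gaussian noise; spikes of +0.45 Å (to ~5.89, near the open-
state 5.86 Å) lasting 3 frames at 0.1 events/ns, Poisson-timed; frame
interval 0.1 ns; a 97.2/2.8 two-state split; a mixed-mode equatorial
flip ratio of 0.1. Passing tests on these fixtures demonstrates that the
estimators recover known inputs under realistic magnitudes — they say
nothing about force fields, sampling convergence, or real solvent
behaviour.

Specific constructions:

- **Cage.** Real assembly topology; synthetic geometry. One residue's
  deterministic unit layout (two cylindrical bands mimicking the two
  bowls) is scaled by the radius and rotated by exact 360/n° increments,
  so n-fold symmetry is exact and every observable is homogeneous in the
  radius — which is also why a cage can be calibrated to any target
  cavity Rg exactly. The in-vacuo open/closed reference conformations
  used in tests are such calibrated cages (synthetic stand-ins, not the
  published coordinates); a PDB loader accepts the real structures where
  available.
- **Breathing.** The cage is scaled per frame so the cavity Rg equals an
  injected target series (baseline + noise + Poisson-timed excursions).
  Overlapping excursions are merged in the returned event list, so
  ground truth counts maximal above-baseline runs exactly as the
  detector does.
- **Rotation.** Axial mode uses golden-angle increments (phases cover
  the circle uniformly without commensurability artifacts). Isotropic
  mode samples Haar-uniform rotations via random unit quaternions —
  never Euler-angle sampling, which is biased — drawn in antithetic
  quadruples `{R, R·Rx(π), R·Ry(π), R·Rz(π)}` whose matrix sum is
  identically zero: each frame is still marginally uniform, but the
  finite-sample rotational mean vanishes exactly, so the averaged guest
  collapses at any frame count instead of at the N → ∞ limit. Mixed mode
  flips a Bernoulli(ratio) subset of frames 90° onto an equatorial axis
  before the axial spin.
- **Two-state.** The open reference is the closed cage with one residue
  pushed radially outward, rescaled iteratively (proportional updates on
  the push magnitude) until the best-fit RMSD between references matches
  the target to 1e-9. State counts are deterministic roundings of the
  requested fractions — so "exact population recovery" is well-defined —
  and every frame gets an independent random rigid motion, forcing the
  clustering metric to actually superpose.

All generators draw from a single `numpy.random.Generator` seeded by the
config, and return their ground truth alongside the data; identical
seeds give byte-identical trajectories.

## Problem sizes used in the test suite

The suite exercises 2000-frame clustering (the pairwise stage is the
dominant cost, ~25 s), 10⁴-frame breathing series for rate recovery
(Poisson sampling error ~10% at the default rate, inside the 20%
acceptance band), and 20 seeds × 3 modes × 1000 frames for motion
classification. These sizes keep the full suite under a minute of
fixture generation while leaving the statistical margins comfortable.

## Known limitations

- The HC1 template's non-junction connectivity is a plausible completion
  of a drawn structure, suitable for topology bookkeeping and selections
  but not a substitute for the published structure files.
- The charge module fits point charges only; no bonded force-field
  terms, no quantum ESP computation, no basis-set logic.
- Clustering holds the full F×F distance matrix in memory (fine to a few
  thousand frames; a sieve would be needed beyond that).
- Cavity volume is proxied by Rg; no grid or Monte-Carlo probe volumes.
- Per-portal distance metrics are configurable atom pairs only; no
  default pairs are claimed, since the defining atoms are not published.
- The guest classifier assumes the host is rigid enough for host-frame
  superposition to be meaningful; a host undergoing large conformational
  changes would smear the guest average for reasons unrelated to guest
  spin.
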