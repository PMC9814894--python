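# cagekit

Modular modelling and trajectory characterization of container molecules
(hemicarcerand-style host–guest cages).

Container molecules — two bowl-shaped resorcinarene fragments tethered
rim-to-rim by four linkers — encapsulate small-molecule guests that pass
through portals in the host shell. Simulating them is awkward for two
practical reasons: a host has >200 atoms whose three-dimensional topology
is tedious to build by hand, and its atomic charges are conformation-
dependent and must be fit under multiple equality constraints. `cagekit`
implements the modular approach to both problems, plus the trajectory
analyses used to characterize the host cavity and guest motion, for
computational chemists working on host–guest complexation.

## What it does

**Topology assembly** (`cagekit.assembly`). The host is treated like a
polypeptide: a residue template (the building block, with designated head
and tail atoms) is replicated along a sequence; residues are joined
tail-to-head, the chain is cyclized, and *cross-link rules* install the
remaining inter-residue bonds — for the packaged four-fold symmetric
octa-anionic host, three rules applied at all four positions (C4→C18a,
O5→C17a, O16a→C6b) yield 12 cross-link bonds plus 1 cyclization bond.
Every bond carries its provenance, and the assembly round-trips through a
human-readable leap-style build script.

**Constrained RESP charges** (`cagekit.resp`). Atom-centered charges are
fit to one or more conformers' electrostatic-potential grids by
restrained least squares,

```
min_q  Σ_g w_g Σ_p (V_gp − Σ_j q_j/r_gpj)²  +  Σ_j a_j (√(q_j²+b²) − b)
s.t.   Σ q_j = Q_total,   Σ_{j∈blocking} q_j = 0,   q_i = q_k (equivalences)
```

with equality constraints enforced exactly through Lagrange multipliers
and equivalent atoms sharing a single unknown (so equivalence across
conformations is exact by construction). The classic two-stage protocol
refits methyl/methylene groups with hydrogen equivalence while freezing
everything else. Building-block charges are extracted from a blocked
fragment fit in which the capping groups are constrained to zero total
charge. A synthetic ESP generator (vdW-shell grids, exact Coulomb
potentials from known charges) provides ground truth for testing.

**Cavity dynamics** (`cagekit.cavity`). The cavity volume proxy is the
mass-weighted radius of gyration `Rg = √(Σ w_i|r_i − r̄|²/Σ w_i)` of the
88 cavity-lining atoms (22 per building block). Portal openings appear as
transient spikes of the Rg series above a threshold (default 5.70 Å);
`detect_spikes` counts maximal above-threshold runs and dwell fractions,
and `summarize_replicates` reports the mean ± standard error across
replicate simulations (SE over replicate means, never over frames).

**Conformational clustering** (`cagekit.clustering`). Frames are compared
by best-fit (Kabsch) RMSD over all carbon atoms and agglomerated with
average linkage until the smallest inter-cluster average distance exceeds
ε = 1.0 Å. Clusters are reported by descending population with
representative (medoid) and unminimized average structures.

**Guest motion** (`cagekit.guest`). Frames are superposed on the host and
the guest coordinates averaged; the averaged structure's gyration-tensor
shape (relative anisotropy κ², end-to-end length) classifies the guest as
ball / short rod / long rod, which maps onto free spin / partially free
spin / axial spin. Also provided: geometric maximal dimension (optionally
vdW-padded), orientation against the host axial axis, and torsions.

**Synthetic fixtures** (`cagekit.synthetic`). Seeded generators produce
cages with exact four-fold symmetry, breathing trajectories with
Poisson-timed portal openings, guests rotating in axial / isotropic /
mixed modes (isotropic via Haar-uniform quaternions), and two-state
conformational mixtures — each returning its exact ground truth.

## Worked example

```python
from cagekit import (assemble, builtin_templates, octacid4_spec,
                     hc1_template, select_atoms, validate_topology,
                     rg_time_series, detect_spikes)
from cagekit.synthetic import FixtureConfig, make_breathing_trajectory

spec, templates = octacid4_spec(), builtin_templates()
top = assemble(spec, templates)
report = validate_topology(top)
cavity = select_atoms(top, hc1_template().cavity_atoms)
print(f"atoms={top.n_atoms} bonds={len(top.bonds)} "
      f"symmetry={report.symmetry_order} cavity_atoms={len(cavity)}")

traj, truth = make_breathing_trajectory(FixtureConfig(seed=0, n_frames=5000))
series = rg_time_series(traj, traj.select_names(hc1_template().cavity_atoms))
s = detect_spikes(series, threshold=5.7)
print(f"mean Rg = {series.values.mean():.2f} A, "
      f"{s.spike_count} portal openings ({s.spike_frequency:.3f}/ns), "
      f"open fraction {s.dwell_above:.4f}  [injected: {len(truth.events)}]")
```

prints

```
atoms=156 bonds=172 symmetry=4 cavity_atoms=88
mean Rg = 5.45 A, 43 portal openings (0.086/ns), open fraction 0.0268  [injected: 43]
```

i.e. the assembled host is a connected, four-fold symmetric topology of
156 heavy atoms; its cavity selection contains 88 atoms; and on a
500-ns-equivalent synthetic breathing trajectory the detector recovers
all 43 injected portal-opening events, with the cavity spending ~2.7% of
the time open. The same pipelines are available from the shell via the
`cagekit` command (`build`, `charges`, `rg`, `cluster`, `guest`,
`fixtures`).

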