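"""Restrained electrostatic-potential (RESP) charge fitting with linear
equality constraints.

Atom-centered point charges are fit to one or more conformers'
electrostatic-potential grids by minimizing

    sum_g w_g sum_p (V_gp - sum_j q_j / r_gpj)^2
        + sum_j a_j (sqrt(q_j^2 + b^2) - b)

subject to linear equality constraints (total charge, group sums, frozen
charges) enforced exactly through Lagrange multipliers.  Equivalence
constraints are implemented by variable sharing -- one unknown per
equivalence class -- so equivalent atoms carry bitwise-identical charges
by construction.  Because all conformers of a molecule share one charge
vector, equivalence across conformations is automatic.  The hyperbolic
restraint is handled by iterating the linearized normal equations, as in
the classic two-stage protocol.

Distances enter the design matrix in Bohr so that potentials are in
atomic units (hartree/e); coordinates are held in Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import ANGSTROM_TO_BOHR, vdw_radius

CONSTRAINT_KINDS = ("total_charge", "group_sum", "equivalence", "frozen")


class ChargeFitError(ValueError):
    """Raised for ill-posed inputs, singular systems or non-convergence."""


@dataclass
class EspGrid:
    """One conformer's ESP sample: atom positions, grid points, potentials.

    Coordinates in Angstrom; potentials in atomic units.  ``elements`` is
    optional per-atom metadata used to exempt hydrogens from the
    restraint.  ``weight`` scales this conformer's contribution to the
    joint fit (all conformers equal by default).
    """

    conformer_id: str
    atom_coords: np.ndarray
    grid_points: np.ndarray
    potentials: np.ndarray
    elements: list[str] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, float).reshape(-1, 3)
        self.grid_points = np.asarray(self.grid_points, float).reshape(-1, 3)
        self.potentials = np.asarray(self.potentials, float).ravel()
        if len(self.potentials) != len(self.grid_points):
            raise ChargeFitError("one potential per grid point required")
        if len(self.grid_points) < len(self.atom_coords):
            raise ChargeFitError(
                f"under-determined grid: {len(self.grid_points)} points for "
                f"{len(self.atom_coords)} atoms")
        d = np.linalg.norm(self.grid_points[:, None, :] -
                           self.atom_coords[None, :, :], axis=2)
        if np.any(d < 1e-6):
            raise ChargeFitError("grid point coincident with an atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_coords)

    def design_matrix(self) -> np.ndarray:
        """(M, N) matrix of 1/r_pj in inverse Bohr."""
        d = np.linalg.norm(self.grid_points[:, None, :] -
                           self.atom_coords[None, :, :], axis=2)
        return 1.0 / (d * ANGSTROM_TO_BOHR)


@dataclass(frozen=True)
class ChargeConstraint:
    """Linear equality constraint on the fitted charges.

    kind ``total_charge``: sum of all charges equals ``value``;
    ``group_sum``: sum over ``atoms`` equals ``value``; ``equivalence``:
    all ``atoms`` carry one shared charge; ``frozen``: each atom in
    ``atoms`` is pinned at ``value``.
    """

    kind: str
    atoms: tuple[int, ...] = ()
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONSTRAINT_KINDS:
            raise ChargeFitError(f"unknown constraint kind {self.kind!r}")
        if self.kind != "total_charge" and not self.atoms:
            raise ChargeFitError(f"{self.kind} constraint needs atom indices")
        if self.kind != "equivalence" and self.value is None:
            raise ChargeFitError(f"{self.kind} constraint needs a value")


@dataclass
class RestraintParams:
    """Hyperbolic restraint parameters (atomic units).

    Defaults follow the canonical two-stage protocol: stage-1 strength
    ``a = 0.0005`` au, tightness ``b = 0.1`` au, hydrogens unrestrained.
    """

    a: float = 0.0005
    b: float = 0.1
    restrain_hydrogens: bool = False
    max_iter: int = 200
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0:
            raise ChargeFitError("require a >= 0 and b > 0")


@dataclass
class ChargeFitResult:
    """Fitted charges plus fit diagnostics."""

    charges: np.ndarray
    rrms: float
    iterations: int
    constraint_residuals: list[float] = field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # merge toward the smaller root for deterministic classes
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _reduction(n_atoms: int, constraints) -> tuple[np.ndarray, int]:
    """Atom -> variable map from the equivalence constraints.

    Returns ``(var_of_atom, n_vars)`` with classes numbered by first
    atom occurrence, so permuting constraint order cannot change them.
    """
    uf = _UnionFind(n_atoms)
    for c in constraints:
        if c.kind == "equivalence":
            first = c.atoms[0]
            for other in c.atoms[1:]:
                uf.union(first, other)
    roots: dict[int, int] = {}
    var_of_atom = np.empty(n_atoms, dtype=int)
    for i in range(n_atoms):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots)
        var_of_atom[i] = roots[r]
    return var_of_atom, len(roots)


def resp_fit(grids: list[EspGrid], constraints: list[ChargeConstraint],
             restraint: RestraintParams | None = None) -> ChargeFitResult:
    """Restrained least-squares charge fit over one or more conformers.

    All grids must describe the same atoms (one shared charge vector).
    Equality constraints are enforced exactly via a KKT system; the
    hyperbolic restraint is iterated to self-consistency.  Raises
    :class:`ChargeFitError` on a rank-deficient constrained system or
    when the iteration does not converge within ``max_iter``.
    """
    if not grids:
        raise ChargeFitError("at least one ESP grid required")
    restraint = restraint or RestraintParams()
    n = grids[0].n_atoms
    for g in grids[1:]:
        if g.n_atoms != n:
            raise ChargeFitError("conformer grids disagree on atom count")
    # canonical conformer order: the joint fit is then independent of the
    # order the grids were passed in, down to floating-point identity
    grids = sorted(grids, key=lambda g: (g.conformer_id, len(g.grid_points),
                                         g.weight))

    var_of_atom, m = _reduction(n, constraints)
    # P maps variables to atoms: q_atoms = P @ q_vars
    p = np.zeros((n, m))
    p[np.arange(n), var_of_atom] = 1.0

    # stacked, weight-scaled design matrix and targets in variable space
    blocks, targets, weights = [], [], []
    for g in grids:
        sw = np.sqrt(g.weight)
        blocks.append(sw * g.design_matrix() @ p)
        targets.append(sw * g.potentials)
        weights.append(g.weight)
    a_mat = np.vstack(blocks)
    v = np.concatenate(targets)
    ata = a_mat.T @ a_mat
    atv = a_mat.T @ v

    # equality constraints B q_vars = d
    rows, vals = [], []
    frozen_atoms: set[int] = set()
    for c in constraints:
        if c.kind == "equivalence":
            continue
        if c.kind == "total_charge":
            rows.append(np.ones(n) @ p)
            vals.append(c.value)
        elif c.kind == "group_sum":
            sel = np.zeros(n)
            sel[list(c.atoms)] = 1.0
            rows.append(sel @ p)
            vals.append(c.value)
        elif c.kind == "frozen":
            for i in c.atoms:
                sel = np.zeros(n)
                sel[i] = 1.0
                rows.append(sel @ p)
                vals.append(c.value)
                frozen_atoms.add(i)
    b_mat = np.array(rows).reshape(-1, m)
    d = np.array(vals, float)
    k = len(d)
    if k:
        if np.linalg.matrix_rank(b_mat) < k:
            # redundant-but-consistent rows (e.g. duplicated constraints) are
            # tolerated; contradictory ones surface as a singular KKT solve
            pass

    # per-variable restraint strength: sum of per-atom strengths over the
    # class, hydrogens exempt unless requested, frozen atoms exempt
    a_atom = np.full(n, restraint.a)
    elems = grids[0].elements
    if elems is not None and not restraint.restrain_hydrogens:
        a_atom[np.array([e == "H" for e in elems])] = 0.0
    if frozen_atoms:
        a_atom[list(frozen_atoms)] = 0.0
    a_var = a_atom @ p

    def solve(diag: np.ndarray) -> np.ndarray:
        kkt = np.zeros((m + k, m + k))
        kkt[:m, :m] = ata + np.diag(diag)
        if k:
            kkt[:m, m:] = b_mat.T
            kkt[m:, :m] = b_mat
        rhs = np.concatenate([atv, d])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            rank = np.linalg.matrix_rank(kkt)
            raise ChargeFitError(
                f"singular constrained system (KKT rank {rank} < {m + k}); "
                "check for contradictory or redundant constraints") from None
        return sol[:m]

    q = solve(np.zeros(m))
    iterations = 0
    if restraint.a > 0 and np.any(a_var > 0):
        for iterations in range(1, restraint.max_iter + 1):
            diag = a_var / np.sqrt(q**2 + restraint.b**2)
            q_new = solve(diag)
            delta = np.max(np.abs(q_new - q))
            q = q_new
            if delta < restraint.tol:
                break
        else:
            raise ChargeFitError(
                f"restraint iteration did not converge in "
                f"{restraint.max_iter} steps (last max |dq| = {delta:.3e})")

    charges = p @ q
    v_fit = a_mat @ q
    denom = float(v @ v)
    rrms = float(np.sqrt(np.sum((v - v_fit) ** 2) / denom)) if denom > 0 else 0.0
    residuals = [float(abs(row @ q - val)) for row, val in zip(b_mat, d)]
    return ChargeFitResult(charges=charges, rrms=rrms, iterations=iterations,
                           constraint_residuals=residuals)


@dataclass(frozen=True)
class MethylGroup:
    """A methyl/methylene group: the carbon center and its hydrogens."""

    carbon: int
    hydrogens: tuple[int, ...]


def two_stage_fit(grids: list[EspGrid], constraints: list[ChargeConstraint],
                  groups: list[MethylGroup] = (),
                  stage1: RestraintParams | None = None,
                  stage2: RestraintParams | None = None) -> ChargeFitResult:
    """Two-stage protocol for molecules with methyl/methylene groups.

    Stage 1 fits every atom under a weak restraint without intra-group
    hydrogen equivalence.  Stage 2 refits only the group carbons and
    hydrogens under a stronger restraint with the hydrogens of each group
    tied equivalent, every other charge frozen at its stage-1 value.
    With no groups declared the result is the stage-1 fit itself.
    """
    stage1 = stage1 or RestraintParams(a=0.0005)
    stage2 = stage2 or RestraintParams(a=0.001)
    elems = grids[0].elements
    for grp in groups:
        if elems is None:
            raise ChargeFitError("element metadata required to validate groups")
        if elems[grp.carbon] != "C":
            raise ChargeFitError(
                f"group center atom {grp.carbon} is {elems[grp.carbon]!r}, "
                "expected a carbon")
        for h in grp.hydrogens:
            if elems[h] != "H":
                raise ChargeFitError(f"group atom {h} is not a hydrogen")

    result1 = resp_fit(grids, list(constraints), stage1)
    if not groups:
        return result1

    free = sorted({grp.carbon for grp in groups} |
                  {h for grp in groups for h in grp.hydrogens})
    n = grids[0].n_atoms
    frozen = [i for i in range(n) if i not in free]
    stage2_constraints: list[ChargeConstraint] = [
        c for c in constraints if c.kind == "total_charge"]
    for i in frozen:
        stage2_constraints.append(
            ChargeConstraint("frozen", (i,), float(result1.charges[i])))
    for grp in groups:
        if len(grp.hydrogens) > 1:
            stage2_constraints.append(
                ChargeConstraint("equivalence", tuple(grp.hydrogens)))

    result2 = resp_fit(grids, stage2_constraints, stage2)
    return ChargeFitResult(charges=result2.charges, rrms=result2.rrms,
                           iterations=result1.iterations + result2.iterations,
                           constraint_residuals=result2.constraint_residuals)


def extract_block_charges(result: ChargeFitResult, blocking_atoms,
                          tol: float = 1e-8) -> np.ndarray:
    """Charges of the residue atoms of a blocked-fragment fit.

    ``blocking_atoms`` indexes the capping atoms whose total charge was
    constrained to zero during the fit; after verifying that constraint
    held (within ``tol``), the remaining (residue) charges are returned.
    Their sum then equals the fragment's constrained total exactly.
    """
    blocking = np.asarray(sorted(set(int(i) for i in blocking_atoms)), dtype=int)
    block_sum = float(result.charges[blocking].sum()) if len(blocking) else 0.0
    if abs(block_sum) > tol:
        raise ChargeFitError(
            f"blocking-group charges sum to {block_sum:.3e}, not 0: the fit "
            "was run without the required group-sum constraint")
    mask = np.ones(len(result.charges), dtype=bool)
    mask[blocking] = False
    return result.charges[mask]


def synth_esp_grid(coords, true_charges, elements,
                   shells=(1.4, 1.6, 1.8, 2.0), density: float = 1.0,
                   conformer_id: str = "synthetic",
                   weight: float = 1.0) -> EspGrid:
    """Synthesize an ESP grid from known ground-truth point charges.

    Grid points are laid on scaled van-der-Waals shells around every atom
    (the classic connolly-shell construction: default scale factors 1.4,
    1.6, 1.8 and 2.0), points falling inside the current scaled surface
    of any other atom are discarded, and the exact Coulomb potential
    ``V(r) = sum_j q_j / |r - r_j|`` of the ground-truth charges is
    evaluated in atomic units.  ``density`` is points per Angstrom^2 of
    shell surface.  Deterministic (Fibonacci-lattice shells).
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    q = np.asarray(true_charges, float).ravel()
    if len(q) != len(coords):
        raise ChargeFitError("one charge per atom required")
    if density <= 0:
        raise ChargeFitError("density must be positive")
    radii = np.array([vdw_radius(e) for e in elements])
    if min(shells) <= 1.0:
        raise ChargeFitError("shell scale factors must exceed 1.0")

    points = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for scale in shells:
        for i, (center, r) in enumerate(zip(coords, radii)):
            rad = scale * r
            n_pts = max(int(round(density * 4.0 * np.pi * rad**2)), 8)
            k = np.arange(n_pts)
            z = 1.0 - 2.0 * (k + 0.5) / n_pts
            rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
            theta = golden * k
            sphere = rad * np.stack([rho * np.cos(theta),
                                     rho * np.sin(theta), z], axis=1) + center
            d = np.linalg.norm(sphere[:, None, :] - coords[None, :, :], axis=2)
            limit = scale * radii[None, :]
            keep = np.all(d >= limit - 1e-9, axis=1)
            points.append(sphere[keep])
    grid = np.vstack(points)
    if len(grid) == 0:
        raise ChargeFitError("no grid points survive the exclusion rule")

    d = np.linalg.norm(grid[:, None, :] - coords[None, :, :], axis=2)
    v = (1.0 / (d * ANGSTROM_TO_BOHR)) @ q
    return EspGrid(conformer_id=conformer_id, atom_coords=coords,
                   grid_points=grid, potentials=v,
                   elements=list(elements), weight=weight)
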