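"""Synthetic ground-truth fixtures for every analysis in the package.

Nothing here is molecular dynamics: the generators are kinematic
stand-ins that reproduce the *statistical structure* of host-guest
trajectories -- a cavity whose radius of gyration sits at a baseline
with Poisson-timed excursions above a portal-opening threshold, a guest
spinning axially / isotropically / in a mixed mode inside a rigid cage,
and a two-state conformational mixture -- while returning the exact
injected ground truth alongside the data.  All randomness flows through
one seeded :class:`numpy.random.Generator`, so a fixed seed reproduces
identical bytes.

Default magnitudes mirror the observed host behaviour: baseline cavity
Rg 5.44 Angstrom with spikes toward the open-state value near 5.9, a
portal-open threshold of 5.7 sitting between them, and a dominant/minor
conformer split of 97.2 / 2.8 percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AssemblySpec, MolecularTopology, assemble, select_atoms
from .cavity import radius_of_gyration
from .core import Conformation, Trajectory
from .geometry import kabsch_rmsd_coords
from .templates import hc1_template, octacid4_spec

ROTATION_MODES = ("axial", "isotropic", "mixed")


@dataclass
class FixtureConfig:
    """Knobs shared by the trajectory generators.

    ``spike_rate`` is in events per ns, ``spike_amplitude`` and
    ``noise_sd`` in Angstrom, ``frame_interval`` in ns.  ``mixed_ratio``
    is the fraction of frames a mixed-mode guest spends flipped onto an
    equatorial axis.
    """

    seed: int = 0
    n_frames: int = 1000
    frame_interval: float = 0.1
    baseline_rg: float = 5.44
    spike_rate: float = 0.1
    spike_amplitude: float = 0.45
    spike_duration_frames: int = 3
    rotation_mode: str = "axial"
    mixed_ratio: float = 0.1
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.spike_rate, self.spike_amplitude, self.noise_sd) < 0:
            raise ValueError("rates, amplitudes and noise sd must be >= 0")
        if not (0.0 < self.mixed_ratio < 1.0):
            raise ValueError("mixed_ratio must lie in (0, 1)")
        if self.rotation_mode not in ROTATION_MODES:
            raise ValueError(f"unknown rotation mode {self.rotation_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _unit_layout(n_atoms: int) -> np.ndarray:
    """Deterministic unit-scale local coordinates for one residue.

    Atoms are spread over an upper and a lower band of a cylinder of
    unit radius (mimicking the two bowl fragments) within the residue's
    angular sector; all coordinates are proportional to the cage radius
    by construction, so every cage observable scales linearly with it.
    """
    k = np.arange(n_atoms)
    rho = 0.85 + 0.15 * np.cos(2.0 * np.pi * k / 7.0)
    phi = -0.5 + (k / max(n_atoms - 1, 1))  # radians within the sector
    z = 0.45 * np.sign(np.cos(np.pi * k / 5.0)) + 0.1 * np.sin(2 * np.pi * k / 11.0)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation matrix via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_cage(n_residues: int = 4, radius: float = 7.0,
              spec: AssemblySpec | None = None,
              cavity_rg: float | None = None,
              weighting: str = "mass") -> tuple[Conformation, MolecularTopology]:
    """A rigid synthetic cage with exact n-fold rotational symmetry.

    The topology is the real building-block assembly (HC1 sequence,
    cyclization, cross-link rules); the geometry is synthetic: each
    residue's deterministic local layout, scaled by ``radius``, is
    rotated into its sector by exact 360/n-degree increments.  When
    ``cavity_rg`` is given the cage is rescaled so the cavity selection's
    Rg equals it exactly (legitimate because Rg is homogeneous of degree
    one in the coordinates).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    template = hc1_template()
    if spec is None:
        base = octacid4_spec()
        spec = AssemblySpec(sequence=[template.name] * n_residues,
                            cyclic=True, cross_links=base.cross_links)
    top = assemble(spec, {template.name: template})
    per_res = len(template.atoms)
    local = radius * _unit_layout(per_res)
    coords = np.vstack([local @ _rot_z(2.0 * np.pi * r / n_residues).T
                        for r in range(n_residues)])
    conf = Conformation(coords, top.names, top.elements, top.resids)
    if cavity_rg is not None:
        sel = select_atoms(top, template.cavity_atoms)
        current = radius_of_gyration(conf, sel, weighting=weighting)
        conf = conf.with_coords(conf.coords * (cavity_rg / current))
    return conf, top


def cavity_selection(top: MolecularTopology) -> np.ndarray:
    """Global indices of the cavity-lining atoms of a cage topology."""
    return select_atoms(top, hc1_template().cavity_atoms)


@dataclass
class BreathingTruth:
    """Injected ground truth of a breathing trajectory."""

    events: list[tuple[int, int]]  # [start, end) frame ranges, merged
    rg_targets: np.ndarray  # exact per-frame cavity Rg
    rate: float  # events per ns actually requested
    threshold_window: tuple[float, float]  # thresholds that separate states


def make_breathing_trajectory(cfg: FixtureConfig | None = None,
                              ) -> tuple[Trajectory, BreathingTruth]:
    """Cage trajectory whose cavity Rg breathes around a baseline.

    Per frame the cage is scaled radially so the cavity Rg equals
    baseline + Gaussian noise, with Poisson-timed excursions of the
    configured amplitude and duration added on top.  The exact injected
    Rg series and the merged excursion list are returned, so detection
    results can be checked against ground truth.
    """
    cfg = cfg or FixtureConfig()
    rng = cfg.rng()
    conf, top = make_cage(cavity_rg=cfg.baseline_rg)
    sel = cavity_selection(top)
    base_rg = radius_of_gyration(conf, sel)

    f = cfg.n_frames
    total_ns = f * cfg.frame_interval
    targets = cfg.baseline_rg + rng.normal(0.0, cfg.noise_sd, size=f)

    n_events = rng.poisson(cfg.spike_rate * total_ns)
    starts = np.sort(rng.integers(0, f, size=n_events))
    open_mask = np.zeros(f, dtype=bool)
    for s in starts:
        open_mask[s:s + cfg.spike_duration_frames] = True
    targets = np.where(open_mask, targets + cfg.spike_amplitude, targets)

    # merged event list = maximal runs of the open mask
    events: list[tuple[int, int]] = []
    in_run = False
    for i, flag in enumerate(open_mask):
        if flag and not in_run:
            run_start, in_run = i, True
        elif not flag and in_run:
            events.append((run_start, i))
            in_run = False
    if in_run:
        events.append((run_start, f))

    scales = targets / base_rg
    coords = conf.coords[None, :, :] * scales[:, None, None]
    traj = Trajectory(coords, conf.names, conf.elements, conf.resids,
                      frame_interval=cfg.frame_interval)
    window = (cfg.baseline_rg + 4 * cfg.noise_sd,
              cfg.baseline_rg + cfg.spike_amplitude - 4 * cfg.noise_sd)
    return traj, BreathingTruth(events=events, rg_targets=targets,
                                rate=cfg.spike_rate, threshold_window=window)


def rod_guest(length: float = 7.2, n_backbone: int = 6,
              offset: float = 0.8) -> Conformation:
    """Synthetic rod-shaped guest: a carbon backbone along z spanning
    ``length`` Angstrom plus off-axis atoms (so the structure is
    genuinely three-dimensional, like a fused-ring or ester guest)."""
    z = np.linspace(-length / 2.0, length / 2.0, n_backbone)
    backbone = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    # equatorial cross at the midplane: keeps the principal axis exactly
    # on z (no off-diagonal gyration moments) while making the guest 3-D
    side = np.array([[offset, 0.0, 0.0], [-offset, 0.0, 0.0],
                     [0.0, offset, 0.0], [0.0, -offset, 0.0]])
    coords = np.vstack([backbone, side])
    n = len(coords)
    names = np.array([f"G{i + 1}" for i in range(n)], dtype=object)
    elements = np.array(["C"] * n, dtype=object)
    return Conformation(coords, names, elements, np.zeros(n, dtype=int))


def compact_guest() -> Conformation:
    """Synthetic compact guest (sulfoxide-like pyramid of 4 heavy atoms)."""
    coords = np.array([
        [0.0, 0.0, 0.3],      # S
        [0.0, 1.45, -0.4],    # O
        [1.35, -0.75, -0.4],  # C
        [-1.35, -0.75, -0.4],  # C
    ])
    names = np.array(["G1", "G2", "G3", "G4"], dtype=object)
    elements = np.array(["S", "O", "C", "C"], dtype=object)
    return Conformation(coords, names, elements, np.zeros(4, dtype=int))


#: canonical guest per rotation mode, emulating the three observed guest
#: classes (long rigid rod / medium rod / compact near-spherical guest)
CANONICAL_GUESTS = {
    "axial": lambda: rod_guest(length=7.2),
    "mixed": lambda: rod_guest(length=5.6, n_backbone=5),
    "isotropic": lambda: compact_guest(),
}

_KLEIN_FOUR = [np.eye(3), _rot_x(np.pi), _rot_z(np.pi) @ _rot_x(np.pi),
               _rot_z(np.pi)]


@dataclass
class RotationTruth:
    """Ground truth of a rotation trajectory."""

    mode: str
    rotations: np.ndarray  # (F, 3, 3) applied to the guest template
    flip_mask: np.ndarray | None  # mixed mode: frames spent equatorial
    guest_indices: np.ndarray
    host_indices: np.ndarray


def make_rotation_trajectory(guest: Conformation | None = None,
                             cfg: FixtureConfig | None = None,
                             ) -> tuple[Trajectory, RotationTruth]:
    """Guest spinning inside a rigid cage, by mode.

    ``axial``: deterministic increments about the cage (z) axis, with an
    irrational step so spin phases cover the circle uniformly.
    ``isotropic``: uniform random rotations sampled as Haar quaternions,
    drawn in antithetic quadruples ``{R, R Rx(pi), R Ry(pi), R Rz(pi)}``
    whose matrix sum vanishes identically -- the finite-sample rotational
    mean is then exactly zero and the averaged guest collapses cleanly
    (the marginal distribution of each frame is still uniform).  For
    frame counts not divisible by four the last quadruple is truncated.
    ``mixed``: axial increments, with a ``mixed_ratio`` fraction of
    frames additionally flipped 90 degrees onto an equatorial axis.

    Per-atom Gaussian jitter of ``noise_sd`` is added to every frame.
    With a single frame the guest is placed unrotated.
    """
    cfg = cfg or FixtureConfig()
    guest = guest or CANONICAL_GUESTS[cfg.rotation_mode]()
    gc = guest.coords - guest.coords.mean(axis=0)
    if np.linalg.matrix_rank(gc - gc.mean(axis=0)) < 2 or len(gc) < 3:
        raise ValueError("guest needs at least 3 non-collinear atoms")
    rng = cfg.rng()
    cage, top = make_cage(cavity_rg=5.44)
    f = cfg.n_frames

    rotations = np.empty((f, 3, 3))
    flip_mask = None
    if f == 1:
        rotations[0] = np.eye(3)
    elif cfg.rotation_mode == "axial":
        step = 2.0 * np.pi * 0.38196601125  # golden-ratio conjugate turn
        for t in range(f):
            rotations[t] = _rot_z(t * step)
    elif cfg.rotation_mode == "isotropic":
        for b in range(0, f, 4):
            r = random_rotation(rng)
            for i, v in enumerate(_KLEIN_FOUR):
                if b + i < f:
                    rotations[b + i] = r @ v
    else:  # mixed
        step = 2.0 * np.pi * 0.38196601125
        flip_mask = rng.random(f) < cfg.mixed_ratio
        flip = _rot_x(np.pi / 2.0)
        for t in range(f):
            rz = _rot_z(t * step)
            rotations[t] = rz @ flip if flip_mask[t] else rz

    n_host, n_guest = cage.n_atoms, len(gc)
    coords = np.empty((f, n_host + n_guest, 3))
    coords[:, :n_host, :] = cage.coords[None]
    for t in range(f):
        coords[t, n_host:, :] = gc @ rotations[t].T
    if cfg.noise_sd > 0:
        coords += rng.normal(0.0, cfg.noise_sd, size=coords.shape)

    names = np.concatenate([cage.names, guest.names])
    elements = np.concatenate([cage.elements, guest.elements])
    resids = np.concatenate([cage.resids, np.full(n_guest, cage.resids.max() + 1)])
    traj = Trajectory(coords, names, elements, resids,
                      frame_interval=cfg.frame_interval)
    truth = RotationTruth(mode=cfg.rotation_mode, rotations=rotations,
                          flip_mask=flip_mask,
                          guest_indices=np.arange(n_host, n_host + n_guest),
                          host_indices=np.arange(n_host))
    return traj, truth


@dataclass
class TwoStateTruth:
    """Ground truth of a two-state conformational mixture."""

    labels: np.ndarray  # 0 = majority (closed), 1 = minority (open)
    reference_closed: np.ndarray
    reference_open: np.ndarray
    sep_rmsd: float  # achieved best-fit RMSD between the references
    fractions: tuple[float, float]


def make_two_state_trajectory(closed_frac: float = 0.972,
                              open_frac: float = 0.028,
                              sep_rmsd: float = 3.0,
                              cfg: FixtureConfig | None = None,
                              ) -> tuple[Trajectory, TwoStateTruth]:
    """Frames drawn from two rigid reference cages plus Gaussian jitter.

    The open reference is the closed cage with one residue block pushed
    radially outward (a widened portal), scaled so the best-fit RMSD
    between the references equals ``sep_rmsd``.  Frame counts per state
    are deterministic (``round(closed_frac * n_frames)``), the frame
    order is a seeded shuffle, and each frame receives a random rigid
    rotation + translation so clustering must superpose.  True labels
    are returned for parameter-recovery checks.
    """
    if abs(closed_frac + open_frac - 1.0) > 1e-9:
        raise ValueError("state fractions must sum to 1")
    cfg = cfg or FixtureConfig(noise_sd=0.2)
    rng = cfg.rng()
    closed, top = make_cage(cavity_rg=5.37)
    # outward push of residue 0, iteratively rescaled to the target RMSD
    direction = np.zeros_like(closed.coords)
    block = np.flatnonzero(closed.resids == 0)
    centroid = closed.coords[block].mean(axis=0)
    push = centroid / np.linalg.norm(centroid)
    direction[block] = push
    scale = sep_rmsd * np.sqrt(closed.n_atoms / len(block))
    open_ref = closed.coords + scale * direction
    for _ in range(8):
        achieved = kabsch_rmsd_coords(closed.coords, open_ref)
        if abs(achieved - sep_rmsd) < 1e-9:
            break
        scale *= sep_rmsd / achieved
        open_ref = closed.coords + scale * direction
    achieved = kabsch_rmsd_coords(closed.coords, open_ref)

    f = cfg.n_frames
    n_open = int(round(open_frac * f))
    labels = np.zeros(f, dtype=int)
    labels[rng.choice(f, size=n_open, replace=False)] = 1

    coords = np.empty((f, closed.n_atoms, 3))
    for t in range(f):
        ref = open_ref if labels[t] else closed.coords
        frame = ref + rng.normal(0.0, cfg.noise_sd, size=ref.shape)
        r = random_rotation(rng)
        shift = rng.uniform(-2.0, 2.0, size=3)
        coords[t] = frame @ r.T + shift
    traj = Trajectory(coords, closed.names, closed.elements, closed.resids,
                      frame_interval=cfg.frame_interval)
    truth = TwoStateTruth(labels=labels, reference_closed=closed.coords,
                          reference_open=open_ref, sep_rmsd=achieved,
                          fractions=(closed_frac, open_frac))
    return traj, truth
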