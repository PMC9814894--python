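"""Core coordinate containers: a single conformation and an ordered trajectory.

These are thin numpy-backed containers carrying per-atom metadata (name,
element, residue index) alongside Cartesian coordinates in Angstroms.  A
:class:`Trajectory` is a stack of frames over a fixed atom table, with
optional frame-time metadata (ns per frame) and an optional orthorhombic
periodic box per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import mass_of


@dataclass
class Conformation:
    """One set of atomic coordinates with per-atom metadata.

    Parameters
    ----------
    coords : (N, 3) float array, Angstrom
    names : sequence of atom names (e.g. ``"C4"``, ``"O16a"``)
    elements : sequence of element symbols
    resids : (N,) int array of residue indices (0-based block index)
    """

    coords: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        n = len(self.coords)
        if not (len(self.names) == len(self.elements) == len(self.resids) == n):
            raise ValueError("metadata arrays must match the number of atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def masses(self) -> np.ndarray:
        """Per-atom masses (u) looked up from the element symbols."""
        return np.array([mass_of(e) for e in self.elements], dtype=float)

    def select_names(self, names) -> np.ndarray:
        """Indices of all atoms whose name is in *names*, in global order."""
        wanted = set(names)
        unknown = wanted - set(self.names.tolist())
        if unknown:
            raise KeyError(f"atom name(s) not present: {sorted(unknown)}")
        return np.flatnonzero(np.isin(self.names, list(wanted)))

    def select_element(self, symbol: str) -> np.ndarray:
        """Indices of all atoms of a given element symbol."""
        return np.flatnonzero(self.elements == symbol)

    def select_resids(self, resids) -> np.ndarray:
        return np.flatnonzero(np.isin(self.resids, list(resids)))

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        """Copy of this conformation with new coordinates, same atom table."""
        return Conformation(np.array(coords, dtype=float), self.names,
                            self.elements, self.resids)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table.

    ``coords`` is (F, N, 3) in Angstrom.  ``frame_interval`` is the time
    between consecutive frames in ns, or ``None`` when unknown; operations
    that report rates per ns fall back to :data:`DEFAULT_FRAME_INTERVAL_NS`
    and say so in their output.  ``box`` is an optional (F, 3) array of
    orthorhombic box edge lengths.
    """

    coords: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    frame_interval: float | None = None
    box: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (F, N, 3)")
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.coords.shape[1]
        if not (len(self.names) == len(self.elements) == len(self.resids) == n):
            raise ValueError("metadata arrays must match the number of atoms")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must be (F, 3) edge lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Conformation:
        return Conformation(self.coords[i], self.names, self.elements, self.resids)

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements], dtype=float)

    def select_names(self, names) -> np.ndarray:
        return self.frame(0).select_names(names)

    def select_element(self, symbol: str) -> np.ndarray:
        return np.flatnonzero(self.elements == symbol)

    def with_coords(self, coords, box=None) -> "Trajectory":
        return Trajectory(np.array(coords, dtype=float), self.names, self.elements,
                          self.resids, frame_interval=self.frame_interval,
                          box=box if box is not None else
                          (None if self.box is None else self.box.copy()))

    @classmethod
    def from_conformations(cls, confs, frame_interval=None, box=None) -> "Trajectory":
        """Stack same-topology conformations into a trajectory."""
        confs = list(confs)
        if not confs:
            raise ValueError("need at least one frame")
        first = confs[0]
        for c in confs[1:]:
            if c.n_atoms != first.n_atoms:
                raise ValueError("atom count differs across frames")
        coords = np.stack([c.coords for c in confs])
        return cls(coords, first.names, first.elements, first.resids,
                   frame_interval=frame_interval, box=box)


#: assumed frame spacing (ns) when a trajectory carries no time metadata
DEFAULT_FRAME_INTERVAL_NS = 0.1
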