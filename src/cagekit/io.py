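"""Structure and trajectory I/O: multi-model PDB (via biotite) and XYZ.

PDB is the interchange format for cage structures and synthetic
trajectories (HETATM records, residue id = building-block index, guest
as its own residue).  XYZ frame series are supported as a lighter
element+coordinates format.  Orthorhombic boxes round-trip through the
PDB CRYST1 record.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Conformation, Trajectory


def _to_atom_array(names, elements, resids, coords, box=None):
    n = len(names)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, float)
    arr.atom_name = np.array([str(x) for x in names], dtype="U6")
    arr.element = np.array([str(x).upper() for x in elements], dtype="U2")
    arr.res_id = np.asarray(resids, int) + 1  # PDB residues are 1-based
    arr.res_name = np.array(["MOL"] * n, dtype="U5")
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.hetero = np.ones(n, dtype=bool)
    if box is not None:
        arr.box = np.diag(np.asarray(box, float))
    return arr


def write_pdb(obj: Conformation | Trajectory, path,
              res_names=None) -> None:
    """Write a conformation or trajectory as a (multi-model) PDB file.

    ``res_names`` optionally maps residue index -> residue name (e.g. the
    template name for host blocks, ``GST`` for a guest).
    """
    if isinstance(obj, Conformation):
        frames = obj.coords[None]
        box = None
        meta = obj
    else:
        frames = obj.coords
        box = obj.box
        meta = obj

    arrays = []
    for i, coords in enumerate(frames):
        arr = _to_atom_array(meta.names, meta.elements, meta.resids, coords,
                             box=None if box is None else box[i])
        if res_names:
            arr.res_name = np.array(
                [res_names.get(int(r) - 1, "MOL") for r in arr.res_id],
                dtype="U5")
        arrays.append(arr)
    stack = struc.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, frame_interval: float | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    names = np.array(stack.atom_name, dtype=object)
    elements = np.array([e.capitalize() for e in stack.element], dtype=object)
    resids = np.asarray(stack.res_id, int) - 1
    box = None
    if stack.box is not None:
        box = np.stack([np.diag(b) for b in stack.box])
        if not np.any(box):
            box = None
    return Trajectory(np.asarray(stack.coord, float), names, elements, resids,
                      frame_interval=frame_interval, box=box)


def read_conformation(path) -> Conformation:
    """Read the first model of a PDB file as a :class:`Conformation`."""
    traj = read_pdb(path)
    return traj.frame(0)


def write_xyz(obj: Conformation | Trajectory, path, comment: str = "") -> None:
    """Write an XYZ file (one block per frame for trajectories)."""
    frames = obj.coords[None] if isinstance(obj, Conformation) else obj.coords
    with open(path, "w") as fh:
        for k, coords in enumerate(frames):
            fh.write(f"{len(coords)}\n{comment or f'frame {k}'}\n")
            for el, (x, y, z) in zip(obj.elements, coords):
                fh.write(f"{el:<3s}{x:15.6f}{y:15.6f}{z:15.6f}\n")


def read_xyz(path, frame_interval: float | None = None) -> Trajectory:
    """Read a (multi-frame) XYZ file.

    Atom names are synthesized as ``<element><index>`` and all atoms are
    placed in residue 0 (XYZ carries no residue information).
    """
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError("truncated XYZ frame")
        els, coords = [], []
        for ln in block:
            parts = ln.split()
            els.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError("element order differs across XYZ frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("empty XYZ file")
    elements = np.array(elements, dtype=object)
    names = np.array([f"{e}{k + 1}" for k, e in enumerate(elements)],
                     dtype=object)
    resids = np.zeros(len(elements), dtype=int)
    return Trajectory(np.array(frames, float), names, elements, resids,
                      frame_interval=frame_interval)
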