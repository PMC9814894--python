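"""Reading and writing ESP-grid files and fitted-charge tables.

The grid files follow the classic fixed-width layout used by RESP input
decks: a header line with the atom and point counts (two I5 fields),
one line per atom with its coordinates (17X,3E16.7, Bohr), then one
line per grid point with the potential followed by its coordinates
(4E16.7, hartree/e and Bohr).  A whitespace-separated fallback with the
same line structure is accepted on read.  In memory everything is held
in Angstrom / atomic units (see :mod:`cagekit.resp`).

Charges are written as a plain TSV table or as a minimal MOL2 file with
the partial-charge column filled in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .elements import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .resp import ChargeFitError, EspGrid


def write_esp(grid: EspGrid, path) -> None:
    """Write an ESP grid in the fixed-width layout (Bohr / hartree)."""
    atoms_bohr = grid.atom_coords * ANGSTROM_TO_BOHR
    pts_bohr = grid.grid_points * ANGSTROM_TO_BOHR
    with open(path, "w") as fh:
        fh.write(f"{len(atoms_bohr):5d}{len(pts_bohr):5d}\n")
        for x, y, z in atoms_bohr:
            fh.write(f"{'':17s}{x:16.7E}{y:16.7E}{z:16.7E}\n")
        for v, (x, y, z) in zip(grid.potentials, pts_bohr):
            fh.write(f"{'':1s}{v:16.7E}{x:16.7E}{y:16.7E}{z:16.7E}\n")


def _parse_floats(line: str, n: int) -> list[float]:
    # fortran E-format may fuse fields; fall back to whitespace splitting
    parts = line.split()
    if len(parts) >= n:
        return [float(x) for x in parts[-n:] if True][:n]
    raise ChargeFitError(f"cannot parse {n} floats from line: {line!r}")


def read_esp(path, conformer_id: str | None = None,
             elements: list[str] | None = None) -> EspGrid:
    """Read an ESP grid file (fixed-width or whitespace-separated)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split()
    n_atoms, n_points = int(header[0]), int(header[1])
    if len(lines) < 1 + n_atoms + n_points:
        raise ChargeFitError(
            f"truncated ESP file: expected {n_atoms} atom and {n_points} "
            f"grid lines, found {len(lines) - 1}")
    atoms = np.array([_parse_floats(ln, 3)
                      for ln in lines[1:1 + n_atoms]]) * BOHR_TO_ANGSTROM
    rows = [_parse_floats(ln, 4)
            for ln in lines[1 + n_atoms:1 + n_atoms + n_points]]
    rows = np.asarray(rows)
    potentials = rows[:, 0]
    points = rows[:, 1:] * BOHR_TO_ANGSTROM
    return EspGrid(conformer_id=conformer_id or str(path),
                   atom_coords=atoms, grid_points=points,
                   potentials=potentials, elements=elements)


def write_charges_tsv(charges, path, names=None, elements=None) -> None:
    """Write fitted charges as a TSV table (index, name, element, charge)."""
    charges = np.asarray(charges, float)
    n = len(charges)
    df = pd.DataFrame({
        "atom": np.arange(n),
        "name": list(names) if names is not None else [f"A{i}" for i in range(n)],
        "element": list(elements) if elements is not None else ["X"] * n,
        "charge_e": charges,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_charges_mol2(charges, coords, path, names=None, elements=None,
                       bonds=None, mol_name: str = "MOL") -> None:
    """Write a minimal MOL2 file carrying the partial-charge column."""
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(charges)
    names = list(names) if names is not None else [f"A{i + 1}" for i in range(n)]
    elements = list(elements) if elements is not None else ["C"] * n
    bonds = list(bonds) if bonds is not None else []
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{mol_name}\n{n} {len(bonds)} 1\nSMALL\nRESP_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i in range(n):
            x, y, z = coords[i]
            fh.write(f"{i + 1:>7d} {names[i]:<8s}{x:10.4f}{y:10.4f}{z:10.4f} "
                     f"{elements[i]:<5s} 1 {mol_name:<8s}{charges[i]:10.6f}\n")
        if bonds:
            fh.write("@<TRIPOS>BOND\n")
            for k, (i, j) in enumerate(bonds):
                fh.write(f"{k + 1:>6d}{i + 1:>6d}{j + 1:>6d} 1\n")
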