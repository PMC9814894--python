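"""Building-block topology assembly for container molecules.

A container molecule such as a hemicarcerand is treated the way protein
builders treat a polypeptide: a *residue template* (the building block,
with designated head and tail atoms) is replicated along a sequence,
consecutive residues are joined tail-to-head, the chain is optionally
cyclized head-to-tail, and additional *cross-link rules* install the
remaining inter-residue covalent bonds (e.g. the acetal bridges between
neighbouring quarters of the host).  Every bond in the assembled topology
carries its provenance: ``intra``, ``sequence``, ``cyclization`` or
``cross-link:<from>-<to>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .elements import DEFAULT_MAX_VALENCE, is_valid_element

ATOM_ROLES = ("main-chain", "side-chain", "junction", "blocking")


class AssemblyError(ValueError):
    """Raised for unresolvable names, missing atoms or duplicate bonds."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom of a residue template."""

    name: str
    element: str
    role: str = "side-chain"

    def __post_init__(self) -> None:
        if not is_valid_element(self.element):
            raise AssemblyError(f"invalid element symbol {self.element!r} "
                                f"for atom {self.name!r}")
        if self.role not in ATOM_ROLES:
            raise AssemblyError(f"invalid atom role {self.role!r}")


@dataclass
class ResidueTemplate:
    """A building block: atoms, intra-residue bonds, head/tail designations
    and the subset of atoms that line the host cavity."""

    name: str
    atoms: list[AtomSpec]
    bonds: list[tuple[str, str]]
    head: str
    tail: str
    cavity_atoms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AssemblyError(f"duplicate atom name(s) in template "
                                f"{self.name!r}: {dupes}")
        known = set(names)
        for atom in (self.head, self.tail):
            if atom not in known:
                raise AssemblyError(f"head/tail atom {atom!r} not declared in "
                                    f"template {self.name!r}")
        if self.head == self.tail:
            raise AssemblyError("head and tail atoms must be distinct")
        for a, b in self.bonds:
            if a not in known or b not in known:
                raise AssemblyError(f"bond ({a!r}, {b!r}) references an "
                                    f"undeclared atom in template {self.name!r}")
        missing = [c for c in self.cavity_atoms if c not in known]
        if missing:
            raise AssemblyError(f"cavity atom(s) not declared: {missing}")

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise AssemblyError(f"atom {name!r} not in template {self.name!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueTemplate":
        atoms = [AtomSpec(a["name"], a["element"], a.get("role", "side-chain"))
                 for a in d["atoms"]]
        bonds = [(str(a), str(b)) for a, b in d["bonds"]]
        return cls(name=d["name"], atoms=atoms, bonds=bonds,
                   head=d["head"], tail=d["tail"],
                   cavity_atoms=list(d.get("cavity_atoms", [])))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "head": self.head,
            "tail": self.tail,
            "atoms": [{"name": a.name, "element": a.element, "role": a.role}
                      for a in self.atoms],
            "bonds": [list(b) for b in self.bonds],
            "cavity_atoms": list(self.cavity_atoms),
        }


@dataclass(frozen=True)
class CrossLinkRule:
    """Bond ``from_atom`` of residue i to ``to_atom`` of residue i+offset."""

    from_atom: str
    to_atom: str
    offset: int = 1

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise AssemblyError("cross-link offset must be non-zero")

    @property
    def tag(self) -> str:
        return f"cross-link:{self.from_atom}-{self.to_atom}"


@dataclass
class AssemblySpec:
    """Sequence of residue-template names, cyclization flag and cross-links."""

    sequence: list[str]
    cyclic: bool = False
    cross_links: list[CrossLinkRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AssemblyError("assembly sequence must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblySpec":
        links = [CrossLinkRule(x["from_atom"], x["to_atom"],
                               int(x.get("offset", 1)))
                 for x in d.get("cross_links", [])]
        return cls(sequence=list(d["sequence"]), cyclic=bool(d.get("cyclic", False)),
                   cross_links=links)

    def to_dict(self) -> dict:
        return {
            "sequence": list(self.sequence),
            "cyclic": self.cyclic,
            "cross_links": [{"from_atom": r.from_atom, "to_atom": r.to_atom,
                             "offset": r.offset} for r in self.cross_links],
        }


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two global atom indices with provenance."""

    i: int
    j: int
    provenance: str

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class MolecularTopology:
    """Assembled molecule: globally indexed atoms and provenance-tagged bonds.

    Atoms are indexed residue-major in template declaration order, so atom
    ``k`` of residue ``r`` has global index ``r * len(template) + k`` for a
    homopolymer assembly.
    """

    atoms: list[tuple[int, AtomSpec]]  # (residue index, atom spec)
    bonds: list[Bond]
    residue_templates: list[str]  # template name per residue
    spec: AssemblySpec | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_templates)

    def atom_label(self, i: int) -> tuple[int, str]:
        res, spec = self.atoms[i]
        return res, spec.name

    def index_of(self, residue: int, name: str) -> int:
        for i, (res, spec) in enumerate(self.atoms):
            if res == residue and spec.name == name:
                return i
        raise AssemblyError(f"no atom {name!r} in residue {residue}")

    def bonds_by_provenance(self) -> dict[str, list[Bond]]:
        out: dict[str, list[Bond]] = {}
        for b in self.bonds:
            out.setdefault(b.provenance, []).append(b)
        return out

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(b.key() for b in self.bonds)
        return g

    @property
    def elements(self) -> np.ndarray:
        return np.array([spec.element for _, spec in self.atoms], dtype=object)

    @property
    def names(self) -> np.ndarray:
        return np.array([spec.name for _, spec in self.atoms], dtype=object)

    @property
    def resids(self) -> np.ndarray:
        return np.array([res for res, _ in self.atoms], dtype=int)


def assemble(spec: AssemblySpec,
             templates: dict[str, ResidueTemplate]) -> MolecularTopology:
    """Build a :class:`MolecularTopology` from a spec and residue templates.

    Bonds are installed in four passes: all intra-residue bonds, the n-1
    tail-to-head sequence bonds, one head-to-tail cyclization bond when the
    spec is cyclic, and one bond per cross-link rule per eligible residue
    position (all n positions when cyclic, wrapping modulo the sequence
    length; otherwise only positions whose partner exists).
    """
    resolved: list[ResidueTemplate] = []
    for name in spec.sequence:
        if name not in templates:
            raise AssemblyError(f"unknown residue template {name!r}")
        resolved.append(templates[name])

    offsets = np.cumsum([0] + [len(t.atoms) for t in resolved])
    atoms: list[tuple[int, AtomSpec]] = []
    for r, t in enumerate(resolved):
        atoms.extend((r, a) for a in t.atoms)

    n = len(resolved)
    seen: set[tuple[int, int]] = set()
    bonds: list[Bond] = []

    def add(i: int, j: int, prov: str) -> None:
        key = (i, j) if i < j else (j, i)
        if i == j:
            raise AssemblyError(f"self-bond requested on atom {i}")
        if key in seen:
            raise AssemblyError(f"duplicate bond requested: atoms {key} ({prov})")
        seen.add(key)
        bonds.append(Bond(key[0], key[1], prov))

    def gidx(res: int, name: str) -> int:
        t = resolved[res]
        return int(offsets[res]) + t.index(name)

    for r, t in enumerate(resolved):
        for a, b in t.bonds:
            add(gidx(r, a), gidx(r, b), "intra")

    for r in range(n - 1):
        add(gidx(r, resolved[r].tail), gidx(r + 1, resolved[r + 1].head),
            "sequence")
    if spec.cyclic and n > 1:
        add(gidx(n - 1, resolved[n - 1].tail), gidx(0, resolved[0].head),
            "cyclization")

    for rule in spec.cross_links:
        positions = range(n) if spec.cyclic else range(n - rule.offset)
        for r in positions:
            r2 = (r + rule.offset) % n
            for atom, res in ((rule.from_atom, r), (rule.to_atom, r2)):
                if atom not in resolved[res].atom_names:
                    raise AssemblyError(
                        f"cross-link atom {atom!r} absent from template "
                        f"{resolved[res].name!r}")
            add(gidx(r, rule.from_atom), gidx(r2, rule.to_atom), rule.tag)

    return MolecularTopology(atoms=atoms, bonds=bonds,
                             residue_templates=[t.name for t in resolved],
                             spec=spec)


@dataclass
class ValidationReport:
    """Connectivity, valence and residue-symmetry summary of a topology."""

    connected: bool
    n_components: int
    valence_violations: list[tuple[int, int, int]]  # (atom index, degree, allowed)
    symmetry_order: int

    @property
    def ok(self) -> bool:
        return self.connected and not self.valence_violations


def validate_topology(top: MolecularTopology,
                      max_valence: dict[str, int] | None = None) -> ValidationReport:
    """Check connectivity, per-atom valence and residue-cycle symmetry.

    The symmetry order is the number of residue shifts ``i -> (i+k) mod n``
    (including the identity) that map the bond set, addressed by
    ``(residue, atom name)``, onto itself; a four-fold symmetric host
    assembly therefore reports 4.
    """
    limits = dict(DEFAULT_MAX_VALENCE)
    if max_valence:
        limits.update(max_valence)

    g = top.graph()
    n_comp = nx.number_connected_components(g) if top.n_atoms else 0
    violations = []
    for i, (_, spec) in enumerate(top.atoms):
        allowed = limits.get(spec.element)
        if allowed is not None and g.degree(i) > allowed:
            violations.append((i, g.degree(i), allowed))

    n = top.n_residues
    labelled = {frozenset((top.atom_label(b.i), top.atom_label(b.j)))
                for b in top.bonds}
    order = 0
    homogeneous = len(set(top.residue_templates)) <= 1
    for k in range(n):
        if not homogeneous and k > 0:
            break
        shifted = set()
        for edge in labelled:
            (r1, a1), (r2, a2) = tuple(edge)
            shifted.add(frozenset((((r1 + k) % n, a1), ((r2 + k) % n, a2))))
        if shifted == labelled:
            order += 1

    return ValidationReport(connected=(n_comp == 1), n_components=n_comp,
                            valence_violations=violations, symmetry_order=order)


def select_atoms(top: MolecularTopology, names) -> np.ndarray:
    """Global indices of every atom whose name is in *names*, ascending.

    Matches across all residues, so a per-residue name list of length m on
    an n-residue homopolymer returns m*n indices.  Unknown names raise.
    """
    names = list(names)
    known = {spec.name for _, spec in top.atoms}
    unknown = [x for x in names if x not in known]
    if unknown:
        raise AssemblyError(f"unknown atom name(s): {unknown}")
    wanted = set(names)
    return np.array([i for i, (_, spec) in enumerate(top.atoms)
                     if spec.name in wanted], dtype=int)


# ---------------------------------------------------------------------------
# build-script dialect
#
# A small human-readable dialect mirroring leap-style sequence/bond
# statements.  Residues are 1-based in scripts.  Emission is best-effort
# compatibility with that style, parsed only by this package.
# ---------------------------------------------------------------------------

_BOND_RE = re.compile(r"^bond\s+(\d+)\.(\S+)\s+(\d+)\.(\S+)\s*(?:#\s*(.*))?$")


def emit_build_script(spec: AssemblySpec,
                      templates: dict[str, ResidueTemplate]) -> str:
    """Render an assembly spec as a build script.

    The script carries one ``sequence`` statement and one explicit ``bond``
    statement per cyclization/cross-link bond (sequence bonds are implied
    by the sequence statement, as in leap).  ``parse_build_script`` inverts
    the emission.
    """
    top = assemble(spec, templates)  # validates and enumerates provenance
    lines = ["# cagekit build script",
             "sequence " + " ".join(spec.sequence)]
    by_prov = top.bonds_by_provenance()
    for b in by_prov.get("cyclization", []):
        (r1, a1), (r2, a2) = top.atom_label(b.i), top.atom_label(b.j)
        lines.append(f"bond {r1 + 1}.{a1} {r2 + 1}.{a2}  # cyclization")
    n = len(spec.sequence)
    for rule in spec.cross_links:
        for b in by_prov.get(rule.tag, []):
            (r1, a1), (r2, a2) = top.atom_label(b.i), top.atom_label(b.j)
            # orient the statement as from_atom -> to_atom so the parser
            # recovers the rule's offset, not its modular complement
            if not (a1 == rule.from_atom and (r2 - r1) % n == rule.offset % n):
                (r1, a1), (r2, a2) = (r2, a2), (r1, a1)
            lines.append(f"bond {r1 + 1}.{a1} {r2 + 1}.{a2}  # {rule.tag}")
    return "\n".join(lines) + "\n"


def parse_build_script(text: str) -> AssemblySpec:
    """Parse a build script back into an equivalent :class:`AssemblySpec`."""
    sequence: list[str] | None = None
    cyclic = False
    rules: list[CrossLinkRule] = []
    seen_rules: set[tuple[str, str, int]] = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("sequence"):
            sequence = line.split()[1:]
            continue
        m = _BOND_RE.match(line)
        if not m:
            raise AssemblyError(f"unparsable script line: {raw!r}")
        if sequence is None:
            raise AssemblyError("bond statement before sequence statement")
        r1, a1, r2, a2 = int(m.group(1)) - 1, m.group(2), int(m.group(3)) - 1, m.group(4)
        comment = (m.group(5) or "").strip()
        n = len(sequence)
        if comment == "cyclization":
            cyclic = True
            continue
        offset = (r2 - r1) % n
        key = (a1, a2, offset)
        if key not in seen_rules:
            seen_rules.add(key)
            rules.append(CrossLinkRule(a1, a2, offset))
    if sequence is None:
        raise AssemblyError("script contains no sequence statement")
    return AssemblySpec(sequence=sequence, cyclic=cyclic, cross_links=rules)


def load_template(path) -> ResidueTemplate:
    """Load a residue template from a YAML file."""
    with open(path) as fh:
        return ResidueTemplate.from_dict(yaml.safe_load(fh))


def load_assembly_spec(path) -> AssemblySpec:
    """Load an assembly spec from a YAML file."""
    with open(path) as fh:
        return AssemblySpec.from_dict(yaml.safe_load(fh))
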