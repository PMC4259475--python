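"""Read/write PDB structures and separate protein chains from small-molecule ligands.

Parsing is delegated to :mod:`gemmi`; the in-memory model used throughout the
package is a deliberately small chain -> residue -> atom hierarchy that carries
exactly what the conformational metrics and interaction detectors need.  Kinase
crystal structures typically lack hydrogens, so everything downstream works
from heavy atoms; hydrogens, when present, are kept but never required.

Modified residues common in kinase crystallography (phosphothreonine TPO,
selenomethionine MSE, phosphotyrosine PTR, S,S-(2-hydroxyethyl)thiocysteine
CME) are normalised back to their parent residues so that sequence mapping and
centre-of-mass selections see standard amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "LigandPose",
    "Structure",
    "ParseError",
    "MODIFIED_RESIDUES",
    "DEFAULT_LIGAND_EXCLUDE",
    "STANDARD_AA",
    "THREE_TO_ONE",
    "parse_structure",
    "write_structure",
    "standardize_modified_residues",
    "extract_ligands",
]


class ParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# modified residue -> (parent name, atom renames, parent heavy-atom roster)
# Atoms outside the parent roster (phosphates etc.) are dropped on
# standardisation; the roster is the parent's standard heavy atoms.
_PARENT_ATOMS = {
    "THR": {"N", "CA", "C", "O", "CB", "OG1", "CG2", "OXT"},
    "MET": {"N", "CA", "C", "O", "CB", "CG", "SD", "CE", "OXT"},
    "TYR": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH", "OXT"},
    "CYS": {"N", "CA", "C", "O", "CB", "SG", "OXT"},
}

MODIFIED_RESIDUES: dict[str, tuple[str, dict[str, str]]] = {
    "TPO": ("THR", {}),
    "MSE": ("MET", {"SE": "SD"}),
    "PTR": ("TYR", {}),
    "CME": ("CYS", {}),
}

# waters plus common crystallisation ions/additives; the analysed complexes
# are inhibitor co-crystals, so these are never treated as ligands by default
DEFAULT_LIGAND_EXCLUDE = {
    "HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA", "ZN", "MN",
    "SO4", "PO4", "GOL", "EDO", "ACT", "DMS", "PEG", "MPD", "FMT",
}

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904,
}


def element_mass(element: str) -> float:
    return _ELEMENT_MASS.get(element.upper(), 12.011)


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinate must be 3 finite components")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")

    @property
    def mass(self) -> float:
        return element_mass(self.element)


@dataclass
class Residue:
    author_number: int
    name: str
    atoms: list[Atom]
    chain_id: str
    insertion_code: str = ""
    modified_from: str | None = None  # provenance after standardisation

    @property
    def author_key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class LigandPose:
    """A connected HET group with element/valence-derived pharmacophore typing.

    ``typed_features`` pairs a feature kind (HD hydrogen-bond donor, HA
    acceptor, Ar aromatic ring, Cation, Anion, Hydrophobe) with the indices of
    the implicated atoms in ``atoms``.
    """

    residue_name: str
    atoms: list[Atom]
    chain_id: str = ""
    author_number: int = 0
    typed_features: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for kind, idx in self.typed_features:
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"feature {kind}: atom index out of range")
            if kind == "Ar" and len(idx) < 5:
                raise ValueError("Ar feature must reference a ring of >=5 atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def features(self, kind: str) -> list[tuple[int, ...]]:
        return [idx for k, idx in self.typed_features if k == kind]


@dataclass
class Structure:
    chains: dict[str, list[Residue]]
    ligands: list[LigandPose] = field(default_factory=list)
    model_index: int = 1

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def first_chain_id(self) -> str:
        return next(iter(self.chains))

    def residue(self, chain_id: str, author_number: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.author_number == author_number and r.insertion_code == icode:
                return r
        return None

    def all_protein_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for residues in self.chains.values() for r in residues for a in r.atoms]


def _pick_altloc(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Highest-occupancy alt-loc per atom name; ties prefer altloc 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in raw_atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            continue
        if (a.occ, -ord(a.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            by_name[a.name] = a
    return list(by_name.values())


def parse_structure(
    pdb_text: str,
    model: int = 1,
    ligand_exclude: set[str] | None = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Protein residues (standard amino acids plus recognised modified codes) go
    into chains; other HET groups, excluding waters/ions in ``ligand_exclude``,
    become :class:`LigandPose` entries with typed pharmacophore features.

    ``model`` selects the MODEL serial number (default 1, also used for
    single-model files).
    """
    if ligand_exclude is None:
        ligand_exclude = DEFAULT_LIGAND_EXCLUDE
    if not any(line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()):
        raise ParseError("no ATOM/HETATM records found")
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) < 54:
            raise ParseError(f"malformed coordinate record at line {i}: {line!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message passthrough
        raise ParseError(str(exc)) from exc
    st.setup_entities()

    gmodel = None
    for m in st:
        if m.num == model:
            gmodel = m
            break
    if gmodel is None:
        available = [m.num for m in st]
        raise ParseError(f"model {model} not present (available: {available})")

    chains: dict[str, list[Residue]] = {}
    het_groups: list[Residue] = []
    for gchain in gmodel:
        for gres in gchain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name or "C",
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    is_hetero=gres.het_flag == "H",
                )
                for a in _pick_altloc(list(gres))
            ]
            if not atoms:
                continue
            res = Residue(
                author_number=gres.seqid.num,
                name=gres.name,
                atoms=atoms,
                chain_id=gchain.name,
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            if res.name in STANDARD_AA or res.name in MODIFIED_RESIDUES:
                chains.setdefault(gchain.name, []).append(res)
            elif res.name not in ligand_exclude:
                het_groups.append(res)

    for residues in chains.values():
        seen: set[tuple[int, str]] = set()
        for r in residues:
            if r.author_key in seen:
                raise ParseError(
                    f"duplicate author residue {r.author_number}{r.insertion_code} in chain {r.chain_id}"
                )
            seen.add(r.author_key)

    structure = Structure(chains=chains, model_index=model)
    structure.ligands = _het_groups_to_poses(het_groups)
    return structure


def _format_atom_line(serial: int, atom: Atom, res: Residue, hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # PDB atom-name column convention: element right-aligned in cols 13-14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coord
    return (
        f"{record}{serial:5d} {name:<4s}{res.name:>4s} {res.chain_id[:1] or 'A'}"
        f"{res.author_number:4d}{res.insertion_code[:1] or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element.upper():>2s}"
    )


def write_structure(s: Structure) -> str:
    """Serialise a :class:`Structure` back to PDB text (coordinates to 0.001 A)."""
    lines: list[str] = []
    serial = 0
    for residues in s.chains.values():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(serial, atom, res, hetero=False))
        if residues:
            serial += 1
            last = residues[-1]
            lines.append(
                f"TER   {serial:5d}      {last.name:>3s} {last.chain_id[:1] or 'A'}"
                f"{last.author_number:4d}"
            )
    for pose in s.ligands:
        res = Residue(
            author_number=pose.author_number,
            name=pose.residue_name,
            atoms=pose.atoms,
            chain_id=pose.chain_id or "L",
        )
        for atom in pose.atoms:
            serial += 1
            lines.append(_format_atom_line(serial, atom, res, hetero=True))
    lines.append("END")
    return "\n".join(lines) + "\n"


def standardize_modified_residues(s: Structure) -> Structure:
    """Rename TPO/MSE/PTR/CME to their parent residues, dropping non-parent atoms.

    Idempotent; unknown modified codes are left untouched.  Each converted
    residue records its original code in ``modified_from``.
    """
    new_chains: dict[str, list[Residue]] = {}
    for cid, residues in s.chains.items():
        out = []
        for r in residues:
            if r.name in MODIFIED_RESIDUES:
                parent, renames = MODIFIED_RESIDUES[r.name]
                roster = _PARENT_ATOMS[parent]
                atoms = []
                for a in r.atoms:
                    name = renames.get(a.name, a.name)
                    if name in roster or a.element.upper() == "H":
                        element = "S" if (r.name == "MSE" and a.name == "SE") else a.element
                        atoms.append(Atom(name=name, element=element, coord=a.coord.copy(),
                                          is_hetero=a.is_hetero))
                out.append(
                    Residue(
                        author_number=r.author_number,
                        name=parent,
                        atoms=atoms,
                        chain_id=r.chain_id,
                        insertion_code=r.insertion_code,
                        modified_from=r.name,
                    )
                )
            else:
                out.append(
                    Residue(
                        author_number=r.author_number,
                        name=r.name,
                        atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms],
                        chain_id=r.chain_id,
                        insertion_code=r.insertion_code,
                        modified_from=r.modified_from,
                    )
                )
        new_chains[cid] = out
    return Structure(chains=new_chains, ligands=list(s.ligands), model_index=s.model_index)


# ---------------------------------------------------------------------------
# ligand extraction and rule-based pharmacophore typing
# ---------------------------------------------------------------------------

_COVALENT_CUTOFF = {
    frozenset({"C", "C"}): 1.75, frozenset({"C", "N"}): 1.65,
    frozenset({"C", "O"}): 1.60, frozenset({"C", "S"}): 1.95,
    frozenset({"N", "N"}): 1.55, frozenset({"N", "O"}): 1.55,
    frozenset({"O", "O"}): 1.60, frozenset({"S", "O"}): 1.70,
    frozenset({"S", "N"}): 1.85, frozenset({"S", "S"}): 2.20,
    frozenset({"C", "P"}): 1.95, frozenset({"O", "P"}): 1.75,
}


def _bond_cutoff(e1: str, e2: str) -> float:
    return _COVALENT_CUTOFF.get(frozenset({e1.upper(), e2.upper()}), 1.85)


def _adjacency(atoms: list[Atom]) -> list[set[int]]:
    n = len(atoms)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(atoms[i].coord - atoms[j].coord))
            if 0.4 < d <= _bond_cutoff(atoms[i].element, atoms[j].element):
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _find_small_rings(adj: list[set[int]], max_size: int = 6) -> list[tuple[int, ...]]:
    """Enumerate simple cycles of length 3..max_size (canonicalised)."""
    rings: set[tuple[int, ...]] = set()
    n = len(adj)

    def dfs(start: int, current: int, path: list[int]) -> None:
        for nxt in adj[current]:
            if nxt == start and len(path) >= 3:
                key = tuple(sorted(path))
                rings.add(key)
            elif nxt > start and nxt not in path and len(path) < max_size:
                dfs(start, nxt, path + [nxt])

    for i in range(n):
        dfs(i, i, [i])
    # keep only minimal rings: discard a cycle that is a superset union of smaller ones
    out = [r for r in rings if 5 <= len(r) <= max_size]
    minimal = []
    for r in sorted(out, key=len):
        rs = set(r)
        if not any(set(m) < rs for m in minimal):
            minimal.append(r)
    return minimal


def _ring_is_planar(atoms: list[Atom], ring: tuple[int, ...], tol: float = 0.15) -> bool:
    pts = np.array([atoms[i].coord for i in ring])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    return bool(np.max(np.abs((pts - centroid) @ normal)) < tol)


def type_ligand_features(atoms: list[Atom]) -> list[tuple[str, tuple[int, ...]]]:
    """Element/valence heuristics for heavy-atom-only pharmacophore typing.

    The rules are intentionally simple (no bond-order perception): N/O that can
    plausibly carry a hydrogen are donors, N/O with a free lone pair are
    acceptors, planar 5/6-rings of C/N/O/S are aromatic, terminal primary
    amines and guanidinium-like centres are cations, carboxylate/phosphate/
    sulfate-like groups are anions, and carbons with no polar neighbour are
    hydrophobes.
    """
    adj = _adjacency(atoms)
    feats: list[tuple[str, tuple[int, ...]]] = []
    elems = [a.element.upper() for a in atoms]

    rings = [r for r in _find_small_rings(adj)
             if all(elems[i] in {"C", "N", "O", "S"} for i in r) and _ring_is_planar(atoms, r)]
    ring_atoms = {i for r in rings for i in r}
    for r in rings:
        feats.append(("Ar", tuple(r)))

    anion_atoms: set[int] = set()
    for i, e in enumerate(elems):
        if e in {"C", "P", "S"}:
            terminal_o = [j for j in adj[i] if elems[j] == "O" and len(adj[j]) == 1]
            if (e == "C" and len(terminal_o) == 2) or (e in {"P", "S"} and len(terminal_o) >= 3):
                feats.append(("Anion", tuple(sorted([i] + terminal_o))))
                anion_atoms.update(terminal_o)

    for i, e in enumerate(elems):
        deg = len(adj[i])
        if e == "N":
            if i in ring_atoms and deg == 2:
                feats.append(("HA", (i,)))  # pyridine-like
            elif deg <= 1 and i not in ring_atoms:
                feats.append(("HD", (i,)))
                feats.append(("Cation", (i,)))  # terminal amine, protonatable
            elif deg < 3:
                feats.append(("HD", (i,)))
                feats.append(("HA", (i,)))
            else:
                guanidinium_n = [j for j in adj[i] if elems[j] == "N"]
                if guanidinium_n:
                    feats.append(("Cation", tuple(sorted([i] + guanidinium_n))))
        elif e == "O":
            if i in anion_atoms:
                feats.append(("HA", (i,)))
                continue
            feats.append(("HA", (i,)))
            if deg <= 1:
                neighbour = next(iter(adj[i]), None)
                if neighbour is not None:
                    d = float(np.linalg.norm(atoms[i].coord - atoms[neighbour].coord))
                    if d > 1.30:  # single-bond length: hydroxyl, carries H
                        feats.append(("HD", (i,)))
    for i, e in enumerate(elems):
        if e == "C" and not any(elems[j] in {"N", "O"} for j in adj[i]):
            feats.append(("Hydrophobe", (i,)))
    return feats


def _het_groups_to_poses(groups: list[Residue]) -> list[LigandPose]:
    if not groups:
        return []
    # merge covalently connected HET residues into one pose
    n = len(groups)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mind = min(
                float(np.linalg.norm(a.coord - b.coord))
                for a in groups[i].atoms for b in groups[j].atoms
            )
            if mind <= 1.9:
                parent[find(i)] = find(j)

    merged: dict[int, list[Residue]] = {}
    for i in range(n):
        merged.setdefault(find(i), []).append(groups[i])

    poses = []
    for members in merged.values():
        atoms = [a for m in members for a in m.atoms]
        lead = members[0]
        poses.append(
            LigandPose(
                residue_name=lead.name,
                atoms=atoms,
                chain_id=lead.chain_id,
                author_number=lead.author_number,
                typed_features=type_ligand_features(atoms),
            )
        )
    return poses


def extract_ligands(s: Structure, exclude: set[str] | None = None) -> list[LigandPose]:
    """Return one typed pose per connected HET group not in ``exclude``.

    Structures parsed with :func:`parse_structure` already carry poses; this
    re-derives them (e.g. after editing the structure or with a different
    exclusion list).
    """
    exclude = DEFAULT_LIGAND_EXCLUDE if exclude is None else exclude
    groups = []
    for pose in s.ligands:
        if pose.residue_name in exclude:
            continue
        groups.append(
            Residue(
                author_number=pose.author_number,
                name=pose.residue_name,
                atoms=pose.atoms,
                chain_id=pose.chain_id,
            )
        )
    return _het_groups_to_poses(groups)
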