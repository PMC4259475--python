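"""Detection of non-covalent protein-ligand and intra-protein interactions.

Seven interaction classes are recognised: strong hydrogen bonds (N-H...O,
O-H...O, N-H...N and friends), weak C-H...O / C-H...N hydrogen bonds, salt
bridges, cation-pi, pi-pi stacking (face and edge), CH-pi and van der Waals
contacts.  No single canonical cutoff set exists for
these interaction classes; the defaults below follow common
structure-interaction-fingerprint practice and every one of them is overridable through
:class:`GeometryCriteria` and recorded in serialised output headers.

Crystal structures lack hydrogens, so donor directionality is inferred where
the heavy-atom geometry pins it down (backbone amides); otherwise detection
falls back to a distance-only criterion flagged ``no-angle`` in the record
subtype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .canonical_numbering import ResidueMap
from .structure_io import LigandPose, Residue, Structure

__all__ = [
    "GeometryCriteria", "InteractionRecord",
    "detect_hbonds", "detect_salt_bridges", "detect_cation_pi",
    "detect_pi_stacking", "detect_ch_pi", "detect_vdw", "interaction_table",
]

KINDS = ("HBOND_STRONG", "HBOND_WEAK", "SALT_BRIDGE", "CATION_PI",
         "PI_PI", "CH_PI", "VDW")


@dataclass(frozen=True)
class GeometryCriteria:
    """Per-kind geometric cutoffs (Angstrom / degrees); all user-overridable."""

    hbond_da_max: float = 3.5          # strong H-bond donor...acceptor
    hbond_dha_min: float = 120.0       # D-H...A angle when H is inferable
    hbond_weak_ca_max: float = 3.8     # weak C...A distance
    salt_bridge_max: float = 4.0       # min heavy-atom distance, opposite charges
    cation_pi_dist_max: float = 6.0    # charge centre to ring centroid
    cation_pi_angle_max: float = 30.0  # centroid->cation vs ring normal
    pipi_face_dist_max: float = 5.5
    pipi_face_angle_max: float = 30.0  # interplanar
    pipi_edge_dist_min: float = 4.5
    pipi_edge_dist_max: float = 6.5
    pipi_edge_angle_min: float = 60.0
    chpi_dist_max: float = 4.5         # C to ring centroid
    chpi_elevation_min: float = 30.0   # above the ring plane
    vdw_pad: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"criterion {name} must be positive")

    def header(self) -> str:
        pairs = "; ".join(f"{k}={v:g}" for k, v in sorted(self.__dict__.items()))
        return f"# criteria: {pairs}"


@dataclass
class InteractionRecord:
    kind: str
    chain_id: str
    author_number: int
    residue_name: str
    residue_atoms: tuple[str, ...]
    partner: str                    # ligand feature description or partner residue
    distance: float
    angle: float | None = None
    subtype: str = ""
    ligand_role: str | None = None  # HD/HA/Ar/Cation/Anion for protein-ligand records
    canonical: int | None = None
    anchor: str | None = None

    def key(self) -> tuple:
        return (self.kind, self.chain_id, self.author_number,
                self.residue_atoms, self.partner, self.subtype)


# ---------------------------------------------------------------------------
# protein-side chemistry tables (heavy atoms only)
# ---------------------------------------------------------------------------

SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("ND2",),
    "GLN": ("NE2",), "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",), "CYS": ("SG",),
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),  # ambiguous protonation: donor and acceptor
}

AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
}

CATION_GROUPS: dict[str, tuple[str, tuple[str, ...]]] = {
    # centre atom, full charged-group atoms
    "LYS": ("NZ", ("NZ",)),
    "ARG": ("CZ", ("NE", "NH1", "NH2", "CZ")),
}

ANION_GROUPS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.10,
              "SE": 1.90}


def _ring_geometry(res: Residue, names: tuple[str, ...]):
    pts = []
    for n in names:
        a = res.atom(n)
        if a is None:
            return None
        pts.append(a.coord)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _ligand_ring_geometry(lig: LigandPose, idx: tuple[int, ...]):
    pts = np.array([lig.atoms[i].coord for i in idx])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _protein_residues(s: Structure):
    for residues in s.chains.values():
        yield from residues


def _backbone_nh_direction(chain: list[Residue], i: int) -> np.ndarray | None:
    """Idealised amide H direction: bisector opposite the N-CA and N-C(prev) bonds."""
    r = chain[i]
    n = r.atom("N")
    ca = r.atom("CA")
    if n is None or ca is None or i == 0 or r.name == "PRO":
        return None
    c_prev = chain[i - 1].atom("C")
    if c_prev is None:
        return None
    v1 = ca.coord - n.coord
    v2 = c_prev.coord - n.coord
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    h_dir = -(v1 + v2)
    norm = np.linalg.norm(h_dir)
    if norm < 1e-6:
        return None
    return h_dir / norm


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    return math.degrees(math.acos(c))


def _mk_record(kind, res, atoms, partner, dist, angle=None, subtype="", role=None):
    return InteractionRecord(
        kind=kind, chain_id=res.chain_id, author_number=res.author_number,
        residue_name=res.name, residue_atoms=tuple(atoms), partner=partner,
        distance=float(dist), angle=angle, subtype=subtype, ligand_role=role,
    )


def detect_hbonds(
    s: Structure, lig: LigandPose, crit: GeometryCriteria = GeometryCriteria()
) -> list[InteractionRecord]:
    """Strong and weak hydrogen bonds between protein and ligand.

    Strong: donor...acceptor <= ``hbond_da_max`` with D-H...A >= ``hbond_dha_min``
    when the H direction is inferable (backbone amides); otherwise
    distance-only with a ``no-angle`` flag.  Weak: aromatic/sp2 ligand C-H
    donors to protein acceptors within ``hbond_weak_ca_max``.
    """
    records: list[InteractionRecord] = []
    lig_donors = [i for idx in lig.features("HD") for i in idx]
    lig_acceptors = [i for idx in lig.features("HA") for i in idx]
    ar_carbons = sorted({i for idx in lig.features("Ar") for i in idx
                         if lig.atoms[i].element.upper() == "C"})

    for residues in s.chains.values():
        for ridx, res in enumerate(residues):
            # protein acceptors <- ligand donors (strong, distance-only: ligand H unknown)
            acceptor_atoms = [("O", "backbone")]
            for name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
                acceptor_atoms.append((name, "sidechain"))
            for aname, where in acceptor_atoms:
                a = res.atom(aname)
                if a is None:
                    continue
                for di in lig_donors:
                    d = float(np.linalg.norm(a.coord - lig.atoms[di].coord))
                    if d <= crit.hbond_da_max:
                        delem = lig.atoms[di].element.upper()
                        records.append(_mk_record(
                            "HBOND_STRONG", res, (aname,),
                            f"ligand:{lig.atoms[di].name}", d,
                            subtype=f"{delem}-H...{a.element.upper()} ({where}, no-angle)",
                            role="HD"))
                # weak: ligand aromatic C-H -> protein acceptor
                for ci in ar_carbons:
                    d = float(np.linalg.norm(a.coord - lig.atoms[ci].coord))
                    if d <= crit.hbond_weak_ca_max:
                        records.append(_mk_record(
                            "HBOND_WEAK", res, (aname,),
                            f"ligand:{lig.atoms[ci].name}", d,
                            subtype=f"C-H...{a.element.upper()} ({where})", role="HD"))

            # protein donors -> ligand acceptors
            n = res.atom("N")
            if n is not None:
                h_dir = _backbone_nh_direction(residues, ridx)
                for ai in lig_acceptors:
                    acc = lig.atoms[ai]
                    d = float(np.linalg.norm(n.coord - acc.coord))
                    if d > crit.hbond_da_max:
                        continue
                    subtype = f"N-H...{acc.element.upper()} (backbone)"
                    angle = None
                    if h_dir is not None:
                        h_pos = n.coord + 1.01 * h_dir
                        angle = _angle_deg(n.coord - h_pos, acc.coord - h_pos)
                        if angle < crit.hbond_dha_min:
                            continue
                    else:
                        subtype += " (no-angle)"
                    records.append(_mk_record("HBOND_STRONG", res, ("N",),
                                              f"ligand:{acc.name}", d, angle,
                                              subtype, role="HA"))
            for dname in SIDECHAIN_DONORS.get(res.name, ()):
                datom = res.atom(dname)
                if datom is None:
                    continue
                for ai in lig_acceptors:
                    acc = lig.atoms[ai]
                    d = float(np.linalg.norm(datom.coord - acc.coord))
                    if d <= crit.hbond_da_max:
                        delem = datom.element.upper()
                        records.append(_mk_record(
                            "HBOND_STRONG", res, (dname,),
                            f"ligand:{acc.name}", d,
                            subtype=f"{delem}-H...{acc.element.upper()} (sidechain, no-angle)",
                            role="HA"))
    return records


def detect_salt_bridges(
    s: Structure, lig: LigandPose | None = None,
    crit: GeometryCriteria = GeometryCriteria(),
) -> list[InteractionRecord]:
    """Opposite formal charges with minimum heavy-atom distance <= cutoff.

    With ``lig=None`` only intra-protein ion pairs (Lys/Arg vs Asp/Glu) are
    reported -- these include the conformation-diagnostic K162-E181 and
    E181-R255 pairs.
    """
    records: list[InteractionRecord] = []
    cations = []
    anions = []
    for res in _protein_residues(s):
        if res.name in CATION_GROUPS:
            _, group = CATION_GROUPS[res.name]
            atoms = [res.atom(n) for n in group]
            atoms = [a for a in atoms if a is not None]
            if atoms:
                cations.append((res, atoms))
        if res.name in ANION_GROUPS:
            atoms = [res.atom(n) for n in ANION_GROUPS[res.name]]
            atoms = [a for a in atoms if a is not None]
            if atoms:
                anions.append((res, atoms))

    def min_dist(atoms_a, coords_b) -> float:
        return min(float(np.linalg.norm(a.coord - c)) for a in atoms_a for c in coords_b)

    if lig is None:
        for cres, catoms in cations:
            for ares, aatoms in anions:
                d = min_dist(catoms, [a.coord for a in aatoms])
                if d <= crit.salt_bridge_max:
                    records.append(_mk_record(
                        "SALT_BRIDGE", cres, tuple(a.name for a in catoms),
                        f"{ares.name}{ares.author_number}", d,
                        subtype="protein-protein"))
        return records

    for kind, groups in (("Anion", lig.features("Anion")), ("Cation", lig.features("Cation"))):
        partners = cations if kind == "Anion" else anions
        for idx in groups:
            coords = [lig.atoms[i].coord for i in idx]
            label = "+".join(lig.atoms[i].name for i in idx)
            for res, atoms in partners:
                d = min_dist(atoms, coords)
                if d <= crit.salt_bridge_max:
                    records.append(_mk_record(
                        "SALT_BRIDGE", res, tuple(a.name for a in atoms),
                        f"ligand:{label}", d, role=kind))
    return records


def _protein_cations(s: Structure):
    for res in _protein_residues(s):
        if res.name in CATION_GROUPS:
            centre_name, _ = CATION_GROUPS[res.name]
            a = res.atom(centre_name)
            if a is not None:
                yield res, centre_name, a.coord


def _protein_rings(s: Structure):
    for res in _protein_residues(s):
        for names in AROMATIC_RINGS.get(res.name, ()):
            geom = _ring_geometry(res, names)
            if geom is not None:
                yield res, names, geom[0], geom[1]


def detect_cation_pi(
    s: Structure, lig: LigandPose | None = None,
    crit: GeometryCriteria = GeometryCriteria(),
) -> list[InteractionRecord]:
    """Cation charge centre within distance of a ring centroid, near the ring normal.

    Protein cations vs ligand rings when a pose is given; intra-protein
    Lys/Arg vs Phe/Tyr/Trp/His rings always (this captures the K162-F275
    coupling of the non-DFG-in conformations).
    """
    records: list[InteractionRecord] = []

    def eval_pair(cpos, centroid, normal):
        d = float(np.linalg.norm(cpos - centroid))
        if d > crit.cation_pi_dist_max:
            return None
        v = cpos - centroid
        ang = _angle_deg(v, normal)
        ang = min(ang, 180.0 - ang)
        if ang > crit.cation_pi_angle_max:
            return None
        return d, ang

    if lig is not None:
        for res, cname, cpos in _protein_cations(s):
            for idx in lig.features("Ar"):
                centroid, normal = _ligand_ring_geometry(lig, idx)
                hit = eval_pair(cpos, centroid, normal)
                if hit:
                    records.append(_mk_record(
                        "CATION_PI", res, (cname,),
                        "ligand:ring(" + ",".join(lig.atoms[i].name for i in idx) + ")",
                        hit[0], hit[1], role="Ar"))
        # ligand cation vs protein ring
        for idx in lig.features("Cation"):
            cpos = np.mean([lig.atoms[i].coord for i in idx], axis=0)
            for res, names, centroid, normal in _protein_rings(s):
                hit = eval_pair(cpos, centroid, normal)
                if hit:
                    records.append(_mk_record(
                        "CATION_PI", res, names,
                        "ligand:cation(" + ",".join(lig.atoms[i].name for i in idx) + ")",
                        hit[0], hit[1], role="Cation"))
    else:
        for res, cname, cpos in _protein_cations(s):
            for rres, names, centroid, normal in _protein_rings(s):
                if rres is res:
                    continue
                hit = eval_pair(cpos, centroid, normal)
                if hit:
                    records.append(_mk_record(
                        "CATION_PI", res, (cname,),
                        f"{rres.name}{rres.author_number}", hit[0], hit[1],
                        subtype="protein-protein"))
    return records


def detect_pi_stacking(
    s: Structure, lig: LigandPose, crit: GeometryCriteria = GeometryCriteria()
) -> list[InteractionRecord]:
    """Face (parallel) and edge (T-shaped) stacking of protein vs ligand rings."""
    records: list[InteractionRecord] = []
    for res, names, centroid, normal in _protein_rings(s):
        for idx in lig.features("Ar"):
            lcent, lnorm = _ligand_ring_geometry(lig, idx)
            d = float(np.linalg.norm(centroid - lcent))
            inter = _angle_deg(normal, lnorm)
            inter = min(inter, 180.0 - inter)
            label = "ligand:ring(" + ",".join(lig.atoms[i].name for i in idx) + ")"
            if d <= crit.pipi_face_dist_max and inter <= crit.pipi_face_angle_max:
                records.append(_mk_record("PI_PI", res, names, label, d, inter,
                                          subtype="face", role="Ar"))
            elif (crit.pipi_edge_dist_min <= d <= crit.pipi_edge_dist_max
                  and inter >= crit.pipi_edge_angle_min):
                records.append(_mk_record("PI_PI", res, names, label, d, inter,
                                          subtype="edge", role="Ar"))
    return records


def detect_ch_pi(
    s: Structure, lig: LigandPose, crit: GeometryCriteria = GeometryCriteria()
) -> list[InteractionRecord]:
    """Ligand carbons over protein rings and protein side-chain carbons over ligand rings."""
    records: list[InteractionRecord] = []
    ring_membership = {i for idx in lig.features("Ar") for i in idx}
    lig_carbons = [i for i, a in enumerate(lig.atoms)
                   if a.element.upper() == "C" and i not in ring_membership]

    def elevation(pos, centroid, normal) -> tuple[float, float] | None:
        d = float(np.linalg.norm(pos - centroid))
        if d > crit.chpi_dist_max:
            return None
        ang = _angle_deg(pos - centroid, normal)
        elev = abs(90.0 - min(ang, 180.0 - ang))
        if elev < crit.chpi_elevation_min:
            return None
        return d, elev

    for res, names, centroid, normal in _protein_rings(s):
        for ci in lig_carbons:
            hit = elevation(lig.atoms[ci].coord, centroid, normal)
            if hit:
                records.append(_mk_record("CH_PI", res, names,
                                          f"ligand:{lig.atoms[ci].name}",
                                          hit[0], hit[1], role="Hydrophobe"))
    for idx in lig.features("Ar"):
        lcent, lnorm = _ligand_ring_geometry(lig, idx)
        label = "ligand:ring(" + ",".join(lig.atoms[i].name for i in idx) + ")"
        for res in _protein_residues(s):
            ring_names = {n for ring in AROMATIC_RINGS.get(res.name, ()) for n in ring}
            for a in res.atoms:
                if a.element.upper() != "C" or a.name in {"C", "CA"} | ring_names:
                    continue
                hit = elevation(a.coord, lcent, lnorm)
                if hit:
                    records.append(_mk_record("CH_PI", res, (a.name,), label,
                                              hit[0], hit[1], role="Ar"))
    return records


def detect_vdw(
    s: Structure, lig: LigandPose, crit: GeometryCriteria = GeometryCriteria()
) -> list[InteractionRecord]:
    """van der Waals contacts (excluded from the fingerprint)."""
    records = []
    for res in _protein_residues(s):
        for a in res.heavy_atoms():
            ra = _VDW_RADII.get(a.element.upper(), 1.7)
            for b in lig.atoms:
                if b.element.upper() == "H":
                    continue
                rb = _VDW_RADII.get(b.element.upper(), 1.7)
                d = float(np.linalg.norm(a.coord - b.coord))
                if d <= ra + rb + crit.vdw_pad:
                    records.append(_mk_record("VDW", res, (a.name,),
                                              f"ligand:{b.name}", d))
    return records


def interaction_table(
    s: Structure,
    lig: LigandPose | None,
    m: ResidueMap | None = None,
    crit: GeometryCriteria = GeometryCriteria(),
    include_vdw: bool = False,
) -> list[InteractionRecord]:
    """Union of all detectors with canonical residue labels, sorted by position.

    With ``lig=None`` only the intra-protein ion pairs and cation-pi couplings
    are reported (the apo case).
    """
    records: list[InteractionRecord] = []
    records += detect_salt_bridges(s, None, crit)
    records += detect_cation_pi(s, None, crit)
    if lig is not None:
        records += detect_hbonds(s, lig, crit)
        records += detect_salt_bridges(s, lig, crit)
        records += detect_cation_pi(s, lig, crit)
        records += detect_pi_stacking(s, lig, crit)
        records += detect_ch_pi(s, lig, crit)
        if include_vdw:
            records += detect_vdw(s, lig, crit)
    if m is not None:
        rev_anchor = {v: k for k, v in m.anchors.items()}
        for rec in records:
            if rec.chain_id == m.chain_id:
                rec.canonical = m.canonical_of(rec.author_number)
                rec.anchor = rev_anchor.get((rec.author_number, ""))
    records.sort(key=lambda r: (r.canonical or 10**6, r.author_number, r.kind, r.partner))
    return records


def table_to_tsv(records: list[InteractionRecord], crit: GeometryCriteria) -> str:
    lines = [crit.header(),
             "kind\tchain\tresidue\tcanonical\tatoms\tpartner\tdistance\tangle\tsubtype"]
    for r in records:
        angle = f"{r.angle:.1f}" if r.angle is not None else ""
        canonical = str(r.canonical) if r.canonical is not None else ""
        lines.append(
            f"{r.kind}\t{r.chain_id}\t{r.residue_name}{r.author_number}\t{canonical}\t"
            f"{'+'.join(r.residue_atoms)}\t{r.partner}\t{r.distance:.2f}\t{angle}\t{r.subtype}"
        )
    return "\n".join(lines) + "\n"
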