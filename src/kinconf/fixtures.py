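"""Deterministic synthetic toy-kinase structures and toy complexes.

Every conformational class (DFG in/out/out-up, alphaC in/out, G-loop
extended/folded) and every fingerprint bit can be realised on demand, so the
whole pipeline is testable without downloading a single structure.  The toy
kinase models only the motif segments that carry the metrics -- G-loop, beta3
strand, alphaC helix, hinge, catalytic loop and the DFG/A-loop -- placed in a
common frame that mimics the spatial organisation of a kinase N/C-lobe cleft:

* the G-loop strand is built residue-by-residue from ideal internal
  coordinates (N-CA 1.458, CA-C 1.525, C-N 1.329 A, ideal angles) so its
  phi/psi are exactly the requested values;
* the remaining segments are "bead" backbones: C-alpha traces at ~3.5 A
  spacing with locally ideal N/C/O geometry, joined by implicit chain breaks.

This is deliberately non-physical (no packing, no loop closure between
segments) but geometrically valid PDB, and the class-dependent side-chain
placements honour the qualitative geometry of the real conformations: DFG-in
keeps the K162-E181 ion pair with F275 packed below the alphaC glutamate;
DFG-out(up) swings the loop parallel to the helix with F275 above E181 and
D274 in the polar Q185/R255 environment; classic DFG-out drops D274 into the
C-lobe with F275 on the opposite side; the folded G-loop curls its backbone
away from the beta reference and drops F144 toward the ATP-site centroid.

Author numbering equals canonical AURKA numbering, so the closed loop runs
through the real sequence-alignment mapping rather than a shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .canonical_numbering import ResidueMap, build_residue_map, load_reference_profile
from .conformation import Calibration, calibrate
from .interactions import _backbone_nh_direction, _ring_geometry, AROMATIC_RINGS
from .structure_io import Atom, LigandPose, Residue, Structure, element_mass

__all__ = ["FixtureSpec", "make_toy_kinase", "make_toy_complex",
           "fixture_residue_map", "default_calibration", "ALL_LABEL_COMBOS"]

DFG_STATES = ("IN", "OUT", "OUT_UP")
ALPHA_C_STATES = ("IN", "OUT")
G_LOOP_STATES = ("EXTENDED", "FOLDED")

ALL_LABEL_COMBOS = tuple(
    (d, a, g) for d in DFG_STATES for a in ALPHA_C_STATES for g in G_LOOP_STATES
)


@dataclass(frozen=True)
class FixtureSpec:
    dfg: str = "IN"
    alpha_c: str = "IN"
    g_loop: str = "EXTENDED"
    noise_sigma: float = 0.0
    seed: int = 0
    ligand_motifs: frozenset[int] = frozenset()  # fingerprint bits to realise

    def __post_init__(self) -> None:
        if self.dfg not in DFG_STATES:
            raise ValueError(f"unknown DFG label {self.dfg!r}")
        if self.alpha_c not in ALPHA_C_STATES:
            raise ValueError(f"unknown alphaC label {self.alpha_c!r}")
        if self.g_loop not in G_LOOP_STATES:
            raise ValueError(f"unknown G-loop label {self.g_loop!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        bad = set(self.ligand_motifs) - set(range(1, 15))
        if bad:
            raise ValueError(f"unknown fingerprint bits requested: {sorted(bad)}")


# ---------------------------------------------------------------------------
# side-chain templates (local frame: CA at origin, side chain along +x,
# branching in the xy-plane, ring normals along +z)
# ---------------------------------------------------------------------------

def _zigzag(names: list[str], elements: list[str]) -> list[tuple[str, str, np.ndarray]]:
    out = []
    for i, (n, e) in enumerate(zip(names, elements)):
        out.append((n, e, np.array([1.5 + 1.3 * i, 0.45 * (-1) ** i, 0.0])))
    return out


def _hexagon(center_x: float, names: list[str]) -> list[tuple[str, str, np.ndarray]]:
    # vertex order: CG at 180 deg (toward CB), then alternating
    angles = {0: 180, 1: 120, 2: 240, 3: 60, 4: 300, 5: 0}
    out = []
    for i, name in enumerate(names):
        th = math.radians(angles[i])
        out.append((name, "C", np.array([center_x + 1.39 * math.cos(th),
                                         1.39 * math.sin(th), 0.0])))
    return out


def _pentagon(center_x: float, names: list[str], elements: list[str]):
    out = []
    for i, (name, e) in enumerate(zip(names, elements)):
        th = math.radians(180 + i * 72)
        out.append((name, e, np.array([center_x + 1.17 * math.cos(th),
                                       1.17 * math.sin(th), 0.0])))
    return out


def _templates() -> dict[str, list[tuple[str, str, np.ndarray]]]:
    t: dict[str, list[tuple[str, str, np.ndarray]]] = {}
    t["ALA"] = [("CB", "C", np.array([1.5, 0.0, 0.0]))]
    t["SER"] = _zigzag(["CB", "OG"], ["C", "O"])
    t["CYS"] = _zigzag(["CB", "SG"], ["C", "S"])
    t["THR"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("OG1", "O", np.array([2.2, 1.1, 0.0])),
                ("CG2", "C", np.array([2.2, -1.1, 0.0]))]
    t["VAL"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG1", "C", np.array([2.2, 1.2, 0.0])),
                ("CG2", "C", np.array([2.2, -1.2, 0.0]))]
    t["LEU"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.8, 0.5, 0.0])),
                ("CD1", "C", np.array([3.6, 1.6, 0.0])),
                ("CD2", "C", np.array([3.6, -0.7, 0.0]))]
    t["ILE"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG1", "C", np.array([2.8, 0.5, 0.0])),
                ("CG2", "C", np.array([1.9, -1.3, 0.0])),
                ("CD1", "C", np.array([4.1, 0.0, 0.0]))]
    t["MET"] = _zigzag(["CB", "CG", "SD", "CE"], ["C", "C", "S", "C"])
    t["PRO"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.0, 1.2, 0.0])),
                ("CD", "C", np.array([1.0, 2.0, 0.0]))]
    t["LYS"] = _zigzag(["CB", "CG", "CD", "CE", "NZ"], ["C", "C", "C", "C", "N"])
    t["ARG"] = _zigzag(["CB", "CG", "CD", "NE"], ["C", "C", "C", "N"]) + [
        ("CZ", "C", np.array([6.7, 0.0, 0.0])),
        ("NH1", "N", np.array([7.5, 1.1, 0.0])),
        ("NH2", "N", np.array([7.5, -1.1, 0.0]))]
    t["ASP"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.9, 0.0, 0.0])),
                ("OD1", "O", np.array([3.6, 1.1, 0.0])),
                ("OD2", "O", np.array([3.6, -1.1, 0.0]))]
    t["GLU"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.8, 0.45, 0.0])),
                ("CD", "C", np.array([4.2, 0.0, 0.0])),
                ("OE1", "O", np.array([4.9, 1.1, 0.0])),
                ("OE2", "O", np.array([4.9, -1.1, 0.0]))]
    t["ASN"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.9, 0.0, 0.0])),
                ("OD1", "O", np.array([3.6, 1.1, 0.0])),
                ("ND2", "N", np.array([3.6, -1.1, 0.0]))]
    t["GLN"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.8, 0.45, 0.0])),
                ("CD", "C", np.array([4.2, 0.0, 0.0])),
                ("OE1", "O", np.array([4.9, 1.1, 0.0])),
                ("NE2", "N", np.array([4.9, -1.1, 0.0]))]
    t["PHE"] = [("CB", "C", np.array([1.5, 0.0, 0.0]))] + _hexagon(
        4.29, ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])
    t["TYR"] = [("CB", "C", np.array([1.5, 0.0, 0.0]))] + _hexagon(
        4.29, ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]) + [
        ("OH", "O", np.array([7.05, 0.0, 0.0]))]
    t["HIS"] = [("CB", "C", np.array([1.5, 0.0, 0.0]))] + _pentagon(
        4.07, ["CG", "ND1", "CE1", "NE2", "CD2"], ["C", "N", "C", "N", "C"])
    # approximate planar indole: fused pentagon + hexagon sharing CD2-CE2
    t["TRP"] = [("CB", "C", np.array([1.5, 0.0, 0.0])),
                ("CG", "C", np.array([2.9, 0.0, 0.0])),
                ("CD1", "C", np.array([3.6, 1.1, 0.0])),
                ("NE1", "N", np.array([4.95, 0.7, 0.0])),
                ("CE2", "C", np.array([4.95, -0.7, 0.0])),
                ("CD2", "C", np.array([3.6, -1.1, 0.0])),
                ("CE3", "C", np.array([3.5, -2.5, 0.0])),
                ("CZ3", "C", np.array([4.7, -3.3, 0.0])),
                ("CH2", "C", np.array([5.95, -2.85, 0.0])),
                ("CZ2", "C", np.array([6.1, -1.45, 0.0]))]
    t["GLY"] = []
    return t


_TEMPLATES = _templates()


def _template_com(resname: str) -> np.ndarray:
    atoms = _TEMPLATES[resname]
    if not atoms:
        return np.zeros(3)
    w = np.array([element_mass(e) for _, e, _ in atoms])
    pts = np.array([p for _, _, p in atoms])
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def sidechain_reach(resname: str) -> float:
    """Distance from C-alpha to the template side-chain COM."""
    return float(np.linalg.norm(_template_com(resname)))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return v / n


def _perp(v: np.ndarray, hint: np.ndarray | None = None) -> np.ndarray:
    h = np.array([0.31, 0.52, 0.8]) if hint is None else np.asarray(hint, float)
    p = h - np.dot(h, v) * v
    if np.linalg.norm(p) < 1e-6:
        p = np.array([1.0, 0.0, 0.0]) - v[0] * v
    return _unit(p)


def _frame_rotation(axis: np.ndarray, normal_hint: np.ndarray | None) -> np.ndarray:
    """Rotation taking local +x to ``axis`` and local +z toward ``normal_hint``."""
    f1 = _unit(axis)
    f3 = _perp(f1, normal_hint)
    f2 = np.cross(f3, f1)
    return np.column_stack([f1, f2, f3])


def place_side_chain(
    resname: str, ca: np.ndarray, aim: np.ndarray,
    normal_hint: np.ndarray | None = None,
) -> list[Atom]:
    """Side-chain atoms for ``resname`` with the chain axis along ``aim``-``ca``.

    The side-chain COM lands on the ray from CA toward ``aim`` at the
    template's reach; ring planes contain the axis with normal steered by
    ``normal_hint``.
    """
    template = _TEMPLATES[resname]
    if not template:
        return []
    com_local = _template_com(resname)
    axis = _unit(np.asarray(aim, float) - ca)
    rot = _frame_rotation(axis, normal_hint)
    # align the local COM direction (not raw +x) with the requested axis so
    # the realised COM sits exactly on the CA->aim ray
    a_local = _unit(com_local)
    e2 = _unit(np.array([-a_local[1], a_local[0], 0.0])) if abs(a_local[2]) < 0.99 \
        else np.array([1.0, 0.0, 0.0])
    e3 = np.cross(a_local, e2)
    local_frame = np.column_stack([a_local, e2, e3])
    full_rot = rot @ local_frame.T
    return [Atom(name=n, element=e, coord=ca + full_rot @ p) for n, e, p in template]


def _bead_backbone(ca: np.ndarray, t_hat: np.ndarray, u: np.ndarray,
                   flip: bool = False) -> list[Atom]:
    """Locally ideal N/C/O around a C-alpha for a bead (non-NeRF) residue.

    ``flip`` alternates the carbonyl side residue-by-residue, mimicking the
    alternation of a real strand so that neighbouring hydrogen-bond sites do
    not superimpose.
    """
    n_dir = _unit(-t_hat - 0.4 * u)
    c_dir = _unit(t_hat - 0.4 * u)
    w = _unit(np.cross(t_hat, u)) * (-1.0 if flip else 1.0)
    n = ca + 1.458 * n_dir
    c = ca + 1.525 * c_dir
    o = c + 1.229 * w
    return [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c), Atom("O", "O", o)]


# ---------------------------------------------------------------------------
# ideal-internal-coordinate backbone (for the G-loop strand)
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place the next atom from three predecessors (natural-extension reference frame)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(angle),
                  bond * math.sin(angle) * math.cos(torsion),
                  bond * math.sin(angle) * math.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O backbone from per-residue (phi, psi), ideal bonds/angles, omega=180."""
    n_res = len(phi_psi)
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = ca0 + 1.525 * np.array([math.cos(math.radians(180 - 111.2)),
                                 math.sin(math.radians(180 - 111.2)), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi_prev)
        ca_next = _nerf(prev["CA"], prev["C"], n_next, 1.458, 121.7, 180.0)
        c_next = _nerf(prev["C"], n_next, ca_next, 1.525, 111.2, phi_psi[i][0])
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, r in enumerate(res):
        if i + 1 < n_res:
            bisector = _unit(_unit(r["CA"] - r["C"]) + _unit(res[i + 1]["N"] - r["C"]))
            r["O"] = r["C"] - 1.229 * bisector
        else:
            r["O"] = r["C"] + 1.229 * _unit(np.cross(r["C"] - r["CA"],
                                                     np.array([0.0, 0.0, 1.0])))
    return res


# ---------------------------------------------------------------------------
# toy-kinase layout
# ---------------------------------------------------------------------------

_PROFILE = load_reference_profile()
_ONE_TO_THREE = {v: k for k, v in
                 {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
                  "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
                  "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
                  "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}.items()}


def _ref_name(pos: int) -> str:
    return _ONE_TO_THREE[_PROFILE.residue_at(pos)]


# class-dependent side-chain COM aim points (Angstrom, common frame with the
# ATP cleft near the origin)
_E181_AIM = {"IN": np.array([-2.5, 3.0, 0.5]), "OUT": np.array([-8.5, 9.0, 5.5])}
_E181_CA = {"IN": np.array([-0.5, 5.0, 2.3]), "OUT": np.array([-6.5, 7.0, 4.0])}

_DFG_LAYOUT: dict[str, dict[int, tuple[np.ndarray, np.ndarray | None]]] = {
    # canonical -> (CA position, side-chain aim point or None for default)
    "IN": {
        271: (np.array([9.5, 0.5, -5.0]), None),
        273: (np.array([7.0, 0.5, -5.0]), np.array([7.2, 1.2, -3.7])),
        274: (np.array([3.5, 0.0, -5.5]), np.array([3.0, 1.0, -3.3])),
        275: (np.array([0.5, -0.5, -5.5]), np.array([-1.9, 1.2, -3.1])),
        276: (np.array([-2.0, -2.0, -6.0]), None),
        277: (np.array([-2.5, -4.5, -4.0]), np.array([-1.5, -6.6, -0.4])),
        280: (np.array([4.5, -7.5, -0.5]), np.array([3.8, -9.5, 2.4])),
        284: (np.array([6.5, -9.0, -2.5]), None),
        288: (np.array([7.5, -11.0, -1.5]), np.array([6.4, -12.2, -0.3])),
        292: (np.array([9.0, -13.5, -2.5]), None),
    },
    "OUT_UP": {
        271: (np.array([2.0, 0.5, 1.0]), None),
        273: (np.array([-2.0, 2.0, 3.0]), np.array([-2.5, 3.2, 3.8])),
        274: (np.array([-4.5, 3.0, 4.5]), np.array([-5.3, 4.8, 6.1])),
        275: (np.array([-4.05, 6.15, 4.0]), np.array([-6.5, 8.0, 7.0])),
        276: (np.array([-2.0, 6.5, 2.0]), None),
        277: (np.array([-0.5, 4.0, -0.5]), np.array([0.5, -3.5, 4.0])),
        280: (np.array([3.0, -3.0, 3.0]), np.array([4.5, -5.5, 5.5])),
        284: (np.array([6.0, -6.0, 1.5]), None),
        288: (np.array([8.0, -8.5, 1.0]), np.array([7.0, -9.8, 2.2])),
        292: (np.array([10.0, -11.0, 0.0]), None),
    },
    "OUT": {
        271: (np.array([8.0, -1.0, -6.0]), None),
        273: (np.array([5.0, -1.0, -6.5]), np.array([5.0, -0.3, -5.2])),
        274: (np.array([2.5, -2.5, -7.0]), np.array([1.9, -4.0, -8.9])),
        275: (np.array([-1.9, 1.1, 3.1]), np.array([-4.5, 1.5, 6.5])),
        276: (np.array([-4.0, -1.0, -7.5]), None),
        277: (np.array([-3.5, -3.5, -5.0]), np.array([-2.5, -5.5, 1.0])),
        280: (np.array([2.0, -7.0, -2.0]), np.array([0.5, -9.0, 1.0])),
        284: (np.array([5.0, -9.0, -3.0]), None),
        288: (np.array([6.5, -11.5, -2.0]), np.array([5.4, -12.8, -0.8])),
        292: (np.array([8.5, -14.0, -3.0]), None),
    },
}

_GLOOP_F144_CA = {"EXTENDED": np.array([3.0, 2.5, 8.5]),
                  "FOLDED": np.array([2.0, 1.5, 4.5])}
_GLOOP_DIR = {"EXTENDED": np.array([0.9, 0.35, 0.2]),
              "FOLDED": np.array([0.8, -0.5, 0.3])}
_GLOOP_F144_AIM = {"EXTENDED": np.array([3.0, 1.2, 12.6]),
                   "FOLDED": np.array([8.7, 0.4, -0.2])}


def _interp_path(controls: dict[int, np.ndarray], positions: list[int]) -> dict[int, np.ndarray]:
    """Piecewise-linear C-alpha path through the control points."""
    keys = sorted(controls)
    out: dict[int, np.ndarray] = {}
    for pos in positions:
        if pos <= keys[0]:
            d = _unit(controls[keys[1]] - controls[keys[0]])
            out[pos] = controls[keys[0]] - 3.5 * (keys[0] - pos) * d
        elif pos >= keys[-1]:
            d = _unit(controls[keys[-1]] - controls[keys[-2]])
            out[pos] = controls[keys[-1]] + 3.5 * (pos - keys[-1]) * d
        else:
            hi = next(k for k in keys if k >= pos)
            lo = max(k for k in keys if k <= pos)
            if lo == hi:
                out[pos] = controls[lo].copy()
            else:
                f = (pos - lo) / (hi - lo)
                out[pos] = (1 - f) * controls[lo] + f * controls[hi]
    return out


def _bead_residue(pos: int, ca: np.ndarray, t_hat: np.ndarray,
                  aim: np.ndarray | None, normal_hint: np.ndarray | None = None) -> Residue:
    name = _ref_name(pos)
    if aim is None:
        u = _perp(t_hat) * (-1.0 if pos % 2 else 1.0)  # strand-like alternation
        aim_pt = ca + 2.0 * u
    else:
        u = _unit(aim - ca)
        aim_pt = aim
    atoms = _bead_backbone(ca, t_hat, u, flip=bool(pos % 2))
    atoms += place_side_chain(name, ca, aim_pt, normal_hint)
    return Residue(author_number=pos, name=name, atoms=atoms, chain_id="A")


def _segment(positions: list[int], ca_path: dict[int, np.ndarray],
             aims: dict[int, np.ndarray] | None = None,
             normals: dict[int, np.ndarray] | None = None) -> list[Residue]:
    aims = aims or {}
    normals = normals or {}
    residues = []
    for pos in positions:
        ca = ca_path[pos]
        nxt = ca_path.get(pos + 1)
        prv = ca_path.get(pos - 1)
        if nxt is not None and np.linalg.norm(nxt - ca) > 1e-6:
            t_hat = _unit(nxt - ca)
        elif prv is not None:
            t_hat = _unit(ca - prv)
        else:
            t_hat = np.array([1.0, 0.0, 0.0])
        residues.append(_bead_residue(pos, ca, t_hat, aims.get(pos), normals.get(pos)))
    return residues


def _gloop_segment(state: str) -> list[Residue]:
    positions = list(range(132, 153))
    beta = (-140.0, 135.0)
    folded_window = set(range(140, 147))
    phi_psi = [(-70.0, -40.0) if (state == "FOLDED" and p in folded_window) else beta
               for p in positions]
    backbone = build_backbone(phi_psi)
    # rigid placement: chain direction onto the state direction, F144 CA onto target
    i144 = positions.index(144)
    v_local = backbone[-1]["CA"] - backbone[0]["CA"]
    d_target = _unit(_GLOOP_DIR[state])
    axis_rot = _frame_rotation(v_local, None).T  # local chain dir -> +x
    rot = _frame_rotation(d_target, None) @ axis_rot
    ca144_local = backbone[i144]["CA"]
    shift = _GLOOP_F144_CA[state] - rot @ ca144_local
    residues = []
    for pos, bb in zip(positions, backbone):
        coords = {k: rot @ v + shift for k, v in bb.items()}
        name = _ref_name(pos)
        atoms = [Atom("N", "N", coords["N"]), Atom("CA", "C", coords["CA"]),
                 Atom("C", "C", coords["C"]), Atom("O", "O", coords["O"])]
        ca = coords["CA"]
        if name != "GLY":
            if pos == 144:
                aim = _GLOOP_F144_AIM[state]
                normal = None
            else:
                cb_dir = -(_unit(coords["N"] - ca) + _unit(coords["C"] - ca))
                aim = ca + 2.0 * _unit(cb_dir)
                normal = None
            atoms += place_side_chain(name, ca, aim, normal)
        residues.append(Residue(author_number=pos, name=name, atoms=atoms, chain_id="A"))
    return residues


def _helix_segment(spec: FixtureSpec) -> list[Residue]:
    positions = list(range(173, 191))
    ca_e = _E181_CA[spec.alpha_c]
    aim_e = _E181_AIM[spec.alpha_c]
    axis = _unit(np.array([-0.25, 0.85, 0.47]))
    e1 = _perp(ca_e - aim_e, hint=None)
    e1 = _unit(e1 - np.dot(e1, axis) * axis)
    e2 = np.cross(axis, e1)
    origin = ca_e - 2.3 * e1
    ca_path = {}
    for pos in positions:
        k = pos - 181
        th = math.radians(100.0 * k)
        ca_path[pos] = origin + 1.5 * k * axis + 2.3 * (math.cos(th) * e1 + math.sin(th) * e2)
    return _segment(positions, ca_path, aims={181: aim_e})


def make_toy_kinase(spec: FixtureSpec) -> Structure:
    """Build a toy kinase realising the requested conformational labels.

    Deterministic for a fixed spec; Gaussian coordinate noise of
    ``spec.noise_sigma`` Angstrom is applied from ``spec.seed``.
    """
    residues: list[Residue] = []

    residues += _gloop_segment(spec.g_loop)

    # beta3 strand carrying K162, aimed at the salt-bridge partner position
    b3_pos = list(range(156, 169))
    ca_k = np.array([1.5, 8.5, 3.0])
    d_b3 = _unit(np.array([0.97, -0.2, 0.14]))
    b3_path = {p: ca_k + 3.5 * (p - 162) * d_b3 for p in b3_pos}
    residues += _segment(b3_pos, b3_path, aims={162: np.array([0.0, 5.0, 1.5])})

    residues += _helix_segment(spec)

    # hinge strand: gatekeeper L210 and the GK+n ladder
    hinge_pos = list(range(205, 223))
    ca_210 = np.array([10.0, -3.0, 1.0])
    hinge_path = {p: ca_210 + 3.5 * (p - 210) * np.array([1.0, 0.0, 0.0]) for p in hinge_pos}
    residues += _segment(hinge_pos, hinge_path,
                         aims={210: np.array([8.0, -1.0, 0.0]),
                               212: np.array([13.0, 0.0, 2.0])})

    # catalytic loop with the HRD arginine R255 near the alphaC-out glutamate
    cat_pos = list(range(250, 261))
    ca_255 = np.array([-6.5, 5.5, 9.0])
    d_cat = _unit(np.array([0.9, -0.3, -0.3]))
    cat_path = {p: ca_255 + 3.5 * (p - 255) * d_cat for p in cat_pos}
    residues += _segment(cat_pos, cat_path, aims={255: np.array([-9.5, 8.0, 7.0])})

    # DFG motif and A-loop, the class-defining segment
    layout = _DFG_LAYOUT[spec.dfg]
    dfg_pos = list(range(269, 293))
    controls = {p: ca for p, (ca, _) in layout.items()}
    dfg_path = _interp_path(controls, dfg_pos)
    aims = {p: aim for p, (_, aim) in layout.items() if aim is not None}
    normals = {}
    if spec.dfg == "IN":
        # keep the F275 ring normal perpendicular to the K162 direction so the
        # DFG-in fixture does not fake the non-DFG-in K162/F275 cation-pi
        f_aim = aims[275]
        k_dir = np.array([0.0, 5.0, 1.5]) - f_aim
        normals[275] = np.cross(_unit(f_aim - dfg_path[275]), _unit(k_dir))
    residues += _segment(dfg_pos, dfg_path, aims=aims, normals=normals)

    residues.sort(key=lambda r: r.author_number)
    s = Structure(chains={"A": residues}, model_index=1)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for r in residues:
            for a in r.atoms:
                a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)
    return s


_MAP_CACHE: dict[str, ResidueMap] = {}


def fixture_residue_map(s: Structure) -> ResidueMap:
    """ResidueMap for a toy kinase via the real alignment path (cached by sequence)."""
    seq = "".join(r.one_letter for r in s.chain("A"))
    if seq not in _MAP_CACHE:
        _MAP_CACHE[seq] = build_residue_map(s, "A")
    return _MAP_CACHE[seq]


def default_calibration() -> Calibration:
    """Calibration from the twelve noise-free labelled fixtures."""
    refs = []
    for d, a, g in ALL_LABEL_COMBOS:
        s = make_toy_kinase(FixtureSpec(dfg=d, alpha_c=a, g_loop=g))
        refs.append((s, fixture_residue_map(s),
                     {"dfg": d, "alpha_c": a, "g_loop": g}))
    return calibrate(refs, provenance="synthetic-fixtures-v1")


# ---------------------------------------------------------------------------
# toy complexes realising fingerprint bits
# ---------------------------------------------------------------------------

def _amine_fragment(p: np.ndarray, away: np.ndarray, prefix: str) -> list[Atom]:
    """Secondary amine: an H-bond donor nitrogen with two shielding methyls."""
    d = _unit(away)
    q = _perp(d)
    return [Atom(f"N{prefix}", "N", p),
            Atom(f"C{prefix}A", "C", p + 1.45 * _unit(d + 0.9 * q)),
            Atom(f"C{prefix}B", "C", p + 1.45 * _unit(d - 0.9 * q))]


def _carbonyl_fragment(p: np.ndarray, away: np.ndarray, prefix: str) -> list[Atom]:
    """C=O acceptor: terminal oxygen at ``p`` pointing back along ``away``."""
    d = _unit(away)
    q = _perp(d)
    c1 = p + 1.23 * d
    return [Atom(f"O{prefix}", "O", p),
            Atom(f"C{prefix}A", "C", c1),
            Atom(f"C{prefix}B", "C", c1 + 1.5 * _unit(d + 0.8 * q))]


def _benzene_fragment(centroid: np.ndarray, normal: np.ndarray, prefix: str) -> list[Atom]:
    n = _unit(normal)
    e1 = _perp(n)
    e2 = np.cross(n, e1)
    atoms = []
    for i in range(6):
        th = math.radians(60.0 * i)
        pos = centroid + 1.39 * (math.cos(th) * e1 + math.sin(th) * e2)
        atoms.append(Atom(f"C{prefix}{i + 1}", "C", pos))
    return atoms


def _protein_ring(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    rings = AROMATIC_RINGS[res.name]
    geom = _ring_geometry(res, rings[-1])  # 6-ring for TRP
    assert geom is not None
    return geom


def _sphere_directions(n: int = 26) -> list[np.ndarray]:
    dirs = []
    for x in (-1, 0, 1):
        for y in (-1, 0, 1):
            for z in (-1, 0, 1):
                if x == y == z == 0:
                    continue
                dirs.append(_unit(np.array([x, y, z], dtype=float)))
    return dirs


def _clearance(point: np.ndarray, rings: list[np.ndarray], cations: list[np.ndarray],
               lig_atoms: list[Atom]) -> float:
    """Smallest normalised margin of a candidate ring centroid to cross-talk sources.

    Protein rings threaten spurious pi-pi out to ~6.5 A, cations spurious
    cation-pi out to 6 A, and already-placed ligand atoms can covalently merge
    with the new ring below ~3 A; each distance is normalised by its own
    danger radius so the maximin choice balances them.
    """
    margins = [1.0]
    for ring_c in rings:
        margins.append(float(np.linalg.norm(point - ring_c)) / 6.5)
    for cat in cations:
        margins.append(float(np.linalg.norm(point - cat)) / 6.0)
    for a in lig_atoms:
        margins.append(float(np.linalg.norm(point - a.coord)) / 4.3)
    return min(margins)


def make_toy_complex(spec: FixtureSpec) -> tuple[Structure, LigandPose, list[dict]]:
    """Toy kinase plus a ligand realising exactly the requested fingerprint bits.

    Returns (structure-with-ligand, pose, audit list); the audit records the
    intended (bit, residue, kind) triples for oracle comparison.
    """
    s = make_toy_kinase(FixtureSpec(dfg=spec.dfg, alpha_c=spec.alpha_c,
                                    g_loop=spec.g_loop))
    chain = s.chain("A")
    by_pos = {r.author_number: r for r in chain}
    lig_atoms: list[Atom] = []
    audit: list[dict] = []

    # cross-talk context: every protein ring centroid and cation charge centre
    all_rings: list[tuple[int, np.ndarray]] = []
    all_cations: list[tuple[int, np.ndarray]] = []
    for r in chain:
        for names in AROMATIC_RINGS.get(r.name, ()):
            geom = _ring_geometry(r, names)
            if geom is not None:
                all_rings.append((r.author_number, geom[0]))
        centre = {"LYS": "NZ", "ARG": "CZ"}.get(r.name)
        if centre and r.atom(centre) is not None:
            all_cations.append((r.author_number, r.atom(centre).coord))

    def rings_except(pos: int) -> list[np.ndarray]:
        return [c for p, c in all_rings if p != pos]

    def cations_except(pos: int) -> list[np.ndarray]:
        return [c for p, c in all_cations if p != pos]

    def add(bit: int, atoms: list[Atom], res_pos: int, kind: str) -> None:
        lig_atoms.extend(atoms)
        audit.append({"bit": bit, "canonical": res_pos, "kind": kind})

    counter = [0]

    def tag() -> str:
        counter[0] += 1
        return str(counter[0])

    for bit in sorted(spec.ligand_motifs):
        if bit in (1, 2, 5, 6):
            pos = {1: 210, 2: 211, 5: 216, 6: 273}[bit]
            res = by_pos[pos]
            o, c = res.atom("O"), res.atom("C")
            d = _unit(o.coord - c.coord)
            add(bit, _amine_fragment(o.coord + 2.9 * d, d, tag()), pos, "HBOND_STRONG")
        elif bit in (3, 4):
            pos = {3: 212, 4: 213}[bit]
            res = by_pos[pos]
            idx = chain.index(res)
            h = _backbone_nh_direction(chain, idx)
            p = res.atom("N").coord + 2.9 * h
            add(bit, _carbonyl_fragment(p, h, tag()), pos, "HBOND_STRONG")
        elif bit == 7:
            res = by_pos[181]
            oe, cd = res.atom("OE1"), res.atom("CD")
            d = _unit(oe.coord - cd.coord)
            add(bit, _amine_fragment(oe.coord + 2.9 * d, d, tag()), 181, "HBOND_STRONG")
        elif bit == 8:
            res = by_pos[274]
            od, cg = res.atom("OD1"), res.atom("CG")
            d = _unit(od.coord - cg.coord)
            add(bit, _amine_fragment(od.coord + 2.9 * d, d, tag()), 274, "HBOND_STRONG")
        elif bit == 9:
            res = by_pos[280]
            centroid, _ = _protein_ring(res)
            ne2 = res.atom("NE2")
            d = _unit(ne2.coord - centroid)
            add(bit, _carbonyl_fragment(ne2.coord + 2.9 * d, d, tag()), 280, "HBOND_STRONG")
        elif bit == 10:
            res = by_pos[162]
            nz = res.atom("NZ").coord
            # ring normal must point at NZ; the placement direction is free,
            # so pick the candidate with the best cross-talk clearance
            best, best_score = None, -1.0
            for d in _sphere_directions():
                cand = nz + 4.0 * d
                score = _clearance(cand, rings_except(162), cations_except(162),
                                   lig_atoms)
                if score > best_score:
                    best, best_score = d, score
            add(bit, _benzene_fragment(nz + 4.0 * best, best, tag()), 162, "CATION_PI")
        elif bit in (11, 12, 13, 14):
            pos = {11: 275, 12: 277, 13: 280, 14: 144}[bit]
            res = by_pos[pos]
            c, n = _protein_ring(res)
            cands = [c + 3.8 * sgn * n for sgn in (1.0, -1.0)]
            centroid = max(cands, key=lambda p: _clearance(
                p, rings_except(pos), cations_except(pos), lig_atoms))
            add(bit, _benzene_fragment(centroid, _unit(centroid - c), tag()),
                pos, "PI_PI")

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        for a in lig_atoms:
            a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)

    from .structure_io import type_ligand_features  # late import, avoids cycle at module load

    pose = LigandPose(residue_name="LIG", atoms=lig_atoms, chain_id="L",
                      author_number=900,
                      typed_features=type_ligand_features(lig_atoms))
    s.ligands = [pose] if lig_atoms else []
    return s, pose, audit
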