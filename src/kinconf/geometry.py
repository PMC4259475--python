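"""Centre-of-mass, distance, angle and backbone-dihedral primitives.

These are the building blocks of both conformational metrics.  The default
centre-of-mass rule is the one with the best discriminating power between
kinase conformations: the mass-weighted COM of side-chain heavy atoms, with a
C-alpha fallback for glycine.  Alternative selections (all heavy atoms,
C-alpha only) and unit weighting are selectable for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import Residue

__all__ = ["COMSpec", "residue_com", "distance", "angle_at_vertex",
           "dihedral", "backbone_dihedrals"]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class COMSpec:
    """Atom-selection rule for residue centres of mass.

    selection: 'sidechain' (default), 'heavy', or 'ca'.
    weighting: 'mass' (default) or 'unit'.
    """

    selection: str = "sidechain"
    weighting: str = "mass"

    def __post_init__(self) -> None:
        if self.selection not in {"sidechain", "heavy", "ca"}:
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.weighting not in {"mass", "unit"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")


def _select_atoms(r: Residue, spec: COMSpec):
    heavy = r.heavy_atoms()
    if spec.selection == "ca":
        sel = [a for a in heavy if a.name == "CA"]
    elif spec.selection == "heavy":
        sel = heavy
    else:
        sel = [a for a in heavy if a.name not in _BACKBONE]
        if not sel:  # glycine (or side chain unresolved): fall back to CA
            sel = [a for a in heavy if a.name == "CA"]
    return sel


def residue_com(r: Residue, spec: COMSpec = COMSpec()) -> np.ndarray:
    """Weighted mean position of the atoms selected by ``spec`` (Angstrom)."""
    sel = _select_atoms(r, spec)
    if not sel:
        raise ValueError(
            f"residue {r.name}{r.author_number}: no atoms satisfy COM selection {spec.selection!r}"
        )
    coords = np.array([a.coord for a in sel])
    if spec.weighting == "mass":
        w = np.array([a.mass for a in sel])
    else:
        w = np.ones(len(sel))
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_at_vertex(a: np.ndarray, v: np.ndarray, b: np.ndarray) -> float:
    """Angle a-v-b in degrees, in [0, 180]."""
    u1 = np.asarray(a, float) - np.asarray(v, float)
    u2 = np.asarray(b, float) - np.asarray(v, float)
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle undefined: zero-length arm at vertex")
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, IUPAC convention, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_dihedrals(chain: list[Residue], i: int) -> tuple[float, float]:
    """(phi, psi) of residue ``chain[i]``; needs N/CA/C of i-1, i, i+1."""
    if i <= 0 or i >= len(chain) - 1:
        raise ValueError("phi/psi undefined at chain terminus")
    prev_r, r, next_r = chain[i - 1], chain[i], chain[i + 1]
    needed = [(prev_r, "C"), (r, "N"), (r, "CA"), (r, "C"), (next_r, "N")]
    coords = {}
    for res, name in needed:
        a = res.atom(name)
        if a is None:
            raise ValueError(
                f"missing backbone atom {name} in {res.name}{res.author_number}"
            )
        coords[(res.author_key, name)] = a.coord
    phi = dihedral(coords[(prev_r.author_key, "C")], coords[(r.author_key, "N")],
                   coords[(r.author_key, "CA")], coords[(r.author_key, "C")])
    psi = dihedral(coords[(r.author_key, "N")], coords[(r.author_key, "CA")],
                   coords[(r.author_key, "C")], coords[(next_r.author_key, "N")])
    return phi, psi


def circular_difference(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)
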