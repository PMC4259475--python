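"""Inter- and intra-motif conformational metrics and the DFG/alphaC/G-loop calls.

The inter-motif metric gauges the relative arrangement of four key residues --
the beta3 lysine K162, the alphaC glutamate E181, the gatekeeper (GK) L210 and
the DFG phenylalanine F275 -- through side-chain centre-of-mass distances
(r2 GK-E181, r3 GK-F275, r4 K162-F275, r5 E181-F275 diagnostic, r6 K162-E181)
and three angles with vertices at the GK+2 or GK centre of mass.  The
intra-motif metric measures the spread of the DFG motif and adjoining A-loop
(r1 A273-D274 ... r6 F275-T288, angles at F275 and W277).

Classification is nearest-centroid in the z-scored discriminative subspace:
inter {r2, r3, r4, r6, ang_E_GK_F} union intra {r5, r6, ang_DFG, ang_FWH}.
No opaque fitted weights are involved: an explicit calibration object (class
centroids plus z-scoring constants, built from any labelled reference set)
carries the whole decision rule, so results are reproducible from it alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .canonical_numbering import ResidueMap
from .geometry import (COMSpec, angle_at_vertex, backbone_dihedrals,
                       circular_difference, distance, residue_com)
from .structure_io import Residue, Structure

__all__ = [
    "InterMotifMetric", "IntraMotifMetric", "ConformationCall", "Calibration",
    "compute_inter_motif", "compute_intra_motif", "calibrate",
    "classify_dfg", "classify_alpha_c", "classify_gloop", "classify",
    "DFG_LABELS", "DISCRIMINATIVE_FEATURES",
]

DFG_LABELS = ("IN", "OUT", "OUT_UP")
ALPHA_C_LABELS = ("IN", "OUT")
G_LOOP_LABELS = ("EXTENDED", "FOLDED")

# ideal beta-sheet backbone reference for the G-loop strands
BETA_PHI_PSI = (-140.0, 135.0)

DISCRIMINATIVE_FEATURES = (
    "inter.r2_GK_E181", "inter.r3_GK_F275", "inter.r4_K162_F275",
    "inter.r6_K162_E181", "inter.ang_E_GK_F",
    "intra.r5_F275_W277", "intra.r6_F275_T288", "intra.ang_DFG", "intra.ang_FWH",
)


@dataclass(frozen=True)
class InterMotifMetric:
    r2_GK_E181: float
    r3_GK_F275: float
    r4_K162_F275: float
    r5_E181_F275: float  # diagnostic: varies little across conformations
    r6_K162_E181: float
    ang_K_GK2_E: float
    ang_K_GK2_F: float
    ang_E_GK_F: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class IntraMotifMetric:
    r1_A273_D274: float
    r2_D274_F275: float
    r3_F275_G276: float
    r4_D274_G276: float
    r5_F275_W277: float
    r6_F275_T288: float
    ang_DFG: float  # vertex F275, arms D274 / G276
    ang_FWH: float  # vertex W277, arms F275 / H280
    ang_FWT: float  # vertex W277, arms F275 / T288

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class ConformationCall:
    dfg: str
    alpha_c: str
    g_loop: str
    margins: dict[str, float]
    inter: InterMotifMetric
    intra: IntraMotifMetric
    diagnostics: dict[str, float] = field(default_factory=dict)


def _anchor_com(s: Structure, m: ResidueMap, name: str, spec: COMSpec) -> np.ndarray:
    try:
        res = m.anchor_residue(s, name)
    except KeyError as exc:
        raise ValueError(f"missing anchor {name}: {exc}") from exc
    return residue_com(res, spec)


def compute_inter_motif(s: Structure, m: ResidueMap, spec: COMSpec = COMSpec()) -> InterMotifMetric:
    """Distances/angles among K162, E181, GK, GK+2 and F275 side-chain COMs."""
    K = _anchor_com(s, m, "K162", spec)
    E = _anchor_com(s, m, "E181", spec)
    GK = _anchor_com(s, m, "GK", spec)
    GK2 = _anchor_com(s, m, "GK+2", spec)
    F = _anchor_com(s, m, "F275", spec)
    return InterMotifMetric(
        r2_GK_E181=distance(GK, E),
        r3_GK_F275=distance(GK, F),
        r4_K162_F275=distance(K, F),
        r5_E181_F275=distance(E, F),
        r6_K162_E181=distance(K, E),
        ang_K_GK2_E=angle_at_vertex(K, GK2, E),
        ang_K_GK2_F=angle_at_vertex(K, GK2, F),
        ang_E_GK_F=angle_at_vertex(E, GK, F),
    )


def compute_intra_motif(s: Structure, m: ResidueMap, spec: COMSpec = COMSpec()) -> IntraMotifMetric:
    """Spread of the DFG motif and conjoined A-loop (A273..G276, W277, H280, T288)."""
    A = _anchor_com(s, m, "A273", spec)
    D = _anchor_com(s, m, "D274", spec)
    F = _anchor_com(s, m, "F275", spec)
    G = _anchor_com(s, m, "G276", spec)
    W = _anchor_com(s, m, "W277", spec)
    H = _anchor_com(s, m, "H280", spec)
    T = _anchor_com(s, m, "T288", spec)
    return IntraMotifMetric(
        r1_A273_D274=distance(A, D),
        r2_D274_F275=distance(D, F),
        r3_F275_G276=distance(F, G),
        r4_D274_G276=distance(D, G),
        r5_F275_W277=distance(F, W),
        r6_F275_T288=distance(F, T),
        ang_DFG=angle_at_vertex(D, F, G),
        ang_FWH=angle_at_vertex(F, W, H),
        ang_FWT=angle_at_vertex(F, W, T),
    )


def _feature_vector(inter: InterMotifMetric, intra: IntraMotifMetric) -> np.ndarray:
    d = {f"inter.{k}": v for k, v in inter.as_dict().items()}
    d.update({f"intra.{k}": v for k, v in intra.as_dict().items()})
    return np.array([d[f] for f in DISCRIMINATIVE_FEATURES])


@dataclass
class Calibration:
    """Decision constants for the three classifiers.

    DFG: per-class centroids in the z-scored discriminative subspace.
    alphaC: salt-bridge boundary on r6(K162-E181) between side-chain COMs.
    G-loop: circular phi/psi deviation threshold from the beta reference and
    the F144-to-ATP-centroid displacement threshold.
    """

    features: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    centroids: dict[str, np.ndarray]
    alpha_c_r6_boundary: float = 6.0
    gloop_deviation_threshold: float = 60.0
    gloop_f144_dist_threshold: float = 6.0
    provenance: str = ""

    def zscore(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def to_text(self) -> str:
        lines = ["# kinconf calibration v1", f"provenance\t{self.provenance}"]
        lines.append("features\t" + ",".join(self.features))
        lines.append("mean\t" + ",".join(f"{v:.6f}" for v in self.mean))
        lines.append("std\t" + ",".join(f"{v:.6f}" for v in self.std))
        for label, c in sorted(self.centroids.items()):
            lines.append(f"centroid.{label}\t" + ",".join(f"{v:.6f}" for v in c))
        lines.append(f"alpha_c_r6_boundary\t{self.alpha_c_r6_boundary:.6f}")
        lines.append(f"gloop_deviation_threshold\t{self.gloop_deviation_threshold:.6f}")
        lines.append(f"gloop_f144_dist_threshold\t{self.gloop_f144_dist_threshold:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Calibration":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("\t")
            kv[key] = value
        centroids = {
            key.split(".", 1)[1]: np.array([float(v) for v in val.split(",")])
            for key, val in kv.items() if key.startswith("centroid.")
        }
        return cls(
            features=tuple(kv["features"].split(",")),
            mean=np.array([float(v) for v in kv["mean"].split(",")]),
            std=np.array([float(v) for v in kv["std"].split(",")]),
            centroids=centroids,
            alpha_c_r6_boundary=float(kv["alpha_c_r6_boundary"]),
            gloop_deviation_threshold=float(kv["gloop_deviation_threshold"]),
            gloop_f144_dist_threshold=float(kv["gloop_f144_dist_threshold"]),
            provenance=kv.get("provenance", ""),
        )


def atp_site_centroid(s: Structure, m: ResidueMap, spec: COMSpec = COMSpec()) -> np.ndarray:
    """Reference point for the ATP site: mean COM of GK, GK+3, K162 and A273."""
    pts = [_anchor_com(s, m, name, spec) for name in ("GK", "GK+3", "K162", "A273")]
    return np.mean(pts, axis=0)


def gloop_deviation(s: Structure, m: ResidueMap) -> float:
    """Mean circular (phi, psi) deviation of canonical 139-147 from the beta reference."""
    chain = s.chain(m.chain_id)
    canon_of = {r.author_key: m.canonical_of(r.author_number, r.insertion_code) for r in chain}
    span = [p for p in range(136, 149)]
    devs = []
    missing = 0
    for pos in range(139, 148):
        idx = next((i for i, r in enumerate(chain) if canon_of[r.author_key] == pos), None)
        if idx is None:
            missing += 1
            continue
        try:
            phi, psi = backbone_dihedrals(chain, idx)
        except ValueError:
            missing += 1
            continue
        devs.append(math.hypot(circular_difference(phi, BETA_PHI_PSI[0]),
                               circular_difference(psi, BETA_PHI_PSI[1])))
    present = sum(1 for p in span if p in canon_of.values())
    if present < len(span) / 2:
        raise ValueError("more than half of the G-loop span (136-148) is missing")
    if not devs:
        raise ValueError("no G-loop residue with computable phi/psi")
    return float(np.mean(devs))


def calibrate(
    references: list[tuple[Structure, ResidueMap, dict[str, str]]],
    spec: COMSpec = COMSpec(),
    provenance: str = "user",
) -> Calibration:
    """Build decision constants from labelled reference structures.

    Each reference carries a (possibly partial) label dict with keys 'dfg'
    (IN/OUT/OUT_UP), 'alpha_c' (IN/OUT), 'g_loop' (EXTENDED/FOLDED).  At least
    one reference per DFG class is required; alphaC and G-loop thresholds fall
    back to defaults when a class is unrepresented.
    """
    vectors: dict[str, list[np.ndarray]] = {}
    r6_by_alpha: dict[str, list[float]] = {}
    gdev_by_state: dict[str, list[float]] = {}
    f144_by_state: dict[str, list[float]] = {}
    all_vecs = []
    for s, m, labels in references:
        inter = compute_inter_motif(s, m, spec)
        intra = compute_intra_motif(s, m, spec)
        v = _feature_vector(inter, intra)
        all_vecs.append(v)
        if "dfg" in labels:
            vectors.setdefault(labels["dfg"], []).append(v)
        if "alpha_c" in labels:
            r6_by_alpha.setdefault(labels["alpha_c"], []).append(inter.r6_K162_E181)
        if "g_loop" in labels:
            gdev_by_state.setdefault(labels["g_loop"], []).append(gloop_deviation(s, m))
            f144 = _anchor_com(s, m, "F144", spec)
            f144_by_state.setdefault(labels["g_loop"], []).append(
                distance(f144, atp_site_centroid(s, m, spec)))

    missing = [lab for lab in DFG_LABELS if lab not in vectors]
    if missing:
        raise ValueError(f"no reference structure for DFG class(es): {missing}")

    X = np.array(all_vecs)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-9] = 1.0
    centroids = {
        label: ((np.array(vs) - mean) / std).mean(axis=0) for label, vs in vectors.items()
    }

    cal = Calibration(
        features=DISCRIMINATIVE_FEATURES, mean=mean, std=std,
        centroids=centroids, provenance=provenance,
    )
    if {"IN", "OUT"} <= set(r6_by_alpha):
        cal.alpha_c_r6_boundary = float(
            (np.mean(r6_by_alpha["IN"]) + np.mean(r6_by_alpha["OUT"])) / 2.0)
    if {"EXTENDED", "FOLDED"} <= set(gdev_by_state):
        cal.gloop_deviation_threshold = float(
            (np.mean(gdev_by_state["EXTENDED"]) + np.mean(gdev_by_state["FOLDED"])) / 2.0)
        cal.gloop_f144_dist_threshold = float(
            (np.mean(f144_by_state["EXTENDED"]) + np.mean(f144_by_state["FOLDED"])) / 2.0)
    return cal


def classify_dfg(
    inter: InterMotifMetric, intra: IntraMotifMetric, cal: Calibration
) -> tuple[str, float]:
    """Nearest-centroid DFG label and margin (gap to the second-best class)."""
    if set(DFG_LABELS) - set(cal.centroids):
        raise ValueError("calibration does not cover all three DFG classes")
    z = cal.zscore(_feature_vector(inter, intra))
    dists = {label: float(np.linalg.norm(z - c)) for label, c in cal.centroids.items()}
    ordered = sorted(dists.items(), key=lambda kv: kv[1])
    (best, d1), (_, d2) = ordered[0], ordered[1]
    if math.isclose(d1, d2, abs_tol=1e-12):
        return "IN", 0.0  # tie-break toward the most populous class
    return best, d2 - d1


def classify_alpha_c(
    s: Structure, m: ResidueMap, inter: InterMotifMetric, cal: Calibration,
    spec: COMSpec = COMSpec(),
) -> tuple[str, float, dict[str, float]]:
    """alphaC in/out from the K162-E181 salt-bridge distance r6.

    OUT when r6 exceeds the calibrated boundary (default 6.0 A between
    side-chain COMs).  Helix-geometry diagnostics (E181 i->i+/-4 C-alpha
    distances to Q177/Q185) are reported but not decisive.
    """
    diagnostics: dict[str, float] = {}
    try:
        e_res = m.anchor_residue(s, "E181")
        for name, anchor in (("E_to_Q177_ca", "Q177"), ("E_to_Q185_ca", "Q185")):
            q_res = m.anchor_residue(s, anchor)
            ca1, ca2 = e_res.atom("CA"), q_res.atom("CA")
            if ca1 is not None and ca2 is not None:
                diagnostics[name] = distance(ca1.coord, ca2.coord)
    except KeyError:
        pass
    margin = abs(inter.r6_K162_E181 - cal.alpha_c_r6_boundary)
    label = "OUT" if inter.r6_K162_E181 > cal.alpha_c_r6_boundary else "IN"
    return label, margin, diagnostics


def classify_gloop(
    s: Structure, m: ResidueMap, cal: Calibration, spec: COMSpec = COMSpec(),
) -> tuple[str, float, dict[str, float]]:
    """G-loop extended/folded call.

    FOLDED requires both (a) mean circular (phi,psi) deviation of residues
    139-147 from the beta-sheet reference (-140, 135) above the calibrated
    threshold and (b) the F144 side-chain COM displaced toward the ATP-site
    centroid below the calibrated distance threshold.
    """
    dev = gloop_deviation(s, m)
    f144 = _anchor_com(s, m, "F144", spec)
    f144_dist = distance(f144, atp_site_centroid(s, m, spec))
    folded = dev > cal.gloop_deviation_threshold and f144_dist < cal.gloop_f144_dist_threshold
    margin = min(abs(dev - cal.gloop_deviation_threshold),
                 abs(f144_dist - cal.gloop_f144_dist_threshold))
    diags = {"gloop_deviation": dev, "f144_atp_distance": f144_dist}
    return ("FOLDED" if folded else "EXTENDED"), margin, diags


def classify(
    s: Structure, m: ResidueMap, cal: Calibration, spec: COMSpec = COMSpec(),
) -> ConformationCall:
    """Full conformational call (DFG, alphaC, G-loop) for one chain."""
    inter = compute_inter_motif(s, m, spec)
    intra = compute_intra_motif(s, m, spec)
    dfg, dfg_margin = classify_dfg(inter, intra, cal)
    alpha_c, ac_margin, ac_diag = classify_alpha_c(s, m, inter, cal, spec)
    g_loop, gl_margin, gl_diag = classify_gloop(s, m, cal, spec)
    return ConformationCall(
        dfg=dfg, alpha_c=alpha_c, g_loop=g_loop,
        margins={"dfg": dfg_margin, "alpha_c": ac_margin, "g_loop": gl_margin},
        inter=inter, intra=intra,
        diagnostics={**ac_diag, **gl_diag},
    )
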