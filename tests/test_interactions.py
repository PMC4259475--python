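import math

import numpy as np
import pytest

from kinconf.fixtures import FixtureSpec, fixture_residue_map, make_toy_complex
from kinconf.interactions import (GeometryCriteria, detect_cation_pi,
                                  detect_ch_pi, detect_hbonds, detect_pi_stacking,
                                  detect_salt_bridges, interaction_table)
from kinconf.structure_io import Atom, LigandPose, Residue, Structure

from conftest import random_rotation, transform_structure


def _residue(name, atoms, num=1, chain="A"):
    return Residue(author_number=num, name=name, chain_id=chain,
                   atoms=[Atom(n, e, np.array(c, float)) for n, e, c in atoms])


def _gly_with_carbonyl(num=1, origin=(0.0, 0.0, 0.0)):
    o = np.array(origin)
    return _residue("GLY", [("N", "N", o + (0, 1.4, 1.0)), ("CA", "C", o + (1.2, 0.7, 0.5)),
                            ("C", "C", o + (0.6, 0, 0)), ("O", "O", o)], num=num)


def _donor_pose(pos):
    atoms = [Atom("N1", "N", np.array(pos, float)),
             Atom("C1", "C", np.array(pos, float) + (1.2, 0.9, 0)),
             Atom("C2", "C", np.array(pos, float) + (1.2, -0.9, 0))]
    return LigandPose(residue_name="LIG", atoms=atoms,
                      typed_features=[("HD", (0,)), ("HA", (0,))])


def _benzene_pose(centroid, normal):
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    h = np.array([0.3, 0.5, 0.81])
    e1 = h - np.dot(h, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    atoms = [Atom(f"C{i}", "C", np.asarray(centroid, float)
                  + 1.39 * (math.cos(math.radians(60 * i)) * e1
                            + math.sin(math.radians(60 * i)) * e2))
             for i in range(6)]
    return LigandPose(residue_name="LIG", atoms=atoms,
                      typed_features=[("Ar", tuple(range(6)))])


def test_strong_hbond_within_and_beyond_cutoff():
    res = _gly_with_carbonyl()
    s = Structure(chains={"A": [res]})
    near = detect_hbonds(s, _donor_pose((0.0, -2.5, 0.0)))
    assert any(r.kind == "HBOND_STRONG" and r.residue_atoms == ("O",)
               and r.subtype.startswith("N-H...O") for r in near)
    far = detect_hbonds(s, _donor_pose((0.0, -5.0, 0.0)))
    assert not [r for r in far if r.kind == "HBOND_STRONG"]


def test_hbond_record_carries_geometry():
    res = _gly_with_carbonyl()
    s = Structure(chains={"A": [res]})
    recs = [r for r in detect_hbonds(s, _donor_pose((0.0, -2.5, 0.0)))
            if r.kind == "HBOND_STRONG"]
    assert recs[0].distance == pytest.approx(2.5, abs=1e-9)
    assert recs[0].ligand_role == "HD"


def test_cation_pi_angle_window():
    phe = _residue("PHE", [("CB", "C", (0, 0, -2.9)), ("CG", "C", (-1.39, 0, 0)),
                           ("CD1", "C", (-0.695, 1.2, 0)), ("CD2", "C", (-0.695, -1.2, 0)),
                           ("CE1", "C", (0.695, 1.2, 0)), ("CE2", "C", (0.695, -1.2, 0)),
                           ("CZ", "C", (1.39, 0, 0))])
    lys = _residue("LYS", [("NZ", "N", (0, 0, 4.0))], num=2)
    above = Structure(chains={"A": [phe, lys]})
    recs = detect_cation_pi(above, None)
    assert any(r.residue_name == "LYS" and "PHE1" in r.partner for r in recs)

    lys_in_plane = _residue("LYS", [("NZ", "N", (4.0, 0, 0))], num=2)
    flat = Structure(chains={"A": [phe, lys_in_plane]})
    assert not detect_cation_pi(flat, None)


def test_pi_stacking_face_and_edge():
    phe = _residue("PHE", [("CB", "C", (0, 0, -2.9)), ("CG", "C", (-1.39, 0, 0)),
                           ("CD1", "C", (-0.695, 1.2, 0)), ("CD2", "C", (-0.695, -1.2, 0)),
                           ("CE1", "C", (0.695, 1.2, 0)), ("CE2", "C", (0.695, -1.2, 0)),
                           ("CZ", "C", (1.39, 0, 0))])
    s = Structure(chains={"A": [phe]})
    face = detect_pi_stacking(s, _benzene_pose((0, 0, 3.8), (0, 0, 1)))
    assert [r.subtype for r in face] == ["face"]
    edge = detect_pi_stacking(s, _benzene_pose((0, 0, 5.0), (1, 0, 0)))
    assert [r.subtype for r in edge] == ["edge"]
    nothing = detect_pi_stacking(s, _benzene_pose((0, 0, 9.0), (0, 0, 1)))
    assert nothing == []


def test_salt_bridge_state_switch(toy_in, toy_out_up):
    """DFG-in keeps the K162-E181 ion pair; alphaC-out swaps it for E181-R255."""
    s, m = toy_in
    table = interaction_table(s, None, m)
    bridges = {(r.residue_name, r.author_number, r.partner)
               for r in table if r.kind == "SALT_BRIDGE"}
    assert ("LYS", 162, "GLU181") in bridges
    assert not any(p == "ARG255" for _, _, p in bridges)

    s2, m2 = toy_out_up
    table2 = interaction_table(s2, None, m2)
    bridges2 = {(r.residue_name, r.author_number, r.partner)
                for r in table2 if r.kind == "SALT_BRIDGE"}
    assert ("LYS", 162, "GLU181") not in bridges2
    assert ("ARG", 255, "GLU181") in bridges2


def _oracle_records(s, pose, crit):
    """Exhaustive all-pairs re-implementation of the H-bond criteria (plain loops)."""
    out = set()
    donors = [i for k, idx in pose.typed_features if k == "HD" for i in idx]
    acceptors = [i for k, idx in pose.typed_features if k == "HA" for i in idx]
    side_acc = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
                "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
                "HIS": ["ND1", "NE2"]}
    side_don = {"SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "ASN": ["ND2"],
                "GLN": ["NE2"], "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
                "HIS": ["ND1", "NE2"], "TRP": ["NE1"], "CYS": ["SG"]}
    for residues in s.chains.values():
        for ridx, res in enumerate(residues):
            acc_names = ["O"] + side_acc.get(res.name, [])
            for an in acc_names:
                a = res.atom(an)
                if a is None:
                    continue
                for di in donors:
                    if np.linalg.norm(a.coord - pose.atoms[di].coord) <= crit.hbond_da_max:
                        out.add(("HBOND_STRONG", res.author_number, an,
                                 pose.atoms[di].name))
            don_names = ["N"] + side_don.get(res.name, [])
            for dn in don_names:
                datom = res.atom(dn)
                if datom is None:
                    continue
                for ai in acceptors:
                    if np.linalg.norm(datom.coord - pose.atoms[ai].coord) > crit.hbond_da_max:
                        continue
                    if dn == "N":
                        # angle gate with the idealised amide H
                        ca = res.atom("CA")
                        cp = residues[ridx - 1].atom("C") if ridx > 0 else None
                        if cp is not None and res.name != "PRO":
                            v1 = ca.coord - datom.coord
                            v2 = cp.coord - datom.coord
                            h = -(v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2))
                            h = datom.coord + 1.01 * h / np.linalg.norm(h)
                            u1, u2 = datom.coord - h, pose.atoms[ai].coord - h
                            ang = math.degrees(math.acos(np.clip(
                                np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2)),
                                -1, 1)))
                            if ang < crit.hbond_dha_min:
                                continue
                    out.add(("HBOND_STRONG", res.author_number, dn,
                             pose.atoms[ai].name))
    return out


def test_hbond_detector_matches_exhaustive_oracle(rng):
    """Detector output equals a brute-force all-pairs oracle on random fixtures."""
    crit = GeometryCriteria()
    residues = [_gly_with_carbonyl(num=i + 1, origin=tuple(rng.uniform(-6, 6, 3)))
                for i in range(6)]
    ser = _residue("SER", [("N", "N", (10, 0, 1.4)), ("CA", "C", (10.7, 0.5, 0.2)),
                           ("C", "C", (12, 0, 0)), ("O", "O", (12.5, -1, 0)),
                           ("CB", "C", (10.5, 2, 0)), ("OG", "O", (10, 3.2, 0))], num=7)
    s = Structure(chains={"A": residues + [ser]})
    for trial in range(50):
        pos = rng.uniform(-8, 12, 3)
        pose = _donor_pose(tuple(pos))
        got = {(r.kind, r.author_number, r.residue_atoms[0],
                r.partner.split(":")[1])
               for r in detect_hbonds(s, pose, crit) if r.kind == "HBOND_STRONG"}
        want = _oracle_records(s, pose, crit)
        assert got == want


def test_monotonicity_under_criteria_loosening():
    s, pose, _ = make_toy_complex(FixtureSpec(ligand_motifs=frozenset({1, 4, 10, 14})))
    m = fixture_residue_map(s)
    tight = GeometryCriteria()
    loose = GeometryCriteria(hbond_da_max=4.2, cation_pi_dist_max=7.0,
                             pipi_face_dist_max=6.0, hbond_weak_ca_max=4.2,
                             salt_bridge_max=5.0, chpi_dist_max=5.0)
    keys_tight = {r.key() for r in interaction_table(s, pose, m, tight)}
    keys_loose = {r.key() for r in interaction_table(s, pose, m, loose)}
    assert keys_tight <= keys_loose


def test_record_geometry_rigid_motion_invariant(rng):
    s, pose, _ = make_toy_complex(FixtureSpec(ligand_motifs=frozenset({4, 11})))
    m = fixture_residue_map(s)
    base = sorted((r.kind, r.author_number, round(r.distance, 6))
                  for r in interaction_table(s, pose, m))
    for _ in range(5):
        q, t = random_rotation(rng)
        s2 = transform_structure(s, q, t)
        moved = sorted((r.kind, r.author_number, round(r.distance, 6))
                       for r in interaction_table(s2, s2.ligands[0], m))
        assert moved == base


def test_interaction_table_is_union_of_detectors():
    s, pose, _ = make_toy_complex(FixtureSpec(ligand_motifs=frozenset({4, 10, 12})))
    m = fixture_residue_map(s)
    crit = GeometryCriteria()
    table = {r.key() for r in interaction_table(s, pose, m, crit)}
    manual = set()
    for recs in (detect_salt_bridges(s, None, crit), detect_cation_pi(s, None, crit),
                 detect_hbonds(s, pose, crit), detect_salt_bridges(s, pose, crit),
                 detect_cation_pi(s, pose, crit), detect_pi_stacking(s, pose, crit),
                 detect_ch_pi(s, pose, crit)):
        manual |= {r.key() for r in recs}
    assert table == manual
    # sorted by canonical position where assigned
    canon = [r.canonical for r in interaction_table(s, pose, m, crit)
             if r.canonical is not None]
    assert canon == sorted(canon)
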