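import numpy as np
import pytest

from kinconf.fixtures import FixtureSpec, make_toy_complex, make_toy_kinase
from kinconf.structure_io import (Atom, ParseError, Residue, Structure,
                                  extract_ligands, parse_structure,
                                  standardize_modified_residues,
                                  type_ligand_features, write_structure)

GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def test_parse_minimal_glycine():
    s = parse_structure(GLY_PDB)
    assert list(s.chains) == ["A"]
    (res,) = s.chains["A"]
    assert res.name == "GLY" and len(res.atoms) == 3
    np.testing.assert_allclose(res.atoms[1].coord, [1.458, 0.0, 0.0])


def test_parse_errors():
    with pytest.raises(ParseError):
        parse_structure("HEADER  only\nEND\n")
    with pytest.raises(ParseError, match="line"):
        parse_structure("ATOM      1  N   GLY A   1       0.0\n")
    with pytest.raises(ParseError, match="model"):
        parse_structure(GLY_PDB, model=3)


def test_altloc_highest_occupancy_tie_prefers_a():
    pdb = (
        "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.50  0.00           N\n"
        "ATOM      2  N  BGLY A   1       9.000   0.000   0.000  0.50  0.00           N\n"
        "ATOM      3  CA AGLY A   1       1.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      4  CA BGLY A   1       8.000   0.000   0.000  0.70  0.00           C\n"
        "END\n"
    )
    (res,) = parse_structure(pdb).chains["A"]
    assert res.atom("N").coord[0] == pytest.approx(0.0)   # tie -> altloc A
    assert res.atom("CA").coord[0] == pytest.approx(8.0)  # higher occupancy wins


def test_roundtrip_write_parse_identity():
    s = make_toy_kinase(FixtureSpec(dfg="OUT_UP", alpha_c="OUT", g_loop="FOLDED"))
    s2 = parse_structure(write_structure(s))
    r1 = s.chains["A"]
    r2 = s2.chains["A"]
    assert [(r.author_number, r.name) for r in r1] == [(r.author_number, r.name) for r in r2]
    for a, b in zip((a for r in r1 for a in r.atoms), (a for r in r2 for a in r.atoms)):
        assert a.name == b.name
        np.testing.assert_allclose(a.coord, b.coord, atol=5e-4)


def _mk_res(name, atoms, num=1):
    return Residue(author_number=num, name=name, chain_id="A",
                   atoms=[Atom(n, e, np.array(c, float)) for n, e, c in atoms])


def test_standardize_tpo_and_mse():
    tpo = _mk_res("TPO", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                          ("C", "C", (2, 1, 0)), ("O", "O", (2, 2, 0)),
                          ("CB", "C", (1.5, -1.5, 0)), ("OG1", "O", (2.5, -2, 0)),
                          ("CG2", "C", (0.5, -2.4, 0)),
                          ("P", "P", (3.5, -3, 0)), ("O1P", "O", (4.5, -3, 1)),
                          ("O2P", "O", (4.0, -4, -1)), ("O3P", "O", (3.0, -4, 1))])
    mse = _mk_res("MSE", [("N", "N", (5, 0, 0)), ("CA", "C", (6.5, 0, 0)),
                          ("CB", "C", (7, 1.4, 0)), ("CG", "C", (8.4, 1.5, 0)),
                          ("SE", "SE", (9.2, 3.0, 0)), ("CE", "C", (10.8, 2.6, 0)),
                          ("C", "C", (7, -1.4, 0)), ("O", "O", (6.5, -2.5, 0))], num=2)
    s = standardize_modified_residues(Structure(chains={"A": [tpo, mse]}))
    thr, met = s.chains["A"]
    assert thr.name == "THR" and thr.modified_from == "TPO"
    assert {a.name for a in thr.atoms} == {"N", "CA", "C", "O", "CB", "OG1", "CG2"}
    assert met.name == "MET"
    sd = met.atom("SD")
    assert sd is not None and sd.element == "S"
    np.testing.assert_allclose(sd.coord, [9.2, 3.0, 0.0])


def test_standardize_is_idempotent_and_noop_on_clean(toy_in):
    s, _ = toy_in
    once = standardize_modified_residues(s)
    twice = standardize_modified_residues(once)
    flat1 = [(r.name, a.name, tuple(a.coord)) for r in once.chains["A"] for a in r.atoms]
    flat2 = [(r.name, a.name, tuple(a.coord)) for r in twice.chains["A"] for a in r.atoms]
    assert flat1 == flat2
    flat0 = [(r.name, a.name, tuple(a.coord)) for r in s.chains["A"] for a in r.atoms]
    assert flat0 == flat1


def test_extract_ligands_apo_and_typing():
    s = make_toy_kinase(FixtureSpec())
    assert extract_ligands(s) == []

    # benzene: one aromatic ring of six atoms, all hydrophobes, no donors
    import math
    ring = [Atom(f"C{i}", "C",
                 np.array([1.39 * math.cos(math.radians(60 * i)),
                           1.39 * math.sin(math.radians(60 * i)), 0.0]))
            for i in range(6)]
    feats = type_ligand_features(ring)
    ar = [idx for k, idx in feats if k == "Ar"]
    assert len(ar) == 1 and len(ar[0]) == 6
    assert not [1 for k, _ in feats if k in ("HD", "HA")]

    # acetate: carboxylate -> Anion feature, oxygens acceptor-only
    acetate = [Atom("C1", "C", np.array([0.0, 0.0, 0.0])),
               Atom("C2", "C", np.array([1.5, 0.0, 0.0])),
               Atom("O1", "O", np.array([2.2, 1.05, 0.0])),
               Atom("O2", "O", np.array([2.2, -1.05, 0.0]))]
    feats = type_ligand_features(acetate)
    kinds = {k for k, _ in feats}
    assert "Anion" in kinds and "HD" not in kinds


def test_ligand_atom_count_conserved_across_extraction():
    s, pose, _ = make_toy_complex(FixtureSpec(ligand_motifs=frozenset({4, 10, 14})))
    reparsed = parse_structure(write_structure(s))
    assert sum(len(p.atoms) for p in reparsed.ligands) == len(pose.atoms)
    re_extracted = extract_ligands(reparsed)
    assert sum(len(p.atoms) for p in re_extracted) == len(pose.atoms)


def test_duplicate_residue_numbers_rejected():
    pdb = GLY_PDB.replace("END", "") + (
        "ATOM      4  N   ALA A   1       5.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      5  CA  ALA A   1       6.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      6  CB  ALA A   1       6.458   1.000   0.000  1.00  0.00           C\nEND\n")
    with pytest.raises(ParseError, match="duplicate"):
        parse_structure(pdb)
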