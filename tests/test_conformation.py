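import numpy as np
import pytest

from kinconf.conformation import (Calibration, DISCRIMINATIVE_FEATURES, calibrate,
                                  classify, classify_alpha_c, classify_dfg,
                                  classify_gloop, compute_inter_motif,
                                  compute_intra_motif)
from kinconf.fixtures import (ALL_LABEL_COMBOS, FixtureSpec, fixture_residue_map,
                              make_toy_kinase)
from kinconf.geometry import COMSpec, residue_com
from kinconf.structure_io import Structure

from conftest import random_rotation, transform_structure


def test_dfg_in_fixture_keeps_salt_bridge_distance(toy_in):
    s, m = toy_in
    inter = compute_inter_motif(s, m)
    assert 0 < inter.r6_K162_E181 < 4.5  # ion-pair compatible
    assert 0 < inter.r2_GK_E181
    assert 0 <= inter.ang_E_GK_F <= 180


def test_metrics_match_bruteforce_recomputation(toy_out_up):
    """Metric fields equal an independent recomputation from raw coordinates."""
    s, m = toy_out_up
    spec = COMSpec()
    com = {name: residue_com(m.anchor_residue(s, name), spec)
           for name in ("K162", "E181", "GK", "GK+2", "F275", "A273", "D274",
                        "G276", "W277", "H280", "T288")}

    def d(a, b):
        return float(np.sqrt(((com[a] - com[b]) ** 2).sum()))

    def ang(a, v, b):
        u1, u2 = com[a] - com[v], com[b] - com[v]
        c = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))

    inter = compute_inter_motif(s, m, spec)
    assert inter.r2_GK_E181 == pytest.approx(d("GK", "E181"), abs=1e-9)
    assert inter.r3_GK_F275 == pytest.approx(d("GK", "F275"), abs=1e-9)
    assert inter.r4_K162_F275 == pytest.approx(d("K162", "F275"), abs=1e-9)
    assert inter.r5_E181_F275 == pytest.approx(d("E181", "F275"), abs=1e-9)
    assert inter.r6_K162_E181 == pytest.approx(d("K162", "E181"), abs=1e-9)
    assert inter.ang_K_GK2_E == pytest.approx(ang("K162", "GK+2", "E181"), abs=1e-9)
    assert inter.ang_E_GK_F == pytest.approx(ang("E181", "GK", "F275"), abs=1e-9)

    intra = compute_intra_motif(s, m, spec)
    assert intra.r1_A273_D274 == pytest.approx(d("A273", "D274"), abs=1e-9)
    assert intra.r5_F275_W277 == pytest.approx(d("F275", "W277"), abs=1e-9)
    assert intra.r6_F275_T288 == pytest.approx(d("F275", "T288"), abs=1e-9)
    assert intra.ang_DFG == pytest.approx(ang("D274", "F275", "G276"), abs=1e-9)
    assert intra.ang_FWH == pytest.approx(ang("F275", "W277", "H280"), abs=1e-9)
    assert intra.ang_FWT == pytest.approx(ang("F275", "W277", "T288"), abs=1e-9)


def test_metrics_and_calls_rigid_motion_invariant(toy_in, calibration, rng):
    s, m = toy_in
    inter0 = compute_inter_motif(s, m)
    call0 = classify(s, m, calibration)
    for _ in range(10):
        q, t = random_rotation(rng)
        s2 = transform_structure(s, q, t)
        inter2 = compute_inter_motif(s2, m)
        for k, v in inter0.as_dict().items():
            assert inter2.as_dict()[k] == pytest.approx(v, abs=1e-6), k
        call2 = classify(s2, m, calibration)
        assert (call2.dfg, call2.alpha_c, call2.g_loop) == \
            (call0.dfg, call0.alpha_c, call0.g_loop)


def test_missing_anchor_error_names_anchor(toy_in):
    s, m = toy_in
    pruned = Structure(chains={"A": [r for r in s.chains["A"] if r.author_number != 162]})
    with pytest.raises(ValueError, match="K162"):
        compute_inter_motif(pruned, m)


def test_calibration_self_recovery(calibration):
    """Classifying any calibration reference returns its own labels."""
    for d, a, g in ALL_LABEL_COMBOS:
        s = make_toy_kinase(FixtureSpec(dfg=d, alpha_c=a, g_loop=g))
        m = fixture_residue_map(s)
        call = classify(s, m, calibration)
        assert (call.dfg, call.alpha_c, call.g_loop) == (d, a, g)
        assert call.margins["dfg"] > 0


def test_calibrate_requires_all_dfg_classes(toy_in):
    s, m = toy_in
    with pytest.raises(ValueError, match="OUT"):
        calibrate([(s, m, {"dfg": "IN"})])


def test_single_reference_per_class_recovers_itself():
    refs = []
    for d in ("IN", "OUT", "OUT_UP"):
        s = make_toy_kinase(FixtureSpec(dfg=d))
        refs.append((s, fixture_residue_map(s), {"dfg": d}))
    cal = calibrate(refs)
    for (s, m, labels) in refs:
        inter = compute_inter_motif(s, m)
        intra = compute_intra_motif(s, m)
        label, margin = classify_dfg(inter, intra, cal)
        assert label == labels["dfg"] and margin > 0


def test_tie_breaks_toward_in(toy_in):
    s, m = toy_in
    inter = compute_inter_motif(s, m)
    intra = compute_intra_motif(s, m)
    n = len(DISCRIMINATIVE_FEATURES)
    same = np.zeros(n)
    cal = Calibration(features=DISCRIMINATIVE_FEATURES, mean=np.zeros(n),
                      std=np.ones(n),
                      centroids={"IN": same, "OUT": same.copy(), "OUT_UP": same.copy()})
    label, margin = classify_dfg(inter, intra, cal)
    assert label == "IN" and margin == 0.0


def test_alpha_c_boundary_and_diagnostics(toy_in, toy_out_up, calibration):
    s, m = toy_in
    inter = compute_inter_motif(s, m)
    label, margin, diags = classify_alpha_c(s, m, inter, calibration)
    assert label == "IN" and margin > 0
    # helix i->i+/-4 C-alpha distances reported and helix-like (~5-7 A)
    assert 4.0 < diags["E_to_Q177_ca"] < 8.0
    assert 4.0 < diags["E_to_Q185_ca"] < 8.0

    s2, m2 = toy_out_up
    inter2 = compute_inter_motif(s2, m2)
    label2, _, _ = classify_alpha_c(s2, m2, inter2, calibration)
    assert label2 == "OUT"


def test_gloop_states_and_f144_displacement(toy_in, toy_folded, calibration):
    s, m = toy_in
    label, _, diags = classify_gloop(s, m, calibration)
    assert label == "EXTENDED"
    assert diags["gloop_deviation"] < 5.0  # ideal beta strand: essentially zero

    s2, m2 = toy_folded
    label2, _, diags2 = classify_gloop(s2, m2, calibration)
    assert label2 == "FOLDED"
    assert diags2["f144_atp_distance"] < diags["f144_atp_distance"]


def test_separation_property_r3_r4_larger_outside_dfg_in(calibration):
    """GK-F275 and K162-F275 separations are larger in non-DFG-in conformations."""
    by_class = {}
    for d in ("IN", "OUT", "OUT_UP"):
        s = make_toy_kinase(FixtureSpec(dfg=d))
        inter = compute_inter_motif(s, fixture_residue_map(s))
        by_class[d] = inter
    for other in ("OUT", "OUT_UP"):
        assert by_class[other].r3_GK_F275 > by_class["IN"].r3_GK_F275
        assert by_class[other].r4_K162_F275 > by_class["IN"].r4_K162_F275


def test_calibration_text_roundtrip(calibration):
    text = calibration.to_text()
    back = Calibration.from_text(text)
    assert back.features == calibration.features
    np.testing.assert_allclose(back.mean, calibration.mean, atol=1e-6)
    for label, c in calibration.centroids.items():
        np.testing.assert_allclose(back.centroids[label], c, atol=1e-6)
    assert back.alpha_c_r6_boundary == pytest.approx(calibration.alpha_c_r6_boundary,
                                                     abs=1e-6)
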