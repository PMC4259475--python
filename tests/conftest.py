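import numpy as np
import pytest

from kinconf.conformation import Calibration
from kinconf.fixtures import (FixtureSpec, default_calibration, fixture_residue_map,
                              make_toy_kinase)


@pytest.fixture(scope="session")
def calibration() -> Calibration:
    return default_calibration()


@pytest.fixture(scope="session")
def toy_in():
    s = make_toy_kinase(FixtureSpec(dfg="IN", alpha_c="IN", g_loop="EXTENDED"))
    return s, fixture_residue_map(s)


@pytest.fixture(scope="session")
def toy_out_up():
    s = make_toy_kinase(FixtureSpec(dfg="OUT_UP", alpha_c="OUT", g_loop="EXTENDED"))
    return s, fixture_residue_map(s)


@pytest.fixture(scope="session")
def toy_folded():
    s = make_toy_kinase(FixtureSpec(dfg="IN", alpha_c="IN", g_loop="FOLDED"))
    return s, fixture_residue_map(s)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation matrix (QR of a Gaussian) plus random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-50, 50, 3)
    return q, t


def transform_structure(s, q, t):
    from copy import deepcopy
    s2 = deepcopy(s)
    for residues in s2.chains.values():
        for res in residues:
            for a in res.atoms:
                a.coord = q @ a.coord + t
    for pose in s2.ligands:
        for a in pose.atoms:
            a.coord = q @ a.coord + t
    return s2
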