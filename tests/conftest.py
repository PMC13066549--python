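import numpy as np
import pytest

from eetnet.pigment_model import default_site_params, default_templates, extract_pigment_sites
from eetnet.structure_io import classify_cofactors, default_cofactor_table


@pytest.fixture(scope="session")
def params():
    return default_site_params()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def cofactor_table():
    return default_cofactor_table()


@pytest.fixture
def unscreened_params(params):
    """Default parameters with screening factor 1 (for constant oracles)."""
    import copy

    p = copy.deepcopy(params)
    p.screening_factor = 1.0
    return p


def sites_of(model, table=None):
    table = table or default_cofactor_table()
    inventory = classify_cofactors(model, table)
    sites, skips = extract_pigment_sites(model, inventory)
    return sites, skips


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_model(model, rotation=None, translation=None):
    """Rigidly transform a StructureModel in place-copy."""
    import copy

    rotation = np.eye(3) if rotation is None else rotation
    translation = np.zeros(3) if translation is None else np.asarray(translation, float)
    out = copy.deepcopy(model)
    for res in out.residues():
        for atom in res.atoms:
            atom.position = rotation @ atom.position + translation
    return out
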