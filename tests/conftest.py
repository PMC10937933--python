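import logging

import numpy as np
import pytest

from xlink3d import fixtures as fx

logging.getLogger("xlink3d").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def stack_fixture():
    """Guanine parallel to a Phe ring: 0 deg, 3.4 A vertical, 0.5 A lateral."""
    return fx.make_stack_fixture(fx.StackFixtureSpec(
        base="G", partner="PHE", interplane_angle=0.0,
        vertical_sep=3.4, lateral_offset=0.5))


@pytest.fixture(scope="session")
def hairpin():
    return fx.make_hairpin(stem=4, loop=4)


@pytest.fixture(scope="session")
def sim_dataset():
    return fx.simulate_feature_table(fx.TableSimSpec(seed=11))


def rigid_transform(rng: np.random.Generator):
    """A random rotation + translation for invariance tests."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=int(rng.integers(1 << 31)))
    shift = rng.normal(scale=20.0, size=3)
    return lambda xyz: rot.apply(xyz) + shift


def apply_rigid(structure, transform):
    import copy
    st = copy.deepcopy(structure)
    for chain in st.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = transform(atom.xyz)
    return st
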