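"""Shared fixtures: synthetic pentamers and derived objects.

Everything is generated programmatically at session start; no data files.
"""

import numpy as np
import pytest

from plgicmap import make_homolog_pair, make_pentamer, pore_axis
from plgicmap.pockets import PocketConfig
from plgicmap.synthetic import FIXTURE_CONTACT_CUTOFF, SyntheticSpec


@pytest.fixture(scope="session")
def pentamer():
    """Default noise-free pentamer with its ground truth."""
    return make_pentamer(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def occluded_pentamer():
    """Same construction with the vestibule-occluding strand 5-5' insertion."""
    return make_pentamer(SyntheticSpec(seed=0, occluding_insertion=True))


@pytest.fixture(scope="session")
def anchor_maps(pentamer):
    _, gt = pentamer
    return gt.anchor_maps()


@pytest.fixture(scope="session")
def pore(pentamer):
    s, gt = pentamer
    return pore_axis(s, gt.m2_keys())


@pytest.fixture(scope="session")
def fixture_config():
    """Pocket thresholds adapted to Cα-only fixtures."""
    return PocketConfig(contact_cutoff=FIXTURE_CONTACT_CUTOFF)


@pytest.fixture(scope="session")
def homologs():
    """Noise-free homolog pair sharing a template, plus their alignment."""
    return make_homolog_pair(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
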