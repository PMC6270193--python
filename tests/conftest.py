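"""Shared fixtures: packaged activity tables, canonical poses, synthetic series."""

from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from fragqsar import (
    SeriesConfig,
    generate_series,
    load_paper_tables,
    lupane_cut_rule,
    parse_smiles,
    reference_config,
    split_molecule,
    topomer_pose,
)
from fragqsar.fragmentation import BETULINIC_ACID_SMILES, BETULIN_SMILES


@pytest.fixture(scope="session")
def paper_records():
    return load_paper_tables()


@pytest.fixture(scope="session")
def table1_records(paper_records):
    """The 37-compound train/test table."""
    return [r for r in paper_records if not r.compound_id.startswith("ester-")]


@pytest.fixture(scope="session")
def test_pairs(table1_records):
    return [
        (r.exp_pic50, r.pred_pic50) for r in table1_records if r.role == "test"
    ]


@pytest.fixture(scope="session")
def train_mean(table1_records):
    return float(
        np.mean([r.exp_pic50 for r in table1_records if r.role == "train"])
    )


@pytest.fixture(scope="session")
def ba_fragments():
    mol = parse_smiles(BETULINIC_ACID_SMILES, "BA")
    return split_molecule(mol, lupane_cut_rule())


@pytest.fixture(scope="session")
def be_fragments():
    mol = parse_smiles(BETULIN_SMILES, "BE")
    return split_molecule(mol, lupane_cut_rule())


@pytest.fixture(scope="session")
def oh_pose(ba_fragments):
    return topomer_pose(ba_fragments.fragments["R2"])


@pytest.fixture(scope="session")
def reference_series():
    """Seeded reference synthetic series (n=37, 26/11, σ=0.15)."""
    return generate_series(reference_config(seed=1))


@pytest.fixture(scope="session")
def noise_free_series():
    return generate_series(
        SeriesConfig(seed=3, noise_sigma=0.0, censor_threshold_uM=None)
    )


@dataclass
class StubFragment:
    """Minimal stand-in implementing the Fragment3D field interface."""

    coords: np.ndarray
    elements: list
    charges: np.ndarray
    field_mask: np.ndarray = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        self.charges = np.asarray(self.charges, float)
        if self.field_mask is None:
            self.field_mask = np.ones(len(self.coords), dtype=bool)


@pytest.fixture
def stub_fragment_factory():
    return StubFragment
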