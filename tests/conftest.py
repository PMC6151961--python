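import numpy as np
import pytest

from iqspr.data_model import DescriptorTable, PropertyTable
from iqspr.preprocess import kennard_stone_split
from iqspr.synthetic import SyntheticSpec, generate


@pytest.fixture
def small_tables():
    """Tiny hand-written descriptor/property pair (4 compounds, 3 descriptors)."""
    desc = DescriptorTable(
        compound_ids=["c1", "c2", "c3", "c4"],
        descriptor_names=["d_bin", "d_int", "d_cont"],
        values=np.array([[0, 2, 1.5], [1, 3, 2.5], [0, 5, 3.5], [1, 4, 0.5]],
                        dtype=float),
    )
    props = PropertyTable(["c1", "c2", "c3", "c4"],
                          logkw=np.array([1.0, 2.0, 3.0, 4.0]),
                          logKi=np.array([0.5, 1.5, 2.5, 3.5]))
    return desc, props


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Moderate seeded dataset shared by model-level tests."""
    spec = SyntheticSpec(n_compounds=45, n_descriptors=40, latent_dim=3,
                         n_informative=10, n_binary=2, noise_sd_x=0.2,
                         noise_sd_y=0.1, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def split_dataset(synthetic_dataset):
    """(train desc, train props, test desc, test props) after Kennard-Stone."""
    desc, props, truth = synthetic_dataset
    split = kennard_stone_split(desc, 33)
    return (desc.reorder(split.train_ids), props.select(split.train_ids),
            desc.reorder(split.test_ids), props.select(split.test_ids), truth)
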