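import pytest

from amfdyn.simulate import SimulationConfig, generate_dataset, paper_design


@pytest.fixture(scope="session")
def paper_dataset():
    """One 90-sample two-site dataset shared by read-only tests."""
    return generate_dataset(paper_design(seed=11))


@pytest.fixture
def small_config():
    """A fast single-site configuration for tests that regenerate data."""
    return SimulationConfig(
        seed=5,
        n_sites=1,
        n_trees_per_site=3,
        months=("May", "July", "September"),
        n_otus=60,
        n_dominant=8,
        dominant_mean_props=(0.20, 0.15, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02),
        n_seasonal=6,
        n_compartment_preferential=10,
        depth_range=(500, 1500),
    )
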