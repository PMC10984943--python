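import numpy as np
import pytest

from ectcraft.synthetic import SimConfig, generate_sections


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: 3 sections, 400 spots, 12 types, 5 niches."""
    return SimConfig(
        n_sections=3,
        spots_per_section=400,
        n_cell_types=12,
        n_niches=5,
        niche_center_concentration=300.0,
        n_ect_blocks=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_sections(small_config)


@pytest.fixture(scope="session")
def small_sections(small_study):
    return [s for s, _ in small_study]


@pytest.fixture(scope="session")
def small_truth_labels(small_study) -> np.ndarray:
    return np.concatenate([t.spot_niche_labels for _, t in small_study])
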