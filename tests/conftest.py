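import numpy as np
import pytest

from muscalib import default_scenario, generate_scan, load_material_library


@pytest.fixture(scope="session")
def materials():
    return load_material_library()


@pytest.fixture(scope="session")
def scan70(materials):
    """Noise-free default-layout scan at a true effective energy of 70 keV."""
    return generate_scan(default_scenario(true_energy=70.0, seed=11), materials)


def sample_means(volume: np.ndarray, mask: np.ndarray, labels) -> np.ndarray:
    return np.array([float(volume[mask == l].mean()) for l in labels])
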