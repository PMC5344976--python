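import numpy as np
import pytest

import nucleoid3d as n3
from nucleoid3d.domains import DomainSegmentation


@pytest.fixture(scope="session")
def planted_truth():
    """273-bin genome with borders every 5 bins (15 kb at 3 kb), boost 3."""
    borders = np.arange(0, 270, 5)
    return n3.PlantedTruth(n_bins=273, true_borders=borders,
                           decay_exponent=-1.0, domain_boost=3.0)


@pytest.fixture(scope="session")
def planted_map(planted_truth):
    return n3.simulate_contact_map(planted_truth, 273, 50.0, seed=11)


@pytest.fixture(scope="session")
def small_annotation():
    return n3.generate_genome_annotation(90_000, 30, 3000, seed=5)


@pytest.fixture(scope="session")
def true_segmentation(planted_truth):
    return DomainSegmentation(n_bins=273, borders=planted_truth.true_borders, bin_size=3000)


def circular_gap(candidates, target, n):
    """Smallest circular distance from target to any candidate bin."""
    candidates = np.asarray(candidates)
    d = np.abs(candidates - target)
    return int(np.min(np.minimum(d, n - d)))
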