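import numpy as np
import pytest

from metspgs import CohortConfig, VariantSpec, simulate_retrospective
from metspgs.io import load_mets_loci, load_mets_odds_ratios


@pytest.fixture(scope="session")
def panel():
    """The packaged 18-locus metabolic-syndrome panel."""
    return load_mets_loci()


@pytest.fixture(scope="session")
def panel_ors():
    return load_mets_odds_ratios()


@pytest.fixture(scope="session")
def cohort():
    return CohortConfig(n_case=279, n_control=397)


@pytest.fixture(scope="session")
def reference_dataset(panel, cohort):
    """One simulated study cohort, shared across read-only tests."""
    return simulate_retrospective(panel, cohort, seed=20240101)


@pytest.fixture()
def toy_variants():
    return [
        VariantSpec("rsA", "G1", "1", "A", "G", 0.30, 0.45),
        VariantSpec("rsB", "G2", "2", "C", "T", 0.20, 0.20),
        VariantSpec("rsC", "G3", "2", "G", "A", 0.50, 0.60),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
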