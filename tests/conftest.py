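import numpy as np
import pytest

from msrisk.cohort import CohortSpec, generate_cohort
from msrisk.panels import Panel, StudyConfig, VariantSpec, builtin_panel


@pytest.fixture(scope="session")
def panel_6():
    return builtin_panel("panel_6")


@pytest.fixture(scope="session")
def panel_24():
    return builtin_panel("panel_24")


@pytest.fixture(scope="session")
def panel_53():
    return builtin_panel("panel_53")


@pytest.fixture(scope="session")
def panel_empirical_6():
    return builtin_panel("panel_empirical_6")


@pytest.fixture(scope="session")
def hla_variant(panel_6):
    return next(v for v in panel_6.variants if v.rsid == "rs3135388")


@pytest.fixture
def single_variant_panel():
    def make(raf, or_value, rsid="rs_test"):
        return Panel(
            name="single",
            variants=(VariantSpec("GENE", rsid, "1", "A", raf, or_value),),
        )

    return make


@pytest.fixture
def small_config():
    # reduced scale for unit tests; full scale lives in test_acceptance.py
    return StudyConfig(n_individuals=20_000, n_reps=5, master_seed=123)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def complete_cohort():
    # no missingness: every subject enters the score analyses
    return generate_cohort(CohortSpec(seed=42, missing_rate=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
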