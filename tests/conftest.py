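import pytest

from holotools.alignment_prep import filter_gap_columns, group_profile
from holotools.synthetic import (
    MsaScenario,
    SnpScenario,
    simulate_osc_msa,
    simulate_snp_landscape,
)

#: seed fixed for every scenario-level fixture
SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def msa_default():
    """Default grouped-alignment scenario: (alignment, groups, truth)."""
    return simulate_osc_msa(MsaScenario(seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def msa_filtered(msa_default):
    """Gap-filtered alignment with column map and the three group profiles."""
    aln, groups, truth = msa_default
    filtered, column_map = filter_gap_columns(aln)
    profiles = {
        name: group_profile(filtered, groups, functional_group=name)
        for name in ("animal_LAS", "plant_BAS", "plant_CAS")
    }
    return filtered, column_map, groups, profiles, truth


@pytest.fixture(scope="session")
def snp_default():
    """Default SNP landscape scenario: (snps, truth, genes)."""
    return simulate_snp_landscape(SnpScenario(seed=SCENARIO_SEED))
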