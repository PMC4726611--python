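import pytest

from oldowan import (
    DEFAULT_GM_FIELDS,
    SimParams,
    generate_experimental_assemblage,
    standardize_table,
)


@pytest.fixture(scope="session")
def experimental():
    """Two-material experimental assemblage (~2,700 detached pieces), standardized."""
    params = [
        SimParams(n_cores=185, material="basalt", seed=11),
        SimParams(n_cores=130, material="quartzite", seed=12),
    ]
    assemblage = generate_experimental_assemblage(params)
    assemblage.flakes = standardize_table(assemblage.flakes, DEFAULT_GM_FIELDS)
    return assemblage


@pytest.fixture(scope="session")
def labelled(experimental):
    """Whole, behavior-labelled flakes of the experimental assemblage."""
    flakes = experimental.flakes
    return flakes[flakes["behavior"] != ""].reset_index(drop=True)
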