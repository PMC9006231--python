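import pytest

from wolsweep.design import Community, HostFig, StudyDesign
from wolsweep.io import patristic_matrix
from wolsweep.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def toy_design():
    """Two single-host communities with two sites each."""
    return StudyDesign(
        communities=(
            Community("north", (HostFig("F_alpha", ("200", "700")),)),
            Community("south", (HostFig("F_beta", ("200", "700")),)),
        )
    )


@pytest.fixture(scope="session")
def study():
    """A full-scale synthetic study under the default conditions."""
    return generate_study(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def study_distances(study):
    return patristic_matrix(study.tree)


@pytest.fixture(scope="session")
def clean_study():
    """Perfect penetrance, no noise: every infected clade fully typed."""
    return generate_study(GeneratorConfig(seed=7, penetrance=1.0, noise_rate=0.0))
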