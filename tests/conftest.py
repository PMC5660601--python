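import pytest

from nicheflow.model_io import read_metabolite_reference
from nicheflow.pipeline import packaged_data
from nicheflow.synthetic_data import (
    CommunitySimSpec,
    ProfileSimConfig,
    generate_exometabolome,
    generate_toy_community,
)


@pytest.fixture(scope="session")
def reference():
    return read_metabolite_reference(packaged_data("metabolite_reference.tsv"))


@pytest.fixture(scope="session")
def two_species():
    """Donor feeds one obligate receiver through a single metabolite."""
    spec = CommunitySimSpec(
        biomass_requirements={"donor": ["nh4"], "receiver": ["gln", "nh4"]},
        designed_exchanges=[("gln", "donor", "receiver")],
        medium_metabolites={"nh4": 10.0},
    )
    return generate_toy_community(spec), spec


@pytest.fixture(scope="session")
def three_species():
    """One donor feeds two receivers through different metabolites."""
    spec = CommunitySimSpec(
        biomass_requirements={
            "yeast": ["nh4"],
            "lab1": ["gln", "nh4"],
            "lab2": ["ser", "nh4"],
        },
        designed_exchanges=[("gln", "yeast", "lab1"), ("ser", "yeast", "lab2")],
        medium_metabolites={"nh4": 10.0},
    )
    return generate_toy_community(spec), spec


@pytest.fixture(scope="session")
def noise_free_table(reference):
    config = ProfileSimConfig(n_ions=120, noise_sd=0.0, seed=11)
    return generate_exometabolome(config, reference=reference), config
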