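import pytest
from hypothesis import HealthCheck, settings

from peppr.hotpep import ProfileSet
from peppr.ppr_core import PPRParams, load_profiles, partition_family, write_profiles
from peppr.synthetic_data import PlantSpec, generate_family

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FAMILY_ECS = ("3.2.1.4", "3.2.1.21", "3.2.1.91")


@pytest.fixture(scope="session")
def planted_family():
    """Three planted subfamilies of 20 (fully conserved vocabularies) + 10 decoys."""
    spec = PlantSpec(ec_labels=FAMILY_ECS, random_seed=11)
    return generate_family(spec)


@pytest.fixture(scope="session")
def planted_subfamilies(planted_family):
    proteins, _ = planted_family
    subfamilies, ungrouped = partition_family(proteins, PPRParams(), "GH5")
    return subfamilies, ungrouped


@pytest.fixture(scope="session")
def profile_set(planted_subfamilies, tmp_path_factory):
    """ProfileSet round-tripped through the on-disk profile format."""
    subfamilies, _ = planted_subfamilies
    outdir = tmp_path_factory.mktemp("profiles")
    write_profiles(subfamilies, outdir)
    return ProfileSet(load_profiles(outdir))
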