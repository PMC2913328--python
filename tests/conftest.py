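import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bcfkit.chemdata import parse_structure
from bcfkit.synthetic import fixture_structures


@pytest.fixture(scope="session")
def parsed_fixtures():
    """name -> (Structure, expected fragment counts) for the toy set."""
    return {
        name: (parse_structure(smi), counts)
        for name, smi, counts in fixture_structures()
    }


@pytest.fixture()
def simple_csv(tmp_path):
    path = tmp_path / "compounds.csv"
    path.write_text(
        "id,smiles,logbcf,logp_mlogp\n"
        "c1,c1ccccc1,1.2,2.1\n"
        "c2,CCO,0.5,-0.3\n"
        "c3,CCCCCCCC,2.4,3.9\n"
    )
    return path
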