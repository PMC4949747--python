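import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import napesrm as n
from napesrm import studies
from napesrm.simulate import SamplePlan

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_species(rng: np.random.Generator, level=None) -> n.NapeSpecies:
    """One random valid NAPE species (species or molecular level)."""

    def chain() -> n.FattyAcyl:
        c = int(rng.integers(2, 27))
        d = int(rng.integers(0, (c - 2) // 2 + 1))
        return n.FattyAcyl(c, d)

    molecular = rng.random() < 0.5 if level is None else (level == "molecular")
    if molecular:
        return n.NapeSpecies.molecular(chain(), chain(), chain())
    sn1, sn2 = chain(), chain()
    return n.NapeSpecies.species(
        sn1.carbons + sn2.carbons, sn1.double_bonds + sn2.double_bonds, chain()
    )


@pytest.fixture(scope="session")
def rt_model() -> n.RetentionModel:
    """Retention model fitted on noiseless synthetic observations with known
    coefficients (intercept 2.0 min, +0.30 min/C, -0.55 min/DB)."""
    return studies.reference_retention_model()


@pytest.fixture(scope="session")
def fig2_trio() -> list:
    """The canonical co-isobaric trio: one composition, three N-acyl chains."""
    return [
        n.parse_name("PE 38:2-N-16:0"),
        n.parse_name("PE 36:2-N-18:0"),
        n.parse_name("PE 36:1-N-18:1"),
    ]


IS_NAME = studies.DEFAULT_IS_NAME


@pytest.fixture(scope="session")
def validation_method(rt_model) -> n.MethodTable:
    return studies.validation_method(rt_model)


@pytest.fixture()
def noiseless_plan() -> SamplePlan:
    return SamplePlan(noise_sd=0.0, rt_jitter_sd_s=0.0, seed=0)
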