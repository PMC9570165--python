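import numpy as np
import pytest

from mafld_pbpk import Subject
from mafld_pbpk.datasets import (
    HEALTHY_CYP_ABUNDANCE,
    healthy_population_spec,
    mafld_population_spec,
)


@pytest.fixture(scope="session")
def healthy_spec():
    return healthy_population_spec()


@pytest.fixture(scope="session")
def mafld_spec():
    return mafld_population_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_subject(abundances=None, weight_kg=80.0, q_h=90.0, mppgl=40.0, liver_g=1650.0):
    """A fixed, fully deterministic subject for engine unit tests."""
    if abundances is None:
        abundances = dict(HEALTHY_CYP_ABUNDANCE)
    return Subject(
        sex="male",
        age_years=40.0,
        height_cm=176.0,
        weight_kg=weight_kg,
        haematocrit_pct=43.0,
        cyp_abundance=abundances,
        mppgl_mg_per_g=mppgl,
        liver_mass_g=liver_g,
        hepatic_blood_flow_l_per_h=q_h,
    )


@pytest.fixture
def zero_variance_spec(healthy_spec):
    """Healthy spec with every sampling CV collapsed to zero."""
    spec = healthy_spec.model_copy(deep=True)
    spec.name = "degenerate"
    for sex in ("male", "female"):
        ss = getattr(spec, sex)
        ss.height_sd_cm = 0.0
        ss.haematocrit_cv = 0.0
        ss.height_weight.residual_gsd = 1.0
    spec.cyp_abundance_cv = {k: 0.0 for k in spec.cyp_abundance_cv}
    spec.age_range_years = (40.0, 40.0)
    return spec
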