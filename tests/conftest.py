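import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from overtreat.cohort import CaseRecord, Cohort  # noqa: E402
from overtreat.propensity import ModelSpec, fit_and_predict  # noqa: E402
from overtreat.simulate import default_config, generate_cohort, true_propensities  # noqa: E402


def make_case(case_id="c1", **kw) -> CaseRecord:
    """A benign, eligible invasive case; override any field via kwargs."""
    base = dict(
        case_id=case_id,
        age_years=62,
        stage="I",
        tumor_size_cm=1.2,
        nodes_positive=0,
        grade="II",
        her2="neg",
        hr="pos",
        histology_icdo3=8500,
        behavior="invasive",
        invades_fascia_muscle_chestwall=False,
        skin_ulceration_or_adjacent_skin=False,
        distant_metastasis=False,
        surgery_class="bcs",
        region="Iowa",
        race="White",
    )
    base.update(kw)
    return CaseRecord(**base)


def make_cohort(records) -> Cohort:
    return Cohort.from_records(records)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(n_cases=4000, seed=11)


@pytest.fixture(scope="session")
def cohort4k(default_cfg):
    return generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def oracle4k(cohort4k, default_cfg):
    return true_propensities(cohort4k, default_cfg)


@pytest.fixture(scope="session")
def logistic4k(cohort4k):
    return fit_and_predict(cohort4k, ModelSpec(model_family="logistic", seed=5))


@pytest.fixture(scope="session")
def cohort50k():
    return generate_cohort(default_config(n_cases=50_000, seed=23))
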