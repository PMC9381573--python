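import numpy as np
import pytest

from mrsdx import default_study_spec, generate_cohort, prepare_features
from mrsdx.cohort import METABOLITES, CohortSpec, GroupSpec


@pytest.fixture(scope="session")
def default_table():
    """The packaged 68-record study cohort, raw (2 missing GABA cells)."""
    return generate_cohort(default_study_spec(seed=0))


@pytest.fixture(scope="session")
def prepared_table(default_table):
    """Default cohort after imputation and age correction."""
    return prepare_features(default_table)


def two_group_spec(
    n_a=20,
    n_b=20,
    shift=None,
    seed=0,
    sds=1.0,
    names=("RR-MS", "P-MS"),
    age_sd=10.0,
):
    """Simple two-group cohort spec: unit-SD features, optional mean shifts.

    ``shift`` maps metabolite -> additive mean offset applied to group B.
    """
    means = {m: 5.0 for m in METABOLITES}
    sds_map = {m: float(sds) for m in METABOLITES}
    means_b = dict(means)
    for m, delta in (shift or {}).items():
        means_b[m] = means_b[m] + delta
    return CohortSpec(
        groups=(
            GroupSpec(names[0], n_a, 45.0, age_sd, means, sds_map),
            GroupSpec(names[1], n_b, 45.0, age_sd, means_b, sds_map),
        ),
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
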