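"""Shared fixtures: all test data is generated programmatically at test time."""

import pytest

from cleftdnm.dnm_discovery import FilterConfig, discover_dnms
from cleftdnm.synthetic_cohort import CohortSpec, generate_cohort, generate_resources
from cleftdnm.trio_qc import apply_qc

SMALL_SPEC_KWARGS = dict(
    n_trios=12,
    qc_failures={"missingness": 1, "sex_mismatch": 1, "relatedness": 1, "mendelian_outlier": 1},
    n_background_autosomal=400,
    n_background_x=300,
    n_mendelian_errors=30,
    decoys={
        "low_gq": 1,
        "low_dp": 1,
        "inherited": 1,
        "common_maf": 1,
        "noncoding": 1,
        "parent_missing": 1,
        "double_hit": 1,
    },
    seed=3,
)


@pytest.fixture(scope="session")
def resources():
    return generate_resources(1)


@pytest.fixture(scope="session")
def transcripts_by_gene(resources):
    return {t.gene: t for t in resources.transcripts}


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(**SMALL_SPEC_KWARGS))


@pytest.fixture(scope="session")
def small_qc(small_cohort):
    return apply_qc(small_cohort.pedigrees, small_cohort.trios)


@pytest.fixture(scope="session")
def small_discovery(small_cohort, small_qc):
    retained = [p for p in small_cohort.pedigrees if p.trio_id in set(small_qc.retained)]
    return discover_dnms(
        retained,
        small_cohort.trios,
        small_cohort.resources,
        FilterConfig(),
        excluded_sites=small_qc.excluded_sites,
        track_attribution=True,
    )


@pytest.fixture(scope="session")
def full_cohort():
    """Default-scale 150-trio cohort (the acceptance-criterion cohort)."""
    return generate_cohort(CohortSpec(seed=20220711))


@pytest.fixture(scope="session")
def full_qc(full_cohort):
    return apply_qc(full_cohort.pedigrees, full_cohort.trios)
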