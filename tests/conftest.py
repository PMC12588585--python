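import pytest

from dcepref import (
    BehaviorMix,
    CoefficientSet,
    RawResponseSet,
    REMOTE_CARE_SCHEME,
    REMOTE_CARE_WEIGHTS,
    build_design,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def scheme():
    return REMOTE_CARE_SCHEME


@pytest.fixture(scope="session")
def design(scheme):
    return build_design(scheme, order_seed=0)


@pytest.fixture(scope="session")
def published_coeffs(scheme):
    """The published preference weights as a coefficient set."""
    return CoefficientSet(
        scheme=scheme,
        alpha=REMOTE_CARE_WEIGHTS.alpha,
        betas=dict(REMOTE_CARE_WEIGHTS.betas),
    )


@pytest.fixture(scope="session")
def clean_cohort(design):
    """500 rational respondents at the published weights, no contamination."""
    return simulate_cohort(design, REMOTE_CARE_WEIGHTS, BehaviorMix(), 500, seed=42)


@pytest.fixture(scope="session")
def clean_rows(design, clean_cohort):
    from dcepref import expand_to_rows, run_qc

    raw = RawResponseSet(design, clean_cohort.records())
    valid, _ = run_qc(raw)
    return expand_to_rows(valid)
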