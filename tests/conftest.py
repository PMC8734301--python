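import pytest

import urateburden as ub


@pytest.fixture(scope="session")
def annotations():
    return ub.load_packaged_annotations()


@pytest.fixture(scope="session")
def ann_by_rs(annotations):
    return {a.rs_id: a for a in annotations}


@pytest.fixture(scope="session")
def cohort_counts():
    return ub.load_packaged_cohort_counts()


@pytest.fixture(scope="session")
def counts_by(cohort_counts):
    return {(g.rs_id, g.population): g for g in cohort_counts}


@pytest.fixture(scope="session")
def reference():
    return ub.load_packaged_reference()


@pytest.fixture(scope="session")
def fixture_report(annotations, cohort_counts, reference):
    """Full pipeline run on the packaged study fixture at default thresholds."""
    return ub.run_pipeline(annotations, cohort_counts, reference)
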