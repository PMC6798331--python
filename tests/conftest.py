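import pytest

from bleedvalidate import (
    build_contingency,
    classify_cohort,
    cohort_from_contingency,
    default_index_map,
    default_screen_set,
    diagnostic_metrics,
    label_cohort,
    table2_spec,
)


@pytest.fixture(scope="session")
def index_map():
    return default_index_map()


@pytest.fixture(scope="session")
def screen_set():
    return default_screen_set()


@pytest.fixture(scope="session")
def table2_cohort():
    """The packaged deterministic 16,012-stay cohort; construction itself
    verifies every declared margin."""
    return cohort_from_contingency(table2_spec())


@pytest.fixture(scope="session")
def table2_pipeline(table2_cohort, index_map, screen_set):
    """Full pipeline products on the deterministic cohort:
    (labeling, reference, contingency, accuracy report)."""
    labeling = classify_cohort(table2_cohort, index_map)
    reference = label_cohort(table2_cohort, screen_set)
    table = build_contingency(labeling, reference)
    report = diagnostic_metrics(table)
    return labeling, reference, table, report
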