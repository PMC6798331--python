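import pytest

from bleedvalidate.accuracy import build_contingency, diagnostic_metrics
from bleedvalidate.classify import classify_cohort
from bleedvalidate.codesets import Category
from bleedvalidate.reference import label_cohort
from bleedvalidate.synthetic import (
    ContingencySpec,
    ContingencySpecError,
    GeneratorConfig,
    Stratum,
    cohort_from_contingency,
    generate_cohort,
    recovery_experiment,
    table2_spec,
)


def test_same_config_and_seed_reproduce_identical_cohorts():
    config = GeneratorConfig(n_stays=300)
    a = generate_cohort(config, seed=42)
    b = generate_cohort(config, seed=42)
    assert list(a) == list(b)
    c = generate_cohort(config, seed=43)
    assert list(a) != list(c)


def test_zero_prevalence_and_zero_fpr_give_no_positives(index_map, screen_set):
    config = GeneratorConfig(n_stays=1000, prevalence=0.0, coding_fpr=0.0)
    cohort = generate_cohort(config, seed=5)
    labeling = classify_cohort(cohort, index_map)
    reference = label_cohort(cohort, screen_set)
    assert labeling.positives() == []
    assert all(r.verdict == "NOT_MAJOR" for r in reference.values())


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_stays": 0},
        {"prevalence": 1.5},
        {"coding_sensitivity": -0.1},
        {"type_mix": (0.5, 0.5, 0.5)},
    ],
)
def test_invalid_generator_config_rejected(kwargs):
    with pytest.raises(ValueError):
        GeneratorConfig(**kwargs)


def test_major_stays_always_satisfy_a_criterion():
    from bleedvalidate.reference import adjudicate

    cohort = generate_cohort(GeneratorConfig(n_stays=800), seed=9)
    for stay in cohort:
        if stay.latent_truth == "MAJOR":
            assert adjudicate(stay.chart).verdict == "MAJOR"


def test_reference_recovers_latent_truth_with_perfect_screen(index_map, screen_set):
    cohort = generate_cohort(GeneratorConfig(n_stays=2000, screen_sensitivity=1.0), seed=13)
    reference = label_cohort(cohort, screen_set)
    for stay in cohort:
        assert reference[stay.stay_id].verdict == stay.latent_truth


def test_screen_sensitivity_is_the_only_truth_leak(screen_set):
    config = GeneratorConfig(n_stays=6000, screen_sensitivity=0.8)
    cohort = generate_cohort(config, seed=17)
    reference = label_cohort(cohort, screen_set)
    majors = [s for s in cohort if s.latent_truth == "MAJOR"]
    agree = sum(reference[s.stay_id].verdict == "MAJOR" for s in majors)
    assert agree / len(majors) == pytest.approx(0.8, abs=0.06)
    non_majors = [s for s in cohort if s.latent_truth == "NOT_MAJOR"]
    assert all(reference[s.stay_id].verdict == "NOT_MAJOR" for s in non_majors)


def test_empirical_sensitivity_converges_to_operating_point(index_map, screen_set):
    """At large n the pipeline estimate sits within ±0.02 of the configured
    operating sensitivity."""
    config = GeneratorConfig(n_stays=50000)
    cohort = generate_cohort(config, seed=2014)
    labeling = classify_cohort(cohort, index_map)
    reference = label_cohort(cohort, screen_set)
    report = diagnostic_metrics(build_contingency(labeling, reference))
    truth = config.operating_point()
    assert report.se.point == pytest.approx(truth["se"], abs=0.02)
    assert report.sp.point == pytest.approx(truth["sp"], abs=0.005)


def test_operating_point_accounts_for_screen_misses():
    config = GeneratorConfig(prevalence=0.1, screen_sensitivity=0.5, coding_fpr=0.0,
                             coding_sensitivity=1.0)
    op = config.operating_point()
    assert op["se"] == 1.0
    # screen-missed true bleeds are reference-negative yet carry bleeding codes
    assert op["sp"] < 1.0


def test_contingency_spec_all_negative():
    spec = ContingencySpec(
        strata=[Stratum(n=5, primary_dx="I10", truth="NOT_MAJOR")],
        expected={"cells": {"NONE": [0, 5]}},
    )
    cohort = cohort_from_contingency(spec)
    assert len(cohort) == 5
    assert all(s.latent_truth == "NOT_MAJOR" for s in cohort)


def test_contingency_spec_violated_margin_is_named():
    spec = ContingencySpec(
        strata=[Stratum(n=5, primary_dx="I10", truth="NOT_MAJOR")],
        expected={"cells": {"NONE": [0, 4]}},
    )
    with pytest.raises(ContingencySpecError, match="NONE"):
        cohort_from_contingency(spec)
    spec2 = ContingencySpec(
        strata=[Stratum(n=5, primary_dx="I10", truth="NOT_MAJOR")],
        expected={"screened_in": 3},
    )
    with pytest.raises(ContingencySpecError, match="screened_in"):
        cohort_from_contingency(spec2)


def test_packaged_fixture_has_16012_stays(table2_cohort):
    assert len(table2_cohort) == 16012
    assert table2_spec().n_stays == 16012


def test_recovery_single_replicate_equals_that_replicate(index_map, screen_set):
    config = GeneratorConfig(n_stays=1200)
    summary = recovery_experiment(config, n_replicates=1, seed=21)
    cohort = generate_cohort(config, seed=21)
    labeling = classify_cohort(cohort, index_map)
    reference = label_cohort(cohort, screen_set)
    report = diagnostic_metrics(build_contingency(labeling, reference))
    assert summary.estimates["se"] == [report.se.point]
    assert summary.estimates["sp"] == [report.sp.point]
    assert summary.bias["se"] == pytest.approx(report.se.point - config.operating_point()["se"])


def test_perfect_coding_has_zero_bias():
    config = GeneratorConfig(
        n_stays=500, coding_sensitivity=1.0, coding_fpr=0.0, screen_sensitivity=1.0
    )
    summary = recovery_experiment(config, n_replicates=3, seed=8)
    assert summary.bias["se"] == 0.0
    assert summary.coverage["se"] == 1.0
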