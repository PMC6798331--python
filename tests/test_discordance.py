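import pytest

from bleedvalidate.classify import classify_cohort
from bleedvalidate.codesets import Category, match_category
from bleedvalidate.discordance import (
    chapter_group,
    discordant_stays,
    false_negative_code_table,
    false_positive_pathway_split,
    profile_discordance,
)
from bleedvalidate.cohort import Cohort, HospitalStay
from bleedvalidate.codesets import normalize_code
from bleedvalidate.reference import label_cohort
from bleedvalidate.synthetic import GeneratorConfig, generate_cohort


def test_fixture_discordant_counts(table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    fp, fn = discordant_stays(labeling, reference)
    assert len(fp) == 155
    assert len(fn) == 254


def test_fixture_false_positive_category_split(table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    fp, _ = discordant_stays(labeling, reference)
    by_cat = {c: 0 for c in Category}
    for sid in fp:
        by_cat[labeling.labels[sid]] += 1
    assert by_cat[Category.ICH] == 12
    assert by_cat[Category.GI] == 56
    assert by_cat[Category.OTHER] == 87


def test_fixture_false_positive_pathway_split(table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    fp, _ = discordant_stays(labeling, reference)
    split = false_positive_pathway_split(fp, reference)
    assert split == {"screened_in": 141, "not_screened": 14}


def test_pathway_split_with_no_false_positives(table2_pipeline):
    assert false_positive_pathway_split([], table2_pipeline[1]) == {
        "screened_in": 0,
        "not_screened": 0,
    }


def test_fixture_false_negative_most_cited_codes(table2_cohort, table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    _, fn = discordant_stays(labeling, reference)
    freq = false_negative_code_table(table2_cohort, fn)
    counts = dict(zip(freq["code"], freq["count"]))
    assert counts["K625"] == 26
    assert counts["D649"] == 20
    assert counts["R571"] == 16
    percents = dict(zip(freq["code"], freq["percent"]))
    assert percents["K625"] == pytest.approx(10.2, abs=0.06)
    assert percents["D649"] == pytest.approx(7.87, abs=0.01)


def test_display_cutoff_keeps_only_frequent_codes(table2_cohort, table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    _, fn = discordant_stays(labeling, reference)
    head = false_negative_code_table(table2_cohort, fn, min_percent=2.0)
    assert len(head) == 12  # the published most-cited list
    assert head["count"].min() >= 6


def test_false_negatives_with_index_map_ew_codes(table2_cohort, table2_pipeline, index_map):
    labeling, reference, _, _ = table2_pipeline
    _, fn = discordant_stays(labeling, reference)
    freq = false_negative_code_table(table2_cohort, fn)
    in_map = freq[
        [match_category(code, index_map) is not Category.NONE for code in freq["code"]]
    ]
    assert int(in_map["count"].sum()) == 107
    assert len(in_map) == 18


def test_fixture_false_negative_chapters(table2_cohort, table2_pipeline):
    labeling, reference, _, _ = table2_pipeline
    _, fn = discordant_stays(labeling, reference)
    chapters = chapter_group(table2_cohort, fn)
    counts = dict(zip(chapters["chapter"], chapters["count"]))
    assert counts["S"] == 94
    assert counts["D"] == 34
    assert counts["I"] == 34
    assert counts["K"] == 30
    percents = dict(zip(chapters["chapter"], chapters["percent"]))
    assert percents["S"] == pytest.approx(37.0, abs=0.06)
    assert percents["D"] == pytest.approx(13.4, abs=0.06)


def test_single_code_chapter_is_100_percent():
    stay = HospitalStay(stay_id="a", age=60, sex="F", primary_dx=normalize_code("K62.5"))
    chapters = chapter_group(Cohort([stay]), ["a"])
    assert list(chapters.itertuples(index=False)) != []
    assert chapters.iloc[0]["chapter"] == "K"
    assert chapters.iloc[0]["percent"] == 100.0


def test_empty_false_negative_table(table2_cohort):
    assert len(false_negative_code_table(table2_cohort, [])) == 0


def test_bookkeeping_identities_on_generated_cohort(index_map, screen_set):
    cohort = generate_cohort(GeneratorConfig(n_stays=1500), seed=11)
    labeling = classify_cohort(cohort, index_map)
    reference = label_cohort(cohort, screen_set)
    fp, fn = discordant_stays(labeling, reference)
    positives = len(labeling.positives())
    tp = sum(
        1
        for sid, cat in labeling.labels.items()
        if cat is not Category.NONE and reference[sid].verdict == "MAJOR"
    )
    tn = sum(
        1
        for sid, cat in labeling.labels.items()
        if cat is Category.NONE and reference[sid].verdict == "NOT_MAJOR"
    )
    assert len(fp) + tp == positives
    assert len(fn) + tn == len(cohort) - positives


def test_profiles_are_stay_order_invariant(index_map, screen_set):
    cohort = generate_cohort(GeneratorConfig(n_stays=400), seed=3)
    reversed_cohort = Cohort(list(cohort)[::-1])
    for c in (cohort, reversed_cohort):
        labeling = classify_cohort(c, index_map)
        reference = label_cohort(c, screen_set)
        profiles = profile_discordance(c, labeling, reference)
        fp_freq = profiles["FALSE_POSITIVE"].code_freq
        if c is cohort:
            first = fp_freq
        else:
            assert fp_freq.equals(first)
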