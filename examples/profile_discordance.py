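"""Profile the classification errors on the packaged deterministic cohort:
where false positives came from, and what false negatives looked like in
the emergency ward."""

from bleedvalidate import (
    Category,
    chapter_group,
    classify_cohort,
    cohort_from_contingency,
    default_index_map,
    default_screen_set,
    discordant_stays,
    false_negative_code_table,
    false_positive_pathway_split,
    label_cohort,
    match_category,
    table2_spec,
)

cohort = cohort_from_contingency(table2_spec())
index_map = default_index_map()
labeling = classify_cohort(cohort, index_map)
reference = label_cohort(cohort, default_screen_set())
fp, fn = discordant_stays(labeling, reference)

print(f"false positives: {len(fp)}, false negatives: {len(fn)}")
print("FP screen pathway:", false_positive_pathway_split(fp, reference))

head = false_negative_code_table(cohort, fn, min_percent=2.0)
print("\nmost cited emergency-ward codes among false negatives (>2%):")
print(head.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
full = false_negative_code_table(cohort, fn)
in_map = sum(
    int(c) for code, c in zip(full["code"], full["count"])
    if match_category(code, index_map) is not Category.NONE
)
print(f"\nstays whose emergency code is on the index list "
      f"(coded as bleeding at the ward, not at discharge): {in_map}")

print("\nfalse-negative primary discharge chapters:")
print(chapter_group(cohort, fn).head(4).to_string(index=False,
      float_format=lambda v: f"{v:.1f}"))
# Injury (S), blood disease (D), circulatory (I) and digestive (K) chapters
# dominate: discharge coding favours etiology over the bleeding event.
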