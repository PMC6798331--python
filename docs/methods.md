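# Methods

## The validation design

The package evaluates a rule-based phenotyping algorithm (the *index
test*) against a two-step *reference standard* on a cohort of adult
hospital stays admitted through an emergency ward, in a cross-sectional
design: every stay receives one index label and one reference label, and
the two are crossed in a typed contingency table.

**Index test.** The primary hospital discharge ICD-10 code — and nothing
else — is matched against three fixed code lists (7 intracranial, 22
gastrointestinal, 23 other-bleeding codes, shipped in
`data/index_codes.yaml`), yielding one of four exclusive categories
(ICH / GI / OTHER / NONE). Emergency-ward codes and secondary diagnoses
never influence the index label.

Matching semantics: codes are normalized (uppercase, dot stripped, so
"K27.2" ≡ "K272"). A 3-character list entry (I60, I61, I62, D62, N02,
R31, R58) matches the bare code and every 4th-character extension; a
4-character entry matches exactly. The exact-match rule for 4-character
entries is deliberate: the lists include S06.3–S06.6 but not the rest of
S06, so a prefix rule at 4 characters would wrongly swallow sibling codes.
The packaged list forbids any code appearing in two categories and any
cross-category nesting; for user-supplied lists an optional precedence
mode (ICH > GI > OTHER, the category listing order) resolves overlaps
instead of rejecting them.

**Reference standard, step 1 (automated screen).** A stay is selected for
chart review when any emergency-ward code matches the screen code list
(same matching semantics) or when the stay received one of six emergency
therapies: red-blood-cell transfusion, platelet transfusion, vitamin K,
protamine sulfate, prothrombin complex concentrate, FEIBA. A stay the
screen does not select is labelled NOT_MAJOR without review — a step-1
miss is final. This is the design's known blind spot and is preserved
faithfully; the composition test asserts that a screened-out stay whose
chart would adjudicate MAJOR still ends NOT_MAJOR.

The shipped screen list (`data/screen_codes.yaml`) is the union of the
index codes and a stand-in list of hemorrhage-compatible emergency-ward
codes (anemia D64.9, hypovolemic shock R57.1, injuries S00.0/S39.0,
procedure complications T81.0, …); the original request's exact list is
not public, so the default is explicitly replaceable via a user config.

**Reference standard, step 2 (adjudication).** A selected stay is MAJOR
iff at least one criterion holds on its structured chart features:

| criterion | rule |
|---|---|
| hemodynamic | SBP < 90 mmHg, or MAP < 65 mmHg, or shock |
| uncontrollable | uncontrollable bleeding charted |
| transfusion/hemostasis | transfusion, or embolization / endoscopy / surgery |
| life-threatening location | intracranial, intraspinal, intraocular, retroperitoneal, pericardial, thoracic, intra-articular, intramuscular with compartment syndrome, acute GI |
| epistaxis rule | ≥ 2 nasal packing procedures |
| hematuria rule | bleeding > 12 h **and** bladder washing attempted |

All inequalities are strict as written; "at least two packings" is ≥ 2.
An undocumented item never triggers a criterion and an absent chart
adjudicates NOT_MAJOR: chart review can only use what is charted
(undocumented = absent). "Shock" and "uncontrollable bleeding" are taken
as charted flags — no operational sub-definition is imposed. The hematuria
rule requires washing to have been attempted ("despite bladder washing");
prolonged hematuria without washing does not qualify. Hemoglobin-drop
criteria (as in the ISTH definition) are deliberately out of scope:
discharge databases carry no laboratory values.

## Statistics

From the typed table, TP pools the reference-positives of the three
bleeding categories, FN is the reference-positives labelled NONE, etc.
Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN);
per-category PPV uses a single category row. LR⁺ = Se/(1−Sp),
LR⁻ = (1−Se)/Sp.

**Exact intervals.** Proportions get two-sided Clopper–Pearson intervals
via beta quantiles: lower = B(α/2; k, n−k+1) (0 when k = 0), upper =
B(1−α/2; k+1, n−k) (1 when k = n); α defaults to 0.05 and is
configurable, always two-sided. The test suite checks the implementation
against an independent bisection on binomial tail probabilities (agreement
to 1e-9 over all 0 ≤ k ≤ n ≤ 200) and against
`statsmodels.proportion_confint(method="beta")`.

**Likelihood-ratio intervals** use the standard log-normal (Simel-type)
construction: on the log scale, SE(ln LR⁺) = √(1/TP − 1/(TP+FN) + 1/FP −
1/(FP+TN)), analogously with the FN/TN cells for LR⁻. When a required
cell is zero, +0.5 is added to all four cells *for the interval only* and
the result is flagged `adjusted`; the point estimate is always the
closed-form ratio (0, or not-applicable when the denominator cell makes
the ratio infinite). Any quantity with an empty denominator is reported
as not-applicable with a reason, never as 0. No multiplicity adjustment
is applied across per-type analyses.

**Rounding** is for display only: percentages to one decimal, LR⁺ to one
decimal and LR⁻ to two, decimal round-half-up; full precision is retained
internally and in `report.json`.

## Synthetic cohorts

Real discharge and emergency-ward extracts cannot be redistributed, so
validation runs on two kinds of synthetic data.

**Deterministic contingency expansion.** `cohort_from_contingency` expands
an explicit list of strata (count, primary code, emergency-ward code,
therapies, chart, latent truth) into a cohort, then runs the full
pipeline and verifies every margin the spec declares, raising on the
first violation. The packaged `data/table2_fixture.yaml` (16,012 stays)
reproduces, end to end, a published validation study's typed contingency
table (281/12, 141/56, 60/87, 254/15,121), screen split
(1959 selected = 736 major + 1223 not major; 14,053 discarded),
false-positive pathway split (141/14), per-code-family frequency table,
and false-negative profile (107 of 254 with an index-list emergency code
over 18 distinct codes; discharge chapters S/D/I/K = 94/34/34/30). Where
the printed record constrains only margins, the joint choices are
arbitrary but fixed and documented in the file: the false-negative
(primary code, emergency code) pairing zips the two marginal lists in
listed order, and adjudication criteria cycle across strata. Ages and
sexes follow deterministic cosmetic patterns; no computation consumes
them.

**Stochastic generator.** Each stay draws, in order: latent truth
(Bernoulli at `prevalence`), a bleeding type from `type_mix` if MAJOR, a
primary code — from the correct category's list with probability
`coding_sensitivity`, else a filler non-bleeding code
(`data/filler_codes.yaml`, replaceable); a NOT_MAJOR stay draws a
bleeding code with probability `coding_fpr`. Every MAJOR stay's chart
satisfies at least one criterion (type-consistent location 50%,
transfusion 30%, hypotension 20%); it is screen-visible with probability
`screen_sensitivity` (emergency code mirroring its discharge code, or an
anemia/shock signal code). A NOT_MAJOR stay is screen-selected with
probability 1 − `screen_specificity`, carrying a signal code and no
adjudicable chart. The screen is therefore the only leak between latent
truth and reference label. Randomness uses one global seed with per-stay
counter-based substreams (`default_rng([seed, index])`), so cohorts are
reproducible under any chunking.

Defaults are the observed study conditions: n = 16,012; prevalence
736/16,012; type mix 0.46/0.31/0.23; coding sensitivity 0.655; coding
false-positive rate 0.0101; screen sensitivity 1.0 and specificity 0.92
(= 1 − 1223/15,276); age ~ Normal(61.7, 22.7²) truncated at 18 years;
52.2% male.

`operating_point()` converts generator parameters into the index test's
true operating values against the *reference* (not the latent truth):
sensitivity equals `coding_sensitivity` (coding and screening are
independent), while reference-negatives mix true negatives with
screen-missed true bleeds, whose coding behaves like a bleed — so
specificity is 1 − [p(1−s)·se_c + (1−p)·fpr_c] / [p(1−s) + (1−p)] with
p the prevalence and s the screen sensitivity.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: correlated coding practices across sites
and coders, secondary-diagnosis structure, in-hospital (as opposed to
admission-motive) bleeding, length of stay and dates, drug exposure, any
dependence of coding error on severity, and realistic joint distributions
of emergency codes within a stay. Recovery experiments show the
*pipeline* is consistent for its operating point under the stated
misclassification model, not that the model matches any hospital.

## Problem sizes and numerical checks

The test suite runs the deterministic 16,012-stay cohort once (shared
session fixture, ~2 s), the Clopper–Pearson oracle over all n ≤ 200, an
interval-coverage simulation (2,000 binomial draws at p = 0.7, n = 50,
expecting ≥ 93% coverage from a conservative exact interval), a
generative-consistency check at n = 50,000, and a 100-replicate recovery
experiment at n = 2,000 per replicate with fixed seeds. Property-based
tests (hypothesis, derandomized) cover normalization idempotence and
adjudication monotonicity: charting one more criterion can never downgrade
a MAJOR verdict.

## Known limitations

* The reference standard is emulated from structured chart features; no
  free-text chart parsing is attempted.
* The screen code list is a documented stand-in, not the historical one;
  results on user data should swap in the site's own list.
* Per-type sensitivity/specificity against a binary reference is not
  offered — its definition is ambiguous and the package computes only
  per-type PPV.
* The likelihood-ratio intervals are the standard log-normal ones; exact
  or profile-likelihood LR intervals are not implemented.
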