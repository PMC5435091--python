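# Methods

## Problem setting

The package operationalizes chart-level case finding for
physician-diagnosed COPD in primary-care EMRs and the study design used to
validate such case definitions: a cohort of charts manually abstracted
into four labels (definite COPD / possible COPD / COPD ruled out / no
mention), with "definite COPD" as the reference standard and everything
else as reference negative. "Possible COPD" charts (typically short-acting
bronchodilator users without a confirmed diagnosis) therefore count
against an algorithm's PPV by default; `exclude_possible=True` drops them
instead, as a sensitivity analysis.

## Chart model

A chart carries demographics (birth date required; sex may be `unknown`
because source records sometimes lack it), ordered free-text CPP entries
(problem list / past medical history), dated billing events, dated
prescription texts, structured smoking records, and a boolean flag for a
pulmonary function test on the chart. PFT *content* is deliberately not
modelled: scanned or faxed reports are not text-searchable in practice, so
presence is the only usable signal. Dates are ISO calendar dates — daily
granularity is the finest any criterion needs. Billing codes are
normalized for comparison by trimming, uppercasing and stripping decimal
subcodes to the stem ("491.2" → "491"), with the original string retained
for audit; normalization is idempotent.

## Text matching

Matching is string search, not NLP: lowercase, collapse whitespace, then
boundary-aware substring search (flanking characters must be
non-alphanumeric, so "copd" never fires inside another word). An
uncertainty marker *before* the matched term in the same entry excludes
the hit; markers after the term, and compound qualifiers such as
"Asthma/COPD", never exclude — this asymmetry reproduces the documented
false-positive mode of CPP search and is what the discordance categories
key on. The exclusion scope is the whole entry by default
(`lookback_tokens` can narrow it). The shipped term list — COPD spellings,
"emphysema", "chronic bronchitis", a small misspelling list — and the
marker list ("?", "possible" active by default; "query"/"r/o"/"rule out"
available opt-in) are package choices, fully overridable from a YAML/JSON
lexicon, because no canonical list is published. `strict_paper` mode
restricts terms to explicit COPD spellings and markers to "?"/"possible".
Drug texts classify longest-variant-first so combination products beat
their components; anything outside the three COPD-specific classes is
`other` by construction, since short-acting bronchodilators are not
specific to COPD.

## Atomic criteria

* **Billing count in window.** "Within 1 year" means any sliding 365-day
  span (inclusive endpoints), evaluated by anchoring candidate windows at
  each qualifying event date — sufficient because an optimal window can be
  slid until its left edge touches an event; a property test checks this
  against an exhaustive all-anchors oracle. A calendar-year mode exists for
  sensitivity analysis. Same-day claims each count once per claim record
  (no de-duplication rule is published); per-day de-duplication is a
  switch.
* **Drug criterion.** Scope "ever" (any prescription date) or "active"
  (currently active only). All cataloged algorithms use "ever".
* **Smoking.** The most-recent-dated record governs; a date tie resolves
  to the later record in chart order. A most-recent "non-smoker" after an
  earlier "current" reads literally as negative — whether the source study
  re-interpreted such sequences as ex-smokers is unknowable, so the
  literal rule is implemented.

## Algorithm engine

Algorithms are AND/OR trees over the atomic leaves; NOT is rejected so
every expressible algorithm is monotone (adding positive evidence can
never flip positive → negative, which is property-tested). Evaluation
never short-circuits: every true leaf is recorded in `fired_criteria` so
discordance analysis can see what drove a call. In the final algorithm's
ipratropium clause, the paired "≥1 billing code" has no time-proximity
constraint to the prescription ("at any time in the chart"). The catalog
is frozen and hashed into run logs.

## Interval methods

Clopper–Pearson was chosen for the four proportions (it is the exact
binomial method and reproduces the published bounds, e.g. 72.2–81.2 for
280/364); Simel's log method for LRs and Woolf's log method for the DOR
likewise reproduce the published bounds (142.3–351.6; 578.8–1612.1).
Display rounding is half-up: proportions, LR+ and DOR to 1 decimal, LR−
to 2. Zero cells: 0.5 is added to all four cells (Haldane–Anscombe) for
the affected ratio estimate only, flagged `corrected`; proportions are
never corrected (Clopper–Pearson handles k=0 and k=n natively). Cohen's κ
is computed from the contingency table directly (cross-checked against
scikit-learn in tests) so that the degenerate single-category case can
return an explicit NaN flag rather than a warning.

Two published cells disagree with their own printed counts by one
rounding step — the ex-smoker LR− lower bound (printed 0.76, recomputed
0.7667 → 0.77) and the ipratropium DOR (printed 51.1, recomputed
51.049 → 51.0) — and two whole rows are internally inconsistent as
printed (the tiotropium row's counts do not sum to 364 reference cases;
the combined-prescription row's printed sensitivity contradicts its own
counts and its CI is malformed). These are recorded in
`copdemr.studydata` and excluded from exact-reproduction testing; no
corrected values are guessed.

## Discordance taxonomy

False negatives: uncertainty phrasing (matched-but-excluded CPP term) is
checked first; then sub-threshold billing (some COPD codes but below the
algorithm's threshold); then incomplete CPP (no COPD language and no
billing trace); else other. Sub-threshold billing precedes incomplete CPP
because any non-uncertainty false negative of a monotone OR rule
necessarily lacks a CPP match — checking "no CPP match" first would make
the billing category unreachable, and the mechanisms are better separated
by the presence of a billing trace. False positives: billing-only (all
fired leaves are billing counts), ambiguous/stale CPP (the firing entry
carries compound or uncertainty phrasing the strict rules do not catch),
else other (e.g. drug-trial prescriptions). Planted-mechanism recovery is
tested at 100%.

## Synthetic cohort generator

The generator emulates the validation cohort's *marginal* structure:
n = 5889, prevalence 6.2%, and per-label conditional rates taken from the
published per-feature counts (CPP documentation 205/364 vs 11/5525,
billing ≥1 ever 188/364 vs 120/5525, billing ≥2-in-a-year 100/364 vs
15/5525, tiotropium 186/364, ipratropium-class 47/364, smoking recorded
254/364 with a 102/127/25 current/ex/non split, PFT 147/364 vs 283/5525,
age 68.6 ± 11.5 vs 55.4 ± 13.2 truncated at 35, female 162/364 vs
3157/5525). Two rates are assumptions: the ≥3-in-a-year billing rate is
interpolated geometrically from the ≥1 and ≥2-in-a-year rates
(p₃ = p₂²/p₁ per label), and the uncertain-phrasing rate among CPP
mentions is 5/210, reflecting the handful of reference cases reported
hidden behind "?"/"possible" phrasing. Index date is fixed at 2010-12-31
with a 10-year chart window.

Billing tiers are *realized*, not just drawn: a tier-3 chart receives ≥3
claims inside one 365-day span, tier-2 exactly two inside a span, tier-1
one claim (occasionally a second more than 400 days away). CPP entries,
prescriptions and smoking histories are rendered as free text through the
lexicon templates, so generated cohorts exercise the whole matching
pipeline, including "?COPD" exclusions and "Asthma/COPD" false positives.

Features are conditionally independent by default; a single latent
"documentation completeness" variable (knob in [0,1]) can shift all
documentation probabilities on the logit scale for dependence studies.
Because only marginals are published, joint behavior is emergent: the
combination algorithms come out a few points more sensitive on synthetic
cohorts (≈82% vs 76.9% for the final rule at these defaults) than on the
real cohort, where documentation behaviors correlate. Passing
marginal-recovery tests therefore show the generator is calibrated, not
that combination-rule performance on real charts is reproduced; the exact
reproduction surface is the from-counts recomputation.

About 3% of non-COPD charts are labeled "possible COPD" (and receive a
salbutamol prescription) and 0.5% "COPD ruled out", so all four reference
labels occur. The generator does not attempt realistic clinical
narratives, longitudinal disease progression, inter-provider variation, or
coding drift.

## Problem sizes and determinism

All randomness flows from a single integer seed through one
`numpy` generator; identical seeds give byte-identical cohorts. The test
suite uses an 800-chart cohort for pipeline-level checks and one
study-sized (5889) cohort for calibration checks (fixed seed, 3-standard-
error bands); window-oracle agreement is checked on 1000 random event
sets. The acceptance script recomputes the published statistics from
printed counts and runs one fresh 5889-chart end-to-end evaluation;
everything completes in seconds on one CPU.

## Known limitations

* The term/misspelling lists are package defaults, not the (unpublished)
  study lists; results on real text will depend on local vocabulary.
* No negation/uncertainty handling beyond the marker-before-term rule; no
  spelling correction.
* PFT results, severity grading, administrative-data linkage and
  socioeconomic analyses are out of scope.
* Billing-code semantics assume 3-digit stem codes; other jurisdictions'
  code systems need a custom code set.
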