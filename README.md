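# copdemr

Rule-based case finding for physician-diagnosed chronic obstructive
pulmonary disease (COPD) in primary-care electronic medical records, with
the full diagnostic-accuracy validation harness and a synthetic
labeled-cohort generator.

Primary-care EMRs hold the information needed to assemble COPD cohorts for
quality-of-care and health-services research, but the signal is scattered
across free-text problem lists, physician billing claims and medication
lists. `copdemr` is for epidemiologists and EMR researchers who need to
(1) apply validated COPD case definitions to chart-level data, (2) validate
case definitions of their own against a chart-abstraction reference
standard, and (3) develop and test against realistic synthetic cohorts
when the real charts are access-restricted.

## What it implements

**Case-finding algorithms.** A phenotyping algorithm is a monotone AND/OR
tree over four atomic chart criteria:

* *CPP documentation* — a COPD term (acronyms, full spellings, common
  misspellings) in the cumulative patient profile, found by boundary-aware
  string search with uncertainty exclusion: a "?" or "possible" marker
  before the term in the same entry suppresses the hit, while trailing
  qualifiers ("Asthma/COPD") do not;
* *billing counts* — ≥ *k* COPD diagnostic codes (491 chronic bronchitis,
  492 emphysema, 496 other COPD) either ever or within a sliding 365-day
  window;
* *drug classes* — COPD-specific prescriptions (tiotropium, ipratropium,
  ipratropium/salbutamol) matched by generic/trade-name variants,
  longest-variant-first;
* *smoking status* — the most recent structured smoking record.

The shipped catalog holds twelve validated definitions, including the
final algorithm

```
CPP  OR  tiotropium  OR  (ipratropium AND ≥1 billing code)  OR  ≥3 billing codes in 1 year
```

**Validation statistics.** Against a per-chart reference label (reference
positive = "definite COPD" from manual abstraction), each algorithm is
summarized by Se, Sp, PPV, NPV with Clopper–Pearson exact binomial 95%
CIs (beta-quantile form), the likelihood ratios LR+ = Se/(1−Sp) and
LR− = (1−Se)/Sp with Simel log-scale CIs, and the diagnostic odds ratio
DOR = (TP·TN)/(FP·FN) with the Woolf log interval
exp(ln DOR ± z·√(1/TP+1/FP+1/FN+1/TN)), z = 1.959964. Zero cells trigger
a flagged Haldane–Anscombe correction for the ratio measures only.
Cohen's κ is provided for abstractor agreement.

**Synthetic cohorts.** `generate_cohort(default_params(seed=...))` draws a
labeled 5889-chart cohort (prevalence 6.2%) whose per-label marginal rates
of CPP documentation, billing intensity, prescriptions, smoking recording,
PFT presence and demographics are calibrated to the validation study,
rendered as real free text through the lexicon (including planted "?COPD"
and "Asthma/COPD" entries).

**Discordance analysis.** False negatives/positives are categorized by
mechanism: uncertainty phrasing, incomplete CPP, sub-threshold billing,
billing-only positives, ambiguous/stale CPP.

## Worked example

```python
from copdemr import ConfusionMatrix, row_from_confusion

row = row_from_confusion("combo_final", ConfusionMatrix(tp=280, fp=19, fn=84, tn=5506))
print(row.sensitivity.rounded(1))   # (76.9, 72.2, 81.2)
print(row.ppv.rounded(1))           # (93.6, 90.3, 96.1)
print(row.dor.rounded(1))           # (966.0, 578.8, 1612.1)
```

Of 364 reference COPD cases the final algorithm finds 280 — sensitivity
76.9% (95% CI 72.2–81.2) — while only 19 of 5525 non-cases are called
positive (PPV 93.6%); the DOR of 966 means the odds of a positive call are
about 966 times higher in cases than in non-cases.

Running `python examples/evaluate_synthetic_cohort.py` generates a
synthetic study-sized cohort end to end and prints the twelve-row
validation table for it; the other scripts under `examples/` demonstrate
free-text matching, published-row recomputation and discordance
categorization. A `copdemr` console command exposes the same workflows
(`simulate`, `classify`, `evaluate`, `discordance`) for shell pipelines.

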