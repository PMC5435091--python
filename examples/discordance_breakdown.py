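"""Categorize the final algorithm's errors on a synthetic cohort.

Each false negative / false positive is assigned the documentation
mechanism that produced it: uncertainty phrasing in the CPP, an
incomplete CPP, sub-threshold billing, billing-only positives, or
ambiguous/stale CPP entries such as "Asthma/COPD".
"""

from copdemr import (
    ReferenceLabel,
    apply_algorithm,
    catalog_algorithms,
    categorize_discordant,
    default_lexicon,
    default_params,
    discordance_summary,
    generate_cohort,
)

lexicon = default_lexicon()
spec = catalog_algorithms()["combo_final"]
cohort = generate_cohort(default_params(seed=1))

records = []
for chart in cohort:
    res = apply_algorithm(chart, spec, lexicon)
    truth = chart.reference_label is ReferenceLabel.DEFINITE_COPD
    if truth != res.positive:
        records.append(categorize_discordant(chart, res, lexicon))

for (error_type, category), stats in discordance_summary(records).items():
    print(f"{error_type:15s} {category:24s} {stats['count']:4d} ({stats['percent']}%)")
# Percentages are within each error type. Most false negatives come from
# charts with no CPP mention and too few billing codes; false positives
# split between billing-only charts and ambiguous CPP phrasing.
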