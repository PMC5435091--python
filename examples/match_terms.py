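"""CPP free-text matching with uncertainty exclusion.

The matcher is a boundary-aware string search: a diagnosis term anywhere
in a problem-list entry counts as documentation unless an uncertainty
marker ("?", "possible") precedes it in the same entry. Qualifiers after
the term never exclude — "Asthma/COPD" still counts, which is exactly the
false-positive mode chart review attributes to ambiguous problem lists.
"""

from copdemr import classify_drug, default_lexicon, match_copd_term

lexicon = default_lexicon()

for text in ["COPD - stable", "?COPD", "possible COPD", "Asthma/COPD",
             "patient coping well", "emphysema"]:
    m = match_copd_term(text, lexicon)
    verdict = "counts" if m.positive else ("excluded" if m.matched else "no match")
    print(f"{text!r:28s} -> {verdict:9s}"
          + (f" (trigger {m.exclusion_trigger!r})" if m.excluded else ""))

print()
for rx in ["Spiriva 18 mcg inh od", "Combivent UDV prn", "Atrovent 20 mcg",
           "salbutamol 100 mcg"]:
    print(f"{rx!r:28s} -> {classify_drug(rx, lexicon).value}")
# Combivent maps to the ipratropium/salbutamol combination (longest variant
# wins); salbutamol alone is 'other' because it is not COPD-specific.
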