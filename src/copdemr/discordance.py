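"""Mechanism taxonomy for discordant calls.

False negatives and false positives of a phenotyping algorithm are sorted
into the documentation mechanisms that produced them:

False negatives (reference definite COPD, algorithm negative), in
priority order:

1. ``uncertainty_phrasing`` — the CPP mentions COPD but the phrasing met
   an exclusion rule (a "?" or "possible" marker before the term) despite
   a definitive diagnosis elsewhere in the record;
2. ``insufficient_billing`` — some COPD billing exists but below the
   algorithm's count/window threshold;
3. ``incomplete_cpp`` — no COPD language in the CPP and no billing trace;
4. ``other``.

False positives (algorithm positive, reference not definite):

* ``billing_only`` — the call fired exclusively through billing-count
  leaves, with no CPP or prescription evidence;
* ``ambiguous_or_stale_cpp`` — the call fired through a CPP entry whose
  phrasing carries uncertainty or compound qualifiers that the strict
  exclusion rules do not catch (e.g. "Asthma/COPD"), or that a chart
  review would read as suspected/outdated;
* ``other`` — e.g. drug-trial prescriptions without a confirmed diagnosis.
"""

from __future__ import annotations

import csv
import enum
import re
from collections import Counter
from dataclasses import dataclass
from typing import IO, Sequence

from .algorithms import AlgorithmResult
from .charts import PatientChart, ReferenceLabel
from .errors import DiscordanceContractError
from .features import COPD_BILLING_CODES
from .lexicon import Lexicon, match_copd_term
from .metrics import round_half_up


class ErrorType(str, enum.Enum):
    FALSE_NEGATIVE = "false_negative"
    FALSE_POSITIVE = "false_positive"


class DiscordanceCategory(str, enum.Enum):
    UNCERTAINTY_PHRASING = "uncertainty_phrasing"
    INCOMPLETE_CPP = "incomplete_cpp"
    INSUFFICIENT_BILLING = "insufficient_billing"
    AMBIGUOUS_OR_STALE_CPP = "ambiguous_or_stale_cpp"
    BILLING_ONLY = "billing_only"
    OTHER = "other"


_FN_ONLY = {DiscordanceCategory.INCOMPLETE_CPP, DiscordanceCategory.INSUFFICIENT_BILLING}
_FP_ONLY = {DiscordanceCategory.BILLING_ONLY, DiscordanceCategory.AMBIGUOUS_OR_STALE_CPP}


@dataclass(frozen=True)
class DiscordanceRecord:
    patient_id: str
    error_type: ErrorType
    category: DiscordanceCategory
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.error_type is ErrorType.FALSE_NEGATIVE and self.category in _FP_ONLY:
            raise ValueError(f"{self.category.value} is a false-positive-only category")
        if self.error_type is ErrorType.FALSE_POSITIVE and self.category in _FN_ONLY:
            raise ValueError(f"{self.category.value} is a false-negative-only category")


# Phrasing that a strict "?"/"possible" rule misses but a chart reviewer
# reads as uncertain, compound or unresolved.
_AMBIGUITY_HINTS = ("/", "?", "possible", "query", "rule out", "suspected", "vs")


def _ambiguity_hints(text: str) -> list[str]:
    found = []
    for hint in _AMBIGUITY_HINTS:
        if hint.isalpha() or " " in hint:
            if re.search(r"\b" + re.escape(hint) + r"\b", text):
                found.append(hint)
        elif hint in text:
            found.append(hint)
    return found


def categorize_discordant(
    chart: PatientChart, result: AlgorithmResult, lexicon: Lexicon
) -> DiscordanceRecord:
    """Assign one mechanism category to a discordant chart/result pair."""
    if chart.reference_label is None:
        raise DiscordanceContractError(
            f"chart {chart.patient_id} has no reference label"
        )
    truth = chart.reference_label is ReferenceLabel.DEFINITE_COPD
    if truth == result.positive:
        raise DiscordanceContractError(
            f"chart {chart.patient_id} is concordant (truth={truth}, "
            f"prediction={result.positive})"
        )

    matches = [(e, match_copd_term(e.text, lexicon)) for e in chart.cpp_entries]
    copd_billing = [
        ev for ev in chart.billing_events if ev.normalized_code in COPD_BILLING_CODES
    ]

    if not result.positive:  # false negative
        excluded = [(e, m) for e, m in matches if m.matched and m.excluded]
        if excluded:
            entry, m = excluded[0]
            return DiscordanceRecord(
                chart.patient_id,
                ErrorType.FALSE_NEGATIVE,
                DiscordanceCategory.UNCERTAINTY_PHRASING,
                evidence=(f"cpp: {entry.text!r} (trigger {m.exclusion_trigger!r})",),
            )
        # A non-uncertainty FN of a monotone OR rule necessarily lacks a
        # CPP match, so "incomplete CPP" is reserved for charts with no
        # billing trace either; sub-threshold billing is the more specific
        # mechanism and is checked first.
        if copd_billing:
            return DiscordanceRecord(
                chart.patient_id,
                ErrorType.FALSE_NEGATIVE,
                DiscordanceCategory.INSUFFICIENT_BILLING,
                evidence=tuple(
                    f"billing {ev.code} @ {ev.date.isoformat()}" for ev in copd_billing
                ),
            )
        if not any(m.matched for _, m in matches):
            return DiscordanceRecord(
                chart.patient_id,
                ErrorType.FALSE_NEGATIVE,
                DiscordanceCategory.INCOMPLETE_CPP,
                evidence=("no COPD language in CPP",),
            )
        return DiscordanceRecord(
            chart.patient_id, ErrorType.FALSE_NEGATIVE, DiscordanceCategory.OTHER
        )

    # false positive
    fired = result.fired_criteria
    if fired and all(f.startswith("billing_") for f in fired):
        return DiscordanceRecord(
            chart.patient_id,
            ErrorType.FALSE_POSITIVE,
            DiscordanceCategory.BILLING_ONLY,
            evidence=tuple(fired),
        )
    if any(f == "cpp_mention" for f in fired):
        for entry, m in matches:
            if not m.positive:
                continue
            hints = _ambiguity_hints(entry.text.lower())
            if hints:
                return DiscordanceRecord(
                    chart.patient_id,
                    ErrorType.FALSE_POSITIVE,
                    DiscordanceCategory.AMBIGUOUS_OR_STALE_CPP,
                    evidence=(f"cpp: {entry.text!r} (hints {hints})",),
                )
    return DiscordanceRecord(
        chart.patient_id, ErrorType.FALSE_POSITIVE, DiscordanceCategory.OTHER,
        evidence=tuple(fired),
    )


def discordance_summary(
    records: Sequence[DiscordanceRecord],
) -> dict[tuple[str, str], dict]:
    """Counts and within-error-type percentages per (error_type, category).

    Percentages are of each error type's total, rounded to 1 decimal.
    """
    totals = Counter(r.error_type for r in records)
    pairs = Counter((r.error_type, r.category) for r in records)
    return {
        (et.value, cat.value): {
            "count": count,
            "percent": round_half_up(100.0 * count / totals[et], 1),
        }
        for (et, cat), count in sorted(
            pairs.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        )
    }


def write_discordance_csv(records: Sequence[DiscordanceRecord], stream: IO[str]) -> None:
    writer = csv.writer(stream, lineterminator="\r\n")
    writer.writerow(["patient_id", "error_type", "category", "evidence"])
    for rec in records:
        writer.writerow(
            [rec.patient_id, rec.error_type.value, rec.category.value, "; ".join(rec.evidence)]
        )
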