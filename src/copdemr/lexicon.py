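"""Term-level matching of COPD diagnosis language and COPD-specific drugs.

The matcher is deliberately a string-search engine, not an NLP pipeline:
boundary-aware substring matching over lowercased, whitespace-collapsed
text, with an uncertainty-exclusion rule that suppresses a diagnosis hit
when a query marker ("?", "possible", ...) precedes it within the same
entry. Qualifiers *after* a matched term never exclude, so compound
phrasings like "Asthma/COPD" still count as positive documentation — the
documented false-positive mode of CPP string search.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

from .errors import ConfigError


class DrugClass(str, enum.Enum):
    TIOTROPIUM = "tiotropium"
    IPRATROPIUM = "ipratropium"
    IPRATROPIUM_SALBUTAMOL = "ipratropium_salbutamol"
    OTHER = "other"


#: COPD-specific drug classes (everything else classifies as OTHER because
#: short-acting beta-agonists etc. are not specific for COPD).
COPD_DRUG_CLASSES = frozenset(
    {DrugClass.TIOTROPIUM, DrugClass.IPRATROPIUM, DrugClass.IPRATROPIUM_SALBUTAMOL}
)

_CORE_DIAGNOSIS_TERMS = frozenset(
    {
        "copd",
        "c.o.p.d",
        "chronic obstructive pulmonary disease",
        "chronic obstructive lung disease",
    }
)

_EXTENDED_DIAGNOSIS_TERMS = frozenset({"emphysema", "chronic bronchitis"})

# Shipped misspelling list; real CPP text is typed free-hand.
_MISSPELLING_TERMS = frozenset(
    {
        "chronic obstructive pulmonry disease",
        "chronic obstuctive pulmonary disease",
        "chronic obstructive pulm disease",
        "emphysyma",
        "emphasema",
    }
)

_STRICT_UNCERTAINTY_MARKERS = frozenset({"?", "possible"})
_EXTENDED_UNCERTAINTY_MARKERS = frozenset({"query", "r/o", "rule out"})

_DEFAULT_DRUGS: dict[str, DrugClass] = {
    # combination products first conceptually; matching is longest-first anyway
    "combivent": DrugClass.IPRATROPIUM_SALBUTAMOL,
    "ipratropium/salbutamol": DrugClass.IPRATROPIUM_SALBUTAMOL,
    "ipratropium-salbutamol": DrugClass.IPRATROPIUM_SALBUTAMOL,
    "salbutamol/ipratropium": DrugClass.IPRATROPIUM_SALBUTAMOL,
    "ipratropium and salbutamol": DrugClass.IPRATROPIUM_SALBUTAMOL,
    "tiotropium": DrugClass.TIOTROPIUM,
    "tiotropium bromide": DrugClass.TIOTROPIUM,
    "spiriva": DrugClass.TIOTROPIUM,
    "ipratropium": DrugClass.IPRATROPIUM,
    "ipratropium bromide": DrugClass.IPRATROPIUM,
    "atrovent": DrugClass.IPRATROPIUM,
}


@dataclass(frozen=True)
class TermMatch:
    """Outcome of matching one free-text entry against the lexicon."""

    matched: bool
    excluded: bool = False
    matched_term: Optional[str] = None
    exclusion_trigger: Optional[str] = None

    def __post_init__(self) -> None:
        if self.excluded and not self.matched:
            raise ValueError("excluded implies matched")
        if self.matched != (self.matched_term is not None):
            raise ValueError("matched_term present iff matched")

    @property
    def positive(self) -> bool:
        """Matched and not suppressed by an uncertainty marker."""
        return self.matched and not self.excluded


@dataclass(frozen=True)
class Lexicon:
    """Diagnosis terms, uncertainty markers and drug-name variants.

    All entries are lowercase, non-empty. ``lookback_tokens=None`` means an
    uncertainty marker anywhere earlier in the same entry excludes the hit.
    """

    diagnosis_terms: frozenset[str]
    uncertainty_markers: frozenset[str]
    drug_entries: Mapping[str, DrugClass] = field(default_factory=dict)
    lookback_tokens: Optional[int] = None

    def __post_init__(self) -> None:
        for group, entries in (
            ("diagnosis_terms", self.diagnosis_terms),
            ("uncertainty_markers", self.uncertainty_markers),
            ("drug_entries", self.drug_entries),
        ):
            for term in entries:
                if not term:
                    raise ConfigError(f"{group} contains an empty string")
                if term != term.lower():
                    raise ConfigError(f"{group} entry {term!r} is not lowercase")


def default_lexicon(
    strict_paper: bool = False, extended_markers: bool = False
) -> Lexicon:
    """The shipped lexicon.

    ``strict_paper=True`` restricts diagnosis terms to explicit COPD
    spellings (drops "emphysema"/"chronic bronchitis" free text and the
    misspelling list) and keeps only the "?"/"possible" markers.
    ``extended_markers=True`` additionally enables conservative marker
    extensions ("query", "r/o", "rule out"); off by default.
    """
    if strict_paper:
        terms = _CORE_DIAGNOSIS_TERMS
    else:
        terms = _CORE_DIAGNOSIS_TERMS | _EXTENDED_DIAGNOSIS_TERMS | _MISSPELLING_TERMS
    markers = _STRICT_UNCERTAINTY_MARKERS
    if extended_markers and not strict_paper:
        markers = markers | _EXTENDED_UNCERTAINTY_MARKERS
    return Lexicon(
        diagnosis_terms=frozenset(terms),
        uncertainty_markers=frozenset(markers),
        drug_entries=dict(_DEFAULT_DRUGS),
    )


def load_lexicon(path) -> Lexicon:
    """Load a lexicon from a YAML or JSON configuration file.

    Expected keys: ``diagnosis_terms`` (list), ``uncertainty_markers``
    (list), ``drugs`` (mapping variant -> class), optional
    ``lookback_tokens`` (int).
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    except Exception as exc:
        raise ConfigError(f"cannot parse lexicon file {path}: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"lexicon file {path} must contain a mapping")
    try:
        drugs = {
            str(k).lower(): DrugClass(v) for k, v in (data.get("drugs") or {}).items()
        }
    except ValueError as exc:
        raise ConfigError(f"bad drug class in {path}: {exc}") from None
    return Lexicon(
        diagnosis_terms=frozenset(str(t).lower() for t in data.get("diagnosis_terms", [])),
        uncertainty_markers=frozenset(
            str(m).lower() for m in data.get("uncertainty_markers", [])
        ),
        drug_entries=drugs,
        lookback_tokens=data.get("lookback_tokens"),
    )


_WS = re.compile(r"\s+")


def _canonical(text: str) -> str:
    return _WS.sub(" ", text.lower()).strip()


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def _find_bounded(text: str, term: str, start: int = 0) -> int:
    """Index of the first boundary-respecting occurrence of ``term`` in
    ``text`` at or after ``start``; -1 if none.

    A boundary requires the characters flanking the occurrence not to be
    alphanumeric, so "copd" does not fire inside an unrelated word. Terms
    whose own edges are non-word characters (e.g. "?") need no boundary on
    that side.
    """
    pos = text.find(term, start)
    while pos != -1:
        left_ok = (
            pos == 0
            or not _is_word_char(text[pos - 1])
            or not _is_word_char(term[0])
        )
        end = pos + len(term)
        right_ok = (
            end == len(text)
            or not _is_word_char(text[end])
            or not _is_word_char(term[-1])
        )
        if left_ok and right_ok:
            return pos
        pos = text.find(term, pos + 1)
    return -1


def match_copd_term(text: str, lexicon: Lexicon) -> TermMatch:
    """Match one free-text entry for COPD diagnosis language.

    ``matched`` is true iff any diagnosis term occurs (case-insensitive,
    boundary-aware). ``excluded`` is true iff an uncertainty marker occurs
    *before* the matched term within the entry, within the lexicon's
    lookback window. Text after the match never triggers exclusion.
    """
    canon = _canonical(text)
    if not canon:
        return TermMatch(matched=False)

    best_pos, best_term = -1, None
    for term in lexicon.diagnosis_terms:
        pos = _find_bounded(canon, term)
        if pos != -1 and (best_pos == -1 or pos < best_pos or (pos == best_pos and len(term) > len(best_term or ""))):
            best_pos, best_term = pos, term
    if best_term is None:
        return TermMatch(matched=False)

    prefix = canon[:best_pos]
    trigger = None
    trigger_end = -1
    for marker in lexicon.uncertainty_markers:
        pos = _find_bounded(prefix, marker)
        while pos != -1:  # keep the marker closest to the term
            end = pos + len(marker)
            if end > trigger_end:
                trigger, trigger_end = marker, end
            pos = _find_bounded(prefix, marker, pos + 1)
    if trigger is not None and lexicon.lookback_tokens is not None:
        between = prefix[trigger_end:].split()
        if len(between) > lexicon.lookback_tokens:
            trigger = None
    if trigger is not None:
        return TermMatch(
            matched=True, excluded=True, matched_term=best_term, exclusion_trigger=trigger
        )
    return TermMatch(matched=True, excluded=False, matched_term=best_term)


def classify_drug(raw_text: str, lexicon: Lexicon) -> DrugClass:
    """Classify a prescription's free text into a drug class.

    Variants are tried longest-first so combination products beat their
    components ("Combivent" -> ipratropium_salbutamol, not ipratropium).
    Unrecognized text classifies as OTHER.
    """
    canon = _canonical(raw_text)
    if not canon:
        return DrugClass.OTHER
    for variant in sorted(lexicon.drug_entries, key=len, reverse=True):
        if _find_bounded(canon, variant) != -1:
            return lexicon.drug_entries[variant]
    return DrugClass.OTHER
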