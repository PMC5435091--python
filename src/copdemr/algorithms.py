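"""Phenotyping algorithms as monotone boolean trees over atomic criteria.

An :class:`AlgorithmSpec` is an AND/OR tree whose leaves are the atomic
criteria of :mod:`copdemr.features`. The shipped catalog holds the twelve
validated COPD case definitions: single-component rules (CPP
documentation, billing-count thresholds, smoking status, drug classes)
and the combination rules, including the final algorithm

    CPP OR tiotropium OR (ipratropium AND >=1 billing code)
        OR >=3 billing codes in 1 year

and the alternative

    CPP OR any COPD prescription OR >=2 billing codes in 1 year.

All catalog trees are monotone (no NOT nodes): adding positive evidence to
a chart can never flip a positive call to negative.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import yaml

from .charts import PatientChart, SmokingStatus
from .errors import ConfigError
from .features import (
    COPD_BILLING_CODES,
    Window,
    billing_criterion_met,
    cpp_indicates_copd,
    drug_criterion_met,
    smoking_status_is,
)
from .lexicon import DrugClass, Lexicon

# ---------------------------------------------------------------------------
# Leaves


@dataclass(frozen=True)
class CPPMention:
    """CPP documents COPD (non-excluded lexicon match)."""

    kind: str = field(default="cpp_mention", init=False)

    @property
    def leaf_id(self) -> str:
        return "cpp_mention"

    def evaluate(self, chart: PatientChart, lexicon: Lexicon) -> bool:
        return cpp_indicates_copd(chart, lexicon)


@dataclass(frozen=True)
class BillingCount:
    """At least ``min_count`` qualifying billing events, ever or within a
    sliding window of ``window_days``."""

    codes: frozenset[str] = COPD_BILLING_CODES
    min_count: int = 1
    window_days: Window = "ever"
    kind: str = field(default="billing_count", init=False)

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("billing_count: min_count must be >= 1")
        if self.window_days != "ever" and int(self.window_days) <= 0:
            raise ConfigError("billing_count: window_days must be positive")

    @property
    def leaf_id(self) -> str:
        win = self.window_days if self.window_days == "ever" else f"{self.window_days}d"
        return f"billing_ge{self.min_count}_{win}"

    def evaluate(self, chart: PatientChart, lexicon: Lexicon) -> bool:
        return billing_criterion_met(chart, self.codes, self.min_count, self.window_days)


@dataclass(frozen=True)
class DrugCriterion:
    """A prescription in one of ``classes``; scope "ever" or "active"."""

    classes: frozenset[DrugClass]
    scope: Literal["ever", "active"] = "ever"
    kind: str = field(default="drug_class", init=False)

    @property
    def leaf_id(self) -> str:
        names = "+".join(sorted(c.value for c in self.classes))
        return f"drug_{names}_{self.scope}"

    def evaluate(self, chart: PatientChart, lexicon: Lexicon) -> bool:
        return drug_criterion_met(chart, self.classes, self.scope, lexicon)


@dataclass(frozen=True)
class SmokingCriterion:
    """Most recent smoking record has a status in ``statuses``."""

    statuses: frozenset[SmokingStatus] = frozenset(
        {SmokingStatus.CURRENT, SmokingStatus.EX}
    )
    kind: str = field(default="smoking_positive", init=False)

    @property
    def leaf_id(self) -> str:
        return "smoking_" + "+".join(sorted(s.value for s in self.statuses))

    def evaluate(self, chart: PatientChart, lexicon: Lexicon) -> bool:
        return smoking_status_is(chart, self.statuses)


Leaf = Union[CPPMention, BillingCount, DrugCriterion, SmokingCriterion]


# ---------------------------------------------------------------------------
# Expression tree


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ConfigError("AND node must have children")


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ConfigError("OR node must have children")


Expr = Union[And, Or, Leaf]


def _evaluate(expr: Expr, chart: PatientChart, lexicon: Lexicon, fired: list[str]) -> bool:
    # full evaluation, no short-circuit: every true leaf lands in `fired`
    # so discordance analysis can see exactly which criteria drove a call
    if isinstance(expr, And):
        results = [_evaluate(c, chart, lexicon, fired) for c in expr.children]
        return all(results)
    if isinstance(expr, Or):
        results = [_evaluate(c, chart, lexicon, fired) for c in expr.children]
        return any(results)
    value = expr.evaluate(chart, lexicon)
    if value:
        fired.append(expr.leaf_id)
    return value


def iter_leaves(expr: Expr):
    if isinstance(expr, (And, Or)):
        for child in expr.children:
            yield from iter_leaves(child)
    else:
        yield expr


@dataclass(frozen=True)
class AlgorithmSpec:
    id: str
    expr: Expr


@dataclass(frozen=True)
class AlgorithmResult:
    patient_id: str
    positive: bool
    fired_criteria: tuple[str, ...]


def apply_algorithm(
    chart: PatientChart, spec: AlgorithmSpec, lexicon: Lexicon
) -> AlgorithmResult:
    """Evaluate one algorithm on one chart, recording every leaf that fired."""
    fired: list[str] = []
    positive = _evaluate(spec.expr, chart, lexicon, fired)
    return AlgorithmResult(
        patient_id=chart.patient_id, positive=positive, fired_criteria=tuple(fired)
    )


# ---------------------------------------------------------------------------
# Catalog

_CPP = CPPMention()
_TIO = DrugCriterion(classes=frozenset({DrugClass.TIOTROPIUM}))
_IPRA = DrugCriterion(
    classes=frozenset({DrugClass.IPRATROPIUM, DrugClass.IPRATROPIUM_SALBUTAMOL})
)
_ANY_DRUG = DrugCriterion(
    classes=frozenset(
        {DrugClass.TIOTROPIUM, DrugClass.IPRATROPIUM, DrugClass.IPRATROPIUM_SALBUTAMOL}
    )
)
_SMOKING = SmokingCriterion()
_BILL1_EVER = BillingCount(min_count=1, window_days="ever")
_BILL2_1YR = BillingCount(min_count=2, window_days=365)
_BILL3_1YR = BillingCount(min_count=3, window_days=365)

_FINAL_EXPR = Or((_CPP, _TIO, And((_IPRA, _BILL1_EVER)), _BILL3_1YR))
_ALT_EXPR = Or((_CPP, _ANY_DRUG, _BILL2_1YR))


def catalog_algorithms() -> dict[str, AlgorithmSpec]:
    """The twelve validated case definitions, keyed by id.

    Drug scope throughout is "ever" (prescribed at any point in time);
    active-only variants remain constructible via :class:`DrugCriterion`.
    """
    specs = [
        AlgorithmSpec("cpp_only", _CPP),
        AlgorithmSpec("billing_ge1_ever", _BILL1_EVER),
        AlgorithmSpec("billing_ge2_1yr", _BILL2_1YR),
        AlgorithmSpec(
            "smoker_current", SmokingCriterion(frozenset({SmokingStatus.CURRENT}))
        ),
        AlgorithmSpec("smoker_ex", SmokingCriterion(frozenset({SmokingStatus.EX}))),
        AlgorithmSpec("drug_tio_or_ipra", _ANY_DRUG),
        AlgorithmSpec("drug_tio", _TIO),
        AlgorithmSpec("drug_ipra", _IPRA),
        AlgorithmSpec("combo_final", _FINAL_EXPR),
        AlgorithmSpec("combo_alt", _ALT_EXPR),
        AlgorithmSpec(
            "combo_final_plus_smoking", Or(_FINAL_EXPR.children + (_SMOKING,))
        ),
        AlgorithmSpec("combo_alt_plus_smoking", Or(_ALT_EXPR.children + (_SMOKING,))),
    ]
    return {s.id: s for s in specs}


def _expr_to_obj(expr: Expr):
    if isinstance(expr, And):
        return {"and": [_expr_to_obj(c) for c in expr.children]}
    if isinstance(expr, Or):
        return {"or": [_expr_to_obj(c) for c in expr.children]}
    if isinstance(expr, CPPMention):
        return {"cpp_mention": {}}
    if isinstance(expr, BillingCount):
        return {
            "billing_count": {
                "codes": sorted(expr.codes),
                "min_count": expr.min_count,
                "window_days": expr.window_days,
            }
        }
    if isinstance(expr, DrugCriterion):
        return {
            "drug_class": {
                "classes": sorted(c.value for c in expr.classes),
                "scope": expr.scope,
            }
        }
    if isinstance(expr, SmokingCriterion):
        return {"smoking_positive": {"statuses": sorted(s.value for s in expr.statuses)}}
    raise TypeError(f"unknown expression node {expr!r}")


def _expr_from_obj(obj) -> Expr:
    if not isinstance(obj, dict) or len(obj) != 1:
        raise ConfigError(f"algorithm node must be a single-key mapping, got {obj!r}")
    key, val = next(iter(obj.items()))
    if key == "and":
        return And(tuple(_expr_from_obj(c) for c in val))
    if key == "or":
        return Or(tuple(_expr_from_obj(c) for c in val))
    if key == "not":
        raise ConfigError("NOT nodes are not supported: catalog algorithms are monotone")
    val = val or {}
    if key == "cpp_mention":
        return CPPMention()
    if key == "billing_count":
        window = val.get("window_days", "ever")
        return BillingCount(
            codes=frozenset(str(c) for c in val.get("codes", COPD_BILLING_CODES)),
            min_count=int(val.get("min_count", 1)),
            window_days="ever" if window == "ever" else int(window),
        )
    if key == "drug_class":
        try:
            classes = frozenset(DrugClass(c) for c in val["classes"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"drug_class leaf: {exc}") from None
        return DrugCriterion(classes=classes, scope=val.get("scope", "ever"))
    if key == "smoking_positive":
        statuses = val.get("statuses", ["current", "ex"])
        try:
            return SmokingCriterion(frozenset(SmokingStatus(s) for s in statuses))
        except ValueError as exc:
            raise ConfigError(f"smoking_positive leaf: {exc}") from None
    raise ConfigError(f"unknown algorithm node kind {key!r}")


def load_algorithms(path) -> dict[str, AlgorithmSpec]:
    """Load custom algorithm definitions from YAML/JSON: a mapping of
    algorithm id -> nested AND/OR tree over named atomic leaves."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"algorithm file {path} must map ids to expression trees")
    return {
        str(aid): AlgorithmSpec(str(aid), _expr_from_obj(tree))
        for aid, tree in data.items()
    }


def catalog_hash() -> str:
    """Stable short hash of the frozen catalog definitions, for run logs."""
    payload = json.dumps(
        {aid: _expr_to_obj(s.expr) for aid, s in catalog_algorithms().items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
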