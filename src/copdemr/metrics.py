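"""Diagnostic-accuracy evaluation against the chart-abstraction reference.

Implements the full validation table for a set of phenotyping algorithms:
confusion counts, sensitivity/specificity/PPV/NPV with Clopper-Pearson
exact binomial intervals, likelihood ratios and the diagnostic odds ratio
with log-scale intervals, predicted prevalence, and Cohen's kappa for
abstractor agreement.

Interval conventions
--------------------
Proportions use the Clopper-Pearson exact method via beta quantiles:

    lower = B(alpha/2; k, n-k+1),  upper = B(1-alpha/2; k+1, n-k)

with lower=0 at k=0 and upper=1 at k=n.  LR+ and LR- use the Simel log
method, e.g. for LR+:

    exp( ln LR+  +/-  z * sqrt((1-sens)/TP + spec/FP) )

and the DOR uses the Woolf log method with SE sqrt(1/TP+1/FP+1/FN+1/TN),
z = Phi^-1(0.975) = 1.959964.  When a required cell is zero, the
Haldane-Anscombe correction (0.5 added to all four cells) is applied to
that ratio estimate only — never to proportions — and the estimate is
flagged ``corrected``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import beta as _beta
from scipy.stats import norm as _norm

from .algorithms import AlgorithmResult, AlgorithmSpec, apply_algorithm
from .charts import PatientChart, ReferenceLabel
from .errors import EvaluationError, UndefinedMetricError
from .lexicon import Lexicon


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (display rounding; 0.25 -> 0.3 at 1 digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


class CIMethod(str, enum.Enum):
    CLOPPER_PEARSON = "clopper_pearson"
    LOG_WALD = "log_wald"


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI.

    ``value`` is on the percent scale for proportions and on the ratio
    scale for LR+/LR-/DOR. ``corrected`` marks estimates computed under the
    zero-cell (Haldane-Anscombe) policy.
    """

    value: float
    ci_low: float
    ci_high: float
    method: CIMethod
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket {self.value}"
            )

    def rounded(self, ndigits: int) -> tuple[float, float, float]:
        return (
            round_half_up(self.value, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negatives(self) -> int:
        return self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """Exchange the roles of cases and non-cases (tp<->tn, fp<->fn)."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


_Z95 = float(_norm.ppf(0.975))  # 1.959964


def proportion_with_ci(k: int, n: int, conf: float = 0.95) -> MetricEstimate:
    """Exact binomial proportion: 100*k/n with a Clopper-Pearson CI."""
    if n < 1:
        raise UndefinedMetricError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return MetricEstimate(
        value=100.0 * k / n,
        ci_low=100.0 * low,
        ci_high=100.0 * high,
        method=CIMethod.CLOPPER_PEARSON,
    )


@dataclass(frozen=True)
class RatioMetrics:
    lr_pos: MetricEstimate
    lr_neg: MetricEstimate
    dor: MetricEstimate


def _log_interval(value: float, se: float, conf: float) -> tuple[float, float]:
    z = float(_norm.ppf(0.5 + conf / 2))
    return math.exp(math.log(value) - z * se), math.exp(math.log(value) + z * se)


def ratio_metrics(cm: ConfusionMatrix, conf: float = 0.95) -> RatioMetrics:
    """LR+, LR- and DOR with log-scale CIs (Simel / Woolf methods)."""

    def cells(required: tuple[int, ...]) -> tuple[float, float, float, float, bool]:
        if any(c == 0 for c in required):
            return cm.tp + 0.5, cm.fp + 0.5, cm.fn + 0.5, cm.tn + 0.5, True
        return float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn), False

    # LR+ needs tp (sens>0) and fp (1-spec>0); LR- needs fn and tn; DOR all.
    tp, fp, fn, tn, corr_p = cells((cm.tp, cm.fp))
    sens, spec = tp / (tp + fn), tn / (fp + tn)
    lrp = sens / (1 - spec)
    lo, hi = _log_interval(lrp, math.sqrt((1 - sens) / tp + spec / fp), conf)
    lr_pos = MetricEstimate(lrp, lo, hi, CIMethod.LOG_WALD, corrected=corr_p)

    tp, fp, fn, tn, corr_n = cells((cm.fn, cm.tn))
    sens, spec = tp / (tp + fn), tn / (fp + tn)
    lrn = (1 - sens) / spec
    lo, hi = _log_interval(lrn, math.sqrt(sens / fn + (1 - spec) / tn), conf)
    lr_neg = MetricEstimate(lrn, lo, hi, CIMethod.LOG_WALD, corrected=corr_n)

    tp, fp, fn, tn, corr_d = cells((cm.tp, cm.fp, cm.fn, cm.tn))
    dor_val = (tp * tn) / (fp * fn)
    lo, hi = _log_interval(
        dor_val, math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn), conf
    )
    dor = MetricEstimate(dor_val, lo, hi, CIMethod.LOG_WALD, corrected=corr_d)
    return RatioMetrics(lr_pos=lr_pos, lr_neg=lr_neg, dor=dor)


def predicted_prevalence(cm: ConfusionMatrix, cohort_n: int) -> float:
    """Percent of the cohort the algorithm calls positive."""
    if cohort_n != cm.n:
        raise EvaluationError(
            f"cohort_n={cohort_n} does not match confusion total {cm.n}"
        )
    return 100.0 * (cm.tp + cm.fp) / cohort_n


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for two raters over the same items.

    Returns NaN (the undefined flag) when expected agreement is 1, i.e.
    both raters use a single identical category and chance-corrected
    agreement has no meaning.
    """
    if len(ratings_a) != len(ratings_b):
        raise EvaluationError(
            f"rating sequences differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if len(ratings_a) == 0:
        raise EvaluationError("rating sequences are empty")
    labels = sorted(set(ratings_a) | set(ratings_b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in zip(ratings_a, ratings_b):
        table[index[a], index[b]] += 1
    n = table.sum()
    p_obs = np.trace(table) / n
    p_exp = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_exp >= 1.0 - 1e-12:
        return float("nan")
    return float((p_obs - p_exp) / (1 - p_exp))


# ---------------------------------------------------------------------------
# Cohort-level evaluation


def build_confusion(
    results: Mapping[str, bool] | Sequence[AlgorithmResult],
    charts: Sequence[PatientChart],
    exclude_possible: bool = False,
) -> ConfusionMatrix:
    """Tally algorithm calls against the chart-abstraction reference.

    Reference positive is the "definite COPD" label only; "possible COPD",
    "COPD ruled out" and "no mention" all count as reference negative.
    ``exclude_possible`` drops possible-COPD charts from the tally
    (sensitivity-analysis mode).
    """
    if not charts:
        raise EvaluationError("cannot evaluate an empty cohort")
    if not isinstance(results, Mapping):
        results = {r.patient_id: r.positive for r in results}
    chart_ids = {c.patient_id for c in charts}
    if set(results) != chart_ids:
        missing = chart_ids - set(results)
        extra = set(results) - chart_ids
        raise EvaluationError(
            f"results/charts id mismatch (missing={sorted(missing)[:5]}, "
            f"extra={sorted(extra)[:5]})"
        )
    tp = fp = fn = tn = 0
    for chart in charts:
        if chart.reference_label is None:
            raise EvaluationError(
                f"chart {chart.patient_id} lacks reference_label; "
                "unlabeled charts cannot enter evaluation"
            )
        if exclude_possible and chart.reference_label is ReferenceLabel.POSSIBLE_COPD:
            continue
        truth = chart.reference_label is ReferenceLabel.DEFINITE_COPD
        pred = bool(results[chart.patient_id])
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ReportRow:
    """One validation-table row: counts plus the eight derived statistics."""

    algorithm_id: str
    cm: ConfusionMatrix
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    lr_pos: MetricEstimate
    lr_neg: MetricEstimate
    dor: MetricEstimate
    predicted_prevalence: float


@dataclass(frozen=True)
class ValidationReport:
    rows: tuple[ReportRow, ...]
    cohort_n: int


def row_from_confusion(
    algorithm_id: str, cm: ConfusionMatrix, conf: float = 0.95
) -> ReportRow:
    """Derive every validation statistic from raw confusion counts."""
    ratios = ratio_metrics(cm, conf=conf)
    return ReportRow(
        algorithm_id=algorithm_id,
        cm=cm,
        sensitivity=proportion_with_ci(cm.tp, cm.tp + cm.fn, conf),
        specificity=proportion_with_ci(cm.tn, cm.fp + cm.tn, conf),
        ppv=proportion_with_ci(cm.tp, cm.tp + cm.fp, conf),
        npv=proportion_with_ci(cm.tn, cm.tn + cm.fn, conf),
        lr_pos=ratios.lr_pos,
        lr_neg=ratios.lr_neg,
        dor=ratios.dor,
        predicted_prevalence=predicted_prevalence(cm, cm.n),
    )


def build_report(
    charts: Sequence[PatientChart],
    specs: Sequence[AlgorithmSpec] | Mapping[str, AlgorithmSpec],
    lexicon: Lexicon,
    conf: float = 0.95,
    exclude_possible: bool = False,
) -> ValidationReport:
    """Evaluate each algorithm on a labeled cohort; one row per algorithm."""
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    if not specs:
        raise EvaluationError("no algorithm specs supplied")
    rows = []
    for spec in specs:
        results = [apply_algorithm(c, spec, lexicon) for c in charts]
        cm = build_confusion(results, charts, exclude_possible=exclude_possible)
        rows.append(row_from_confusion(spec.id, cm, conf=conf))
    return ValidationReport(rows=tuple(rows), cohort_n=rows[0].cm.n)
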