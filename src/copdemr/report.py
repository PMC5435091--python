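"""Validation-report serialization (CSV table mirror + machine JSON).

Display rounding follows the validation-table convention: proportions,
LR+ and DOR to 1 decimal, LR- to 2 decimals, half-up. Internal estimates
keep full precision; re-reading a written CSV reproduces the rounded
numbers bit-identically.
"""

from __future__ import annotations

import csv
import json
from typing import IO

from .metrics import MetricEstimate, ReportRow, ValidationReport, round_half_up

_PROPORTIONS = ("sensitivity", "specificity", "ppv", "npv")
_RATIOS = (("lr_pos", 1), ("lr_neg", 2), ("dor", 1))

HEADER = (
    ["algorithm", "tp", "tn", "fp", "fn"]
    + [f"{m}{s}" for m in _PROPORTIONS for s in ("", "_low", "_high")]
    + [f"{m}{s}" for m, _ in _RATIOS for s in ("", "_low", "_high")]
    + ["predicted_prevalence", "zero_cell_corrected"]
)


def _row_values(row: ReportRow) -> list:
    values: list = [row.algorithm_id, row.cm.tp, row.cm.tn, row.cm.fp, row.cm.fn]
    for name in _PROPORTIONS:
        values.extend(getattr(row, name).rounded(1))
    corrected = []
    for name, nd in _RATIOS:
        est: MetricEstimate = getattr(row, name)
        values.extend(est.rounded(nd))
        if est.corrected:
            corrected.append(name)
    values.append(round_half_up(row.predicted_prevalence, 1))
    values.append("|".join(corrected))
    return values


def write_validation_report(report: ValidationReport, stream: IO[str]) -> None:
    """Write the report as RFC-4180 CSV, one row per algorithm."""
    writer = csv.writer(stream, lineterminator="\r\n")
    writer.writerow(HEADER)
    for row in report.rows:
        writer.writerow(_row_values(row))


def read_validation_report(stream: IO[str]) -> list[dict]:
    """Read a written report CSV back into per-algorithm dicts of numbers."""
    reader = csv.DictReader(stream)
    out = []
    for rec in reader:
        parsed: dict = {"algorithm": rec["algorithm"]}
        for key in HEADER[1:5]:
            parsed[key] = int(rec[key])
        for key in HEADER[5:-1]:
            parsed[key] = float(rec[key])
        parsed["zero_cell_corrected"] = rec["zero_cell_corrected"]
        out.append(parsed)
    return out


def report_to_json_dict(report: ValidationReport) -> dict:
    """Full-precision machine-readable form, keyed by algorithm id."""
    out: dict = {"cohort_n": report.cohort_n, "algorithms": {}}
    for row in report.rows:
        est = {
            name: {
                "value": getattr(row, name).value,
                "ci_low": getattr(row, name).ci_low,
                "ci_high": getattr(row, name).ci_high,
                "method": getattr(row, name).method.value,
                "corrected": getattr(row, name).corrected,
            }
            for name in _PROPORTIONS + tuple(m for m, _ in _RATIOS)
        }
        out["algorithms"][row.algorithm_id] = {
            "counts": {
                "tp": row.cm.tp,
                "tn": row.cm.tn,
                "fp": row.cm.fp,
                "fn": row.cm.fn,
            },
            "metrics": est,
            "predicted_prevalence": row.predicted_prevalence,
        }
    return out


def write_report_json(report: ValidationReport, stream: IO[str]) -> None:
    json.dump(report_to_json_dict(report), stream, indent=2)
    stream.write("\n")
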