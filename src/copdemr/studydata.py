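"""Published validation-study inputs.

The validation study abstracted 5889 primary-care charts (364 definite
COPD, prevalence 6.2%) and published, for each of twelve case-finding
algorithms, the confusion counts against the reference standard together
with the derived test characteristics. Those printed counts and statistics
are recorded here verbatim as study inputs: the counts drive
recomputation, and the printed statistics serve as the comparison surface.

Two printed rows are internally inconsistent and are excluded from
``CONSISTENT_ROWS``:

* ``drug_tio`` — the printed TP/FN do not sum to the 364 reference cases;
* ``drug_tio_or_ipra`` — the printed sensitivity (52.2%) disagrees with
  its own counts (198/364 = 54.4%) and its CI (46.9-51.4) is malformed.

Two further single cells sit on a rounding boundary and differ from their
own counts by one rounding step (see ``BOUNDARY_CELLS``): the ex-smoker
LR- lower bound (printed 0.76, recomputes 0.77) and the ipratropium DOR
point (printed 51.1, recomputes 51.0).
"""

from __future__ import annotations

STUDY_N = 5889
STUDY_CASES = 364

#: (tp, fp, fn, tn) per algorithm, as printed.
PUBLISHED_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "cpp_only": (205, 11, 159, 5514),
    "billing_ge1_ever": (188, 120, 176, 5405),
    "billing_ge2_1yr": (100, 15, 264, 5510),
    "smoker_current": (102, 554, 262, 4971),
    "smoker_ex": (118, 994, 246, 4531),
    "drug_tio_or_ipra": (198, 17, 166, 5508),
    "drug_tio": (186, 11, 159, 5524),
    "drug_ipra": (47, 16, 317, 5509),
    "combo_final": (280, 19, 84, 5506),
    "combo_alt": (288, 42, 76, 5483),
    "combo_final_plus_smoking": (325, 1556, 39, 3969),
    "combo_alt_plus_smoking": (329, 1570, 35, 3955),
}

#: metric -> (value, ci_low, ci_high) per algorithm, as printed.
#: Proportions are percents; LR+/DOR rounded to 1 decimal, LR- to 2.
PUBLISHED_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    "cpp_only": {
        "sensitivity": (56.3, 51.1, 61.5),
        "specificity": (99.8, 99.6, 99.9),
        "ppv": (94.9, 91.1, 97.4),
        "npv": (97.2, 96.7, 97.6),
        "lr_pos": (282.9, 155.7, 514.0),
        "lr_neg": (0.44, 0.39, 0.49),
        "dor": (646.3, 345.3, 1209.6),
    },
    "billing_ge1_ever": {
        "sensitivity": (51.6, 46.4, 56.9),
        "specificity": (97.8, 97.4, 98.2),
        "ppv": (61.0, 55.3, 66.5),
        "npv": (96.8, 96.4, 97.3),
        "lr_pos": (23.8, 19.4, 29.1),
        "lr_neg": (0.49, 0.44, 0.55),
        "dor": (48.1, 36.6, 63.3),
    },
    "billing_ge2_1yr": {
        "sensitivity": (27.5, 22.9, 32.4),
        "specificity": (99.7, 99.6, 99.8),
        "ppv": (87.0, 79.4, 92.5),
        "npv": (95.4, 94.9, 96.0),
        "lr_pos": (101.2, 59.4, 172.3),
        "lr_neg": (0.73, 0.68, 0.77),
        "dor": (139.1, 79.8, 242.8),
    },
    "smoker_current": {
        "sensitivity": (28.0, 23.5, 32.9),
        "specificity": (90.0, 89.2, 90.8),
        "ppv": (15.5, 12.9, 18.6),
        "npv": (95.0, 94.4, 95.6),
        "lr_pos": (2.8, 2.3, 3.4),
        "lr_neg": (0.80, 0.75, 0.85),
        "dor": (3.5, 2.7, 4.5),
    },
    "smoker_ex": {
        "sensitivity": (32.4, 27.6, 37.5),
        "specificity": (82.0, 81.0, 83.0),
        "ppv": (10.6, 8.9, 12.6),
        "npv": (94.9, 94.2, 95.5),
        "lr_pos": (1.8, 1.5, 2.1),
        "lr_neg": (0.82, 0.76, 0.89),
        "dor": (2.2, 1.7, 2.8),
    },
    "drug_ipra": {
        "sensitivity": (12.9, 9.6, 16.8),
        "specificity": (99.7, 99.5, 99.8),
        "ppv": (74.6, 62.1, 84.7),
        "npv": (94.6, 93.9, 95.1),
        "lr_pos": (44.6, 25.5, 77.8),
        "lr_neg": (0.87, 0.84, 0.91),
        "dor": (51.1, 28.6, 91.0),
    },
    "combo_final": {
        "sensitivity": (76.9, 72.2, 81.2),
        "specificity": (99.7, 99.5, 99.8),
        "ppv": (93.6, 90.3, 96.1),
        "npv": (98.5, 98.1, 98.8),
        "lr_pos": (223.7, 142.3, 351.6),
        "lr_neg": (0.23, 0.19, 0.28),
        "dor": (966.0, 578.8, 1612.1),
    },
    "combo_alt": {
        "sensitivity": (79.1, 74.6, 83.2),
        "specificity": (99.2, 99.0, 99.5),
        "ppv": (87.3, 83.2, 90.7),
        "npv": (98.6, 98.3, 98.9),
        "lr_pos": (104.1, 76.7, 141.3),
        "lr_neg": (0.21, 0.17, 0.26),
        "dor": (494.7, 333.3, 734.4),
    },
    "combo_final_plus_smoking": {
        "sensitivity": (89.3, 85.6, 92.3),
        "specificity": (71.8, 70.6, 73.0),
        "ppv": (17.3, 15.6, 19.1),
        "npv": (99.0, 98.7, 99.3),
        "lr_pos": (3.2, 3.0, 3.4),
        "lr_neg": (0.15, 0.11, 0.20),
        "dor": (21.3, 15.2, 29.8),
    },
    "combo_alt_plus_smoking": {
        "sensitivity": (90.4, 86.9, 93.2),
        "specificity": (71.6, 70.4, 72.8),
        "ppv": (17.3, 15.6, 19.1),
        "npv": (99.1, 98.8, 99.4),
        "lr_pos": (3.2, 3.0, 3.4),
        "lr_neg": (0.13, 0.10, 0.18),
        "dor": (23.7, 16.6, 33.7),
    },
}

CONSISTENT_ROWS: tuple[str, ...] = tuple(PUBLISHED_METRICS)

#: (algorithm, metric, position) cells whose printed value sits one
#: rounding step away from its own counts; position 0=value, 1=low, 2=high.
BOUNDARY_CELLS: frozenset[tuple[str, str, int]] = frozenset(
    {("smoker_ex", "lr_neg", 1), ("drug_ipra", "dor", 0)}
)

#: Rounding convention of the printed table.
METRIC_DECIMALS: dict[str, int] = {
    "sensitivity": 1,
    "specificity": 1,
    "ppv": 1,
    "npv": 1,
    "lr_pos": 1,
    "lr_neg": 2,
    "dor": 1,
}
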