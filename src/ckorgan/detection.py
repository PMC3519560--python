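"""Spots-above-background (AbB) counting and the three detection rules.

A gene's AbB over a set of arrays is the detection statistic of spotted
arrays: the number of arrays on which its spot exceeded background.  Three
rules derive from it:

* fewer than ``abb_not_expressed`` (default 4) detections over all arrays
  -> "not expressed", excluded from all analyses;
* at least ``abb_model_min`` (default 10) detections over all arrays
  -> eligible for model fitting (weakly detected genes produce a very high
  false-positive rate);
* detected on at least ``abb_subset_fraction`` (default 25%) of an analysis
  subset's arrays -> eligible within that subset (8 of the 32 induction
  arrays; 4 of the 16 deficiency arrays).  BA0 arrays count in both subsets.
"""
from __future__ import annotations

import math

import pandas as pd

from .datamodel import ExpressionMatrix, Thresholds
from .design import StudyDesign


def count_above_background(matrix: ExpressionMatrix,
                           subset_ids: list[str]) -> pd.Series:
    """Per-gene count of above-background cells within an array subset."""
    if len(subset_ids) == 0:
        raise ValueError("empty array subset")
    missing = set(subset_ids) - set(matrix.above_background.columns)
    if missing:
        raise ValueError(f"subset names unknown arrays: {sorted(missing)}")
    return matrix.above_background.loc[:, subset_ids].sum(axis=1).rename("abb")


def apply_detection_filters(matrix: ExpressionMatrix, design: StudyDesign,
                            thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Compute AbB per subset and the four eligibility flags.

    Returns a DataFrame indexed by gene with integer columns ``abb_total``,
    ``abb_induction``, ``abb_deficiency`` and 0/1 flag columns
    ``not_expressed``, ``model_eligible``, ``induction_eligible``,
    ``deficiency_eligible``.  Each flag is monotone in its count.
    """
    th = thresholds or Thresholds()
    induction_ids = design.subset_ids("induction")
    deficiency_ids = design.subset_ids("deficiency")
    report = pd.DataFrame({
        "abb_total": count_above_background(matrix, design.array_ids),
        "abb_induction": count_above_background(matrix, induction_ids),
        "abb_deficiency": count_above_background(matrix, deficiency_ids),
    })
    ind_min = math.ceil(th.abb_subset_fraction * len(induction_ids))
    def_min = math.ceil(th.abb_subset_fraction * len(deficiency_ids))
    report["not_expressed"] = (report["abb_total"] < th.abb_not_expressed).astype(int)
    report["model_eligible"] = (report["abb_total"] >= th.abb_model_min).astype(int)
    report["induction_eligible"] = (report["abb_induction"] >= ind_min).astype(int)
    report["deficiency_eligible"] = (report["abb_deficiency"] >= def_min).astype(int)
    return report


def write_detection_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index_label="probe_id")
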