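"""Condition means, fold-change ratios, and organ-specificity categories.

A gene's expression is summarised per (organ, condition) cell as the
arithmetic mean of its above-background log2 values.  Linear-scale ratios
vs the mock control (BA0) are the quantities the result tables print:
``r(organ, t) = 2^(mean(organ, t) - mean(organ, BA0))``, plus the baseline
organ contrast ``r_base = 2^(mean(root, BA0) - mean(shoot, BA0))``.

The categorization decision list (evaluated over the treatment time points
for the induction analysis, or the single CKX1 contrast for the deficiency
analysis) assigns exactly one category per eligible gene:

1. the gene is *significant* iff the condition-effect q or the
   interaction q is <= alpha (missing q counts as 1, i.e. conservative);
2. per organ, a time point counts *up* if ratio >= T and *down* if
   ratio <= 1/T (inclusive, T = 2.5 by default);
3. not significant, or neither organ regulated  -> ``not_regulated``;
4. exactly one organ regulated -> that organ's specific category — unless
   the optional gray zone is enabled and the quiet organ strays outside
   [1/G, G], which demotes to ``uncategorized``;
5. both organs regulated: mixed direction within an organ ->
   ``uncategorized``; same direction -> ``similar``; opposite ->
   ``differential``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, Thresholds
from .design import CONDITIONS, ORGANS, StudyDesign

CATEGORIES = ("root_specific", "shoot_specific", "differential", "similar",
              "uncategorized", "not_regulated", "not_expressed")

INDUCTION_TIMEPOINTS = ("BA15", "BA120", "BA1080")


def condition_means(matrix: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Per-gene mean log2 per (organ, condition) over above-background
    arrays; a cell with no detected array yields NaN (propagated)."""
    masked = matrix.masked_values()
    cells = {}
    for (organ, cond), grp in design.table.groupby(["organ", "condition"]):
        cells[(organ, cond)] = masked.loc[:, grp["array_id"]].mean(axis=1)
    means = pd.concat(cells, axis=1)
    means.columns = pd.MultiIndex.from_tuples(means.columns,
                                              names=["organ", "condition"])
    order = [(o, c) for o in ORGANS for c in CONDITIONS if (o, c) in cells]
    return means.loc[:, order]


@dataclass
class RatioTable:
    """Linear-scale fold changes vs BA0 per organ plus the baseline organ
    contrast.  ``ratios`` columns are named ``r_{organ}_{condition}``."""

    ratios: pd.DataFrame
    r_base: pd.Series

    def ratio(self, organ: str, condition: str) -> pd.Series:
        return self.ratios[f"r_{organ}_{condition}"]

    @property
    def genes(self) -> pd.Index:
        return self.ratios.index

    @classmethod
    def from_means(cls, means: pd.DataFrame) -> "RatioTable":
        """Ratios from a condition-mean table (missing mean -> missing
        ratio; a missing BA0 mean voids the organ's ratios)."""
        cols = {}
        for organ in ORGANS:
            base = means[(organ, "BA0")]
            for cond in CONDITIONS:
                if cond == "BA0" or (organ, cond) not in means.columns:
                    continue
                cols[f"r_{organ}_{cond}"] = 2.0 ** (means[(organ, cond)] - base)
        r_base = 2.0 ** (means[("root", "BA0")] - means[("shoot", "BA0")])
        return cls(pd.DataFrame(cols), r_base.rename("r_base"))

    @classmethod
    def from_printed(cls, ratios: pd.DataFrame,
                     r_base: pd.Series | None = None) -> "RatioTable":
        """Wrap printed-table ratio columns verbatim (``r_root_BA15`` ...)."""
        if r_base is None:
            r_base = pd.Series(np.nan, index=ratios.index, name="r_base")
        return cls(ratios.copy(), r_base)


def fold_change_ratios(means: pd.DataFrame) -> RatioTable:
    return RatioTable.from_means(means)


def _organ_direction(ratios_row: pd.Series, organ: str,
                     timepoints: tuple, T: float) -> tuple[str, list[str]]:
    """('up'|'down'|'mixed'|'none', crossing timepoints) for one organ.

    Missing ratios are ignored; if every ratio is missing the organ is
    treated as unregulated.
    """
    up, down = [], []
    for t in timepoints:
        r = ratios_row.get(f"r_{organ}_{t}", np.nan)
        if pd.isna(r):
            continue
        if r >= T:
            up.append(t)
        elif r <= 1.0 / T:
            down.append(t)
    if up and down:
        return "mixed", up + down
    if up:
        return "up", up
    if down:
        return "down", down
    return "none", []


def _classify_row(ratios_row: pd.Series, sig: bool, timepoints: tuple,
                  th: Thresholds) -> tuple[str, str]:
    """Category + evidence string for one eligible gene."""
    T = th.fold_change_T
    dirs, evid = {}, {}
    for organ in ORGANS:
        dirs[organ], evid[organ] = _organ_direction(ratios_row, organ,
                                                    timepoints, T)
    regulated = [o for o in ORGANS if dirs[o] != "none"]
    evidence = ";".join(f"{o}:{dirs[o]}@{','.join(evid[o])}" for o in regulated)
    if not sig or not regulated:
        return "not_regulated", evidence
    if len(regulated) == 1:
        organ = regulated[0]
        if dirs[organ] == "mixed":
            return "uncategorized", evidence
        if th.gray_zone_G is not None:
            other = "shoot" if organ == "root" else "root"
            G = th.gray_zone_G
            for t in timepoints:
                r = ratios_row.get(f"r_{other}_{t}", np.nan)
                if pd.notna(r) and not (1.0 / G <= r <= G):
                    return "uncategorized", evidence + f";{other}:gray@{t}"
        return f"{organ}_specific", evidence
    if "mixed" in dirs.values():
        return "uncategorized", evidence
    if dirs["root"] == dirs["shoot"]:
        return "similar", evidence
    return "differential", evidence


def _classify(ratios: RatioTable, stats: pd.DataFrame, eligible: pd.Series,
              timepoints: tuple, th: Thresholds) -> pd.DataFrame:
    q_cond = stats.get("q_condition")
    q_int = stats.get("q_interaction")
    rows = {}
    for gene in ratios.genes:
        if not eligible.get(gene, False):
            rows[gene] = ("not_expressed", "")
            continue
        qs = []
        for q in (q_cond, q_int):
            if q is not None and gene in q.index and pd.notna(q.get(gene)):
                qs.append(q[gene])
        sig = any(q <= th.alpha_q for q in qs)
        rows[gene] = _classify_row(ratios.ratios.loc[gene], sig, timepoints, th)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["category", "evidence"])
    out.index.name = "probe_id"
    return out


def classify_induction(ratios: RatioTable, stats: pd.DataFrame,
                       detection: pd.DataFrame,
                       th: Thresholds | None = None) -> pd.DataFrame:
    """Categorize each gene for the cytokinin-induction analysis (three
    treatment time points).  Genes not induction-eligible are labelled
    ``not_expressed``."""
    th = th or Thresholds()
    eligible = detection["induction_eligible"].astype(bool)
    return _classify(ratios, stats, eligible, INDUCTION_TIMEPOINTS, th)


def classify_deficiency(ratios: RatioTable, stats: pd.DataFrame,
                        detection: pd.DataFrame,
                        th: Thresholds | None = None) -> pd.DataFrame:
    """Categorize for the cytokinin-deficiency analysis (the single CKX1
    vs BA0 contrast; the condition factor is the genotype effect)."""
    th = th or Thresholds()
    eligible = detection["deficiency_eligible"].astype(bool)
    return _classify(ratios, stats, eligible, ("CKX1",), th)
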