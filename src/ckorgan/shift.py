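"""Developmental-shift gene sets and their overlap partition.

A gene indicates a "developmental shift" when its expression in one organ
moves toward the level the gene normally holds in the *other* organ:
in roots after 18 h of cytokinin treatment (mode ``root_under_BA1080``),
or in shoots of constitutively cytokinin-deficient plants (mode
``shoot_under_CKX1``).  Membership requires all three criteria:

(i)   baseline organ differential: ``r_base >= T`` (root-higher) or
      ``<= 1/T`` (shoot-higher), T = 2.5 by default;
(ii)  a >= T-fold treatment change in the direction of the other organ's
      level (e.g. a shoot-higher gene must rise in treated roots);
(iii) at least one of the full-model organ / cytokinin / interaction
      q-values <= alpha (0.03 by default).

The overlap of the two modes partitions into genes enhanced in treated
roots *and* repressed in deficient shoots, and the converse pair — the
particularly cytokinin-sensitive core.  Instead of a live GO enrichment,
the "shootyness" diagnostic is the fraction of a set carrying a given
subcellular localization code (uppercase ``P`` = plastid).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categorize import RatioTable
from .datamodel import GeneAnnotation, Thresholds

log = logging.getLogger(__name__)

MODES = ("root_under_BA1080", "shoot_under_CKX1")


@dataclass
class ShiftGeneSet:
    """Members of one shift mode with their baseline side and direction."""

    mode: str
    table: pd.DataFrame  # index gene; columns baseline_side, direction, q_min

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def find_shift_genes(ratios: RatioTable, stats: pd.DataFrame,
                     th: Thresholds | None = None,
                     mode: str = "root_under_BA1080",
                     direction_consistent: bool = True) -> ShiftGeneSet:
    """Apply the three shift criteria to every gene with the needed ratios.

    ``stats`` must provide the full-model q columns (``q_organ``,
    ``q_condition``, ``q_interaction``).  With
    ``direction_consistent=False`` criterion (ii) only requires a >= T-fold
    change in either direction (sensitivity-analysis variant).
    """
    th = th or Thresholds()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    T = th.fold_change_T
    organ, cond = (("root", "BA1080") if mode == "root_under_BA1080"
                   else ("shoot", "CKX1"))
    rows = {}
    for gene in ratios.genes:
        r_base = ratios.r_base.get(gene, np.nan)
        r_treat = ratios.ratios.at[gene, f"r_{organ}_{cond}"] \
            if f"r_{organ}_{cond}" in ratios.ratios.columns else np.nan
        if pd.isna(r_base) or pd.isna(r_treat):
            log.debug("shift %s: gene %s excluded (missing ratio)", mode, gene)
            continue
        # (i) baseline differential
        if r_base >= T:
            side = "root_higher"
        elif r_base <= 1.0 / T:
            side = "shoot_higher"
        else:
            continue
        # (ii) change toward the other organ's level
        toward_other = "down" if side == f"{organ}_higher" else "up"
        if r_treat >= T:
            direction = "up"
        elif r_treat <= 1.0 / T:
            direction = "down"
        else:
            continue
        if direction_consistent and direction != toward_other:
            continue
        # (iii) at least one significant effect
        qs = [stats.at[gene, c] for c in ("q_organ", "q_condition",
                                          "q_interaction")
              if c in stats.columns and gene in stats.index]
        qs = [q for q in qs if pd.notna(q)]
        if not qs or min(qs) > th.alpha_q:
            continue
        rows[gene] = {"baseline_side": side, "direction": direction,
                      "q_min": min(qs)}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["baseline_side", "direction",
                                            "q_min"])
    table.index.name = "probe_id"
    return ShiftGeneSet(mode=mode, table=table)


def shift_overlap(set_root: ShiftGeneSet,
                  set_shoot: ShiftGeneSet) -> dict[str, pd.Index]:
    """Split the intersection of the two modes by direction pair.

    Returns ``root_up_and_shoot_down`` (enhanced in treated roots,
    repressed in deficient shoots), ``root_down_and_shoot_up``, and
    ``total`` (their disjoint union).
    """
    if set_root.mode != "root_under_BA1080" or set_shoot.mode != "shoot_under_CKX1":
        raise ValueError("shift_overlap expects (root_under_BA1080, "
                         "shoot_under_CKX1) sets in that order")
    common = set_root.genes.intersection(set_shoot.genes)
    root_dir = set_root.table.loc[common, "direction"]
    shoot_dir = set_shoot.table.loc[common, "direction"]
    up_down = common[(root_dir == "up") & (shoot_dir == "down")]
    down_up = common[(root_dir == "down") & (shoot_dir == "up")]
    return {"root_up_and_shoot_down": up_down,
            "root_down_and_shoot_up": down_up,
            "total": up_down.append(down_up)}


def localization_fraction(genes, annotation: GeneAnnotation,
                          code: str = "P") -> tuple[int, float | None]:
    """(count, fraction) of genes whose localization codes contain
    ``code`` (case-sensitive).  An empty gene set yields fraction None."""
    genes = list(genes)
    count = sum(1 for g in genes if code in annotation.localization_codes(g))
    if not genes:
        return 0, None
    return count, count / len(genes)


def write_shift_table(gene_set: ShiftGeneSet, ratios: RatioTable,
                      stats: pd.DataFrame, abb: pd.Series,
                      annotation: GeneAnnotation | None, path) -> None:
    """Shift-set TSV mirroring the printed layout: AbB, the contrast
    ratios, the three q-values, then annotation."""
    order = gene_set.genes
    out = pd.DataFrame(index=order)
    out["AbB"] = abb.reindex(order)
    for col in ("r_root_BA1080", "r_shoot_CKX1"):
        if col in ratios.ratios.columns:
            out[col] = ratios.ratios.loc[order, col]
    out["r_base"] = ratios.r_base.reindex(order)
    for col in ("q_condition", "q_organ", "q_interaction"):
        if col in stats.columns:
            out[col] = stats.reindex(order)[col]
    out = out.join(gene_set.table)
    if annotation is not None:
        out = out.join(annotation.table.reindex(order))
    out.to_csv(path, sep="\t", index_label="probe_id")
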