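"""Per-gene two-factor fixed-effects ANOVA with type-II F-tests and FDR.

For every gene the cell-means model ``value ~ organ + condition +
organ:condition`` is fitted by ordinary least squares on the gene's
non-missing (above-background) observations within an analysis subset.
Type-II sums of squares are computed from nested model comparisons, so
main-effect tests are order-independent also on unbalanced data (cells lose
observations to the detection mask):

* SS(organ | condition)      = RSS(condition-only) - RSS(additive)
* SS(condition | organ)      = RSS(organ-only)     - RSS(additive)
* SS(interaction)            = RSS(additive)       - RSS(cell-means)

Degrees of freedom come from design-matrix ranks; on balanced data these
tests coincide with the classical (type-I/III) two-way ANOVA.  Technical
replicates enter as independent observations.  The condition factor is
reported as the "cytokinin" effect on the induction and full subsets and
as the "genotype" effect on the deficiency subset; the statistics columns
use the neutral name ``condition``.

p-values are corrected for multiple testing across genes per effect with
the Benjamini-Hochberg step-up procedure ("q-values").
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix
from .design import StudyDesign

log = logging.getLogger(__name__)

EFFECTS = ("organ", "condition", "interaction")

#: columns of an effect-statistics table
STAT_COLUMNS = tuple(
    f"{k}_{e}" for e in EFFECTS for k in ("F", "p", "q")
) + ("residual_df", "n_obs", "saturated")

_RESIDUAL_TOL = 1e-10


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of the OLS fit and the rank of X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _design_matrices(organ: np.ndarray, cond: np.ndarray):
    """Dummy design matrices for the four nested models."""
    n = len(organ)
    organs = np.unique(organ)
    conds = np.unique(cond)
    intercept = np.ones((n, 1))
    o_dum = np.column_stack([(organ == o).astype(float) for o in organs[1:]]) \
        if len(organs) > 1 else np.empty((n, 0))
    c_dum = np.column_stack([(cond == c).astype(float) for c in conds[1:]]) \
        if len(conds) > 1 else np.empty((n, 0))
    cells = pd.unique(pd.Series(zip(organ, cond)))
    cell_dum = np.column_stack([
        np.fromiter(((o, c) == cell for o, c in zip(organ, cond)), float, n)
        for cell in cells])
    X_organ = np.hstack([intercept, o_dum])
    X_cond = np.hstack([intercept, c_dum])
    X_add = np.hstack([intercept, o_dum, c_dum])
    return X_organ, X_cond, X_add, cell_dum


def fit_gene_model(values: pd.Series, design_table: pd.DataFrame) -> dict:
    """Fit one gene on one subset; returns the effect-statistics record.

    Parameters
    ----------
    values:
        per-array log2 values indexed by array_id; NaN marks a
        below-background (missing) observation.
    design_table:
        design rows of the subset (columns organ, condition, array_id).

    Raises ``ValueError`` if an (organ, condition) cell of the subset has
    no observation left, or if the observations cannot identify the model.
    """
    obs = values.reindex(design_table["array_id"])
    keep = obs.notna().to_numpy()
    y = obs.to_numpy()[keep]
    organ = design_table["organ"].to_numpy()[keep]
    cond = design_table["condition"].to_numpy()[keep]

    expected_cells = set(zip(design_table["organ"], design_table["condition"]))
    got_cells = set(zip(organ, cond))
    if got_cells != expected_cells:
        empty = sorted(expected_cells - got_cells)
        raise ValueError(f"empty cell(s) after missingness: {empty}")

    X_organ, X_cond, X_add, X_full = _design_matrices(organ, cond)
    rss_o, rank_o = _rss(X_organ, y)
    rss_c, rank_c = _rss(X_cond, y)
    rss_a, rank_a = _rss(X_add, y)
    rss_f, rank_f = _rss(X_full, y)
    n = len(y)
    df_resid = n - rank_f

    rec = {"n_obs": n, "residual_df": df_resid, "saturated": False}
    ss = {
        "organ": (max(rss_c - rss_a, 0.0), rank_a - rank_c),
        "condition": (max(rss_o - rss_a, 0.0), rank_a - rank_o),
        "interaction": (max(rss_a - rss_f, 0.0), rank_f - rank_a),
    }
    if df_resid >= 1:
        mse = rss_f / df_resid
        for eff, (s, df) in ss.items():
            if df < 1:
                rec[f"F_{eff}"], rec[f"p_{eff}"] = np.nan, np.nan
                continue
            if mse == 0.0:
                f = 0.0 if s <= _RESIDUAL_TOL else np.inf
            else:
                f = (s / df) / mse
            rec[f"F_{eff}"] = f
            rec[f"p_{eff}"] = float(sps.f.sf(f, df, df_resid))
    else:
        # zero residual degrees of freedom: interpolating fit
        all_equal = all(s <= _RESIDUAL_TOL for s, _ in ss.values())
        for eff in EFFECTS:
            rec[f"F_{eff}"] = 0.0 if all_equal else np.nan
            rec[f"p_{eff}"] = 1.0 if all_equal else 0.0
        rec["saturated"] = not all_equal
    return rec


def fit_all_genes(matrix: ExpressionMatrix, design: StudyDesign,
                  subset: str = "full",
                  genes: list[str] | None = None,
                  fdr: str = "bh") -> pd.DataFrame:
    """Fit every (eligible) gene on an analysis subset and FDR-adjust.

    Genes whose fit fails a precondition (an empty cell after missingness)
    are skipped with a logged reason and absent from the result.
    """
    design_table = design.subset_table(subset)
    design.validate_replication(minimum=2)
    masked = matrix.masked_values()
    if genes is None:
        genes = matrix.gene_ids
    records = {}
    for gene in genes:
        try:
            records[gene] = fit_gene_model(masked.loc[gene], design_table)
        except ValueError as exc:
            log.warning("skipping gene %s on subset %s: %s", gene, subset, exc)
    stats = pd.DataFrame.from_dict(records, orient="index")
    if stats.empty:
        return stats
    for eff in EFFECTS:
        p = stats[f"p_{eff}"].to_numpy()
        q = np.full_like(p, np.nan, dtype=float)
        finite = np.isfinite(p)
        q[finite] = fdr_adjust(p[finite], method=fdr)
        stats[f"q_{eff}"] = q
    order = [c for c in STAT_COLUMNS if c in stats.columns]
    stats = stats.loc[:, order]
    stats.index.name = "probe_id"
    return stats


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving with input).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    if method != "bh":
        raise ValueError(f"unsupported FDR method {method!r}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def write_stats_table(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index_label="probe_id")
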