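"""TSV readers/writers for expression, annotation and result tables.

All files are tab-delimited UTF-8 with a header row.  Below-background
expression cells are written as the sentinel ``NA`` (single-token,
spreadsheet-safe) and read back as masked-out cells.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneAnnotation
from .design import StudyDesign

SENTINEL = "NA"

#: results-table section letters in output order, mapped to category labels
SECTIONS = {
    "a": "root_specific",
    "b": "shoot_specific",
    "c": "differential",
    "d": "similar",
    "e": "uncategorized",
    "f": "not_regulated",
}


def read_expression_table(path, design: StudyDesign) -> ExpressionMatrix:
    """Read a genes x arrays log2 TSV whose header names the arrays.

    Each cell is either a finite number or the sentinel ``NA`` meaning
    below background.  Columns are reordered to design order; unknown or
    missing arrays, duplicate gene rows, and non-numeric non-sentinel
    cells are fatal.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    unknown = set(raw.columns) - set(design.array_ids)
    if unknown:
        raise ValueError(f"unknown array_id(s) in {path}: {sorted(unknown)}")
    missing = set(design.array_ids) - set(raw.columns)
    if missing:
        raise ValueError(f"arrays missing from {path}: {sorted(missing)}")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    raw = raw.loc[:, design.array_ids]
    mask = raw != SENTINEL
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for j, col in enumerate(raw.columns):
        cells = raw[col]
        sub = cells[mask[col]]
        try:
            values.loc[sub.index, col] = sub.astype(float)
        except ValueError:
            for gene, cell in sub.items():
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, "
                        f"array {col!r} in {path}") from None
    bad = values.to_numpy()[mask.to_numpy()]
    if not np.all(np.isfinite(bad)):
        i, j = np.argwhere(~np.isfinite(values.to_numpy()) & mask.to_numpy())[0]
        raise ValueError(f"non-finite cell at gene {values.index[i]!r}, "
                         f"array {values.columns[j]!r} in {path}")
    return ExpressionMatrix(values, mask)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix with ``NA`` at below-background cells (round-trips
    through :func:`read_expression_table` exactly)."""
    out = matrix.values.astype(object).where(matrix.above_background, SENTINEL)
    out = out.map(lambda v: v if isinstance(v, str) else repr(float(v)))
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# results tables (sections a-f)
# ---------------------------------------------------------------------------

def _section_sort_key(section: str, ratios: pd.DataFrame) -> pd.Series:
    """Per-section sort statistic over a gene's linear-scale ratio columns.

    a: sum of root ratios; b: sum of shoot ratios; c/e: sum of |log2 ratio|
    over both organs; d: sum of all ratios; f: probe_id (handled upstream).
    Sections a-e sort descending, ties broken by probe_id ascending.
    """
    root_cols = [c for c in ratios.columns if c.startswith("r_root")]
    shoot_cols = [c for c in ratios.columns if c.startswith("r_shoot")]
    if section == "a":
        return ratios[root_cols].sum(axis=1)
    if section == "b":
        return ratios[shoot_cols].sum(axis=1)
    if section in ("c", "e"):
        with np.errstate(divide="ignore"):
            return np.abs(np.log2(ratios[root_cols + shoot_cols])).sum(axis=1)
    if section == "d":
        return ratios[root_cols + shoot_cols].sum(axis=1)
    raise ValueError(section)


def write_results_tables(calls: pd.Series, ratios: pd.DataFrame,
                         stats: pd.DataFrame, abb: pd.Series,
                         annotation: GeneAnnotation | None,
                         out_dir, prefix: str = "results") -> dict[str, Path]:
    """Write one TSV per category section a-f.

    Parameters
    ----------
    calls:
        per-gene category label (index: probe_id); must cover the same
        genes as ``ratios``.
    ratios:
        per-gene linear ratio columns (``r_root_*`` / ``r_shoot_*``).
    stats:
        per-gene q-value columns to append.
    abb:
        per-gene spots-above-background count.
    annotation:
        optional probe annotation (AGI + description columns appended).

    Returns a mapping of section letter to file path.  The union of the
    section files is exactly the input gene set.
    """
    missing = calls.index.difference(ratios.index)
    if len(missing):
        raise ValueError(f"gene(s) in calls but absent from ratios: "
                         f"{missing.tolist()[:5]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for letter, category in SECTIONS.items():
        genes = calls.index[calls == category]
        block = ratios.loc[genes].copy()
        if letter == "f" or block.empty:
            order = sorted(genes)
        else:
            # stable sort over an id-ascending frame: ties break by probe_id
            key = _section_sort_key(letter, block).loc[sorted(genes)]
            order = key.sort_values(ascending=False, kind="mergesort").index
        table = pd.DataFrame(index=pd.Index(order, name="probe_id"))
        table["AbB"] = abb.reindex(order)
        table = table.join(ratios.reindex(order))
        table = table.join(stats.reindex(order))
        if annotation is not None:
            table = table.join(annotation.table.reindex(order))
        path = out_dir / f"{prefix}_section_{letter}_{category}.tsv"
        table.to_csv(path, sep="\t")
        paths[letter] = path
    return paths


# ---------------------------------------------------------------------------
# packaged fixtures (the printed example tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("ckorgan").joinpath("data", name)

def load_induction_examples() -> pd.DataFrame:
    """Printed induction examples (organ-specificity categories vs the
    three BA time points), indexed by probe_id."""
    with importlib.resources.as_file(_data_path("printed_induction_examples.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="probe_id")

def load_deficiency_examples() -> pd.DataFrame:
    """Printed deficiency examples (CKX1 vs BA0 per organ)."""
    with importlib.resources.as_file(_data_path("printed_deficiency_examples.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="probe_id")

def load_shift_examples() -> pd.DataFrame:
    """Printed developmental-shift gene table (63 genes with the three
    contrast ratios, three full-model q-values and localization codes)."""
    with importlib.resources.as_file(_data_path("printed_shift_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="probe_id",
                         keep_default_na=False)
    numeric = ["abb", "r_root_BA1080", "r_shoot_CKX1", "r_base",
               "q_cytokinin", "q_organ", "q_interaction"]
    df[numeric] = df[numeric].apply(pd.to_numeric)
    return df
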