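"""Core containers: expression matrix with detection mask, gene annotation,
and the analysis thresholds."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign


@dataclass
class ExpressionMatrix:
    """Genes x arrays log2 intensities with a parallel above-background mask.

    ``values`` holds common-reference single-channel log2 estimates; cells
    whose spot did not exceed the array background are non-quantitative and
    carry ``above_background == False`` (their value is NaN).  Column order
    always matches the associated :class:`~ckorgan.design.StudyDesign`.
    """

    values: pd.DataFrame
    above_background: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.above_background.index) or \
           not self.values.columns.equals(self.above_background.columns):
            raise ValueError("values and above_background must share index/columns")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene row {dup!r}")
        masked = self.values.to_numpy()[self.above_background.to_numpy()]
        if not np.all(np.isfinite(masked)):
            raise ValueError("non-finite value in an above-background cell")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def align_to(self, design: StudyDesign) -> "ExpressionMatrix":
        """Reorder columns to design order (all design arrays required)."""
        ids = design.array_ids
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise ValueError(f"matrix lacks arrays: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[:, ids],
                                self.above_background.loc[:, ids])

    def masked_values(self) -> pd.DataFrame:
        """Values with below-background cells set to NaN (missing)."""
        return self.values.where(self.above_background)


@dataclass
class GeneAnnotation:
    """Probe-level annotation: AGI locus, free-text description and the
    single-character subcellular localization codes (uppercase ``P`` marks
    a plastid-targeted protein; ``—`` or empty means unannotated)."""

    table: pd.DataFrame  # index: probe_id; columns: agi, description, localization

    COLUMNS = ("agi", "description", "localization")

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValueError("duplicate probe_id in annotation")

    def localization_codes(self, probe_id: str) -> frozenset[str]:
        raw = self.table.at[probe_id, "localization"]
        if pd.isna(raw) or raw in ("", "—", "-"):
            return frozenset()
        return frozenset(c.strip() for c in str(raw).split(",") if c.strip())

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", index_col="probe_id",
                         keep_default_na=False, na_values=[])
        return cls(df.loc[:, list(cls.COLUMNS)])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="probe_id")


@dataclass(frozen=True)
class Thresholds:
    """Gates applied throughout the analysis.

    fold_change_T:
        linear fold-change cutoff for calling a gene regulated (applied
        inclusively as >= T or <= 1/T), default 2.5.
    alpha_q:
        FDR-corrected p-value cutoff for significance, default 0.03.
    pca_q:
        stricter q cutoff selecting genes for ordination, default 1e-4.
    abb_not_expressed:
        genes above background on fewer arrays than this (over all arrays)
        are called "not expressed", default 4.
    abb_model_min:
        minimum spots above background (all arrays) for model fitting,
        default 10.
    abb_subset_fraction:
        fraction of a subset's arrays on which a gene must be detected to
        be analysed within that subset, default 0.25 (8 of 32 induction
        arrays, 4 of 16 deficiency arrays).
    gray_zone_G:
        optional "quiet organ" band: with a single regulated organ, any
        ratio of the other organ outside [1/G, G] demotes the call to
        uncategorized.  Disabled (None) by default.
    """

    fold_change_T: float = 2.5
    alpha_q: float = 0.03
    pca_q: float = 1e-4
    abb_not_expressed: int = 4
    abb_model_min: int = 10
    abb_subset_fraction: float = 0.25
    gray_zone_G: float | None = None

    def __post_init__(self):
        if self.fold_change_T <= 1:
            raise ValueError("fold_change_T must be > 1")
        if not 0 <= self.alpha_q <= 1:
            raise ValueError("alpha_q must lie in [0, 1]")
        if self.gray_zone_G is not None and not (1 < self.gray_zone_G <= self.fold_change_T):
            raise ValueError("gray_zone_G must satisfy 1 < G <= fold_change_T")
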