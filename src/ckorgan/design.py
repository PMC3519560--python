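"""Study design: which array measured which organ under which condition.

The experiment crosses two organs (root, shoot) with five cytokinin
conditions: a mock control (BA0), three benzyladenine treatment durations
(BA15 = 15 min, BA120 = 2 h, BA1080 = 18 h) and a constitutively
cytokinin-deficient genotype (CKX1, a *35S:CKX1* cytokinin oxidase
overexpressor).  Each (organ, condition) cell is measured on
``n_bio`` biological samples hybridised onto ``n_tech`` arrays each.

Two analysis subsets are used throughout: the *induction* subset
(BA0 + the three treatments) and the *deficiency* subset (BA0 + CKX1).
They share the BA0 control arrays.
"""
from __future__ import annotations

import pandas as pd

ORGANS = ("root", "shoot")
CONDITIONS = ("BA0", "BA15", "BA120", "BA1080", "CKX1")
INDUCTION_CONDITIONS = ("BA0", "BA15", "BA120", "BA1080")
DEFICIENCY_CONDITIONS = ("BA0", "CKX1")

#: maps an analysis subset name to the conditions it contains
SUBSETS = {
    "induction": INDUCTION_CONDITIONS,
    "deficiency": DEFICIENCY_CONDITIONS,
    "full": CONDITIONS,
}


class StudyDesign:
    """Per-array organ/condition/replicate labels.

    Parameters
    ----------
    table:
        DataFrame with columns ``array_id``, ``organ``, ``condition``,
        ``biological_replicate``, ``technical_replicate``.
    """

    COLUMNS = ("array_id", "organ", "condition",
               "biological_replicate", "technical_replicate")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if table["array_id"].duplicated().any():
            dup = table.loc[table["array_id"].duplicated(), "array_id"].iloc[0]
            raise ValueError(f"duplicate array_id {dup!r} in design")
        bad_organ = set(table["organ"]) - set(ORGANS)
        if bad_organ:
            raise ValueError(f"unknown organ labels: {sorted(bad_organ)}")
        bad_cond = set(table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
        self.table = table

    def validate_replication(self, minimum: int = 2) -> None:
        """Check every (organ, condition) cell has >= ``minimum`` arrays.

        Model fitting needs residual degrees of freedom, hence >= 2 arrays
        per cell; single-replicate designs are allowed for bookkeeping
        (e.g. counting) but rejected here.
        """
        cell_sizes = self.table.groupby(["organ", "condition"]).size()
        if (cell_sizes < minimum).any():
            small = cell_sizes[cell_sizes < minimum].index.tolist()
            raise ValueError(
                f"each (organ, condition) cell needs >= {minimum} arrays; "
                f"too small: {small}")

    # -- basic accessors ----------------------------------------------------
    @property
    def array_ids(self) -> list[str]:
        return self.table["array_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset_ids(self, subset: str) -> list[str]:
        """Array ids belonging to an analysis subset ('induction',
        'deficiency' or 'full').  BA0 arrays belong to all subsets."""
        try:
            conds = SUBSETS[subset]
        except KeyError:
            raise ValueError(f"unknown subset {subset!r}; "
                             f"expected one of {sorted(SUBSETS)}") from None
        mask = self.table["condition"].isin(conds)
        return self.table.loc[mask, "array_id"].tolist()

    def subset_table(self, subset: str) -> pd.DataFrame:
        ids = set(self.subset_ids(subset))
        return self.table[self.table["array_id"].isin(ids)]

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"array_id": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def generate_design(n_bio: int = 2, n_tech: int = 2) -> StudyDesign:
    """Build the standard crossed design: 2 organs x 5 conditions x
    ``n_bio`` biological x ``n_tech`` technical replicates (default 40
    arrays, four per organ-condition cell)."""
    if n_bio < 1 or n_tech < 1:
        raise ValueError("n_bio and n_tech must be >= 1")
    rows = []
    for organ in ORGANS:
        for cond in CONDITIONS:
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    rows.append({
                        "array_id": f"{organ}_{cond}_b{b}t{t}",
                        "organ": organ,
                        "condition": cond,
                        "biological_replicate": b,
                        "technical_replicate": t,
                    })
    return StudyDesign(pd.DataFrame(rows))
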