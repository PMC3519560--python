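"""Synthetic CATMA-like datasets with planted per-gene ground truth.

The generator emulates the study design this pipeline targets — 2 organs x
5 conditions x 2 biological x 2 technical replicates (40 arrays, four per
organ-condition cell) — and plants genes of known regulatory classes so
every downstream stage can be validated against truth:

``root_specific`` / ``shoot_specific``
    a +-``effect_log2`` offset at the two later treatment time points
    (BA120, BA1080) in one organ only.
``similar`` / ``differential``
    the same offset in both organs, with equal respectively opposite signs.
``shift_up_root``
    shoot-higher baseline (+``baseline_organ_log2`` in the shoot); the
    root's BA1080 level rises by ``effect_log2`` toward the shoot level.
``shift_down_root``
    root-higher baseline; the root's BA1080 level falls toward the shoot.
``shift_root_like_shoot``
    shoot-higher baseline; the shoot's CKX1 level falls by ``effect_log2``
    toward the root level (the cytokinin-deficiency shift).
``not_regulated``
    no offsets beyond baseline (the null class).
``not_expressed``
    detected with probability ``detect_prob_unexpressed`` everywhere.

Each observation is ``mu_g + organ_offset + condition_offset(organ) +
biorep_effect + tech_noise`` where the biological-replicate effect
~ N(0, sigma_bio^2) is shared by the technical replicates of one sample
and the technical noise ~ N(0, sigma_tech^2) is independent per array.
The biological-replicate effect is deliberately NOT a term of the fitted
two-factor model: it is a realistic correlation stressor the analysis has
to tolerate.  Detection is an independent Bernoulli draw per cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneAnnotation
from .design import CONDITIONS, ORGANS, StudyDesign, generate_design

CLASSES = (
    "root_specific", "shoot_specific", "similar", "differential",
    "shift_up_root", "shift_down_root", "shift_root_like_shoot",
    "not_regulated", "not_expressed",
)

#: treatment time points carrying the planted induction effect
EFFECT_CONDITIONS = ("BA120", "BA1080")

DEFAULT_PROPORTIONS = {
    "root_specific": 0.05,
    "shoot_specific": 0.05,
    "similar": 0.05,
    "differential": 0.02,
    "shift_up_root": 0.02,
    "shift_down_root": 0.02,
    "shift_root_like_shoot": 0.02,
    "not_regulated": 0.72,
    "not_expressed": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic dataset (defaults are the tested
    conditions: 2.0 log2 effects over sigma 0.25 noise, 95% detection)."""

    n_genes: int = 1000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_log2: float = 2.0
    baseline_organ_log2: float = 3.0
    sigma_tech: float = 0.25
    sigma_bio: float = 0.25
    detect_prob_expressed: float = 0.95
    detect_prob_unexpressed: float = 0.05
    seed: int = 0
    mixed_direction_differential: bool = False

    def __post_init__(self):
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.sigma_tech < 0 or self.sigma_bio < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0 < self.detect_prob_expressed <= 1:
            raise ValueError("detect_prob_expressed must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene class and the per-(organ, condition)
    mean log2 offsets relative to the gene's own BA0 root baseline."""

    classes: pd.Series                 # gene -> class label
    offsets: pd.DataFrame              # gene x MultiIndex (organ, condition)

    def genes_of(self, cls: str) -> pd.Index:
        return self.classes.index[self.classes == cls]

    def write_tsv(self, path) -> None:
        out = self.offsets.copy()
        out.columns = [f"offset_{o}_{c}" for o, c in out.columns]
        out.insert(0, "class", self.classes)
        out.to_csv(path, sep="\t", index_label="probe_id")


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of class counts."""
    raw = {c: cfg.class_proportions.get(c, 0.0) * cfg.n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = cfg.n_genes - sum(counts.values())
    remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)
    return labels


def _planted_offsets(cls: str, sign: float, cfg: SimulationConfig,
                     flip: float) -> dict[tuple[str, str], float]:
    """Mean log2 offset of every (organ, condition) cell for one gene."""
    off = {(o, c): 0.0 for o in ORGANS for c in CONDITIONS}
    e = cfg.effect_log2 * sign
    if cls == "root_specific":
        for c in EFFECT_CONDITIONS:
            off[("root", c)] = e
    elif cls == "shoot_specific":
        for c in EFFECT_CONDITIONS:
            off[("shoot", c)] = e
    elif cls == "similar":
        for c in EFFECT_CONDITIONS:
            off[("root", c)] = e
            off[("shoot", c)] = e
    elif cls == "differential":
        for i, c in enumerate(EFFECT_CONDITIONS):
            s = -1.0 if (cfg.mixed_direction_differential and flip < 0 and i == 0) else 1.0
            off[("root", c)] = e * s
            off[("shoot", c)] = -e * s
    elif cls == "shift_up_root":
        for c in CONDITIONS:
            off[("shoot", c)] += cfg.baseline_organ_log2
        off[("root", "BA1080")] = abs(e)
    elif cls == "shift_down_root":
        for c in CONDITIONS:
            off[("root", c)] += cfg.baseline_organ_log2
        off[("root", "BA1080")] += -abs(e)
    elif cls == "shift_root_like_shoot":
        for c in CONDITIONS:
            off[("shoot", c)] += cfg.baseline_organ_log2
        off[("shoot", "CKX1")] += -abs(e)
    return off


def simulate_dataset(cfg: SimulationConfig,
                     design: StudyDesign | None = None
                     ) -> tuple[ExpressionMatrix, SyntheticTruth, GeneAnnotation]:
    """Draw a dataset; fully reproducible from ``cfg.seed``."""
    if design is None:
        design = generate_design()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    classes = _assign_classes(cfg, rng)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    flips = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    mu = rng.normal(8.0, 1.5, size=cfg.n_genes)

    dt = design.table
    n_arrays = len(dt)
    cols = pd.MultiIndex.from_tuples(
        [(o, c) for o in ORGANS for c in CONDITIONS], names=["organ", "condition"])
    offsets = np.zeros((cfg.n_genes, len(cols)))
    for i, (cls, s, f) in enumerate(zip(classes, signs, flips)):
        off = _planted_offsets(cls, s, cfg, f)
        offsets[i] = [off[oc] for oc in cols]
    offsets = pd.DataFrame(offsets, index=genes, columns=cols)

    # map each array to its (organ, condition) column and biological sample
    cell_idx = [cols.get_loc((o, c))
                for o, c in zip(dt["organ"], dt["condition"])]
    sample_key = dt["organ"] + "|" + dt["condition"] + "|" + \
        dt["biological_replicate"].astype(str)
    sample_codes, _ = pd.factorize(sample_key)
    n_samples = sample_codes.max() + 1

    bio = rng.normal(0.0, cfg.sigma_bio, size=(cfg.n_genes, n_samples))
    tech = rng.normal(0.0, cfg.sigma_tech, size=(cfg.n_genes, n_arrays))
    values = (mu[:, None] + offsets.to_numpy()[:, cell_idx]
              + bio[:, sample_codes] + tech)

    detect_p = np.where(np.array(classes) == "not_expressed",
                        cfg.detect_prob_unexpressed,
                        cfg.detect_prob_expressed)
    mask = rng.random((cfg.n_genes, n_arrays)) < detect_p[:, None]

    values_df = pd.DataFrame(values, index=genes, columns=dt["array_id"])
    values_df = values_df.where(pd.DataFrame(mask, index=genes,
                                             columns=dt["array_id"]))
    matrix = ExpressionMatrix(values_df,
                              pd.DataFrame(mask, index=genes,
                                           columns=dt["array_id"]))
    truth = SyntheticTruth(pd.Series(classes, index=genes, name="class"),
                           offsets)
    # synthetic annotation: plastid code "P" for shift-down classes mimics
    # the plastid bias of shoot-higher genes; others cycle through codes
    codes = []
    for i, cls in enumerate(classes):
        if cls in ("shift_up_root", "shift_root_like_shoot"):
            codes.append("P" if i % 4 else "c")
        else:
            codes.append(["—", "c", "n", "w"][i % 4])
    annotation = GeneAnnotation(pd.DataFrame({
        "agi": [f"AT{1 + i % 5}G{10000 + i:05d}" for i in range(cfg.n_genes)],
        "description": [f"synthetic {cls} gene" for cls in classes],
        "localization": codes,
    }, index=pd.Index(genes, name="probe_id")))
    return matrix, truth, annotation
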