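"""Developmental-shift gene sets, overlap partition, localization fraction."""
import numpy as np
import pandas as pd
import pytest

import ckorgan as ck
from ckorgan.categorize import RatioTable
from ckorgan.datamodel import GeneAnnotation, Thresholds


def _single(r_base, r_root=np.nan, r_shoot=np.nan, qs=(1e-4, 1e-4, 1e-4)):
    ratios = RatioTable.from_printed(
        pd.DataFrame({"r_root_BA1080": [r_root], "r_shoot_CKX1": [r_shoot]},
                     index=["g"]),
        pd.Series([r_base], index=["g"]))
    stats = pd.DataFrame({"q_organ": [qs[0]], "q_condition": [qs[1]],
                          "q_interaction": [qs[2]]}, index=["g"])
    return ratios, stats


class TestFindShiftGenes:
    def test_printed_plastid_ribosomal_row_is_member(self, printed_shift_inputs):
        # shoot-higher gene rising 2.8-fold in long-term treated roots
        ratios, stats, _ = printed_shift_inputs
        members = ck.find_shift_genes(ratios, stats, mode="root_under_BA1080")
        row = members.table.loc["CATMA5a16150"]
        assert row["baseline_side"] == "shoot_higher"
        assert row["direction"] == "up"

    def test_no_baseline_differential_never_member(self):
        ratios, stats = _single(r_base=1.0, r_root=50.0)
        assert len(ck.find_shift_genes(ratios, stats)) == 0

    def test_direction_must_point_at_other_organ(self):
        # root-higher gene rising further in roots: magnitude passes but
        # the movement is away from the shoot level
        ratios, stats = _single(r_base=10.0, r_root=5.0)
        assert len(ck.find_shift_genes(ratios, stats)) == 0
        relaxed = ck.find_shift_genes(ratios, stats,
                                      direction_consistent=False)
        assert len(relaxed) == 1

    def test_requires_one_significant_effect(self):
        ratios, stats = _single(r_base=0.1, r_root=5.0, qs=(0.5, 0.5, 0.5))
        assert len(ck.find_shift_genes(ratios, stats)) == 0
        ratios, stats = _single(r_base=0.1, r_root=5.0, qs=(0.5, 0.5, 0.02))
        assert len(ck.find_shift_genes(ratios, stats)) == 1

    def test_missing_ratio_excludes_gene(self):
        ratios, stats = _single(r_base=0.1, r_root=np.nan)
        assert len(ck.find_shift_genes(ratios, stats)) == 0

    def test_matches_brute_force_three_predicate_filter(self):
        rng = np.random.default_rng(31)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        r_base = rng.lognormal(0, 2, n)
        r_root = rng.lognormal(0, 1.5, n)
        qm = rng.random((n, 3)) * 0.06
        ratios = RatioTable.from_printed(
            pd.DataFrame({"r_root_BA1080": r_root,
                          "r_shoot_CKX1": np.nan}, index=genes),
            pd.Series(r_base, index=genes))
        stats = pd.DataFrame(qm, index=genes,
                             columns=["q_organ", "q_condition", "q_interaction"])
        got = set(ck.find_shift_genes(ratios, stats).genes)
        T = 2.5
        expected = {
            g for g, rb, rr, q in zip(genes, r_base, r_root, qm.min(axis=1))
            if (rb >= T or rb <= 1 / T)
            and ((rb <= 1 / T and rr >= T) or (rb >= T and rr <= 1 / T))
            and q <= 0.03}
        assert got == expected

    def test_membership_invariant_under_gene_relabeling(self, printed_shift_inputs):
        ratios, stats, _ = printed_shift_inputs
        base = ck.find_shift_genes(ratios, stats)
        perm = ratios.genes[::-1]
        shuffled = RatioTable(ratios.ratios.loc[perm], ratios.r_base.loc[perm])
        again = ck.find_shift_genes(shuffled, stats.loc[perm])
        assert set(base.genes) == set(again.genes)


class TestOverlap:
    def test_disjoint_sets_empty_overlap(self):
        r1, s1 = _single(r_base=0.1, r_root=5.0)
        r2, s2 = _single(r_base=0.1, r_shoot=0.1)
        a = ck.find_shift_genes(r1, s1, mode="root_under_BA1080")
        b = ck.ShiftGeneSet(mode="shoot_under_CKX1",
                            table=ck.find_shift_genes(r2, s2, mode="shoot_under_CKX1").table.iloc[:0])
        out = ck.shift_overlap(a, b)
        assert len(out["total"]) == 0

    def test_groups_disjoint_and_within_both_sets(self, printed_shift_inputs):
        ratios, stats, _ = printed_shift_inputs
        a = ck.find_shift_genes(ratios, stats, mode="root_under_BA1080")
        b = ck.find_shift_genes(ratios, stats, mode="shoot_under_CKX1")
        out = ck.shift_overlap(a, b)
        up_down = set(out["root_up_and_shoot_down"])
        down_up = set(out["root_down_and_shoot_up"])
        assert not up_down & down_up
        assert up_down | down_up <= set(a.genes) & set(b.genes)
        assert len(out["total"]) == len(up_down) + len(down_up)

    def test_identical_sets_uniform_direction_saturate_one_group(self):
        genes = ["g1", "g2"]
        tab = pd.DataFrame({"baseline_side": "shoot_higher",
                            "direction": ["up", "up"], "q_min": 1e-4},
                           index=genes)
        a = ck.ShiftGeneSet("root_under_BA1080", tab)
        tab2 = tab.assign(direction="down")
        b = ck.ShiftGeneSet("shoot_under_CKX1", tab2)
        out = ck.shift_overlap(a, b)
        assert list(out["root_up_and_shoot_down"]) == genes
        assert len(out["root_down_and_shoot_up"]) == 0


class TestLocalizationFraction:
    @staticmethod
    def _annotation(codes):
        return GeneAnnotation(pd.DataFrame({
            "agi": "AT1G00001", "description": "x",
            "localization": codes}, index=[f"g{i}" for i in range(len(codes))]))

    def test_counts_and_fraction(self):
        ann = self._annotation(["P", "a,P", "w", "—"])
        count, frac = ck.localization_fraction(["g0", "g1", "g2", "g3"], ann)
        assert (count, frac) == (2, 0.5)

    def test_case_sensitive_codes(self):
        ann = self._annotation(["w,p"])
        assert ck.localization_fraction(["g0"], ann, "P")[0] == 0
        assert ck.localization_fraction(["g0"], ann, "p")[0] == 1

    def test_empty_set_fraction_undefined(self):
        ann = self._annotation(["P"])
        count, frac = ck.localization_fraction([], ann)
        assert count == 0 and frac is None

    def test_unannotated_genes_count_zero(self):
        ann = self._annotation(["—", ""])
        assert ck.localization_fraction(["g0", "g1"], ann) == (0, 0.0)


class TestPlantedShiftRecovery:
    def test_recall_and_false_positive_rate(self, design):
        """Planted shift genes (baseline 3 log2, effect 2.5 log2) are
        recovered from the full-model fit; null genes rarely pass."""
        recalls, fprs = [], []
        for seed in range(3):
            cfg = ck.SimulationConfig(
                n_genes=600, seed=seed, effect_log2=2.5,
                baseline_organ_log2=3.0,
                class_proportions={"shift_up_root": 0.1,
                                   "shift_down_root": 0.1,
                                   "not_regulated": 0.8})
            matrix, truth, _ = ck.simulate_dataset(cfg, design)
            rep = ck.apply_detection_filters(matrix, design)
            genes = rep.index[rep["model_eligible"] == 1].tolist()
            stats = ck.fit_all_genes(matrix, design, "full", genes)
            rt = ck.fold_change_ratios(ck.condition_means(matrix, design))
            members = set(ck.find_shift_genes(rt, stats,
                                              mode="root_under_BA1080").genes)
            planted = set(truth.genes_of("shift_up_root")) \
                | set(truth.genes_of("shift_down_root"))
            null = set(truth.genes_of("not_regulated"))
            recalls.append(len(members & planted) / len(planted))
            fprs.append(len(members & null) / len(null))
        assert np.mean(recalls) >= 0.9
        assert np.mean(fprs) <= 0.05
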