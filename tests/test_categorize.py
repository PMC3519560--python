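"""Condition means, fold-change ratios and the category decision list."""
import numpy as np
import pandas as pd
import pytest

import ckorgan as ck
from ckorgan.categorize import INDUCTION_TIMEPOINTS, RatioTable
from ckorgan.datamodel import Thresholds

from conftest import zero_noise_config


class TestMeansAndRatios:
    def test_missing_aware_cell_mean(self, design):
        genes = ["g0"]
        values = pd.DataFrame(np.nan, index=genes, columns=design.array_ids)
        mask = pd.DataFrame(False, index=genes, columns=design.array_ids)
        cell = design.table.query("organ == 'root' and condition == 'BA0'")
        ids = cell["array_id"].tolist()
        values.loc["g0", ids] = [1.0, 3.0, np.nan, np.nan]
        mask.loc["g0", ids] = [True, True, False, False]
        m = ck.ExpressionMatrix(values, mask)
        means = ck.condition_means(m, design)
        assert means.loc["g0", ("root", "BA0")] == pytest.approx(2.0)
        assert np.isnan(means.loc["g0", ("root", "BA15")])

    def test_ratio_definition(self):
        cols = pd.MultiIndex.from_product([["root", "shoot"],
                                           ["BA0", "BA120"]])
        means = pd.DataFrame([[5.0, 7.0, 5.0, 5.0]], index=["g"], columns=cols)
        rt = ck.fold_change_ratios(means)
        assert rt.ratio("root", "BA120")["g"] == pytest.approx(4.0)   # 2^2
        assert rt.ratio("shoot", "BA120")["g"] == pytest.approx(1.0)
        assert rt.r_base["g"] == pytest.approx(1.0)

    def test_zero_noise_ratios_match_planted_effects(self, design):
        cfg = zero_noise_config(effect_log2=2.0)
        matrix, truth, _ = ck.simulate_dataset(cfg, design)
        rt = ck.fold_change_ratios(ck.condition_means(matrix, design))
        for g in truth.genes_of("root_specific"):
            planted = truth.offsets.loc[g, ("root", "BA120")]
            assert rt.ratio("root", "BA120")[g] == pytest.approx(2.0 ** planted)
            assert rt.ratio("shoot", "BA120")[g] == pytest.approx(1.0)


def _call(r_root, r_shoot, q=1e-4, th=None):
    ratios = RatioTable.from_printed(pd.DataFrame({
        "r_root_BA15": [r_root[0]], "r_root_BA120": [r_root[1]],
        "r_root_BA1080": [r_root[2]],
        "r_shoot_BA15": [r_shoot[0]], "r_shoot_BA120": [r_shoot[1]],
        "r_shoot_BA1080": [r_shoot[2]]}, index=["g"]))
    stats = pd.DataFrame({"q_condition": [q]}, index=["g"])
    detection = pd.DataFrame({"induction_eligible": [1]}, index=["g"])
    calls = ck.classify_induction(ratios, stats, detection, th)
    return calls.loc["g", "category"]


class TestInductionDecisionList:
    # printed induction-table rows with an unambiguous category
    @pytest.mark.parametrize("probe, expected", [
        ("CATMA1a56420", "root_specific"),    # cytochrome P450, putative
        ("CATMA5a49210", "shoot_specific"),   # ERF subfamily B-5 (CRF3)
        ("CATMA5a07985", "similar"),          # flavonol synthase FLS1
        ("CATMA4a13955", "differential"),     # cytochrome P450 family
        ("CATMA5a43410", "uncategorized"),    # mixed shoot direction
    ])
    def test_printed_rows_classify_as_printed(self, probe, expected):
        t1 = ck.load_induction_examples()
        row = t1.loc[probe]
        got = _call([row["r_root_BA15"], row["r_root_BA120"], row["r_root_BA1080"]],
                    [row["r_shoot_BA15"], row["r_shoot_BA120"], row["r_shoot_BA1080"]],
                    q=row["q_cytokinin"])
        assert got == expected

    def test_null_gene_not_regulated(self):
        assert _call([1.0] * 3, [1.0] * 3, q=1.0) == "not_regulated"

    def test_threshold_inclusive(self):
        assert _call([2.5, 1.0, 1.0], [1.0] * 3) == "root_specific"
        assert _call([0.4, 1.0, 1.0], [1.0] * 3) == "root_specific"

    def test_significance_gate(self):
        assert _call([4.0] * 3, [1.0] * 3, q=0.05) == "not_regulated"
        assert _call([4.0] * 3, [1.0] * 3, q=0.03) == "root_specific"

    def test_gray_zone_demotes_single_organ_calls(self):
        th = Thresholds(gray_zone_G=2.0)
        assert _call([4.0] * 3, [1.0] * 3, th=th) == "root_specific"
        assert _call([4.0] * 3, [2.2, 1.0, 1.0], th=th) == "uncategorized"

    def test_monotone_gating(self):
        """Raising T or lowering alpha never promotes a gene out of
        not_regulated."""
        rng = np.random.default_rng(17)
        loose, tight = Thresholds(), Thresholds(fold_change_T=4.0, alpha_q=0.005)
        for _ in range(200):
            r_root = rng.lognormal(0, 1, 3)
            r_shoot = rng.lognormal(0, 1, 3)
            q = rng.random() * 0.06
            call_loose = _call(r_root, r_shoot, q, loose)
            call_tight = _call(r_root, r_shoot, q, tight)
            if call_loose == "not_regulated":
                assert call_tight == "not_regulated"


def _oracle(r_root, r_shoot, q, alpha=0.03, T=2.5):
    """Straight-line reimplementation of the decision list."""
    if q > alpha:
        return "not_regulated"
    def direction(rs):
        up = any(r >= T for r in rs)
        down = any(r <= 1 / T for r in rs)
        return "mixed" if (up and down) else "up" if up else "down" if down else "none"
    d_root, d_shoot = direction(r_root), direction(r_shoot)
    if d_root == "none" and d_shoot == "none":
        return "not_regulated"
    if d_shoot == "none":
        return "uncategorized" if d_root == "mixed" else "root_specific"
    if d_root == "none":
        return "uncategorized" if d_shoot == "mixed" else "shoot_specific"
    if "mixed" in (d_root, d_shoot):
        return "uncategorized"
    return "similar" if d_root == d_shoot else "differential"


def test_random_tuples_match_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        r_root = rng.lognormal(0, 1.2, 3)
        r_shoot = rng.lognormal(0, 1.2, 3)
        q = rng.random() * 0.06
        assert _call(r_root, r_shoot, q) == _oracle(r_root, r_shoot, q)


class TestDeficiency:
    @pytest.mark.parametrize("probe, expected", [
        ("CATMA5a61330", "root_specific"),    # amino acid transporter
        ("CATMA4a00090", "shoot_specific"),   # invertase/PME inhibitor
        ("CATMA5a07985", "similar"),          # FLS1
    ])
    def test_printed_rows_classify_as_printed(self, probe, expected):
        t2 = ck.load_deficiency_examples()
        row = t2.loc[probe]
        ratios = RatioTable.from_printed(pd.DataFrame({
            "r_root_CKX1": [row["r_root_CKX1"]],
            "r_shoot_CKX1": [row["r_shoot_CKX1"]]}, index=["g"]))
        stats = pd.DataFrame({"q_condition": [row["q_genotype"]]}, index=["g"])
        detection = pd.DataFrame({"deficiency_eligible": [1]}, index=["g"])
        calls = ck.classify_deficiency(ratios, stats, detection)
        assert calls.loc["g", "category"] == expected

    def test_ineligible_gene_is_not_expressed(self):
        ratios = RatioTable.from_printed(
            pd.DataFrame({"r_root_CKX1": [9.0], "r_shoot_CKX1": [1.0]},
                         index=["g"]))
        stats = pd.DataFrame({"q_condition": [1e-5]}, index=["g"])
        detection = pd.DataFrame({"deficiency_eligible": [0]}, index=["g"])
        calls = ck.classify_deficiency(ratios, stats, detection)
        assert calls.loc["g", "category"] == "not_expressed"


class TestEndToEndRecovery:
    def test_zero_noise_classification_equals_truth(self, design):
        cfg = zero_noise_config(n_genes=200, seed=6)
        matrix, truth, _ = ck.simulate_dataset(cfg, design)
        rep = ck.apply_detection_filters(matrix, design)
        genes = rep.index[rep["induction_eligible"] == 1].tolist()
        stats = ck.fit_all_genes(matrix, design, "induction", genes)
        rt = ck.fold_change_ratios(ck.condition_means(matrix, design))
        calls = ck.classify_induction(rt, stats, rep)
        for cls in ("root_specific", "shoot_specific", "similar", "differential"):
            planted = truth.genes_of(cls)
            assert (calls.loc[planted, "category"] == cls).all(), cls

    def test_categories_partition_eligible_genes(self, design, small_dataset):
        _, matrix, _, _ = small_dataset
        rep = ck.apply_detection_filters(matrix, design)
        genes = rep.index[rep["induction_eligible"] == 1].tolist()
        stats = ck.fit_all_genes(matrix, design, "induction", genes)
        rt = ck.fold_change_ratios(ck.condition_means(matrix, design))
        calls = ck.classify_induction(rt, stats, rep)
        assert calls["category"].isin(ck.categorize.CATEGORIES).all()
        assert len(calls) == matrix.n_genes
        assert ((calls["category"] == "not_expressed")
                == (rep["induction_eligible"] == 0).reindex(calls.index)).all()
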