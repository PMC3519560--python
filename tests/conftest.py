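import numpy as np
import pandas as pd
import pytest

import ckorgan as ck


@pytest.fixture(scope="session")
def design():
    return ck.generate_design()


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene default simulation shared by read-only tests."""
    cfg = ck.SimulationConfig(n_genes=300, seed=42)
    matrix, truth, annotation = ck.simulate_dataset(cfg)
    return cfg, matrix, truth, annotation


@pytest.fixture(scope="session")
def printed_shift_inputs():
    """RatioTable + full-model q-values + annotation from the printed
    developmental-shift gene table."""
    t3 = ck.load_shift_examples()
    ratios = ck.RatioTable.from_printed(
        t3[["r_root_BA1080", "r_shoot_CKX1"]], t3["r_base"])
    stats = t3[["q_cytokinin", "q_organ", "q_interaction"]].rename(
        columns={"q_cytokinin": "q_condition"})
    annotation = ck.GeneAnnotation(
        t3[["agi", "description", "localization"]])
    return ratios, stats, annotation


def zero_noise_config(**kwargs):
    defaults = dict(n_genes=120, seed=3, sigma_tech=0.0, sigma_bio=0.0,
                    detect_prob_expressed=1.0, detect_prob_unexpressed=0.0)
    defaults.update(kwargs)
    return ck.SimulationConfig(**defaults)
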