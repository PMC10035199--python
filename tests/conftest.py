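import numpy as np
import pandas as pd
import pytest

from protmod.simulate import SimConfig, generate_peptide_report
from protmod.quantify import quantify_report

SUITE_SEED = 20230117


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 3-block cohort reused across module-level tests."""
    cfg = SimConfig(
        n_proteins=200,
        module_sizes=[60, 40, 30],
        module_effects={"M01": {"tau": 0.8}, "M02": {"tau": -0.8}, "M03": {}},
        peptide_mean_extra=3,
    )
    report, truth = generate_peptide_report(cfg, seed=SUITE_SEED)
    return cfg, report, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, report, truth = small_cohort
    matrix, groups = quantify_report(report)
    return matrix, groups, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture()
def toy_contrast():
    """Four-protein two-cohort statistics with hand-computable concordance."""
    disc = pd.DataFrame(
        {"pvalue": [0.05, 0.05, 0.01, 0.9], "log2fc": [1.0, 1.0, 1.0, 1.0]},
        index=["A", "B", "C", "D"],
    )
    val = pd.DataFrame(
        {"pvalue": [0.08, 0.2, 0.01, 0.9], "log2fc": [1.0, 1.0, -1.0, 1.0]},
        index=["A", "B", "C", "D"],
    )
    return disc, val
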