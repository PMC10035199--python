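"""Soft-threshold similarity, dynamic tree cut, module dysregulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from protmod.coexpression import (
    pick_soft_threshold,
    scale_free_fit_index,
    build_similarity,
    ModuleDetector,
    detect_modules,
)
from protmod.coexpression import test_module_dysregulation as module_dysregulation


def block_matrix(rng, sizes=(60, 40, 30), n_noise=40, loading=0.9, noise_sd=0.2, n_samples=26):
    """Latent-level factor-model matrix (no peptide layer) for fast tests."""
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(10 + loading * f + rng.normal(scale=noise_sd, size=n_samples))
            labels.append(f"M{b + 1:02d}")
    for _ in range(n_noise):
        rows.append(10 + rng.normal(scale=noise_sd * 2, size=n_samples))
        labels.append("M00")
    m = pd.DataFrame(2.0 ** np.array(rows), index=[f"P{i:04d}" for i in range(len(rows))])
    return m, np.array(labels)


def test_similarity_is_powered_absolute_correlation():
    x = np.array([[1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1]])
    m = pd.DataFrame(x, index=["A", "B"])
    sim = build_similarity(m, soft_power=7, log_transform=False)
    assert sim.loc["A", "B"] == pytest.approx(1.0)  # r = -1
    rng = np.random.default_rng(0)
    m2 = pd.DataFrame(rng.lognormal(3, 0.5, size=(5, 10)))
    s1 = build_similarity(m2, soft_power=1, log_transform=False)
    corr = np.abs(np.corrcoef(m2.to_numpy()))
    assert np.allclose(s1.to_numpy(), np.where(np.eye(5), 1, corr), atol=1e-12)
    s7 = build_similarity(m2, soft_power=7, log_transform=False)
    assert np.allclose(s7.to_numpy(), s1.to_numpy() ** 7, atol=1e-12)


def test_powered_entry_matches_hand_value():
    assert 0.8**7 == pytest.approx(0.2097152, abs=1e-12)


def test_zero_variance_protein_flagged_with_zero_similarity():
    m = pd.DataFrame([[1.0, 2, 3, 4], [2.0, 2, 2, 2], [4.0, 3, 2, 1]], index=["A", "B", "C"])
    with pytest.warns(UserWarning, match="zero-variance"):
        sim = build_similarity(m, soft_power=2, log_transform=False)
    assert sim.loc["B", "A"] == 0.0 and sim.loc["B", "C"] == 0.0
    assert sim.loc["B", "B"] == 1.0


def test_similarity_invariant_to_per_protein_affine_transform(rng):
    m = pd.DataFrame(rng.lognormal(3, 0.5, size=(8, 12)))
    scaled = m.mul(rng.uniform(0.5, 2.0, size=8), axis=0).add(0.0)
    s1 = build_similarity(m, soft_power=7, log_transform=False)
    s2 = build_similarity(scaled, soft_power=7, log_transform=False)
    assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)


def test_scale_free_fit_index_matches_direct_regression(rng):
    k = np.array([1.0, 2, 2, 3, 3, 3, 5, 8, 13, 21])
    fit, slope = scale_free_fit_index(k, n_bins=5)
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, 6)
    which = np.clip(np.digitize(logk, edges) - 1, 0, 4)
    xs = [logk[which == b].mean() for b in range(5) if (which == b).sum()]
    ys = [np.log10((which == b).sum() / len(k)) for b in range(5) if (which == b).sum()]
    expected_slope, _, r, _, _ = stats.linregress(xs, ys)
    assert slope == pytest.approx(expected_slope)
    assert fit == pytest.approx(-np.sign(expected_slope) * r**2)


def test_pick_soft_threshold_on_modular_and_noise_data(rng):
    m, _ = block_matrix(rng, sizes=(40, 30), n_noise=10)
    power, table = pick_soft_threshold(m, powers=tuple(range(1, 9)), fit_min=0.8)
    assert power in range(1, 9)
    assert {"power", "fit_index", "slope"} <= set(table.columns)
    noise = pd.DataFrame(rng.lognormal(3, 0.1, size=(60, 12)))
    with pytest.warns(UserWarning):
        p_noise, t_noise = pick_soft_threshold(noise, powers=(1, 2, 3), fit_min=0.95)
    assert p_noise == t_noise.loc[t_noise["fit_index"].idxmax(), "power"]


def test_module_detection_recovers_planted_blocks(rng):
    m, labels = block_matrix(rng)
    sim = build_similarity(m, soft_power=7)
    detected = detect_modules(sim, min_size=15)
    assert adjusted_rand_score(labels, detected.values) >= 0.9
    # labels ordered by decreasing size: the 60-block is M01
    assert (detected[labels == "M01"] == "M01").mean() > 0.9


def test_independent_proteins_stay_unassigned(rng):
    m, _ = block_matrix(rng, sizes=(), n_noise=120)
    sim = build_similarity(m, soft_power=7)
    detected = detect_modules(sim, min_size=15)
    assert (detected == "M00").mean() >= 0.8


def test_detection_is_permutation_equivariant(rng):
    m, _ = block_matrix(rng, sizes=(25, 20), n_noise=10, n_samples=20)
    sim = build_similarity(m, soft_power=7)
    base = detect_modules(sim, min_size=10)
    perm = rng.permutation(len(sim))
    sim_p = sim.iloc[perm, perm]
    shuffled = detect_modules(sim_p, min_size=10)
    # same partition, only label names may differ through size ties
    assert adjusted_rand_score(base.loc[sim_p.index].values, shuffled.values) == pytest.approx(1.0)


def test_min_size_larger_than_matrix_leaves_all_unassigned(rng):
    m, _ = block_matrix(rng, sizes=(10,), n_noise=0, n_samples=12)
    sim = build_similarity(m, soft_power=7)
    with pytest.warns(UserWarning):
        det = ModuleDetector(min_size=50).fit(sim)
    assert (det.labels_ == "M00").all()


def test_module_detector_is_sklearn_compatible(rng):
    det = ModuleDetector(min_size=10, deep_split=3)
    assert det.get_params()["min_size"] == 10
    det.set_params(min_size=12)
    assert det.min_size == 12
    m, _ = block_matrix(rng, sizes=(20, 15), n_noise=5, n_samples=20)
    labels = det.fit_predict(build_similarity(m))
    assert len(labels) == len(m)


class TestModuleDysregulation:
    def make_contrast(self, assignment, fc_by_module, rng, sd=0.1):
        fc = {}
        for p, lab in assignment.items():
            fc[p] = rng.normal(fc_by_module.get(lab, 0.0), sd)
        return pd.DataFrame({"log2fc": pd.Series(fc), "pvalue": 0.5})

    def test_shifted_module_is_flagged(self, rng):
        assignment = pd.Series(["M01"] * 100 + ["M02"] * 50,
                               index=[f"P{i}" for i in range(150)])
        contrast = self.make_contrast(assignment, {"M01": 0.5}, rng)
        table = module_dysregulation(assignment, contrast)
        assert table.loc["M01", "dysregulated"]
        assert table.loc["M01", "mean_log2fc"] == pytest.approx(0.5, abs=0.05)
        assert not table.loc["M02", "dysregulated"]

    def test_constant_zero_fold_changes_are_null(self):
        assignment = pd.Series(["M01"] * 10, index=[f"P{i}" for i in range(10)])
        contrast = pd.DataFrame({"log2fc": np.zeros(10), "pvalue": 0.5}, index=assignment.index)
        table = module_dysregulation(assignment, contrast)
        assert table.loc["M01", "p_raw"] == 1.0
        assert not table.loc["M01", "dysregulated"]

    def test_single_module_bh_is_identity(self, rng):
        assignment = pd.Series(["M01"] * 30, index=[f"P{i}" for i in range(30)])
        contrast = self.make_contrast(assignment, {"M01": 0.2}, rng)
        table = module_dysregulation(assignment, contrast)
        assert table.loc["M01", "p_bh"] == pytest.approx(table.loc["M01", "p_raw"])

    def test_tiny_module_flagged_not_tested(self, rng):
        assignment = pd.Series(["M01"] * 2 + ["M02"] * 20,
                               index=[f"P{i}" for i in range(22)])
        contrast = self.make_contrast(assignment, {"M01": 1.0, "M02": 0.3}, rng)
        table = module_dysregulation(assignment, contrast)
        assert table.loc["M01", "p_raw"] == 1.0 and table.loc["M01", "flagged"]

    def test_bh_never_reorders_pvalues(self, rng):
        assignment = pd.Series(
            sum(([f"M{i:02d}"] * 20 for i in range(1, 6)), []),
            index=[f"P{i}" for i in range(100)],
        )
        contrast = self.make_contrast(assignment, {f"M{i:02d}": 0.1 * i for i in range(1, 6)}, rng)
        table = module_dysregulation(assignment, contrast)
        order_raw = table["p_raw"].rank()
        order_bh = table["p_bh"].rank(method="first")
        assert (table["p_bh"] >= table["p_raw"] - 1e-15).all()
        assert stats.spearmanr(order_raw, order_bh).statistic > 0.99
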