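"""Beta-binomial differential abundance, BUM FDR calibration, sample clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from protmod.diffexp import (
    beta_binomial_test,
    BetaUniformMixture,
    fit_bum,
    fdr_threshold,
    cluster_samples,
    to_pseudocounts,
)

GROUPS6v5 = {f"C{i}": "case" for i in range(6)} | {f"R{i}": "ref" for i in range(5)}


def toy_matrix(rng, n_proteins=40, shift_first=0.0):
    base = rng.lognormal(mean=8, sigma=1, size=n_proteins)
    cols = {}
    for s, g in GROUPS6v5.items():
        mult = 2.0**shift_first if g == "case" else 1.0
        noise = rng.lognormal(mean=0, sigma=0.15, size=n_proteins)
        col = base * noise
        col[0] *= mult
        cols[s] = col
    return pd.DataFrame(cols, index=[f"P{i}" for i in range(n_proteins)])


def test_identical_group_profiles_are_null():
    values = np.outer(np.arange(1, 11), np.ones(11)) * 100
    m = pd.DataFrame(values, index=[f"P{i}" for i in range(10)], columns=list(GROUPS6v5))
    res = beta_binomial_test(m, GROUPS6v5, ("case", "ref"))
    assert np.allclose(res["log2fc"], 0.0, atol=1e-9)
    assert (res["pvalue"] >= 0.99).all()


def test_scale_invariance(rng):
    m = toy_matrix(rng, n_proteins=25, shift_first=1.0)
    r1 = beta_binomial_test(m, GROUPS6v5, ("case", "ref"))
    r2 = beta_binomial_test(m * 37.5, GROUPS6v5, ("case", "ref"))
    assert np.allclose(r1["pvalue"], r2["pvalue"], rtol=1e-6)
    assert np.allclose(r1["log2fc"], r2["log2fc"], atol=1e-9)


def test_contrast_symmetry(rng):
    m = toy_matrix(rng, n_proteins=25, shift_first=1.0)
    fwd = beta_binomial_test(m, GROUPS6v5, ("case", "ref"))
    rev = beta_binomial_test(m, GROUPS6v5, ("ref", "case"))
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-9)
    assert np.allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-5)


def test_planted_shift_is_detected(rng):
    m = toy_matrix(rng, n_proteins=30, shift_first=2.0)
    res = beta_binomial_test(m, GROUPS6v5, ("case", "ref"))
    assert res["log2fc"].iloc[0] > 1.0
    assert res["pvalue"].iloc[0] < 0.01
    assert res["pvalue"].iloc[0] < res["pvalue"].iloc[1:].min()


def test_missing_group_raises(rng):
    m = toy_matrix(rng, n_proteins=5)
    with pytest.raises(ValueError, match="nothere"):
        beta_binomial_test(m, GROUPS6v5, ("nothere", "ref"))


def test_pseudocount_scaling_targets_median_total(rng):
    m = toy_matrix(rng, n_proteins=30)
    counts = to_pseudocounts(m)
    assert np.median(counts.sum(axis=0)) == pytest.approx(1e6, rel=0.01)
    assert counts.dtypes.unique().tolist() == [np.dtype("int64")]


def test_null_pvalues_are_uniform_at_cohort_scale():
    """With no group effects planted, the per-protein p-values over a full
    1800-protein cohort pass a Kolmogorov-Smirnov uniformity test at
    alpha = 0.01 (fixed-seed draw)."""
    from protmod.simulate import SimConfig, generate_peptide_report
    from protmod.quantify import quantify_report
    from scipy import stats as sps

    cfg = SimConfig(n_proteins=1800, module_sizes=[10], module_effects={},
                    peptide_mean_extra=3)
    report, _ = generate_peptide_report(cfg, seed=30117)
    matrix, groups = quantify_report(report)
    res = beta_binomial_test(matrix, groups, ("tau", "control"))
    ks = sps.kstest(res["pvalue"].to_numpy(), "uniform")
    assert ks.pvalue > 0.01


class TestBum:
    def test_parameter_recovery(self, rng):
        lam, a, n = 0.6, 0.3, 5000
        uniform = rng.random(n) < lam
        p = np.where(uniform, rng.random(n), rng.beta(a, 1.0, size=n))
        fit = fit_bum(np.clip(p, 1e-12, 1))
        assert fit.lambda_ == pytest.approx(lam, abs=0.07)
        assert fit.a_ == pytest.approx(a, abs=0.07)

    def test_uniform_pvalues_fit_flat(self, rng):
        fit = fit_bum(np.clip(rng.random(5000), 1e-12, 1))
        assert 1.0 - fit.pi_ub_ <= 0.02

    def test_pure_signal_has_no_uniform_component(self, rng):
        fit = fit_bum(np.clip(rng.beta(0.3, 1.0, 5000), 1e-12, 1))
        assert fit.lambda_ <= 0.05

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            fit_bum(np.linspace(0, 1, 100))  # contains 0
        with pytest.raises(ValueError):
            fit_bum(np.full(10, 0.5))  # too few

    @given(lam=st.floats(0.05, 0.95), a=st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_density_integrates_to_one(self, lam, a):
        fit = BetaUniformMixture()
        fit.lambda_, fit.a_ = lam, a
        fit.pi_ub_ = lam + (1 - lam) * a
        # the p^(a-1) endpoint singularity is integrable; let quad refine it
        total, err = integrate.quad(fit.pdf, 0, 1, limit=200)
        assert total == pytest.approx(1.0, abs=max(1e-8, 2 * err))

    def test_threshold_monotone_in_fdr(self, rng):
        lam, a, n = 0.6, 0.3, 5000
        uniform = rng.random(n) < lam
        p = np.clip(np.where(uniform, rng.random(n), rng.beta(a, 1.0, size=n)), 1e-12, 1)
        fit = fit_bum(p)
        taus = [fdr_threshold(fit, f) for f in (0.05, 0.1, 0.2)]
        assert taus[0] <= taus[1] <= taus[2]

    def test_pure_uniform_fit_yields_zero_threshold(self):
        fit = BetaUniformMixture()
        fit.lambda_, fit.a_, fit.pi_ub_ = 1.0, 0.5, 1.0
        with pytest.warns(UserWarning):
            assert fit.fdr_threshold(0.1) == 0.0

    def test_closed_form_equals_root_finding(self):
        fit = BetaUniformMixture()
        fit.lambda_, fit.a_ = 0.6, 0.3
        fit.pi_ub_ = fit.lambda_ + (1 - fit.lambda_) * fit.a_
        for f in (0.01, 0.05, 0.1, 0.3):
            assert fit.fdr_threshold(f) == pytest.approx(fit.fdr_threshold(f, method="root"), abs=1e-6)


def brute_force_average_linkage(dist):
    """Exhaustive agglomeration: repeatedly merge the closest pair under
    average linkage; returns the merge heights in order."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


def test_sample_clustering_matches_exhaustive_average_linkage(rng):
    m = pd.DataFrame(
        rng.lognormal(8, 1, size=(30, 6)),
        index=[f"P{i}" for i in range(30)],
        columns=[f"S{i}" for i in range(6)],
    )
    contrasts = [pd.DataFrame({"pvalue": rng.random(30), "log2fc": rng.normal(size=30)}, index=m.index)]
    clust = cluster_samples(m, contrasts, top_n=30)
    scaled = clust.scaled.to_numpy().T
    corr = np.corrcoef(scaled)
    dist = 1 - corr
    np.fill_diagonal(dist, 0)
    expected = brute_force_average_linkage(dist)
    assert np.allclose(np.sort(clust.sample_linkage[:, 2]), np.sort(expected), atol=1e-9)


def test_identical_samples_merge_first():
    # S1 == S2, so after per-protein centering S3 is exactly -2x the shared
    # column: r(S1, S2) = 1 (distance 0, merged first) and r(S1, S3) = -1
    # (distance 2, joined last)
    m = pd.DataFrame(
        {"S1": [1.0, 2, 3, 4], "S2": [1.0, 2, 3, 4], "S3": [5.0, 1, 4, 2]},
        index=[f"P{i}" for i in range(4)],
    )
    contrasts = [pd.DataFrame({"pvalue": [0.01] * 4, "log2fc": [0.0] * 4}, index=m.index)]
    clust = cluster_samples(m, contrasts, top_n=4)
    first = clust.sample_linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == pytest.approx(0.0, abs=1e-12)
    assert clust.sample_linkage[-1, 2] == pytest.approx(2.0, abs=1e-9)


def test_top_n_selection_uses_min_p_and_warns_when_short(rng):
    m = pd.DataFrame(rng.lognormal(8, 1, size=(10, 6)), index=[f"P{i}" for i in range(10)],
                     columns=[f"S{i}" for i in range(6)])
    c1 = pd.DataFrame({"pvalue": np.linspace(0.01, 1, 10), "log2fc": np.zeros(10)}, index=m.index)
    c2 = pd.DataFrame({"pvalue": np.linspace(1, 0.01, 10), "log2fc": np.zeros(10)}, index=m.index)
    clust = cluster_samples(m, [c1, c2], top_n=4)
    assert set(clust.selected_proteins) == {"P0", "P1", "P8", "P9"}
    with pytest.warns(UserWarning):
        cluster_samples(m, [c1], top_n=50)
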