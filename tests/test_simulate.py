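"""Ground-truth structure and determinism of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from protmod.simulate import (
    SimConfig,
    generate_peptide_report,
    generate_validation_stats,
    generate_annotation_sets,
    generate_specificity_inputs,
    proteome_markers,
    default_module_sizes,
    CNS_MARKERS,
)


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        SimConfig(n_proteins=10, module_sizes=[20])
    with pytest.raises(ValueError):
        SimConfig(within_module_loading=1.5)
    with pytest.raises(ValueError):
        SimConfig(module_sizes=[0, 5])
    with pytest.raises(ValueError):
        SimConfig(noise_sd=0.0)


def test_default_module_ladder_matches_study_shape():
    sizes = default_module_sizes()
    assert len(sizes) == 17
    assert sizes[0] == 272 and sizes[-1] == 18
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    assert sum(sizes) <= 1800


def test_same_config_and_seed_is_byte_identical():
    cfg = SimConfig(n_proteins=60, module_sizes=[20, 15], peptide_mean_extra=2)
    r1, t1 = generate_peptide_report(cfg, seed=3)
    r2, t2 = generate_peptide_report(cfg, seed=3)
    pd.testing.assert_frame_equal(r1, r2)
    assert t1.true_module_of == t2.true_module_of
    assert r1.to_csv() == r2.to_csv()


def test_abundances_positive_and_bad_peptides_flagged():
    cfg = SimConfig(n_proteins=80, module_sizes=[20], bad_peptide_rate=0.2, peptide_mean_extra=2)
    report, _ = generate_peptide_report(cfg, seed=5)
    assert (report["abundance"] > 0).all()
    n_samples = report["sample"].nunique()
    bad = (
        report[report["fraction"] == "F1"]
        .groupby("peptide")["qvalue"]
        .apply(lambda q: (q > 0.01).sum() > n_samples / 2)
    )
    frac_bad = bad.mean()
    assert 0.1 < frac_bad < 0.35  # nominal 0.2 with binomial noise


def test_zero_loading_gives_uncorrelated_proteins():
    cfg = SimConfig(n_proteins=80, module_sizes=[30, 20], within_module_loading=0.0,
                    module_effects={}, peptide_mean_extra=2)
    report, truth = generate_peptide_report(cfg, seed=7)
    from protmod.quantify import quantify_report

    matrix, _ = quantify_report(report)
    logm = np.log2(matrix.to_numpy())
    corr = np.corrcoef(logm)
    off = np.abs(corr[np.triu_indices_from(corr, 1)])
    # sampling bound for n=26 samples: E|r| ~ 0.16 under independence
    assert off.mean() < 0.25


def test_within_module_correlation_exceeds_between(small_matrix):
    matrix, _, truth = small_matrix
    corr = np.abs(np.corrcoef(np.log2(matrix.to_numpy())))
    labels = np.array([truth.true_module_of.get(p) or "none" for p in matrix.index])
    i1 = np.where(labels == "M01")[0]
    i2 = np.where(labels == "M02")[0]
    within = corr[np.ix_(i1, i1)][np.triu_indices(len(i1), 1)]
    between = corr[np.ix_(i1, i2)]
    assert within.mean() > between.mean() + 0.3


class TestValidationStats:
    def setup_method(self):
        self.cfg = SimConfig(n_proteins=150, module_sizes=[50, 40],
                             module_effects={"M01": {"tau": 0.8}, "M02": {"tau": -0.8}},
                             peptide_mean_extra=2)

    def _truth(self, concordant):
        cfg = SimConfig(**{**self.cfg.to_dict(), "concordant_modules": concordant})
        _, truth = generate_peptide_report(cfg, seed=1)
        return cfg, truth

    def test_no_concordance_means_random_signs(self):
        cfg, truth = self._truth(())
        val = generate_validation_stats(truth, cfg, seed=2, dropout=0.0)
        planted = truth.members("M01") + truth.members("M02")
        signs_disc = np.array([np.sign(truth.true_effect[truth.true_module_of[p]]["tau"]) for p in planted])
        agree = (np.sign(val.loc[planted, "log2fc"]) == signs_disc).mean()
        assert 0.35 < agree < 0.65

    def test_full_concordance_replicates_signs_and_significance(self):
        cfg, truth = self._truth(("M01", "M02"))
        val = generate_validation_stats(truth, cfg, seed=2, dropout=0.0)
        planted = truth.members("M01") + truth.members("M02")
        signs_disc = np.array([np.sign(truth.true_effect[truth.true_module_of[p]]["tau"]) for p in planted])
        ok = (np.sign(val.loc[planted, "log2fc"]) == signs_disc) & (val.loc[planted, "pvalue"] < 0.1)
        assert ok.mean() >= 0.9

    def test_zero_dropout_keeps_the_protein_universe(self):
        cfg, truth = self._truth(("M01",))
        val = generate_validation_stats(truth, cfg, seed=2, dropout=0.0)
        assert set(val.index) == set(truth.true_module_of)

    def test_unknown_module_label_raises(self):
        cfg, truth = self._truth(("M01",))
        truth.concordant_modules = ("M99",)
        with pytest.raises(ValueError, match="M99"):
            generate_validation_stats(truth, cfg, seed=2)


class TestAnnotationSets:
    def test_full_alignment_reproduces_module_member_sets(self):
        cfg = SimConfig(n_proteins=100, module_sizes=[30, 20], peptide_mean_extra=2)
        _, truth = generate_peptide_report(cfg, seed=1)
        sets = generate_annotation_sets(truth, n_terms=2, alignment=1.0, seed=3, jitter=0.0)
        members = {frozenset(m) for _, m in sets.values()}
        assert frozenset(truth.members("M01")) in members
        assert frozenset(truth.members("M02")) in members

    def test_random_terms_overlap_at_hypergeometric_rate(self):
        cfg = SimConfig(n_proteins=400, module_sizes=[100], peptide_mean_extra=2)
        _, truth = generate_peptide_report(cfg, seed=1)
        sets = generate_annotation_sets(truth, n_terms=60, alignment=0.0, seed=3,
                                        random_set_size=(40, 41))
        module = set(truth.members("M01"))
        overlaps = [len(module & set(m)) for _, m in sets.values()]
        # closed-form mean overlap: |set| * |module| / N = 40 * 100 / 400
        assert np.mean(overlaps) == pytest.approx(10.0, abs=1.5)

    def test_zero_terms_raises(self):
        cfg = SimConfig(n_proteins=50, module_sizes=[20], peptide_mean_extra=2)
        _, truth = generate_peptide_report(cfg, seed=1)
        with pytest.raises(ValueError):
            generate_annotation_sets(truth, n_terms=0, alignment=0.5, seed=1)


class TestSpecificityInputs:
    def test_marker_panel_covers_the_seven_cns_classes(self):
        cfg = SimConfig(n_proteins=50, module_sizes=[20], peptide_mean_extra=2)
        expr, markers = generate_specificity_inputs(cfg, seed=1)
        assert set(markers) == {
            "astrocytes", "endothelial", "excitatory_neurons", "inhibitory_neurons",
            "microglia", "oligodendrocytes", "OPCs",
        }
        assert "SLC17A7" in markers["excitatory_neurons"]
        assert "AGT" in markers["astrocytes"]

    def test_full_dominance_confines_marker_expression(self):
        cfg = SimConfig(n_proteins=50, module_sizes=[20], peptide_mean_extra=2)
        expr, _ = generate_specificity_inputs(cfg, seed=1, dominance=1.0)
        row = expr.loc["MOBP"]
        assert row["oligodendrocytes"] > 0
        assert (row.drop("oligodendrocytes") == 0).all()

    def test_non_marker_genes_are_near_uniform(self):
        cfg = SimConfig(n_proteins=200, module_sizes=[20], celltype_modules={}, peptide_mean_extra=2)
        expr, _ = generate_specificity_inputs(cfg, seed=1)
        spec = expr.div(expr.sum(axis=1), axis=0)
        non_markers = [g for g in spec.index if not any(g in ms for ms in CNS_MARKERS.values())]
        assert np.allclose(spec.loc[non_markers].mean(axis=0), 1 / 7, atol=0.02)

    def test_proteome_markers_come_from_driven_modules(self):
        cfg = SimConfig(n_proteins=150, module_sizes=[50, 40],
                        celltype_modules={"M01": "astrocytes"}, peptide_mean_extra=2)
        _, truth = generate_peptide_report(cfg, seed=1)
        expr, _ = generate_specificity_inputs(cfg, seed=2, truth=truth)
        markers = proteome_markers(expr, list(truth.true_module_of), n_per_type=5)
        astro = set(markers["astrocytes"])
        m01 = set(truth.members("M01"))
        assert len(astro & m01) >= 4
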