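"""Reference evaluations of the pipeline on its synthetic study conditions.

Each function simulates the relevant inputs from a seed, runs the package's
own machinery, and measures a calibration, recovery or exactness quantity.
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import networkx as nx

from protmod.simulate import SimConfig, generate_peptide_report, generate_validation_stats
from protmod.quantify import quantify_report
from protmod.diffexp import beta_binomial_test, fit_bum, BetaUniformMixture
from protmod.coexpression import build_similarity, detect_modules
from protmod.enrichment import go_overrepresentation, gsea_preranked
from protmod.subnetworks import diffusion_matrix, find_hot_subnetworks
from protmod.gess import concordance_fraction, gess_score, validate_all_modules
from protmod.celltype import compute_specificity, ewce_bootstrap
from protmod.pipeline import PipelineConfig, run_pipeline

__all__ = [
    "gess_null_calibration",
    "gess_power",
    "concordance_exactness",
    "betabinomial_calibration",
    "bum_recovery",
    "module_recovery",
    "hotnet_evaluation",
    "enrichment_evaluation",
    "ewce_evaluation",
    "pipeline_determinism",
]


def _stats_cohorts(rng, n_univ=1700):
    """Statistics-level discovery (strongly dysregulated) and null validation."""
    prot = [f"P{i:04d}" for i in range(n_univ)]
    disc = pd.DataFrame(
        {"pvalue": rng.beta(0.05, 1.0, n_univ),
         "log2fc": rng.normal(0.6, 0.2, n_univ) * np.where(rng.random(n_univ) < 0.5, 1, -1)},
        index=prot,
    )
    val = pd.DataFrame(
        {"pvalue": rng.random(n_univ), "log2fc": rng.normal(0, 0.3, n_univ)},
        index=prot,
    )
    return prot, disc, val


def gess_null_calibration(seed: int, n_modules: int = 200, module_size: int = 50,
                          n_perm: int = 1000) -> float:
    """Fraction of random modules validated when the validation cohort is
    pure noise (signs random, p uniform)."""
    rng = np.random.default_rng(seed)
    prot, disc, val = _stats_cohorts(rng)
    validated = 0
    for m in range(n_modules):
        members = rng.choice(prot, size=module_size, replace=False)
        res = gess_score(members, disc, val, n_perm=n_perm, seed=int(rng.integers(2**31)))
        validated += int(res.validated)
    return validated / n_modules


def gess_power(seed: int, n_perm: int = 1000) -> dict:
    """Planted cross-cohort design: 13 dysregulated modules of which 9
    replicate; counts true and false validations."""
    cfg = SimConfig()
    labels = cfg.module_labels
    effects = cfg.default_effects(n_dysregulated=13)
    concordant = tuple(labels[:9])
    cfg = SimConfig(module_effects=effects, concordant_modules=concordant)
    _, truth = generate_peptide_report(cfg, seed=seed)

    # discovery statistics: every dysregulated module shows its effect
    dys = tuple(l for l in labels if effects[l].get(cfg.group_names[0]))
    truth_disc = dataclasses.replace(truth, concordant_modules=dys)
    disc = generate_validation_stats(truth_disc, cfg, seed=seed + 1, dropout=0.0)
    val = generate_validation_stats(truth, cfg, seed=seed + 2)

    assignment = pd.Series({p: truth.true_module_of[p] or "M00" for p in truth.true_module_of})
    table = validate_all_modules(assignment, disc, {"validation": val},
                                 n_perm=n_perm, seed=seed + 3)
    flagged = set(table.loc[table["validated"], "module"])
    return {
        "true_validated": len(flagged & set(concordant)),
        "false_validated": len(flagged - set(concordant)),
        "n_concordant": len(concordant),
        "n_modules": len(labels),
    }


def concordance_exactness(seed: int, n_tables: int = 1000) -> dict:
    """Hand-computable 4-protein fractions plus monotonicity-in-threshold
    violations over random statistic tables."""
    disc = pd.DataFrame({"pvalue": [0.05, 0.05, 0.01, 0.9], "log2fc": [1.0] * 4},
                        index=list("ABCD"))
    val = pd.DataFrame({"pvalue": [0.08, 0.2, 0.01, 0.9], "log2fc": [1.0, 1.0, -1.0, 1.0]},
                       index=list("ABCD"))
    f_01 = concordance_fraction(list("ABCD"), disc, val, 0.1)
    f_05 = concordance_fraction(list("ABCD"), disc, val, 0.5)

    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_tables):
        n = int(rng.integers(5, 40))
        idx = [f"P{i}" for i in range(n)]
        d = pd.DataFrame({"pvalue": rng.random(n), "log2fc": rng.normal(size=n)}, index=idx)
        v = pd.DataFrame({"pvalue": rng.random(n), "log2fc": rng.normal(size=n)}, index=idx)
        fs = [concordance_fraction(idx, d, v, t) for t in (0.1, 0.2, 0.5, 0.8)]
        violations += int(any(a > b for a, b in zip(fs, fs[1:])))
    return {"f_at_0.1": f_01, "f_at_0.5": f_05, "monotonicity_violations": violations,
            "n_tables": n_tables}


def betabinomial_calibration(seed: int, n_null: int = 1000) -> dict:
    """Type-I error on a null cohort and log2FC sign recovery for planted
    2-fold shifts (case n=6 vs control n=5)."""
    null_cfg = SimConfig(n_proteins=n_null, module_sizes=[10], module_effects={},
                         peptide_mean_extra=3)
    report, _ = generate_peptide_report(null_cfg, seed=seed)
    matrix, groups = quantify_report(report)
    res = beta_binomial_test(matrix, groups, ("tau", "control"))
    type1 = float((res["pvalue"] < 0.05).mean())

    shift_cfg = SimConfig(n_proteins=300, module_sizes=[100],
                          module_effects={"M01": {"tau": 1.0}},
                          peptide_mean_extra=3, noise_sd=0.15)
    report2, truth2 = generate_peptide_report(shift_cfg, seed=seed + 1)
    m2, g2 = quantify_report(report2)
    res2 = beta_binomial_test(m2, g2, ("tau", "control"))
    planted = [p for p in truth2.members("M01") if p in res2.index]
    sign_ok = float((res2.loc[planted, "log2fc"] > 0).mean())
    return {"type1_at_0.05": type1, "sign_recovery": sign_ok,
            "n_null": n_null, "n_planted": len(planted)}


def bum_recovery(seed: int, lam: float = 0.6, a: float = 0.3, n: int = 5000) -> dict:
    """Mixture parameter recovery and the two FDR-threshold routes."""
    rng = np.random.default_rng(seed)
    uniform = rng.random(n) < lam
    p = np.clip(np.where(uniform, rng.random(n), rng.beta(a, 1.0, size=n)), 1e-12, 1.0)
    fit = fit_bum(p)
    taus = [fit.fdr_threshold(f) for f in (0.05, 0.1, 0.2)]
    exact = BetaUniformMixture()
    exact.lambda_, exact.a_ = lam, a
    exact.pi_ub_ = lam + (1 - lam) * a
    dual_gap = max(abs(exact.fdr_threshold(f) - exact.fdr_threshold(f, method="root"))
                   for f in (0.01, 0.05, 0.1, 0.3))
    return {"lambda_hat": fit.lambda_, "a_hat": fit.a_,
            "lambda_error": abs(fit.lambda_ - lam), "a_error": abs(fit.a_ - a),
            "threshold_monotone": bool(taus[0] <= taus[1] <= taus[2]),
            "closed_form_vs_root_gap": float(dual_gap), "n": n}


def module_recovery(seed: int) -> dict:
    """Full peptide-level run of the 17-module study configuration."""
    from sklearn.metrics import adjusted_rand_score

    cfg = SimConfig()
    report, truth = generate_peptide_report(cfg, seed=seed)
    matrix, _ = quantify_report(report)
    assignment = detect_modules(build_similarity(matrix, soft_power=7), min_size=15)
    labels_true = [truth.true_module_of[p] or "M00" for p in matrix.index]
    return {"ari": float(adjusted_rand_score(labels_true, assignment.values)),
            "n_detected": len(set(assignment) - {"M00"}),
            "n_planted": len(cfg.module_sizes),
            "similarity_entry_0.8^7": 0.8**7}


def _chain_module(seed: int, n: int = 40, chain_len: int = 6):
    """A noise-module correlation graph with a planted hot chain: random
    spanning tree plus sparse chance edges, chain members strongly
    significant."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        g.add_edge(int(order[i]), int(order[rng.integers(0, i)]),
                   weight=float(rng.uniform(0.5, 0.9)))
    for _ in range(n // 2):
        u, v = rng.integers(0, n, 2)
        if u != v:
            g.add_edge(int(u), int(v), weight=float(rng.uniform(0.5, 0.9)))
    chain = list(range(chain_len))
    for a, b in zip(chain, chain[1:]):
        g.add_edge(a, b, weight=0.9)
    p = np.concatenate([10 ** rng.uniform(-6, -3, chain_len),
                        rng.uniform(0.05, 1, n - chain_len)])
    scores = pd.Series(np.minimum(-np.log10(p), 16.0), index=list(g.nodes))
    return g, scores, set(chain)


def hotnet_evaluation(seed: int, n_replicates: int = 20) -> dict:
    """Closed-form diffusion check plus planted-chain recovery rate."""
    g2 = nx.Graph()
    g2.add_edge("A", "B", weight=1.0)
    F = diffusion_matrix(g2, beta=0.5).to_numpy()
    diffusion_error = float(np.abs(F - np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])).max())

    recovered = 0
    for r in range(n_replicates):
        g, scores, chain = _chain_module(seed + r)
        res = find_hot_subnetworks(g, scores, beta=0.5, n_perm=100, seed=seed + r)
        if res.subnetworks:
            top = set(res.subnetworks[0])
            jac = len(top & chain) / len(top | chain)
            recovered += int(jac >= 0.8)
    return {"diffusion_2node_max_error": diffusion_error,
            "chain_recovery_rate": recovered / n_replicates,
            "n_replicates": n_replicates}


def enrichment_evaluation(seed: int, n_random_sets: int = 200) -> dict:
    """Exact ORA toy, the worked GSEA running-sum example, and the null NES
    magnitude of random gene sets."""
    ora = go_overrepresentation({"A", "B"}, {"T": ("", ["A", "B"])}, {"A", "B", "C", "D"})
    ora_p = float(ora.loc["T", "p_raw"])

    ranking = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("abcde"))
    es_toy = float(gsea_preranked(ranking, {"S": ("", ["a", "c"])},
                                  n_perm=100, min_set=2, seed=seed).loc["S", "es"])

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(1000)]
    big_ranking = pd.Series(rng.normal(size=1000), index=genes)
    sets = {f"R{i:03d}": ("", list(rng.choice(genes, size=20, replace=False)))
            for i in range(n_random_sets)}
    table = gsea_preranked(big_ranking, sets, n_perm=200, seed=seed + 1)
    mean_abs_nes = float(table["nes"].abs().mean())
    return {"ora_toy_p": ora_p, "es_toy": es_toy, "mean_abs_nes": mean_abs_nes,
            "n_random_sets": n_random_sets}


def ewce_evaluation(seed: int, n_boot: int = 20000) -> dict:
    """Bootstrap p against exhaustive enumeration on an 8-gene background,
    plus the specificity row-sum contract."""
    import itertools

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(8)]
    expr = pd.DataFrame(rng.uniform(0.5, 5.0, size=(8, 3)), index=genes,
                        columns=["astro", "endo", "micro"])
    spec = compute_specificity(expr)
    row_sum_dev = float(np.abs(spec.sum(axis=1) - 1.0).max())

    target = ["g0", "g3"]
    res = ewce_bootstrap(target, spec, genes, n_boot=n_boot, seed=seed)
    obs = spec.loc[target].mean(axis=0)
    max_gap = 0.0
    for c in spec.columns:
        means = [spec.loc[list(pair), c].mean() for pair in itertools.combinations(genes, 2)]
        exact = float(np.mean([m >= obs[c] for m in means]))
        max_gap = max(max_gap, abs(float(res.loc[c, "p"]) - exact))
    return {"bootstrap_vs_exact_max_gap": max_gap, "specificity_row_sum_dev": row_sum_dev,
            "n_boot": n_boot}


def pipeline_determinism(seed: int) -> dict:
    """Run the reduced-scale pipeline twice; byte-compare all artifacts."""
    import tempfile
    from pathlib import Path

    sim = SimConfig(n_proteins=400, module_sizes=[60, 45, 35, 30, 25, 20, 18, 15],
                    peptide_mean_extra=3)
    cfg = PipelineConfig(seed=seed, simulate=sim, gess_n_perm=200, n_boot=2000,
                         hotnet_n_perm=30)
    with tempfile.TemporaryDirectory() as tmp:
        r1 = run_pipeline(cfg, Path(tmp) / "a")
        r2 = run_pipeline(cfg, Path(tmp) / "b")
    return {"identical": r1["artifacts"] == r2["artifacts"],
            "runtime_s": r1["runtime_s"],
            "modules_found": r1["counts"]["modules_found"],
            "n_artifacts": len(r1["artifacts"])}
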