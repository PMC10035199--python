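"""Functional annotation: hypergeometric over-representation of module member
lists and preranked GSEA of contrast rankings.

The GSEA enrichment score is the extremum of the weighted Kolmogorov-Smirnov
running sum over the ranking (hit steps proportional to |score|^weight over
the set, miss steps 1/(N - Nh)); the null is random same-size gene sets, the
standard preranked convention.  NES divides ES by the mean magnitude of
same-sign permuted scores.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["go_overrepresentation", "enrichment_score", "gsea_preranked"]


def go_overrepresentation(
    module_members: Iterable[str],
    collection: Mapping[str, tuple[str, list[str]]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail test per term, on the annotated
    background only, BH-corrected across terms."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(module_members) & background
    if not set(module_members) <= background:
        raise ValueError("module members must be a subset of the background")
    rows = []
    for name, (desc, members) in collection.items():
        term = set(members) & background
        overlap = len(term & query)
        p = stats.hypergeom.sf(overlap - 1, len(background), len(term), len(query))
        rows.append(
            {"term": name, "description": desc, "overlap": overlap, "term_size": len(term),
             "query_size": len(query), "background_size": len(background), "p_raw": float(p)}
        )
    table = pd.DataFrame(rows).set_index("term")
    if len(table):
        table["p_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table.sort_values("p_raw")


def _ordered_ranking(ranking: pd.Series) -> pd.Series:
    # descending score, ties broken by token order for determinism
    order = sorted(zip(-ranking.to_numpy(), ranking.index))
    return pd.Series([-s for s, _ in order], index=[t for _, t in order])


def enrichment_score(scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """Signed maximum deviation of the running sum for one set.

    ``scores`` must already be sorted in descending order; ``hit_mask`` marks
    set members at their rank positions.
    """
    n = len(scores)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores are exactly zero: fall back to equal steps
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranking: pd.Series,
    collection: Mapping[str, tuple[str, list[str]]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_set: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Returns a table per retained term with ES, NES, nominal p, and FDR q
    (positive/negative-pool procedure).  Sets outside the ranking universe or
    smaller than ``min_set`` after intersection (or covering the whole
    universe) are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    ordered = _ordered_ranking(ranking)
    tokens = list(ordered.index)
    pos_of = {t: i for i, t in enumerate(tokens)}
    scores = ordered.to_numpy(dtype=float)
    n = len(tokens)

    retained: dict[str, np.ndarray] = {}
    for name, (_, members) in collection.items():
        idx = np.array(sorted({pos_of[m] for m in members if m in pos_of}), dtype=int)
        if len(idx) < min_set or len(idx) >= n:
            warnings.warn(f"gene set {name!r} skipped (size {len(idx)} of universe {n})", stacklevel=2)
            continue
        retained[name] = idx
    if not retained:
        return pd.DataFrame(columns=["es", "nes", "size", "p_nominal", "fdr_q"])

    def es_of(idx: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        return enrichment_score(scores, mask, weight=weight)

    obs = {name: es_of(idx) for name, idx in retained.items()}

    sizes = sorted({len(idx) for idx in retained.values()})
    perm_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            es_perm[b] = es_of(rng.choice(n, size=k, replace=False))
        perm_by_size[k] = es_perm

    rows = []
    all_perm_nes: list[np.ndarray] = []
    for name, idx in retained.items():
        es = obs[name]
        perm = perm_by_size[len(idx)]
        pos_mean = perm[perm > 0].mean() if (perm > 0).any() else np.nan
        neg_mean = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        same = perm[perm >= 0] if es >= 0 else perm[perm < 0]
        extreme = (same >= es).sum() if es >= 0 else (same <= es).sum()
        p_nom = (1 + extreme) / (1 + len(same)) if len(same) else 1.0
        perm_nes = np.where(perm >= 0, perm / pos_mean if pos_mean else np.nan,
                            perm / neg_mean if neg_mean else np.nan)
        all_perm_nes.append(perm_nes[np.isfinite(perm_nes)])
        rows.append({"term": name, "es": es, "nes": nes, "size": len(idx), "p_nominal": p_nom})
    table = pd.DataFrame(rows).set_index("term")

    pool = np.concatenate(all_perm_nes) if all_perm_nes else np.array([])
    obs_nes = table["nes"].to_numpy()
    qs = np.ones(len(table))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (pool >= nes).mean() / max((pool >= 0).mean(), 1e-12)
            den = (obs_nes[np.isfinite(obs_nes)] >= nes).mean() / max(
                (obs_nes[np.isfinite(obs_nes)] >= 0).mean(), 1e-12)
        else:
            num = (pool <= nes).mean() / max((pool < 0).mean(), 1e-12)
            den = (obs_nes[np.isfinite(obs_nes)] <= nes).mean() / max(
                (obs_nes[np.isfinite(obs_nes)] < 0).mean(), 1e-12)
        qs[i] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr_q"] = qs
    return table.sort_values("p_nominal")
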