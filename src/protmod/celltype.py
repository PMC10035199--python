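"""Expression-weighted cell-type enrichment (EWCE) and directional marker
summaries of module fold changes.

Specificity of a gene for a cell type is the share of the gene's total mean
expression attributable to that type (rows sum to 1).  A target list's mean
specificity per cell type is compared against 20,000 bootstrap lists of the
same size drawn uniformly (without replacement) from the quantified-protein
background; significance is the bootstrap z-score and the empirical p-value
(1 + k) / (1 + n).  The directional summary asks, per cell type, whether its
markers inside a module have systematically higher or lower log2FC than the
other module members (rank-sum test, BH across cell types).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compute_specificity", "ewce_bootstrap", "marker_direction_enrichment"]


def compute_specificity(expression: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a gene x cell-type mean-expression table.

    All-zero genes are dropped with a warning; negative entries are an error.
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    totals = expression.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} gene(s) with zero total expression", stacklevel=2)
        expression = expression.loc[~zero]
        totals = totals[~zero]
    return expression.div(totals, axis=0)


def ewce_bootstrap(
    target: Iterable[str],
    specificity: pd.DataFrame,
    background: Iterable[str],
    n_boot: int = 20000,
    seed: int = 0,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Bootstrap cell-type enrichment of a gene list.

    Returns a table per cell type with the observed mean specificity, the
    bootstrap mean and sd, z = (observed - mean) / sd, and the empirical
    p-value.  Deterministic given the seed; invariant to the order of a
    duplicate-free target list.
    """
    target = sorted(set(target))
    if not target:
        raise ValueError("empty target list")
    background = sorted(set(background))
    if not set(target) <= set(background):
        raise ValueError("target must be a subset of the background")
    if not set(background) <= set(specificity.index):
        raise ValueError("background must be covered by the specificity matrix")
    rng = np.random.default_rng(seed)

    spec_bg = specificity.loc[background].to_numpy()
    n_bg, k = spec_bg.shape
    size = len(target)
    obs = specificity.loc[target].mean(axis=0).to_numpy()

    boot_sum = np.zeros(k)
    boot_sumsq = np.zeros(k)
    ge_count = np.zeros(k, dtype=np.int64)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.random((b, n_bg)).argpartition(size - 1, axis=1)[:, :size]
        means = spec_bg[idx].mean(axis=1)  # (b, k)
        boot_sum += means.sum(axis=0)
        boot_sumsq += (means**2).sum(axis=0)
        ge_count += (means >= obs[np.newaxis, :]).sum(axis=0)
        done += b

    mean = boot_sum / n_boot
    var = boot_sumsq / n_boot - mean**2
    sd = np.sqrt(np.maximum(var, 0.0) * n_boot / max(n_boot - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    p = (1 + ge_count) / (1 + n_boot)
    return pd.DataFrame(
        {"observed": obs, "boot_mean": mean, "boot_sd": sd, "z": z, "p": p, "n_boot": n_boot},
        index=pd.Index(specificity.columns, name="cell_type"),
    )


def marker_direction_enrichment(
    module_members: Iterable[str],
    contrast: pd.DataFrame,
    markers: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per cell type: are its markers' log2FCs inside the module shifted up
    or down relative to the other module members?

    Direction compares marker vs non-marker medians; the two-sided p is a
    Wilcoxon rank-sum test, BH-corrected across cell types.  Cell types with
    no marker in the module are skipped; a single-marker cell type is
    reported but flagged low-power.
    """
    members = [m for m in module_members if m in contrast.index]
    fc = contrast.loc[members, "log2fc"]
    rows = []
    for ct, ms in markers.items():
        in_mod = sorted(set(ms) & set(members))
        if not in_mod:
            continue
        rest = fc.drop(index=in_mod)
        if len(rest) == 0:
            continue
        mfc = fc.loc[in_mod]
        stat, p = stats.mannwhitneyu(mfc, rest, alternative="two-sided")
        rows.append({"cell_type": ct, "n_markers": len(in_mod),
                     "direction": "up" if mfc.median() > rest.median() else "down",
                     "marker_median": float(mfc.median()), "rest_median": float(rest.median()),
                     "p_raw": float(p), "low_power": len(in_mod) < 3})
    if not rows:
        warnings.warn("no cell-type marker present in the module", stacklevel=2)
        return pd.DataFrame(columns=["cell_type", "n_markers", "direction", "marker_median",
                                     "rest_median", "p_raw", "p_bh", "low_power"]).set_index("cell_type")
    table = pd.DataFrame(rows).set_index("cell_type")
    table["p_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table
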