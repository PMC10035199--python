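"""Peptide report -> normalized protein x sample abundance matrix.

The rollup convention: within each fraction, drop peptides whose Q-value
exceeds 0.01 in more than half the samples; sum a peptide's abundance over
fractions; quantify each protein as the sum of its top-5 overall most
abundant peptides (the same peptide set for every sample); scale each sample
so all totals are equal.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "filter_peptides",
    "combine_fractions",
    "rollup_proteins",
    "normalize_total",
    "quantify_report",
]


def filter_peptides(report: pd.DataFrame, q_max: float = 0.01, sample_fraction: float = 0.5) -> pd.DataFrame:
    """Drop a peptide (within its fraction) when its Q-value exceeds ``q_max``
    in strictly more than ``sample_fraction`` of the samples."""
    if not (0 < q_max < 1 and 0 < sample_fraction < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if report.empty:
        warnings.warn("empty peptide report", stacklevel=2)
        return report.copy()
    n_samples = report["sample"].nunique()
    cutoff = sample_fraction * n_samples
    bad_counts = (
        report.assign(bad=report["qvalue"] > q_max)
        .groupby(["fraction", "peptide"], sort=False)["bad"]
        .sum()
    )
    discard = set(bad_counts[bad_counts > cutoff].index)
    if not discard:
        return report.copy()
    keys = list(zip(report["fraction"], report["peptide"]))
    keep = np.array([k not in discard for k in keys])
    return report.loc[keep].reset_index(drop=True)


def combine_fractions(report: pd.DataFrame) -> pd.DataFrame:
    """Sum same-peptide abundance over fractions; one row per (sample, peptide)."""
    mapping = report.groupby("peptide")["protein"].nunique()
    ambiguous = mapping[mapping > 1]
    if len(ambiguous):
        raise ValueError(f"peptides mapped to multiple proteins: {list(ambiguous.index[:5])}")
    combined = (
        report.groupby(["sample", "group", "peptide", "protein"], sort=False, as_index=False)["abundance"]
        .sum()
    )
    return combined


def rollup_proteins(peptide_table: pd.DataFrame, top_k: int = 5) -> tuple[pd.DataFrame, dict[str, str]]:
    """Protein abundance = per-sample sum of the protein's ``top_k`` peptides,
    ranked by total abundance over all samples (ties broken by peptide id).

    Peptides absent from a sample contribute 0.  Returns the protein x sample
    matrix and the sample -> group map.
    """
    totals = (
        peptide_table.groupby(["protein", "peptide"], sort=False)["abundance"]
        .sum()
        .reset_index()
        .sort_values(["protein", "abundance", "peptide"], ascending=[True, False, True])
    )
    selected = totals.groupby("protein", sort=False).head(top_k)
    chosen = set(zip(selected["protein"], selected["peptide"]))
    keep = np.array([k in chosen for k in zip(peptide_table["protein"], peptide_table["peptide"])])
    wide = (
        peptide_table.loc[keep]
        .pivot_table(index="protein", columns="sample", values="abundance", aggfunc="sum", fill_value=0.0)
    )
    groups = dict(zip(peptide_table["sample"], peptide_table["group"]))
    wide = wide[sorted(wide.columns)].sort_index()
    wide.columns.name = None
    return wide, groups


def normalize_total(matrix: pd.DataFrame, target: float | str = "mean") -> pd.DataFrame:
    """Rescale each sample column so totals are equal (default: the mean of
    the input totals); relative abundances within a sample are preserved."""
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    t = float(totals.mean()) if target == "mean" else float(target)
    return matrix * (t / totals)


def quantify_report(
    report: pd.DataFrame,
    q_max: float = 0.01,
    sample_fraction: float = 0.5,
    top_k: int = 5,
    target: float | str = "mean",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Full chain: filter -> combine fractions -> top-k rollup -> normalize."""
    filtered = filter_peptides(report, q_max=q_max, sample_fraction=sample_fraction)
    combined = combine_fractions(filtered)
    matrix, groups = rollup_proteins(combined, top_k=top_k)
    return normalize_total(matrix, target=target), groups
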