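"""Weighted co-expression modules of proteins.

Similarity between proteins is |Pearson r| raised to a soft power (default 7,
selectable by a scale-free-topology criterion).  Modules are branches of an
average-linkage tree over 1 - similarity, extracted with an adaptive
dynamic-tree-cut: a branch qualifies as a module when it is large enough,
internally tight (low core scatter) and well separated from the rest of the
dendrogram (large gap between its joining height and its core scatter).
Detected modules are labelled M01, M02, ... by decreasing size; proteins in
no qualifying branch are collected in M00.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pick_soft_threshold",
    "scale_free_fit_index",
    "build_similarity",
    "ModuleDetector",
    "detect_modules",
    "test_module_dysregulation",
]

# deep_split level -> maximum relative core scatter of a qualifying branch
# (the minimum relative gap is 3/4 of the complement).  Higher levels split
# more aggressively into smaller, looser modules.
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


def scale_free_fit_index(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Bins log10(k), regresses log10(bin frequency) on mean log10(k) per bin and
    returns ``(-sign(slope) * R^2, slope)`` — the scale-free topology fit
    index, penalising a positive slope.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins or np.allclose(k, k[0]):
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        xs.append(logk[m].mean())
        ys.append(np.log10(m.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 13)),
    fit_min: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit index reaches ``fit_min``; if none
    does, the power with the maximal index (with a warning).

    Returns the chosen power and the per-power diagnostic table
    (power, fit_index, slope, mean_connectivity).
    """
    if len(matrix) < 30:
        raise ValueError("need at least 30 proteins to assess scale-free fit")
    corr = np.abs(np.corrcoef(matrix.to_numpy()))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in powers:
        k = (corr**beta).sum(axis=1)
        if np.allclose(k, k[0]):
            warnings.warn("degenerate connectivity; returning smallest power", stacklevel=2)
            return int(powers[0]), pd.DataFrame(rows)
        fit, slope = scale_free_fit_index(k)
        rows.append({"power": beta, "fit_index": fit, "slope": slope, "mean_connectivity": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[table["fit_index"] >= fit_min]
    if len(ok):
        return int(ok["power"].iloc[0]), table
    warnings.warn("no power reaches the scale-free fit target; using argmax", stacklevel=2)
    return int(table.loc[table["fit_index"].idxmax(), "power"]), table


def build_similarity(matrix: pd.DataFrame, soft_power: int = 7, log_transform: bool = True) -> pd.DataFrame:
    """s_ij = |pearson(x_i, x_j)|^soft_power with unit diagonal.

    By default abundances are log2-transformed first (intensities are
    lognormal-ish and heavy tails make the linear-scale Pearson estimate
    unstable at cohort-scale n); pass ``log_transform=False`` to correlate
    raw abundances.  Zero-variance proteins get similarity 0 to everything
    (they carry no co-expression signal); a warning says how many.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    data = matrix.to_numpy()
    if log_transform:
        if (data < 0).any():
            raise ValueError("negative abundances cannot be log-transformed")
        data = np.log2(data + 1.0)
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance protein(s); similarity set to 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data)
    corr[~np.isfinite(corr)] = 0.0
    sim = np.abs(corr) ** soft_power
    np.fill_diagonal(sim, 1.0)
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def _branch_stats(Z: np.ndarray, n: int) -> tuple[list[list[int]], np.ndarray, np.ndarray]:
    """Leaves, merge height and mean internal merge height for every internal
    node of a scipy linkage matrix."""
    leaves: list[list[int]] = [[i] for i in range(n)]
    heights = np.zeros(2 * n - 1)
    scatter = np.zeros(2 * n - 1)  # mean height of merges inside the subtree
    n_merges = np.zeros(2 * n - 1)
    sum_heights = np.zeros(2 * n - 1)
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + m
        leaves.append(leaves[a] + leaves[b])
        heights[node] = h
        sum_heights[node] = sum_heights[a] + sum_heights[b] + h
        n_merges[node] = n_merges[a] + n_merges[b] + 1
        scatter[node] = sum_heights[node] / n_merges[node]
    return leaves, heights, scatter


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Dynamic-tree-cut clustering of a protein similarity matrix.

    Parameters
    ----------
    min_size:
        Smallest branch accepted as a module.
    deep_split:
        0..4; controls how tight and well separated a branch must be
        (higher = more, smaller modules).
    cut_height_quantile:
        Static cut as a fraction of the tallest merge; branches joining above
        it are never merged into one module.

    Attributes after :meth:`fit`: ``labels_`` (module token per protein,
    ``M00`` for unassigned), ``linkage_``, ``module_sizes_``.
    """

    def __init__(self, min_size: int = 15, deep_split: int = 2, cut_height_quantile: float = 0.99):
        self.min_size = min_size
        self.deep_split = deep_split
        self.cut_height_quantile = cut_height_quantile

    def fit(self, similarity: pd.DataFrame, y=None) -> "ModuleDetector":
        sim = similarity.to_numpy() if isinstance(similarity, pd.DataFrame) else np.asarray(similarity)
        ids = list(similarity.index) if isinstance(similarity, pd.DataFrame) else list(range(len(sim)))
        n = len(sim)
        if self.min_size > n:
            warnings.warn("min_size exceeds the number of proteins; everything unassigned", stacklevel=2)
            self.labels_ = np.array(["M00"] * n)
            self.module_sizes_ = {}
            self.linkage_ = None
            return self
        dissim = np.clip(1.0 - sim, 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        Z = hierarchy.average(squareform(dissim, checks=False))
        self.linkage_ = Z

        leaves, heights, scatter = _branch_stats(Z, n)
        cut_height = self.cut_height_quantile * Z[:, 2].max()
        merge_h = Z[:, 2]
        h_lo = np.quantile(merge_h, 0.05)
        h_range = max(cut_height - h_lo, 1e-12)
        mcs = _MAX_CORE_SCATTER[int(self.deep_split)]
        max_scatter = h_lo + mcs * h_range
        min_gap = (1.0 - mcs) * 1.5 * h_range

        # joining height of every node (height of its parent's merge)
        join = np.full(2 * n - 1, cut_height)
        for m, (a, b, h, _) in enumerate(Z):
            join[int(a)] = h
            join[int(b)] = h

        def qualifies(node: int, at_height: float) -> bool:
            # a branch stands on its own when it is big enough, internally
            # tight, and separated from whatever it merges with by a clear gap
            return (
                len(leaves[node]) >= self.min_size
                and scatter[node] <= max_scatter
                and (at_height - scatter[node]) >= min_gap
            )

        # bottom-up, in merge order: two branches are kept apart only when
        # BOTH qualify at the height where they meet; otherwise they fuse and
        # keep growing.  Merges above the static cut never happen, so loose
        # material chaining onto a module stays unassigned.
        modules: list[list[int]] = []
        dead = np.zeros(2 * n - 1, dtype=bool)  # content already settled
        for m in range(n - 1):
            a, b, h = int(Z[m, 0]), int(Z[m, 1]), Z[m, 2]
            node = n + m
            if h > cut_height:
                dead[node] = True
                for child in (a, b):
                    if not dead[child] and qualifies(child, cut_height):
                        modules.append(leaves[child])
                continue
            if dead[a] or dead[b]:
                dead[node] = True
                for child in (a, b):
                    if not dead[child] and qualifies(child, h):
                        modules.append(leaves[child])
                continue
            qa, qb = qualifies(a, h), qualifies(b, h)
            if qa and qb:
                modules.append(leaves[a])
                modules.append(leaves[b])
                dead[node] = True
        root = 2 * n - 2
        if not dead[root] and qualifies(root, cut_height):
            modules.append(leaves[root])

        modules.sort(key=lambda mem: (-len(mem), min(mem)))
        labels = np.array(["M00"] * n, dtype=object)
        sizes: dict[str, int] = {}
        for i, mem in enumerate(modules):
            lab = f"M{i + 1:02d}"
            labels[mem] = lab
            sizes[lab] = len(mem)
        self.labels_ = labels
        self.module_sizes_ = sizes
        self.protein_ids_ = ids
        return self

    def fit_predict(self, similarity, y=None):
        return self.fit(similarity).labels_


def detect_modules(similarity: pd.DataFrame, min_size: int = 15, deep_split: int = 2) -> pd.Series:
    """Protein -> module label (M01.. by decreasing size, M00 unassigned)."""
    det = ModuleDetector(min_size=min_size, deep_split=deep_split).fit(similarity)
    return pd.Series(det.labels_, index=similarity.index, name="module")


def test_module_dysregulation(assignment: pd.Series, contrast: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-test of each module's member log2FC distribution against
    zero, BH-corrected across modules (M00 excluded).

    Returns a table indexed by module with mean_log2fc, t_statistic, p_raw,
    p_bh and the ``dysregulated`` flag (p_bh < alpha).
    """
    rows = []
    modules = sorted(set(assignment) - {"M00"})
    for lab in modules:
        members = assignment.index[assignment == lab]
        fc = contrast["log2fc"].reindex(members).dropna().to_numpy()
        if len(fc) < 3 or np.allclose(fc, fc[0] if len(fc) else 0.0):
            rows.append({"module": lab, "n": len(fc), "mean_log2fc": float(np.mean(fc)) if len(fc) else np.nan,
                         "t_statistic": np.nan, "p_raw": 1.0, "flagged": True})
            continue
        t, p = stats.ttest_1samp(fc, 0.0)
        rows.append({"module": lab, "n": len(fc), "mean_log2fc": float(fc.mean()),
                     "t_statistic": float(t), "p_raw": float(p), "flagged": False})
    table = pd.DataFrame(rows).set_index("module")
    if len(table):
        table["p_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
        table["dysregulated"] = table["p_bh"] < alpha
    return table
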