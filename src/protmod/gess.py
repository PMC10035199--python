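"""Cross-cohort module validation via the gene-expression-set-similarity
(GESS) permutation statistic.

For a module m and p-value threshold t, the concordance fraction is

    F_{m,t} = #{P in m : p_{P,d} < t and p_{P,v} < t
                         and log2FC_{P,d} * log2FC_{P,v} > 0} / N_m,

the fraction of member proteins significant below t in both the discovery
and validation cohorts with the same fold-change direction.  Validation
(p, log2FC) pairs are then reassigned to protein labels by uniform random
permutation over the shared protein universe (1000 times by default) and
F_{m,t} recomputed; at each threshold in {0.1, 0.2, 0.5, 0.8} a one-sided
p-value asks whether the observed F exceeds the permuted ones.  The GESS
score is the mean of the four per-threshold p-values; a module is validated
when GESS < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["concordance_fraction", "gess_score", "validate_all_modules", "GessResult"]

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.5, 0.8)


def _align(module_members, discovery: pd.DataFrame, validation: pd.DataFrame, missing: str = "exclude"):
    """Member stats aligned across cohorts.

    ``missing='exclude'`` drops proteins absent from either cohort from both
    the numerator and N_m (the default, matching partially overlapping
    protein universes); ``missing='fail'`` keeps them in N_m as automatic
    non-concordances.
    """
    members = sorted(set(module_members))
    if not members:
        raise ValueError("empty module")
    present = [m for m in members if m in discovery.index and m in validation.index]
    if missing == "exclude":
        n_m = len(present)
    elif missing == "fail":
        n_m = len(members)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    if n_m == 0:
        raise ValueError("no module member present in both cohorts")
    d = discovery.loc[present]
    v = validation.loc[present]
    return (
        d["pvalue"].to_numpy(), np.sign(d["log2fc"].to_numpy()),
        v["pvalue"].to_numpy(), v["log2fc"].to_numpy(), n_m, present,
    )


def concordance_fraction(module_members, discovery: pd.DataFrame, validation: pd.DataFrame,
                         t: float, missing: str = "exclude") -> float:
    """Exact evaluation of F_{m,t} (strict inequalities; a zero log2FC in
    either cohort counts as non-concordant)."""
    p_d, sign_d, p_v, fc_v, n_m, _ = _align(module_members, discovery, validation, missing)
    hits = (p_d < t) & (p_v < t) & (sign_d * fc_v > 0)
    return float(hits.sum() / n_m)


@dataclass
class GessResult:
    module: str
    n_m: int
    n_perm: int
    thresholds: tuple[float, ...]
    fractions: dict[float, float]
    p_per_threshold: dict[float, float]
    gess: float
    validated: bool
    fraction_same_direction: float
    permuted_fractions: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        row: dict = {"module": self.module, "n_m": self.n_m, "n_perm": self.n_perm,
                     "gess": self.gess, "validated": self.validated,
                     "fraction_same_direction": self.fraction_same_direction}
        for t in self.thresholds:
            row[f"F@{t}"] = self.fractions[t]
            row[f"p@{t}"] = self.p_per_threshold[t]
        return row


def _one_sided_p(f_obs: float, f_perm: np.ndarray, mode: str, n_perm: int) -> float:
    if mode == "empirical":
        return float((1 + (f_perm >= f_obs).sum()) / (1 + n_perm))
    if mode != "ttest":
        raise ValueError(f"unknown mode {mode!r}")
    sd = f_perm.std(ddof=1)
    if sd == 0:  # degenerate permutation sample: fall back to the empirical rule
        return float((1 + (f_perm >= f_obs).sum()) / (1 + n_perm))
    t_stat = (f_obs - f_perm.mean()) / (sd / np.sqrt(len(f_perm)))
    return float(stats.t.sf(t_stat, df=len(f_perm) - 1))


def gess_score(
    module_members,
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "empirical",
    missing: str = "exclude",
    module_label: str = "",
    alpha: float = 0.05,
) -> GessResult:
    """GESS for one module against one validation cohort.

    ``mode='empirical'`` (default) scores each threshold with the standard
    permutation p-value (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    ``mode='ttest'`` instead applies a one-sample one-sided t-test of the
    permuted fractions against the observed value; note its standard error
    shrinks with n_perm, so it anti-conservatively flags any module whose
    observed F merely exceeds the permutation mean (kept as the literal
    reading of the published procedure).
    """
    if not all(0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)

    p_d, sign_d, p_v_mem, fc_v_mem, n_m, present = _align(module_members, discovery, validation, missing)
    universe = validation.index.intersection(discovery.index)
    p_v_all = validation.loc[universe, "pvalue"].to_numpy()
    fc_v_all = validation.loc[universe, "log2fc"].to_numpy()
    n_univ = len(universe)
    n_mem = len(present)

    frac_same = float((sign_d * fc_v_mem > 0).mean())
    fractions = {t: float(((p_d < t) & (p_v_mem < t) & (sign_d * fc_v_mem > 0)).sum() / n_m)
                 for t in thresholds}

    # a global label shuffle assigns the members a uniform without-replacement
    # sample of the universe's validation statistics
    draw = rng.random((n_perm, n_univ)).argpartition(n_mem - 1, axis=1)[:, :n_mem]
    P = p_v_all[draw]
    FC = fc_v_all[draw]

    p_per_t: dict[float, float] = {}
    perm_frac: dict[float, np.ndarray] = {}
    for t in thresholds:
        hits = (p_d[np.newaxis, :] < t) & (P < t) & (sign_d[np.newaxis, :] * FC > 0)
        f_perm = hits.sum(axis=1) / n_m
        perm_frac[t] = f_perm
        p_per_t[t] = _one_sided_p(fractions[t], f_perm, mode, n_perm)

    if all(fractions[t] == 0.0 for t in thresholds):
        gess = 1.0
    else:
        gess = float(np.mean([p_per_t[t] for t in thresholds]))
    return GessResult(
        module=module_label, n_m=n_m, n_perm=n_perm, thresholds=tuple(thresholds),
        fractions=fractions, p_per_threshold=p_per_t, gess=gess,
        validated=bool(gess < alpha), fraction_same_direction=frac_same,
        permuted_fractions=perm_frac,
    )


def validate_all_modules(
    assignment: pd.Series,
    discovery: pd.DataFrame,
    validation_cohorts: dict[str, pd.DataFrame],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "empirical",
    missing: str = "exclude",
) -> pd.DataFrame:
    """GESS per module per validation cohort, with a per-module summary of
    how many cohorts validated it (mirroring one/two-asterisk reporting)."""
    if not validation_cohorts:
        raise ValueError("need at least one validation cohort")
    rows = []
    modules = sorted(set(assignment) - {"M00"})
    seeds = np.random.SeedSequence(seed).spawn(len(modules) * len(validation_cohorts))
    i = 0
    for lab in modules:
        members = list(assignment.index[assignment == lab])
        for cohort, val in validation_cohorts.items():
            sub_seed = int(seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            if not any(m in val.index for m in members):
                warnings.warn(f"module {lab} absent from cohort {cohort!r}; skipped", stacklevel=2)
                continue
            res = gess_score(members, discovery, val, thresholds=thresholds, n_perm=n_perm,
                             seed=sub_seed, mode=mode, missing=missing, module_label=lab)
            row = res.as_row()
            row["cohort"] = cohort
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        counts = table.groupby("module")["validated"].sum().rename("validated_in_n_cohorts")
        table = table.merge(counts, on="module")
    return table
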