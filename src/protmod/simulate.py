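"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a 3-group DIA (SWATH) brain-proteomics study:
two case groups and a control group, ~1800 proteins organised in correlated
co-expression modules with planted group effects, peptide-level reports with
Q-value quality scores split over chromatographic fractions, a partially
concordant second cohort summarised at the statistics level, and a gene ×
cell-type expression table with dominant markers for seven CNS cell classes.

Each protein's latent log2 abundance follows a one-factor-per-module model

    x_ps = baseline_p + loading * f_{m(p), s} + effect_{m(p), g(s)} + eps_ps

with a standard-normal module factor ``f`` per sample, so the expected
within-module correlation is loading^2 / (loading^2 + noise_sd^2).  Peptides
are the protein abundance times a fixed peptide ionisation multiplier times
multiplicative lognormal noise, split across fractions with fixed per-peptide
fraction weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_module_sizes",
    "generate_peptide_report",
    "generate_validation_stats",
    "generate_annotation_sets",
    "generate_specificity_inputs",
    "proteome_markers",
    "CNS_MARKERS",
]

#: Canonical CNS cell-class marker panel (seven classes).
CNS_MARKERS: dict[str, tuple[str, ...]] = {
    "astrocytes": ("AGT", "SLC4A4", "SLC1A2"),
    "endothelial": ("FLT1", "DUSP1", "NOSTRIN"),
    "excitatory_neurons": ("SLC17A7",),
    "inhibitory_neurons": ("GAD1",),
    "microglia": ("APBB1IP", "TYROBP"),
    "oligodendrocytes": ("MOBP",),
    "OPCs": ("PCDH15", "PDGFRA"),
}


def default_module_sizes(n_modules: int = 17, largest: int = 272, smallest: int = 18) -> list[int]:
    """Geometric ladder of module sizes from ``largest`` down to ``smallest``.

    The default emulates a module landscape of 17 modules ranging from 272
    down to 18 member proteins (total ~1650 of 1800, remainder unassigned).
    """
    if n_modules == 1:
        return [largest]
    ratio = (smallest / largest) ** (1.0 / (n_modules - 1))
    sizes = [max(2, round(largest * ratio**i)) for i in range(n_modules)]
    sizes[0], sizes[-1] = largest, smallest
    return sizes


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the discovery cohort structure: control n=5 and two case
    groups (n=6 and n=15), 1800 proteins in 17 modules sized 272..18.
    """

    n_control: int = 5
    n_case_groups: int = 2
    n_per_case: tuple[int, ...] = (6, 15)
    group_names: tuple[str, ...] = ("tau", "tdp")
    n_proteins: int = 1800
    module_sizes: list[int] = field(default_factory=default_module_sizes)
    within_module_loading: float = 0.9
    #: module label -> {contrast group name -> signed log2 shift}
    module_effects: dict[str, dict[str, float]] | None = None
    peptide_mean_extra: float = 5.0  # peptides per protein = 1 + Poisson(mean)
    fraction_count: int = 3
    noise_sd: float = 0.2
    peptide_noise_sd: float = 0.1  # lognormal (log2) sd of peptide-level noise
    bad_peptide_rate: float = 0.05
    concordant_modules: tuple[str, ...] | None = None
    hot_subnetwork: dict[str, list[str]] | None = None
    #: module -> CNS cell class driving it; None selects a small default map
    celltype_modules: dict[str, str] | None = field(
        default_factory=lambda: {"M03": "astrocytes", "M04": "oligodendrocytes",
                                 "M06": "endothelial", "M10": "microglia"}
    )
    baseline_range: tuple[float, float] = (6.0, 14.0)  # log2 intensity span
    unassigned_sd_factor: float = 2.0  # extra independent variability outside modules
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_groups != len(self.n_per_case):
            raise ValueError("n_per_case must have one entry per case group")
        if self.n_case_groups != len(self.group_names):
            raise ValueError("group_names must have one entry per case group")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module_sizes must be strictly positive")
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_proteins={self.n_proteins}"
            )
        if not 0.0 <= self.within_module_loading <= 1.0:
            raise ValueError("within_module_loading must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.bad_peptide_rate <= 1.0:
            raise ValueError("bad_peptide_rate must be a proportion")
        if self.fraction_count < 1 or self.n_control < 2 or any(n < 2 for n in self.n_per_case):
            raise ValueError("need >=1 fraction and >=2 samples per group")

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(len(self.module_sizes))]

    def default_effects(self, n_dysregulated: int = 13, magnitude: float = 0.6) -> dict[str, dict[str, float]]:
        """Planted per-module shifts: the first ``n_dysregulated`` modules get an
        alternating-sign log2 shift in the first case group; a subset of those
        is shifted in the second case group as well."""
        effects: dict[str, dict[str, float]] = {}
        labels = self.module_labels
        for i, lab in enumerate(labels):
            eff: dict[str, float] = {}
            if i < n_dysregulated:
                eff[self.group_names[0]] = magnitude * (1 if i % 2 == 0 else -1)
            if i < max(0, n_dysregulated - 4) and len(self.group_names) > 1:
                eff[self.group_names[1]] = magnitude * (1 if i % 2 == 0 else -1)
            effects[lab] = eff
        return effects

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    true_module_of: dict[str, str | None]
    true_effect: dict[str, dict[str, float]]  # module -> group -> log2 shift
    hot_members: dict[str, list[str]]
    concordant_modules: tuple[str, ...]
    celltype_of_module: dict[str, str]
    sample_groups: dict[str, str]

    def members(self, module: str) -> list[str]:
        return [p for p, m in self.true_module_of.items() if m == module]


def _sample_frame(config: SimConfig) -> tuple[list[str], list[str]]:
    samples, groups = [], []
    for i in range(config.n_control):
        samples.append(f"CTRL{i + 1:02d}")
        groups.append("control")
    for g, n in zip(config.group_names, config.n_per_case):
        for i in range(n):
            samples.append(f"{g.upper()}{i + 1:02d}")
            groups.append(g)
    return samples, groups


def _latent_protein_matrix(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Protein x sample latent log2 abundances plus the planted truth."""
    samples, groups = _sample_frame(config)
    n_s = len(samples)
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]

    baselines = rng.uniform(*config.baseline_range, size=config.n_proteins)

    # the highest-abundance proteins stay outside the disease modules
    # (housekeeping/structural proteins dominate total intensity in brain
    # proteomes); this also keeps the module factors from swinging the
    # sample totals, which total-count normalization would otherwise fold
    # back into every protein as a spurious shared component
    n_unassigned = config.n_proteins - sum(config.module_sizes)
    heavy = set(np.argsort(baselines)[::-1][:n_unassigned].tolist())
    assignable = [i for i in range(config.n_proteins) if i not in heavy]

    module_of: dict[str, str | None] = {p: None for p in proteins}
    idx = 0
    for lab, size in zip(config.module_labels, config.module_sizes):
        for i in assignable[idx : idx + size]:
            module_of[proteins[i]] = lab
        idx += size

    effects = config.module_effects
    if effects is None:
        effects = config.default_effects()
    concordant = config.concordant_modules
    if concordant is None:
        # modules with a planted first-contrast effect replicate by default
        concordant = tuple(
            lab for lab in config.module_labels if effects.get(lab, {}).get(config.group_names[0])
        )

    loading = config.within_module_loading
    factors = {lab: rng.normal(size=n_s) for lab in config.module_labels}
    hot = config.hot_subnetwork or {}
    hot_factors = {lab: rng.normal(size=n_s) for lab in hot}

    x = np.empty((config.n_proteins, n_s))
    member_rank: dict[str, int] = {}
    for i, p in enumerate(proteins):
        lab = module_of[p]
        sd = config.noise_sd if lab is not None else config.noise_sd * config.unassigned_sd_factor
        row = baselines[i] + rng.normal(scale=sd, size=n_s)
        if lab is not None:
            row = row + loading * factors[lab]
            eff = effects.get(lab, {})
            boost = 1.0
            if lab in hot and p in hot[lab]:
                boost = 2.5  # hot-chain members carry amplified shifts
                row = row + 0.4 * hot_factors[lab]
            for g, shift in eff.items():
                mask = np.array([grp == g for grp in groups])
                row = row + boost * shift * mask
        x[i] = row

    # samples contain the same total protein: module factors and group shifts
    # are relative redistributions, as in real tissue where the instrument
    # measures relative abundance.  Without this the per-sample totals would
    # swing with the module factors and total-count normalization downstream
    # would induce spurious correlation between unrelated proteins.
    totals = np.log2((2.0**x).sum(axis=0))
    x = x - (totals - totals.mean())

    truth = GroundTruth(
        true_module_of=module_of,
        true_effect={lab: dict(effects.get(lab, {})) for lab in config.module_labels},
        hot_members={lab: list(mem) for lab, mem in hot.items()},
        concordant_modules=tuple(concordant),
        celltype_of_module=dict(config.celltype_modules or {}),
        sample_groups=dict(zip(samples, groups)),
    )
    frame = pd.DataFrame(x, index=proteins, columns=samples)
    return frame, truth


def generate_peptide_report(config: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format peptide quantification report.

    Returns a DataFrame with columns
    ``sample, group, fraction, peptide, protein, abundance, qvalue``
    and the :class:`GroundTruth` describing the planted structure.
    Fully deterministic for a given ``(config, seed)``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    latent, truth = _latent_protein_matrix(config, rng)
    samples = list(latent.columns)
    groups = [truth.sample_groups[s] for s in samples]
    n_s = len(samples)

    records: list[tuple] = []
    for p, row in zip(latent.index, latent.to_numpy()):
        n_pep = 1 + rng.poisson(config.peptide_mean_extra)
        pep_mult = 2.0 ** rng.normal(scale=1.0, size=n_pep)  # ionisation efficiency
        frac_w = rng.dirichlet(np.ones(config.fraction_count), size=n_pep)
        protein_abund = 2.0**row  # linear intensity per sample
        for j in range(n_pep):
            pep_id = f"{p}_pep{j + 1}"
            bad = rng.random() < config.bad_peptide_rate
            if bad:
                n_bad = rng.integers(n_s // 2 + 1, n_s + 1)
                bad_samples = set(rng.choice(n_s, size=n_bad, replace=False).tolist())
            else:
                bad_samples = set()
            noise = 2.0 ** rng.normal(scale=config.peptide_noise_sd, size=n_s)
            pep_abund = protein_abund * pep_mult[j] * noise
            for si, (s, g) in enumerate(zip(samples, groups)):
                if si in bad_samples:
                    q = rng.uniform(0.011, 0.5)
                else:
                    q = rng.uniform(0.0, 0.01)
                for f in range(config.fraction_count):
                    a = pep_abund[si] * frac_w[j, f]
                    if a <= 0:  # guard: intensities are strictly positive
                        a = np.nextafter(0, 1)
                    records.append((s, g, f"F{f + 1}", pep_id, p, a, q))

    report = pd.DataFrame.from_records(
        records,
        columns=["sample", "group", "fraction", "peptide", "protein", "abundance", "qvalue"],
    )
    return report, truth


def generate_validation_stats(
    truth: GroundTruth,
    config: SimConfig,
    seed: int,
    contrast_group: str | None = None,
    dropout: float = 0.035,
    signal_shape: float = 0.02,
    fc_noise_sd: float = 0.15,
    null_fc_sd: float = 0.3,
) -> pd.DataFrame:
    """Statistics-level second cohort: per-protein ``(log2fc, pvalue)``.

    Proteins in ``truth.concordant_modules`` with a planted effect in
    ``contrast_group`` reproduce the discovery effect sign with small
    p-values (p ~ Beta(signal_shape, 1)); everything else is null (uniform p,
    sign-random log2FC).  A fraction ``dropout`` of the discovery proteins is
    absent, emulating partial overlap of the protein universes.
    """
    if contrast_group is None:
        contrast_group = config.group_names[0]
    rng = np.random.default_rng(seed)
    proteins = list(truth.true_module_of)
    if dropout > 0:
        keep = rng.random(len(proteins)) >= dropout
        proteins = [p for p, k in zip(proteins, keep) if k]

    unknown = set(truth.concordant_modules) - set(config.module_labels)
    if unknown:
        raise ValueError(f"unknown module labels in concordant_modules: {sorted(unknown)}")

    log2fc = np.empty(len(proteins))
    pval = np.empty(len(proteins))
    for i, p in enumerate(proteins):
        lab = truth.true_module_of[p]
        eff = truth.true_effect.get(lab, {}).get(contrast_group) if lab else None
        if lab in truth.concordant_modules and eff:
            log2fc[i] = eff + rng.normal(scale=fc_noise_sd)
            pval[i] = rng.beta(signal_shape, 1.0)
        else:
            log2fc[i] = rng.normal(scale=null_fc_sd)
            pval[i] = rng.uniform()
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({"protein": proteins, "log2fc": log2fc, "pvalue": pval}).set_index("protein")


def generate_annotation_sets(
    truth: GroundTruth,
    n_terms: int,
    alignment: float,
    seed: int,
    jitter: float = 0.0,
    random_set_size: tuple[int, int] = (10, 80),
) -> dict[str, tuple[str, list[str]]]:
    """Gene-set collection where a fraction ``alignment`` of terms coincide
    with planted modules (optionally jittered) and the rest are random draws
    from the proteome.  Returns ``{name: (description, members)}``."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not 0.0 <= alignment <= 1.0:
        raise ValueError("alignment must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = np.array(list(truth.true_module_of))
    modules = sorted({m for m in truth.true_module_of.values() if m is not None})
    n_aligned = round(alignment * n_terms)

    sets: dict[str, tuple[str, list[str]]] = {}
    for t in range(n_terms):
        name = f"TERM{t + 1:03d}"
        if t < n_aligned and modules:
            lab = modules[t % len(modules)]
            members = truth.members(lab)
            if jitter > 0:
                n_swap = round(jitter * len(members))
                keep = rng.choice(len(members), size=len(members) - n_swap, replace=False)
                extra = rng.choice(proteins, size=n_swap, replace=False)
                members = [members[i] for i in sorted(keep)] + list(extra)
            sets[name] = (f"aligned:{lab}", sorted(set(members)))
        else:
            size = int(rng.integers(*random_set_size))
            members = rng.choice(proteins, size=size, replace=False)
            sets[name] = ("random", sorted(members.tolist()))
    return sets


def generate_specificity_inputs(
    config: SimConfig,
    seed: int,
    genes: Sequence[str] | None = None,
    truth: GroundTruth | None = None,
    dominance: float = 0.9,
    module_shift: float = 2.0,
    base_expression: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Gene x cell-type mean-expression table plus the packaged marker panel.

    Declared markers are dominantly expressed in their own cell type
    (``dominance`` of their total expression); non-marker genes are
    near-uniform.  If ``truth`` assigns cell types to modules, member genes
    of those modules lean toward the driving cell type.
    """
    cell_types = list(CNS_MARKERS)
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = list(truth.true_module_of) if truth is not None else [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    genes = list(dict.fromkeys(list(genes) + [m for ms in CNS_MARKERS.values() for m in ms]))

    marker_of = {g: ct for ct, ms in CNS_MARKERS.items() for g in ms}
    ct_index = {ct: i for i, ct in enumerate(cell_types)}
    k = len(cell_types)

    expr = np.empty((len(genes), k))
    for i, g in enumerate(genes):
        if g in marker_of:
            w = np.full(k, (1.0 - dominance) / (k - 1))
            w[ct_index[marker_of[g]]] = dominance
        else:
            w = rng.dirichlet(np.full(k, 20.0))  # near-uniform specificity
            if truth is not None:
                lab = truth.true_module_of.get(g)
                ct = truth.celltype_of_module.get(lab) if lab else None
                if ct is not None:
                    w[ct_index[ct]] *= module_shift
                    w = w / w.sum()
        expr[i] = base_expression * w
    table = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=cell_types)
    return table, {ct: tuple(ms) for ct, ms in CNS_MARKERS.items()}


def proteome_markers(expression: pd.DataFrame, proteome, n_per_type: int = 10) -> dict[str, tuple[str, ...]]:
    """Synthetic marker panel drawn from the quantified proteome: the
    ``n_per_type`` most cell-type-specific proteome genes per cell type
    (named markers live outside the proteome, so directional summaries of
    quantified proteins need proteome-level markers)."""
    proteome = [g for g in proteome if g in expression.index]
    spec = expression.loc[proteome].div(expression.loc[proteome].sum(axis=1), axis=0)
    markers: dict[str, tuple[str, ...]] = {}
    taken: set[str] = set()
    for ct in spec.columns:
        ranked = spec[ct].sort_values(ascending=False, kind="stable")
        top = [g for g in ranked.index if g not in taken][:n_per_type]
        taken.update(top)
        markers[ct] = tuple(top)
    return markers
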