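# Methods

This note documents the models, the numerical choices, and the synthetic
data conditions under which the package's tests and evaluation script run —
including what those conditions do and do not say about real cohorts.

## Quantification model

The peptide report is long-format `(sample, group, fraction, peptide,
protein, abundance, qvalue)`. Filtering removes a peptide *within a
fraction* when its Q-value exceeds `q_max = 0.01` in strictly more than
`sample_fraction = 0.5` of the samples; a peptide may therefore survive in
some fractions and not others, and contributes only where it survives.
Fraction combination sums same-peptide abundance per sample. The protein
rollup ranks a protein's peptides by abundance summed over *all* samples and
adds the top 5 per sample — the same peptide set everywhere, so a peptide
missing from one sample contributes zero there rather than changing the set.
Ties in the overall ranking break by peptide identifier so the selection is
deterministic. Total-count normalization rescales each sample to the mean of
the pre-normalization totals; the constant is arbitrary because every
downstream statistic is scale-invariant.

## Beta-binomial differential abundance

Counts are `round(abundance × s)` with `s` chosen so the median per-sample
total is 10⁶; per-sample totals serve as trial counts. Parameterised by a
proportion π and concentration θ (α = πθ, β = (1−π)θ), H₀ fits one π and θ,
H₁ group-specific π with common θ, both by L-BFGS-B on (logit π, log θ) with
analytic gradients (digamma), a method-of-moments dispersion start and a
second fixed start. H₁ is warm-started from the H₀ optimum, and H₀ is
re-polished at the H₁ dispersion, so the likelihood-ratio statistic is
non-negative and free of solver-tolerance artifacts.

**Null reference.** With cohort sizes of a handful of subjects per group the
asymptotic χ²(1) reference for the 1-df LRT is anticonservative (≈9%
rejections at nominal 5% under the package's own null simulations). The
p-value therefore refers the statistic to F(1, N−1), N the number of samples
in the contrast; the denominator df was fixed by moment-matching the
empirical null mean of the statistic (≈1.25) under the generator's cohort
sizes. Measured type-I error is then 0.032–0.054 across nine independent
null simulations, with seed-to-seed spread at the binomial noise floor.
The χ²(1) tail is recoverable by users via `scipy.stats` from the same
statistic if asymptotic behaviour is wanted. Residual mid-range deviation
from uniformity of order 0.02–0.05 in CDF remains under the lognormal
generator (the count model is deliberately not the generating model); the
rejection-rate calibration at the 0.05 tail is unaffected.

log2FC is `log2((mean case counts + 0.5)/(mean reference counts + 0.5))`;
the pseudocount acts on the count scale so the estimate is invariant to the
raw intensity scale.

## Beta-uniform mixture and FDR thresholds

`f(p|λ,a) = λ + (1−λ)·a·p^(a−1)` is fitted by maximum likelihood with
L-BFGS-B on (logit λ, log a) from five fixed starts (λ₀ ∈ {0.1,…,0.9});
the best likelihood wins, making the fit deterministic. The Pounds–Morris
upper bound on the null proportion is π̂ = λ̂ + (1−λ̂)â = f̂(1). The estimated
FDR at cutoff τ is π̂τ/F̂(τ); solving FDR(τ) = q gives the closed form
τ = [q(1−λ)/(π̂ − qλ)]^{1/(1−a)}, verified against Brent root-finding to
1e−6. A signal-free fit (π̂ ≈ 1) yields τ = 0 with a warning.

## Co-expression modules

Similarity is |Pearson r|^β with β = 7 by default; `pick_soft_threshold`
implements the scale-free-topology criterion (binned log-log degree
regression, R² with a sign penalty, smallest power reaching 0.8). Pearson is
computed on log2(x+1) by default: intensities are lognormal-ish and the
linear-scale estimator is unstable at cohort-scale n (26 samples), which
fragments large modules; `log_transform=False` restores the literal
linear-scale correlation. Similarity of a zero-variance protein is defined
as 0 — it carries no co-expression signal.

Module detection is an average-linkage tree over 1 − s with an adaptive
branch-pruning cut. Processing merges bottom-up in height order, a branch
qualifies as a module when it (i) has ≥ `min_size` leaves, (ii) is
internally tight (mean internal merge height ≤ a `deep_split`-dependent
fraction of the dendrogram height range) and (iii) is separated from its
sibling by a clear gap at the merge; **two branches stay apart only when
both qualify where they meet** — otherwise they fuse and keep growing. No
merge happens above the static cut at 0.99 of the tallest height, so loose
leaves chaining onto a module remain unassigned (M00). The deep-split
tables follow the WGCNA-style core-scatter ladder {0.64…0.95}; the minimum
gap is 1.5·(1 − maxCoreScatter) of the height range, a setting chosen so
that one-factor modules of several hundred proteins survive as single
branches while planted distinct blocks still separate (validated across
eight independent simulation seeds: 17/17 modules, ARI 0.93–0.995).
`min_size = 15` by default because module landscapes with smallest modules
of ~18 members must be reachable.

Module dysregulation is a one-sample two-sided t-test of member log2FC
against zero, BH-corrected across modules within a contrast; M00 is
excluded, modules with <3 usable members get p = 1 and a flag.

## Hot subnetworks

Within one module, the graph has an edge where |r| ≥ 0.5 (threshold
exposed), weighted by |r|. The insulated-heat diffusion
F = β(I − (1−β)W)⁻¹ uses the column-normalized weighted adjacency per
connected component (isolated nodes diffuse to themselves); β = 0.5 by
default, mid-range of published settings. Scores are −log₁₀p capped at 16.
The exchanged-heat matrix S = F·diag(scores) is thresholded over ≤60
quantile-spaced δ values; at each δ the strongly connected components of
the digraph {i→j : S_ij ≥ δ} are the candidate subnetworks. δ is selected
by the ratio of the observed largest-component size to its mean under
score permutation, tie-broken toward the largest near-maximal δ (the
tightest cut that still carries the evidence); an absolute-difference
criterion systematically under-thresholds and absorbs warm neighbours of
the hot set. The largest-component statistic at the chosen δ gets an
empirical permutation p. Diffusion methods of this family operate in a
sparse-graph regime; on near-complete graphs heat spreads uniformly and
subnetwork boundaries blur, which is why module graphs are thresholded
rather than fully weighted by default.

## GESS cross-cohort validation

F_{m,t} uses strict inequalities; a log2FC of exactly zero in either cohort
counts as non-concordant. Proteins absent from either cohort are excluded
from numerator and denominator by default (`missing="fail"` counts them as
failures instead), mirroring partially overlapping protein universes.
Permutation reassigns the validation cohort's (p, log2FC) pairs to protein
labels uniformly over the *shared* universe — within-module shuffling would
leave F invariant. Per threshold, the default p-value is the standard
empirical estimator (1 + #{F_perm ≥ F_obs})/(1 + n_perm). A literal
one-sample t-test of the permuted sample against the observed value is
available as `mode="ttest"`, but its standard error shrinks with the number
of permutations, so it flags any module whose observed F merely exceeds the
permutation mean — measured false-validation rate 14.5% versus 0.5% for the
empirical mode on the same null, which is why the empirical mode is the
default. The GESS score is the mean of the four per-threshold p-values,
thresholds {0.1, 0.2, 0.5, 0.8}; a module with F = 0 at all thresholds is
assigned GESS 1. Validation is declared at GESS < 0.05.

## EWCE and marker directions

Specificity rows are mean expression shares over the seven CNS cell classes.
The bootstrap draws same-size lists uniformly without replacement from the
quantified-protein background (no expression-level binning), 20,000 lists by
default, chunked so memory stays flat; significance is the bootstrap z and
the (1+k)/(1+n) empirical p. The directional module summary compares the
log2FC of a cell type's markers inside a module against the other members
with a two-sided rank-sum test, BH across cell types; with a single marker
the direction is still reported but flagged low-power. The packaged marker
panel covers astrocytes (AGT, SLC4A4, SLC1A2), endothelial cells (FLT1,
DUSP1, NOSTRIN), excitatory neurons (SLC17A7), inhibitory neurons (GAD1),
microglia (APBB1IP, TYROBP), oligodendrocytes (MOBP) and OPCs (PCDH15,
PDGFRA); because these named genes are typically outside a quantified
proteome, the pipeline derives proteome-level marker panels (most specific
quantified genes per cell type) for the directional summaries.

## Synthetic cohort generator

Latent protein log2 abundance follows one Gaussian factor per module:
x = baseline + loading·f_m + effect_{m,group} + N(0, noise_sd), with
baselines uniform on log2 [6, 14], loading 0.9 and noise_sd 0.2 by default —
the regime in which module recovery is tested. Proteins expand into
1 + Poisson(5) peptides (mode ≈ 6) with fixed lognormal ionisation
multipliers, Dirichlet fraction splits across 3 fractions, and lognormal
peptide-level noise (log2 sd 0.1). A `bad_peptide_rate` fraction of peptides
carries Q ~ U(0.011, 0.5) in a random majority of samples (U(0, 0.01)
otherwise), exercising the filter. Defaults mirror a two-case-group cohort
(n = 6 and 15) with 5 controls, 1800 proteins and 17 modules sized 272 down
to 18.

Three generative choices keep total-count normalization from manufacturing
artefactual structure: samples carry equal total latent protein (the
instrument measures relative abundance); the highest-abundance proteins stay
outside the disease modules (housekeeping dominance), so module factors do
not swing the totals; and unassigned proteins get twice the independent
variability of module residuals. Without these, the normalization folds
total-intensity swings back into every protein as a shared component and
unrelated proteins correlate at |r| ≈ 0.7.

The validation cohort is generated at the statistics level — per-protein
(p, log2FC) with concordant-module members drawing p ~ Beta(0.02, 1) and
sign-preserving log2FC, everything else uniform/symmetric — because GESS
consumes statistics only; a raw second cohort is available by re-running the
peptide generator against the same ground truth. Default dropout 3.5%
emulates partial protein-universe overlap.

**What the generator does not emulate.** Real DIA data have missingness
patterns, interference, and retention-time structure none of which are
modelled; within-module correlation (≈0.95) is stronger than typical real
modules; and the shared module factor acts as a module-level random effect,
so with 6 + 5 subjects the realized module fold change can deviate
substantially from the planted effect (occasionally in sign). Passing tests
demonstrate the statistical machinery is calibrated and recovers planted
structure under these conditions — not that a real cohort of this size has
comparable power.

## Evaluation problem sizes

The packaged evaluation (tests and `scripts/acceptance.py`) uses: 200 null
modules of size 50 with 1000 permutations for GESS calibration; the full
17-module, 1800-protein configuration for module recovery; 1000 null
proteins for type-I error; 20 replicates of a 40-node noise-module graph
(random spanning tree + sparse chance edges) with a planted 6-node chain for
subnetwork recovery; and a reduced 400-protein, 8-module configuration run
twice for byte-level determinism. Seeds enter every stochastic step
explicitly; identical config and seed reproduce identical artifacts.
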