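# Methods

`mmnet` analyses paired gut microbiome / metabolome studies with a
multi-group design: species-level relative abundances from shotgun
metagenomics and ion-count metabolite intensities from untargeted
mass spectrometry, measured on the same animals. The canonical design is
four arms — chow or Western diet, crossed with vehicle or Gulf War
chemical (pyridostigmine bromide + permethrin) exposure — with six mice
per arm. This note records the models, the defaults and why, and what
the synthetic validation does and does not establish.

## Differential abundance

All group comparisons use the Mann-Whitney U test. U is computed from
average ranks, so ties (shared zeros in sparse species data) are
handled. For `nA + nB <= 14` the two-sided p-value is exact: all
C(nA+nB, nA) labelings of the pooled sample are enumerated and
`p = min(1, 2 * min(P(U <= u), P(U >= u)))`. This covers a
six-versus-six design exactly; its smallest attainable two-sided p is
2/924 ≈ 0.00216, so two-star (p < 0.01) calls are reachable but the
test is inherently discrete: the largest attainable level below 0.05 is
2·19/924 ≈ 0.041. Above 14 observations a normal approximation with tie
and continuity corrections is used. Per-feature p-values are reported
uncorrected by default, mirroring per-feature p < 0.05 usage in this
study type; Benjamini-Hochberg q-values are available behind a flag.

Fold changes follow the metabolomics-vendor convention: each feature is
divided by its across-sample median (median -> 1) and the fold change is
the ratio of group means on that scale, reported as log2. Zero
intensities are imputed as half the feature's smallest positive value
(standard minimum imputation for MS data); an all-zero denominator
leaves the fold change undefined and flagged rather than fabricated.
Box-plot summaries use natural-log intensities, linear-interpolation
quartiles and Tukey 1.5·IQR whiskers.

## Diversity and ordination

Shannon diversity is computed in nats by default (the base is a flag);
Bray-Curtis dissimilarity is `sum|x-y| / sum(x+y)`. Metabolite beta
diversity uses PCA after log transform and per-feature autoscaling —
i.e. intensities are mapped to zero-mean unit-variance normal scores —
with zero-variance features dropped. Component signs are fixed by
forcing each component's largest-magnitude loading positive, making
scores reproducible across BLAS implementations.

## Correlation layers

Three layers feed the networks, each computed within one experimental
group's samples only (the per-group networks require it):

* **Microbe-microbe (MM): SparCC.** Relative abundances are
  compositional; naive correlations on them are biased. SparCC
  estimates correlations of the latent basis abundances from log-ratio
  variances `t_ij = var(log(x_i/x_j))` under a sparsity approximation:
  row sums of `t` satisfy a linear system in the basis variances
  `omega_i^2`, solved and then iteratively re-solved with the strongest
  correlated pair (|rho| above 0.1) excluded, up to 10 exclusion
  rounds. Zeros are resolved by drawing compositions from
  Dirichlet(counts + 1) per resampling round (20 rounds; the final rho
  is the element-wise median). Input of any scale is first closed to
  fractions and converted to pseudo-counts (×10⁴, rounded), which makes
  the estimate exactly invariant to per-sample sequencing depth.
  p-values come from permuting each species' samples independently
  (100 rounds by default, seeded; `(1 + hits) / (1 + rounds)`, so p is
  never 0). A feature whose solved basis variance is non-positive gets
  NaN correlations rather than invented ones. The algorithm constants
  are the cited method's conventions; the study itself states only its
  significance threshold.
* **Metabolite-metabolite (TT): Spearman.** Average ranks; for n <= 7
  the two-sided p is exact by full permutation enumeration (cached per
  tie pattern), otherwise the t approximation. At n = 6 only
  |rho| >= 0.8857 reaches two-sided p < 0.05 (24/720); |rho| = 0.8286
  is the corresponding one-sided floor.
* **Microbe-metabolite (MT): cross-modal Spearman.** Ranks are taken
  within each modality's own table and correlated pairwise; this is
  mathematically pairwise Spearman but kept as a distinct staged
  operation to mirror the analysis design.

## Heterogeneous networks

Edges are admitted at p <= 0.05 (uncorrected, the default) or at
BH q <= 0.05 (`use_bh`); the signed correlation is the edge weight.
Nodes appear only with at least one admitted edge and carry type
(microbe/metabolite), phylum or pathway annotation, and the group mean
abundance (microbes: mean relative abundance; metabolites: mean
median-scaled intensity). A metabolite is *network-specific* to a group
iff it appears in that group's network and no other's; per-group mean
intensities are attached so fold-change patterns can be inspected
descriptively. KEGG support flags an edge iff its correlation is
positive and both endpoints share a pathway id in the user-supplied
mapping file (support is only claimed for co-occurrence). Layout is
presentation-only: Fruchterman-Reingold with attraction restricted to
positive-weight edges (negative edges impose no pull), deterministic
per seed.

### ATria centrality

The ranking algorithm is a reconstruction of Ablatio Triadum from its
published description; the internals are config-exposed because the
source describes the idea, not the constants. Node pay aggregates
signed influence over paths of length <= 2: `P_ii = 1`, and for
`j != i`, `P_ij` is the signed value of maximum magnitude among the
direct edge `w_ij` and all two-step products `w_ik * w_kj` (absent
terms contribute 0); `pay_i = |sum_j P_ij|`, so strong negative
influence ("villains") ranks as highly as strong positive influence.
Each round extracts the arg-max pay node (ties broken by smallest node
id, for determinism), then ablates its triads: the node, its incident
edges, and every edge that closed a triangle through it are removed, so
the next extraction is not credited for influence already explained.
Extraction stops when every remaining node sits at its self-pay of 1;
the residue is appended to the ranking in id order and also reported
separately. A consequence of the <=2-path rule worth knowing: in a star
with all weights ±1, leaf-leaf two-paths give every leaf the same pay
as the hub, and the hub ranks first by the tie rule; for any |weight|
< 1 the hub strictly dominates. All three behaviors are pinned against
an independent brute-force pay calculator in the tests.

## Synthetic data

The generator emulates the statistical shape of the target study, not
its biology:

* **Species.** A log-normal basis with species log-means spanning ±1.5
  (a ~20-fold abundance range) and per-species log noise `noise_sd`
  (default 0.5); optional planted basis correlations enter through a
  Cholesky factor, and planted group effects multiply the basis by
  `2^log2fc`. Structural zeros are Bernoulli-masked before closure with
  probability cubic in rarity rank (mean = `sparsity`, default 0.3,
  cap 0.95): absence concentrates in rare, mass-poor species, as in
  real metagenomes. This matters quantitatively — masking abundant mass
  would make the closure denominator noisier than the per-species
  signal and destroy the recoverability of planted structure. Closure
  to fractions follows; a sample left all-zero is a configuration
  error, not data.
* **Metabolites.** Log-normal intensities around 10⁶ "ion counts" with
  ~1 decade of between-feature spread. A cross-modal link (s, m, rho)
  constructs the log-intensity of m as `rho * z_s + sqrt(1-rho²) * eps`
  with `z_s` the standardized log *basis* abundance of s — planting
  against the pre-closure basis makes compositional distortion part of
  what the pipeline must overcome. Links carry unit log-variance so the
  target correlation is exact; a link can be restricted to one group's
  samples to create group-specific structure. Group fold changes add
  `log2fc * ln 2` on the log scale.
* **Design.** Four arms of six samples by default; everything is
  deterministic in the config seed (stage streams are spawned from one
  SeedSequence).

What passing the synthetic suite shows: the statistics are exact where
claimed, SparCC removes closure bias it was designed to remove, planted
effects and links of the stated sizes are recovered at the stated
rates, and the pipeline is deterministic. What it does not show:
robustness to real-data features the generator omits — phylogenetic
correlation structure, batch effects, heavy-tailed intensity noise,
compositional totals driven by a few dominant taxa, or informative
missingness in the metabolomics platform.

## Validation scales and numerical choices

Simulation-based checks use scales chosen to make their statistical
claims sharp at desk scale: planted-recovery runs use 20 samples per
group (at six per group the exact Spearman floor |rho| >= 0.8857 makes
power statements mostly vacuous), and the type-I check uses 20 per
group because the exact test's discreteness at n=6 caps its true level
at 0.041 — no correct exact test can sit "at" 0.05 there. Cross-group
metabolite specificity is validated under BH-admitted networks: with
uncorrected 5% per-pair admission and dozens of candidate partners per
group, every metabolite is near-certain to pick up a spurious edge in
some other group, so exclusivity is only a meaningful notion under
family-wise control. (For the same reason the default-scale pipeline
reports few or no network-specific metabolites at n=6 — an honest
property of uncorrected admission, printed as computed.)

Other numerics: exact-test tie comparisons use a 1e-9 slack; Spearman
t-approximation p-values are floored at the smallest positive float;
SparCC correlations are clipped to [-1, 1]; PCA uses full SVD; TSV
readers use round-trip float parsing so write-read is bit-exact; the
run manifest contains no timestamps so reruns are byte-identical.

## Known limitations

* ATria is a reconstruction; other readings of "triad ablation" exist
  (path caps > 2, edge-only ablation). The internals are exposed for
  comparison but no claim is made to bit-compatibility with the
  original tool.
* SparCC permutation p-values at 100 rounds have a resolution floor of
  ~0.01; raise the round count for smaller thresholds.
* The pipeline does not model repeated measures, covariates, or
  compositionality of the metabolome (ion counts are treated as
  unconstrained intensities).
* KEGG support uses a flat feature->pathway mapping file; no database
  access is performed and pathway directionality is not modeled.
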