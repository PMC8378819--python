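# Methods

## The experiment being modelled

A brain coral from the Persian Gulf (hot-adapted, "PG") and the Oman Sea /
Indian Ocean (cooler, "IO") is bred in a dam × sire design: sperm from 17
colonies (10 PG, 7 IO) crossed onto eggs of 4 colonies (2 PG, 2 IO),
realising 50 full-sib families — 18 PG purebreds, 12 IO purebreds and 20
regional hybrids bred in a single direction (IO dam × PG sire) so that any
hybrid gain must be paternal. 270 larvae per family are split across ambient
(27 °C) and elevated (33, 36 °C) treatments, three plates each, and scored
alive/dead at 60 h. Survivor pools and the parents are genotyped by
RAD-style counts: the analysis starts from per-locus nucleotide read counts,
not reads.

## Synthetic data generator

`simdata` emulates that design so every estimator can be tested against
known truth.

**Populations.** Neutral loci follow a Balding–Nichols model: a shared
ancestral frequency `p₀ ~ U(0.1, 0.9)` and per-population frequencies
`Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` with divergence `F = 0.1` by default —
symmetric noise around a common ancestor. Causal loci are set explicitly:
beneficial-allele frequency 0.75 in PG vs 0.35 in IO, with a quarter of them
fixed in PG (frequency 1.0), reflecting beneficial alleles that are more
prevalent, sometimes fixed, in the hot population yet present in the cool
one.

**Survival model.** Each larva's genotype arises by independent Mendelian
segregation from its parents (loci unlinked; the downstream scans treat SNPs
marginally, so linkage would add realism the analyses cannot use). Survival
is Bernoulli with

    logit p = baseline(T) + scale(T)·β·(beneficial copies) + dam + family

where `scale(27) = 0`, `scale(33) = 0.5`, `scale(36) = 1` — genetic heat
effects act only under heat, and the intermediate treatment carries half the
effect because no quantitative intermediate model is available. Dam and
family random effects (SD 0.3 each, logit scale) stand in for maternal
provisioning and shared-container effects. Baselines are calibrated once per
design so mean survival hits 0.93 / 0.75 / 0.55 at 27 / 33 / 36 °C — i.e.
~45 % overall heat mortality at 36 °C.

**Default effect size.** The per-copy log-odds increment is β = 0.12 at 20
causal loci among 2000. With the frequency contrast above this yields
origin-level 36 °C survival of roughly 0.75 (PG) / 0.28 (IO) / 0.52
(hybrid) — the qualitative structure of the real experiment (hot purebreds
best, naïve purebreds worst, hybrids intermediate) at desk scale. Note the
real hybrids matched PG purebreds, which an additive model cannot produce;
this generator is strictly additive.

**Sequencing.** Depth is Poisson (mean 60× parents, 400× pools; a
negative-binomial option adds overdispersion for robustness checks), allele
counts are binomial in the true sample frequency, and each read is miscalled
to a uniformly random other base with probability 0.005. Pools are sequenced
from the survivors of each family × temperature, so finite survivor pools
contribute genuine genetic drift — deliberately, since that drift is what a
selection scan must distinguish from systematic allele-frequency shifts.

**What the generator does not emulate:** linkage and haplotype structure,
reference-alignment artefacts (every simulated locus is a clean biallelic
SNP, so the parental score distribution is far more heterozygous than a
genome-wide panel aligned to a reference), plate-position effects beyond the
family level, symbiont genetics, and non-additive (dominance/epistatic)
architecture. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those artefacts.

## Genotype and frequency calling

Parents: alleles with <5 % of a sample's reads are discarded as sequencing
error (an allele at exactly 5 % is retained — the inequality is strict); if
the remaining coverage is <5 reads the call is missing (exactly 5 is
called); one remaining allele scores 0 (reference) or 1 (alternate), two
score 0.5; more than two surviving alleles is set missing with a warning
rather than dropping the locus. Pools: minor-allele frequency at ≥50×, else
missing.

The minor allele is fixed **globally per locus** as the less frequent of the
two most abundant nucleotides across all ambient pooled samples combined,
ties broken lexicographically. A single consistent axis is required to
compare frequencies across samples and temperatures; per-sample minor
alleles would flip sign incoherently.

Dataset filters run in a fixed order — samples with too much missing data,
then loci with too much missing data, then loci monomorphic across retained
samples — and the report records each step's removals. Parent and pool
matrices keep independent locus sets; operations that need both intersect
them explicitly.

## Survival statistics

Standardised survival is (survival at elevated T) / (survival at 27 °C),
capped at 1.0. The cap is a design choice: the one-tailed "<1" decline test
presumes a [0, 1]-style scale, and a family surviving heat better than
its ambient control carries no extra information for that test. Families with zero ambient
survival give missing values with a warning.

The origin model cubes the response before fitting `resp ~ temperature ×
origin` (variance-stabilising for left-skewed survival fractions), with
Tukey HSD origin comparisons within each temperature computed on the
transformed scale and raw-scale means reported alongside. Partial
η² = SS_effect/(SS_effect + SS_residual) uses Type-II sums of squares, since
the realised mother+father design is unbalanced and no SS convention was
stated.

The survival index (h/m) − 1 expresses a family's 36 °C survival relative
to its maternal mean, isolating the paternal contribution; per-sire means
feed the parent-performance correlation.

## Heritability

The Gaussian sire–dam model `y = μ + sire + dam + ε` is sampled by a Gibbs
sampler with scaled-inverse-χ² (ν = 0.002, V = 1) priors on all three
variances and a flat prior on μ — weakly informative, matching common
MCMC-GLMM practice. Additive variance is extracted by the paternal half-sib
identity V_A = 4·V_sire (the standard choice for a sire-replicated design
focused on paternal inheritance), V_M = V_dam, and both heritability forms
are reported per posterior draw: h² = V_A/(V_A + V_R) and
h² = V_A/(V_A + V_M + V_R). Both are bounded in [0, 1] by construction.
The default chain is a desk-scale 10⁵ iterations (10⁴ burn-in, thinning 10);
`ChainConfig.full_scale()` switches to publication-scale settings
(10⁶ iterations, 10⁵ burn-in, thinning 100). An
effective sample size of h² under 100 triggers a warning, not a failure.
The binary-response ("threshold") model variant is out of scope; only the
Gaussian response is implemented.

Credible-interval coverage is verified at the realised design size (17
sires × 4 dams, 3 replicates) for true h² ∈ {0.25, 0.5}, with truth defined
on the estimator's own scale (4σ²_s/(4σ²_s + σ²_d + σ²_e)). At this design
size the posterior is wide and the point estimate can be biased by ±0.15;
that is a property of 17 sires, not of the sampler.

## Association scan

Per locus, family alive/dead counts at 36 °C are regressed on the ambient
pooled MAF with parental origin as a **fixed** covariate and the MAF slope
tested by likelihood ratio. (A three-level "random factor" in a per-locus
binomial GLM is statistically fragile; the fixed-covariate LRT is the
well-defined equivalent.) Loci observed in fewer than 3 families, or with
constant MAF, report class `none` with p = 1. Bonferroni m is the number of
loci actually tested. The classification follows the reporting convention:
strong ⇔ |R| ≥ 0.5 where R is the unweighted Pearson correlation between
ambient MAF and the raw survival proportion; moderate/weak ⇔ not strong but
Bonferroni-significant; both filters are also available separately.

The per-locus GLMs are fitted by a Newton/IRLS solver batched across loci
sharing a missingness pattern (the origin design block is shared; only the
MAF column differs), verified against statsmodels' GLM in the tests.

Family survival counts are treated as binomial, deliberately ignoring
plate and family overdispersion (the convention for this kind of pooled
scan). The consequence is quantified by
the simulator: with extra-binomial family variance (random effects, or the
polygenic causal variance itself), the per-locus test statistic is inflated
and large fractions of neutral loci reach Bonferroni significance. Error
control therefore holds under the clean null (no causal loci, no
extra-binomial noise), and the planted-signal recovery test uses a panel of
genetically independent families (`make_diagonal_design`, one dam and sire
per family) so that causal loci stand out against a calibrated null rather
than against shared-parent pseudo-replication.

Parent scoring: at each significant locus the beneficial allele is the one
whose higher frequency predicts higher survival (minor allele if R > 0);
two/one/zero parental copies score 1/0.5/0 and the mean over non-missing
loci is the parent's beneficial-allele proportion. Flipping the minor-allele
convention flips R's sign and relabels the beneficial allele but leaves
parent scores unchanged. Paternal clustering uses pairwise Pearson
correlation over shared non-missing loci (pairs sharing <10 loci are flagged
low-confidence) and average-linkage on 1 − r with parents pre-sorted by id
for a deterministic dendrogram.

## Selection scan

Counts are normalised to the median per-sample total depth and rounded
half-to-even (binomial models need integer counts on a comparable scale;
p-values are approximate under rounding). Because temperature is the only
model term, the per-locus binomial GLM has a closed-form fit — one frequency
per temperature — so the deviance test is computed directly on the
aggregated normalised counts; tests verify equality with statsmodels.
Families absent at either temperature are excluded; a family with zero
coverage at a locus is skipped for that locus. Scans run over all families
pooled and per origin, Bonferroni within the tested subset. Family is not a
model term (a stratified exact-test alternative exists behind the
`normalize`/API surface for sensitivity checks).

The per-origin significant fractions order IO > hybrid > PG at default
settings for two compounding reasons: naïve families suffer the most
genotype-dependent mortality (larger systematic shifts at causal loci), and
their smaller survivor pools drift more at every locus, which deep pooled
sequencing resolves as real frequency change. This reproduces, at smaller
absolute shift magnitudes, the naive > hybrid > adapted ordering such
selection experiments report.

The hybrid PCA filters loci to Bonferroni-adjusted p < 0.001 in the
hybrid-subset scan and <10 % missing data, imputes remaining gaps with the
origin-group mean (hybrids by the hybrid group itself), centres columns and
projects on the top two components with a deterministic sign convention
(largest-magnitude loading positive). Fixation is operationalised as group
minor-allele frequency <0.01.

## Enrichment

Study set: genes containing ≥1 significant intragenic SNP; background:
genes containing ≥1 tested intragenic SNP (a flag switches to all annotated
genes). Per GO term, p = P(X ≥ observed) under the hypergeometric
distribution — classic Fisher — with significance requiring p < 0.05 **and**
≥5 background occurrences, and no correction across terms (the reporting
rule is on raw p). Classic Fisher is used rather than a graph-decorrelating algorithm
(e.g. topGO's "weight"): the reporting rule is algorithm-agnostic and
classic Fisher is exactly specifiable and exactly testable. True-path propagation to
ancestors is applied when an OBO-derived graph is supplied.

## Problem sizes and determinism

Default desk-scale sizes: 2000 loci (20 causal), 50 families, 270 larvae
per family, 150 pooled samples; the full pipeline runs in seconds and the
statistical acceptance tests use 20–50 seeded replicates per claim. All
randomness flows from one seed; identical seeds give byte-identical tables
and manifests. Writers sort rows and format floats at six significant
digits so outputs are diffable.

## Known limitations

- Additive genetics only; the real hybrids' parity with hot-origin
  purebreds suggests non-additive effects this model cannot express.
- The naive-binomial association GLM is anti-conservative under any
  extra-binomial family variance (see above); interpret genome-wide
  significant fractions as descriptive, not error-controlled, whenever such
  variance exists.
- The Gibbs model supports the sire–dam design only, not arbitrary
  pedigrees or relationship matrices.
- Selection shift magnitudes are proportional to within-family segregation
  variance and survivor-pool sizes; the simulator's magnitudes are a few
  hundredths of allele frequency, smaller than field experiments report.
- The reconstructed field-deployment table is synthetic: integer survivor
  counts nearest the published per-origin rates, used for rate arithmetic
  only.
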