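"""Associate baseline pooled allele frequencies with family heat survival.

Per locus, the ambient (27 C) minor-allele frequency across families is
related to alive/dead counts at 36 C by a binomial GLM with parental origin
as a covariate; the Pearson R between MAF and survival classifies loci, and
paternal genotypes are scored for beneficial alleles and compared with each
father's offspring performance.
"""

from coralbreed import assoc, genotyping, phenostats, pipeline, simdata

cfg = pipeline.RunConfig(seed=1)
ds = pipeline.simulate_experiment(cfg)

ambient = [s for s in ds.pool_counts["sample_id"].unique()
           if simdata.parse_pool_sample_id(s)[1] == 27.0]
alleles = genotyping.designate_minor_alleles(ds.pool_counts, ambient)
maf = genotyping.call_pooled_mafs(ds.pool_counts, alleles)
names = {s: simdata.parse_pool_sample_id(s) for s in maf.index}
amb_maf = maf.loc[[s for s in maf.index if names[s][1] == 27.0]]
amb_maf.index = [names[s][0] for s in amb_maf.index]

surv36 = (ds.survival[ds.survival["temperature"] == 36.0]
          .groupby(["family_id", "origin"])[["n_start", "n_alive_60h"]]
          .sum().reset_index())
scan = assoc.scan_survival_association(amb_maf, surv36, alleles)
s = scan.summary()
print(f"SNPs tested: {s['n_tested']}")
print(f"strongly predictive (|R| >= 0.5): {s['n_strong']} "
      f"({100 * s['frac_strong']:.1f}%)")
print(f"moderately/weakly predictive: {s['n_moderate_weak']} "
      f"({100 * s['frac_moderate_weak']:.1f}%)")

parent_matrix = genotyping.call_parent_genotypes(ds.parent_counts, ds.registry)
sires = [sid for sid, _ in ds.design.sires]
scores = assoc.score_parents(parent_matrix.loc[sires], scan, ds.registry)
sidx = phenostats.survival_index(ds.survival)
perf = assoc.correlate_parent_performance(
    scores, phenostats.sire_mean_index(sidx))
print(f"paternal beneficial-allele proportion vs offspring survival index: "
      f"R = {perf['R']:.2f} (p = {perf['p']:.2g}, n = {perf['n']} sires)")
print("a high R means a father's genotype at survival-associated SNPs "
      "predicts how much his offspring outperform their maternal mean.")
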