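"""GO-term enrichment of genes containing survival-associated SNPs.

Maps significant intragenic loci to genes, builds the background from all
tested intragenic loci, and applies a one-sided hypergeometric (classic
Fisher) test per term with the reporting rule p < 0.05 and at least five
background occurrences.
"""

from coralbreed import enrichment, genotyping, pipeline, simdata
from coralbreed import assoc

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

locus_gene = ds.registry[ds.registry["gene_id"] != ""][["locus_id", "gene_id"]]
annotation = enrichment.GeneAnnotationMap.from_frames(locus_gene, ds.gene_terms)
study, background = enrichment.genes_from_loci(
    list(scan.significant), list(scan.table.index[scan.table["tested"]]),
    annotation)
result = enrichment.fisher_enrichment(study, background, annotation)

print(f"study genes: {len(study)}; background genes: {len(background)}")
print(f"GO terms tested: {len(result)}; significant: "
      f"{result['significant'].sum()}")
top = result.nsmallest(5, "p")[["term", "study_count", "background_count", "p"]]
print(top.to_string(index=False))
print("the synthetic annotation assigns terms at random, so few or no terms "
      "should pass the significance rule; with a real genome annotation the "
      "same call reports heat-stress processes enriched in tolerant families.")
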