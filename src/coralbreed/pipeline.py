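"""Run configuration and the end-to-end pipeline.

The pipeline chains simulate (or ingest) -> genotype -> phenostats -> assoc
-> select -> enrich, writing tidy result tables and a manifest recording the
seed, thresholds and per-stage record counts.  All randomness flows from the
single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import enrichment as enrich_mod
from . import genotyping, io, phenostats
from . import selection as select_mod
from . import simdata

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, with the analysis thresholds at their study defaults.

    The simulation block defines the default synthetic experiment: 2000 loci
    with 20 causal, a 4-dam x 17-sire design realising 50 families (18 PG,
    12 IO, 20 one-direction hybrids), 270 larvae per family over three
    temperatures, and pooled sequencing of the survivors.
    """

    seed: int = 1
    out_dir: str = "runs/default"
    log_level: str = "INFO"

    # --- simulate ---
    n_loci: int = 2000
    divergence: float = 0.1
    n_causal: int = 20
    causal_effect: float = 0.12
    beneficial_freq_hot: float = 0.75
    beneficial_freq_cool: float = 0.35
    fixation_fraction: float = 0.25
    n_hot_sires: int = 10
    n_cool_sires: int = 7
    n_hot_dams: int = 2
    n_cool_dams: int = 2
    realized_crosses: tuple[int, int, int] = (18, 12, 20)
    n_larvae_per_family: int = 270
    temperatures: tuple[float, ...] = (27.0, 33.0, 36.0)
    dam_effect_sd: float = 0.3
    family_effect_sd: float = 0.3
    target_survival: dict = field(default_factory=lambda: dict(
        simdata.DEFAULT_TARGET_SURVIVAL))
    parent_depth: float = 60.0
    pool_depth: float = 400.0
    error_rate: float = 0.005
    depth_dispersion: float | None = None

    # --- genotyping (study thresholds) ---
    error_maf: float = 0.05
    min_parent_cov: int = 5
    min_pool_cov: int = 50
    max_missing_per_sample: float = 0.5
    max_missing_per_locus: float = 0.5

    # --- assoc ---
    strong_r: float = 0.5
    alpha: float = 0.05

    # --- selection ---
    pca_alpha: float = 0.001
    pca_missing: float = 0.1
    fixation_maf: float = 0.01

    # --- enrichment ---
    go_p: float = 0.05
    go_min_background: int = 5
    run_enrichment: bool = True

    # --- heritability chain ---
    heritability: dict = field(default_factory=lambda: {
        "iterations": 100_000, "burn_in": 10_000, "thin": 10,
        "nu": 0.002, "V": 1.0})

    def population_model(self) -> simdata.PopulationModel:
        return simdata.PopulationModel(
            n_loci=self.n_loci,
            divergence=self.divergence,
            causal_loci=tuple(range(self.n_causal)),
            causal_effect=self.causal_effect,
            beneficial_freq_hot=self.beneficial_freq_hot,
            beneficial_freq_cool=self.beneficial_freq_cool,
            fixation_fraction=self.fixation_fraction,
        )

    def chain_config(self) -> phenostats.ChainConfig:
        return phenostats.ChainConfig(**self.heritability)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "realized_crosses" in raw:
            raw["realized_crosses"] = tuple(raw["realized_crosses"])
        if "temperatures" in raw:
            raw["temperatures"] = tuple(float(t) for t in raw["temperatures"])
        if "target_survival" in raw:
            raw["target_survival"] = {
                float(k): float(v) for k, v in raw["target_survival"].items()}
        return cls(**raw)


@dataclass
class Dataset:
    """One synthetic experiment: tables on disk plus in-memory truth."""

    registry: pd.DataFrame
    gene_terms: pd.DataFrame
    survival: pd.DataFrame
    parent_counts: pd.DataFrame
    pool_counts: pd.DataFrame
    truth: simdata.SimTruth
    design: simdata.CrossDesign


def simulate_experiment(cfg: RunConfig, seed: int | None = None) -> Dataset:
    """Generate the full synthetic experiment defined by a config."""
    seed = cfg.seed if seed is None else seed
    model = cfg.population_model()
    design = simdata.make_cross_design(
        cfg.n_hot_sires, cfg.n_cool_sires, cfg.n_hot_dams, cfg.n_cool_dams,
        cfg.realized_crosses)
    genotypes, truth = simdata.draw_design_parents(design, model, seed)
    baselines = simdata.calibrate_baselines(
        model, design, genotypes, cfg.target_survival)
    survival, truth = simdata.simulate_family_survival(
        design, genotypes, model,
        n_larvae_per_family=cfg.n_larvae_per_family,
        temperatures=cfg.temperatures,
        dam_effect_sd=cfg.dam_effect_sd,
        family_effect_sd=cfg.family_effect_sd,
        seed=seed, baselines=baselines, truth=truth)
    registry = simdata.assign_locus_alleles(cfg.n_loci, seed)
    registry, gene_terms = simdata.make_annotation(registry, seed)

    parent_fracs = {
        pid: genotypes.loc[pid].to_numpy() / 2.0 for pid in genotypes.index}
    parent_counts = simdata.emit_read_counts(
        parent_fracs, registry, cfg.parent_depth, cfg.error_rate,
        seed=(seed * 2 + 1) % (2**31), depth_dispersion=cfg.depth_dispersion)
    pool_fracs = {
        simdata.pool_sample_id(fam, temp): freq
        for (fam, temp), freq in truth.pool_allele_freq.items()}
    pool_counts = simdata.emit_read_counts(
        pool_fracs, registry, cfg.pool_depth, cfg.error_rate,
        seed=(seed * 2 + 2) % (2**31), depth_dispersion=cfg.depth_dispersion)
    return Dataset(registry=registry, gene_terms=gene_terms, survival=survival,
                   parent_counts=parent_counts, pool_counts=pool_counts,
                   truth=truth, design=design)


def write_dataset(ds: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    io.write_table(ds.survival, out / "survival.csv", "survival")
    io.write_table(ds.parent_counts, out / "parent_counts.tsv", "counts")
    io.write_table(ds.pool_counts, out / "pool_counts.tsv", "counts")
    io.write_table(ds.registry, out / "locus_registry.tsv", "registry")
    io.write_table(ds.gene_terms, out / "gene_terms.tsv", "gene_terms")
    truth = {
        "seed": ds.truth.seed,
        "causal_loci": [int(i) for i in ds.truth.model.causal_loci],
        "causal_effect": ds.truth.model.causal_effect,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def pool_sample_metadata(sample_ids, design_frame: pd.DataFrame) -> pd.DataFrame:
    """family / temperature / origin metadata for pooled sample ids."""
    fam_origin = design_frame.set_index("family_id")["origin"]
    rows = []
    for sid in sample_ids:
        fam, temp = simdata.parse_pool_sample_id(sid)
        rows.append({"sample_id": sid, "family_id": fam, "temperature": temp,
                     "origin": fam_origin.get(fam)})
    return pd.DataFrame(rows)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Any stage failure aborts with the stage name; outputs of earlier stages
    are preserved on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "error_maf": cfg.error_maf, "min_parent_cov": cfg.min_parent_cov,
            "min_pool_cov": cfg.min_pool_cov, "strong_r": cfg.strong_r,
            "alpha": cfg.alpha, "pca_alpha": cfg.pca_alpha,
            "pca_missing": cfg.pca_missing, "fixation_maf": cfg.fixation_maf,
            "go_p": cfg.go_p, "go_min_background": cfg.go_min_background,
        },
        "stages": {},
    }
    results: dict = {}
    stage = "simulate"
    t0 = time.time()
    try:
        ds = simulate_experiment(cfg)
        write_dataset(ds, out / "data")
        design_frame = ds.design.to_frame()
        manifest["stages"]["simulate"] = {
            "n_families": int(ds.design.n_families),
            "n_loci": int(cfg.n_loci),
            "n_pool_samples": int(ds.pool_counts["sample_id"].nunique()),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "genotype"
        t0 = time.time()
        parent_matrix = genotyping.call_parent_genotypes(
            ds.parent_counts, ds.registry, cfg.error_maf, cfg.min_parent_cov)
        ambient_ids = [s for s in ds.pool_counts["sample_id"].unique()
                       if simdata.parse_pool_sample_id(s)[1] == 27.0]
        alleles = genotyping.designate_minor_alleles(ds.pool_counts, ambient_ids)
        pool_matrix = genotyping.call_pooled_mafs(
            ds.pool_counts, alleles, cfg.min_pool_cov)
        parent_matrix, pool_matrix, freport = genotyping.filter_dataset(
            parent_matrix, pool_matrix,
            cfg.max_missing_per_sample, cfg.max_missing_per_locus)
        io.write_matrix(parent_matrix, out / "parent_genotypes.tsv")
        io.write_matrix(pool_matrix, out / "pooled_maf.tsv")
        io.export_vcf(parent_matrix, ds.registry, out / "parent_genotypes.vcf")
        manifest["stages"]["genotype"] = {
            "n_parent_loci": int(parent_matrix.shape[1]),
            "n_pool_loci": int(pool_matrix.shape[1]),
            "filter_report": freport.steps,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "phenostats"
        t0 = time.time()
        rel = phenostats.relative_survival(ds.survival)
        origin_res = phenostats.origin_effect_model(rel)
        decline = phenostats.family_decline_tests(rel)
        fam_rel = (rel[rel["temperature"] == 36.0]
                   .groupby(["family_id", "dam_id", "sire_id", "origin"])
                   ["relative_survival"].mean().reset_index())
        eta_family = phenostats.variance_explained(
            rel[rel["temperature"] == 36.0], ["family_id"])
        eta_parents = phenostats.variance_explained(
            rel[rel["temperature"] == 36.0], ["dam_id", "sire_id"])
        sidx = phenostats.survival_index(ds.survival)
        h2 = phenostats.estimate_heritability(
            rel[rel["temperature"] == 36.0], cfg.chain_config(), seed=cfg.seed)
        decline.to_csv(out / "family_decline.csv", index=False)
        sidx.to_csv(out / "survival_index.csv", index=False)
        h2.summary().to_csv(out / "heritability.csv", index=False)
        eta = pd.concat([eta_family, eta_parents], ignore_index=True)
        eta.to_csv(out / "variance_explained.csv", index=False)
        results["phenostats"] = {
            "eta_family": eta_family, "eta_parents": eta_parents,
            "h2": h2, "survival_index": sidx, "origin": origin_res,
        }
        manifest["stages"]["phenostats"] = {
            "n_families_tested": int(len(decline)),
            "n_significant_declines": int(decline["significant_decline"].sum()),
            "h2_maternal_mean": float(h2.samples["h2_maternal"].mean()),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "assoc"
        t0 = time.time()
        meta = pool_sample_metadata(pool_matrix.index, design_frame)
        amb_samples = meta[meta["temperature"] == 27.0]
        ambient_maf = pool_matrix.loc[amb_samples["sample_id"]]
        ambient_maf.index = amb_samples["family_id"].to_numpy()
        surv36 = (ds.survival[ds.survival["temperature"] == 36.0]
                  .groupby(["family_id", "origin"])[["n_start", "n_alive_60h"]]
                  .sum().reset_index())
        scan = assoc_mod.scan_survival_association(
            ambient_maf, surv36, alleles, cfg.strong_r, cfg.alpha)
        scan.table.to_csv(out / "assoc_results.tsv", sep="\t")
        sires = [s for s, _ in ds.design.sires]
        sire_matrix = parent_matrix.loc[parent_matrix.index.intersection(sires)]
        strong = scan.classified("strong")
        scores = assoc_mod.score_parents(sire_matrix, scan, ds.registry)
        scores.to_csv(out / "parent_scores.tsv", sep="\t", index=False)
        sire_means = phenostats.sire_mean_index(results["phenostats"]["survival_index"])
        perf = assoc_mod.correlate_parent_performance(scores, sire_means)
        cluster = None
        if len(strong) >= 2:
            cluster = assoc_mod.cluster_paternal_genotypes(
                sire_matrix, strong.intersection(sire_matrix.columns))
            cluster["correlation"].to_csv(out / "paternal_correlation.tsv", sep="\t")
            (out / "paternal_dendrogram.nwk").write_text(
                assoc_mod.linkage_to_newick(
                    cluster["linkage"],
                    [str(x) for x in cluster["correlation"].index]) + "\n")
        results["assoc"] = {"scan": scan, "scores": scores, "performance": perf}
        manifest["stages"]["assoc"] = {
            **scan.summary(),
            "parent_performance_R": perf["R"],
            "seconds": round(time.time() - t0, 2),
        }

        stage = "select"
        t0 = time.time()
        long_counts = pool_long_counts(ds.pool_counts, alleles, design_frame)
        scans = {}
        for origin in ("all", "PG", "IO", "PGxIO"):
            scans[origin] = select_mod.scan_selection(
                long_counts, origin=origin, alpha=cfg.alpha)
        maf_groups = _group_mafs(pool_matrix, meta)
        summary = select_mod.summarize_selection(
            scans, maf_groups, cfg.fixation_maf)
        summary.to_csv(out / "selection_summary.tsv", sep="\t", index=False)
        scans["all"].table.to_csv(out / "selection_results.tsv", sep="\t")
        pca_res = None
        try:
            pca_res = select_mod.hybrid_shift_pca(
                pool_matrix, meta, scans["PGxIO"].table["p_adj"],
                cfg.pca_alpha, cfg.pca_missing)
            pca_res.to_csv(out / "pca_coordinates.tsv", sep="\t")
        except select_mod.PCAFilterError as exc:
            log.warning("hybrid PCA skipped: %s", exc)
        results["selection"] = {"scans": scans, "summary": summary, "pca": pca_res}
        results["design_frame"] = design_frame
        manifest["stages"]["select"] = {
            "prop_significant": {
                o: (None if np.isnan(v) else float(v)) for o, v in
                zip(summary["origin"], summary["prop_significant"])},
            "seconds": round(time.time() - t0, 2),
        }

        stage = "enrich"
        t0 = time.time()
        if cfg.run_enrichment and not ds.gene_terms.empty:
            locus_gene = ds.registry[ds.registry["gene_id"] != ""][
                ["locus_id", "gene_id"]]
            annotation = enrich_mod.GeneAnnotationMap.from_frames(
                locus_gene, ds.gene_terms)
            sig = list(scan.significant)
            tested = list(scan.table.index[scan.table["tested"]])
            if sig:
                study, background = enrich_mod.genes_from_loci(
                    sig, tested, annotation)
                enr = enrich_mod.fisher_enrichment(
                    study, background, annotation,
                    p_threshold=cfg.go_p, min_background=cfg.go_min_background)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                manifest["stages"]["enrich"] = {
                    "n_study_genes": len(study),
                    "n_background_genes": len(background),
                    "n_significant_terms": int(enr["significant"].sum()),
                    "seconds": round(time.time() - t0, 2),
                }
            else:
                log.info("no significant association loci; enrich skipped")
                manifest["stages"]["enrich"] = {"skipped": "no significant loci"}
        else:
            log.info("enrichment disabled or no annotations; stage skipped")
            manifest["stages"]["enrich"] = {"skipped": "no annotations"}
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageFailure(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["_results"] = results
    return manifest


def pool_long_counts(pool_counts: pd.DataFrame, alleles: pd.DataFrame,
                 design_frame: pd.DataFrame) -> pd.DataFrame:
    """Long per locus x family x temperature major/minor count frame."""
    df = pool_counts.merge(alleles, on="locus_id")
    nt = ["A", "C", "G", "T"]
    arr = df[nt].to_numpy()
    idx = {b: i for i, b in enumerate(nt)}
    rows = np.arange(len(df))
    df["major_count"] = arr[rows, df["major_allele"].map(idx)]
    df["minor_count"] = arr[rows, df["minor_allele"].map(idx)]
    parsed = df["sample_id"].map(simdata.parse_pool_sample_id)
    df["family_id"] = [p[0] for p in parsed]
    df["temperature"] = [p[1] for p in parsed]
    fam_origin = design_frame.set_index("family_id")["origin"]
    df["origin"] = df["family_id"].map(fam_origin)
    return df[["locus_id", "family_id", "origin", "temperature",
               "major_count", "minor_count"]]


def _group_mafs(pool_matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean ambient MAF per origin group (loci x groups)."""
    amb = meta[meta["temperature"] == 27.0]
    out = {}
    for origin, grp in amb.groupby("origin"):
        out[origin] = pool_matrix.loc[grp["sample_id"]].mean(axis=0)
    return pd.DataFrame(out)


# short internal aliases
_long_counts = pool_long_counts
_pool_meta = pool_sample_metadata
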