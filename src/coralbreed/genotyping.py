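"""Genotype and pooled allele-frequency calling from per-locus read counts.

Parents are scored as "distance from reference base": alleles carrying <5% of
a sample's reads at a locus are treated as sequencing error and discarded; if
the remaining coverage is below 5 reads the genotype is missing; otherwise a
single remaining allele scores 0 (reference) or 1 (alternate homozygote) and
two remaining alleles score 0.5.  Pooled larval samples yield a minor-allele
frequency when total coverage reaches 50 reads.  Both thresholds are strict
inequalities: an allele at exactly 5% is retained and a coverage of exactly 5
is called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
log = logging.getLogger(__name__)

ERROR_MAF = 0.05        # alleles below this read fraction are discarded
MIN_PARENT_COV = 5      # minimum post-filter coverage to call a parent genotype
MIN_POOL_COV = 50       # minimum total coverage to call a pooled MAF


def call_parent_genotype(
    counts: dict[str, int],
    reference_base: str,
    error_maf: float = ERROR_MAF,
    min_coverage: int = MIN_PARENT_COV,
) -> float:
    """Score one parent at one locus; returns 0, 0.5, 1 or NaN (missing).

    Multi-allelic calls (more than two alleles surviving the error filter)
    are set to missing with a warning rather than dropping the locus.
    """
    vals = np.array([max(0, int(counts.get(b, 0))) for b in NUCLEOTIDES], dtype=float)
    total = vals.sum()
    if total == 0:
        return float("nan")
    keep = vals / total >= error_maf          # "<5%" is strict: ==5% survives
    remaining = vals[keep].sum()
    if remaining < min_coverage:              # "<5 reads" is strict: ==5 called
        return float("nan")
    alleles = [b for b, k in zip(NUCLEOTIDES, keep) if k and counts.get(b, 0) > 0]
    if len(alleles) == 1:
        return 0.0 if alleles[0] == reference_base else 1.0
    if len(alleles) == 2:
        return 0.5
    log.warning("multi-allelic call (%d alleles) set to missing", len(alleles))
    return float("nan")


def call_parent_genotypes(
    count_table: pd.DataFrame,
    registry: pd.DataFrame,
    error_maf: float = ERROR_MAF,
    min_coverage: int = MIN_PARENT_COV,
) -> pd.DataFrame:
    """Vectorised parent calling over a long count table.

    ``count_table`` has columns locus_id, sample_id, A, C, G, T; the registry
    supplies each locus's reference base.  Returns a parents x loci matrix of
    scores with NaN for missing.
    """
    df = count_table
    counts = df[list(NUCLEOTIDES)].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / total[:, None]
    keep = frac >= error_maf
    kept_counts = np.where(keep, counts, 0.0)
    remaining = kept_counts.sum(axis=1)
    n_alleles = (kept_counts > 0).sum(axis=1)

    ref_base = df["locus_id"].map(
        registry.set_index("locus_id")["ref_base"]).to_numpy()
    ref_col = np.array([NUCLEOTIDES.index(b) for b in ref_base])
    ref_kept = kept_counts[np.arange(len(df)), ref_col] > 0

    score = np.full(len(df), np.nan)
    callable_ = (total > 0) & (remaining >= min_coverage)
    one = callable_ & (n_alleles == 1)
    two = callable_ & (n_alleles == 2)
    score[one & ref_kept] = 0.0
    score[one & ~ref_kept] = 1.0
    score[two] = 0.5
    n_multi = int((callable_ & (n_alleles > 2)).sum())
    if n_multi:
        log.warning("%d multi-allelic parent calls set to missing", n_multi)

    out = df[["locus_id", "sample_id"]].copy()
    out["score"] = score
    return out.pivot(index="sample_id", columns="locus_id", values="score")


def designate_minor_alleles(
    count_table: pd.DataFrame,
    ambient_sample_ids: list[str],
) -> pd.DataFrame:
    """Designate each locus's major and minor allele from pooled ambient counts.

    The minor allele is defined globally per locus as the less frequent of
    the two most abundant nucleotides across all ambient-temperature pooled
    samples combined, ties broken by nucleotide lexicographic order.  A single
    consistent axis is required so frequencies are comparable across samples.
    """
    amb = count_table[count_table["sample_id"].isin(ambient_sample_ids)]
    sums = amb.groupby("locus_id")[list(NUCLEOTIDES)].sum()
    arr = sums.to_numpy()
    # stable lexicographic tie-break: argsort on (-count, base index)
    order = np.argsort(-arr, axis=1, kind="stable")
    major_idx, minor_idx = order[:, 0], order[:, 1]
    bases = np.array(NUCLEOTIDES)
    return pd.DataFrame({
        "locus_id": sums.index,
        "major_allele": bases[major_idx],
        "minor_allele": bases[minor_idx],
    }).reset_index(drop=True)


def call_pooled_maf(
    counts: dict[str, int],
    minor_allele: str,
    min_coverage: int = MIN_POOL_COV,
) -> float:
    """Minor-allele frequency of one pooled sample at one locus, or NaN."""
    total = sum(max(0, int(counts.get(b, 0))) for b in NUCLEOTIDES)
    if total < min_coverage:
        return float("nan")
    return counts.get(minor_allele, 0) / total


def call_pooled_mafs(
    count_table: pd.DataFrame,
    allele_table: pd.DataFrame,
    min_coverage: int = MIN_POOL_COV,
) -> pd.DataFrame:
    """Vectorised pooled-MAF calling; returns a samples x loci matrix (NaN missing)."""
    df = count_table.merge(allele_table, on="locus_id", how="inner")
    counts = df[list(NUCLEOTIDES)].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    minor_col = df["minor_allele"].map({b: i for i, b in enumerate(NUCLEOTIDES)})
    minor = counts[np.arange(len(df)), minor_col.to_numpy()]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total >= min_coverage, minor / total, np.nan)
    out = df[["locus_id", "sample_id"]].copy()
    out["maf"] = maf
    return out.pivot(index="sample_id", columns="locus_id", values="maf")


@dataclass
class FilterReport:
    """Ordered record of what each dataset-level filter removed."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, step: str, n_removed: int) -> None:
        self.steps.append((step, int(n_removed)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed"])


class NoLociSurviveError(ValueError):
    """Every locus was removed by the dataset-level filters."""


def _is_monomorphic(matrix: pd.DataFrame, kind: str) -> pd.Series:
    if kind == "parent":
        # a single shared score of 0 or 1 shows no variation; a shared 0.5
        # means every parent segregates, which is polymorphic
        nunique = matrix.nunique(dropna=True)
        only_val = matrix.max(skipna=True)
        return (nunique == 0) | ((nunique == 1) & only_val.isin([0.0, 1.0]))
    # pooled MAF: monomorphic iff no sample shows the minor allele
    return matrix.max(skipna=True).fillna(0.0) == 0.0


def filter_matrix(
    matrix: pd.DataFrame,
    kind: str,
    max_missing_per_sample: float = 0.5,
    max_missing_per_locus: float = 0.5,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply sample-missingness, locus-missingness and monomorphic filters.

    Removal order: samples with too much missing data first, then loci with
    too much missing data among the retained samples, then loci monomorphic
    across the retained samples.  ``kind`` is ``"parent"`` (scores) or
    ``"pool"`` (MAFs).
    """
    for thr in (max_missing_per_sample, max_missing_per_locus):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("missingness thresholds must be in [0, 1]")
    if report is None:
        report = FilterReport()
    m = matrix
    sample_missing = m.isna().mean(axis=1)
    drop_samples = sample_missing > max_missing_per_sample
    report.add(f"{kind}_samples_missing", drop_samples.sum())
    m = m.loc[~drop_samples]
    locus_missing = m.isna().mean(axis=0)
    drop_loci = locus_missing > max_missing_per_locus
    report.add(f"{kind}_loci_missing", drop_loci.sum())
    m = m.loc[:, ~drop_loci]
    mono = _is_monomorphic(m, kind)
    report.add(f"{kind}_loci_monomorphic", mono.sum())
    m = m.loc[:, ~mono]
    if m.shape[1] == 0:
        raise NoLociSurviveError(f"no {kind} loci survive filtering")
    return m, report


def filter_dataset(
    parent_matrix: pd.DataFrame,
    pooled_matrix: pd.DataFrame,
    max_missing_per_sample: float = 0.5,
    max_missing_per_locus: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Filter the parent and pooled matrices; locus sets stay independent."""
    report = FilterReport()
    parents, report = filter_matrix(
        parent_matrix, "parent", max_missing_per_sample, max_missing_per_locus, report)
    pools, report = filter_matrix(
        pooled_matrix, "pool", max_missing_per_sample, max_missing_per_locus, report)
    return parents, pools, report
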