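"""Allele-frequency shifts between heat-exposed and ambient larval pools.

Each locus is tested by a binomial regression of normalised allele read
counts on temperature (27 vs 36 degC) across the families of an origin
subset, Bonferroni-corrected within the subset.  Because temperature is the
only model term, the maximum-likelihood fit has one frequency per
temperature, so the likelihood-ratio statistic is computed in closed form on
the aggregated normalised counts; this is exactly the two-level binomial GLM
deviance test.  Counts are first scaled to the median per-sample total depth
and rounded half-to-even, so p-values are approximate under rounding.

Also provides per-origin summaries (proportion of significant loci, mean
absolute shift, fixation contrasts) and the PCA of hybrid movement toward
the hot-origin purebreds after heat exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHA = 0.05
PCA_ALPHA = 0.001
PCA_MISSING = 0.10
FIXATION_MAF = 0.01


@dataclass
class SelectionScan:
    """Per-locus selection statistics for one family subset."""

    table: pd.DataFrame      # index locus_id: maf27, maf36, shift, p, p_adj
    origin: str              # "all", "PG", "IO" or "PGxIO"
    n_tested: int

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["p_adj"] < ALPHA]


def _normalize_counts(long_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample's counts to the median per-sample total depth.

    Rounding is half-to-even so totals stay integral on average; binomial
    GLMs need integer counts on a comparable scale across libraries.
    """
    df = long_counts.copy()
    key = ["family_id", "temperature"]
    totals = df.groupby(key)[["major_count", "minor_count"]].sum().sum(axis=1)
    target = totals.median()
    factor = pd.MultiIndex.from_frame(df[key]).map(target / totals)
    for col in ("major_count", "minor_count"):
        df[col] = np.rint(df[col] * np.asarray(factor)).astype(np.int64)
    return df


def scan_selection(
    long_counts: pd.DataFrame,
    ambient: float = 27.0,
    heat: float = 36.0,
    origin: str = "all",
    alpha: float = ALPHA,
    min_families: int = 2,
    normalize: bool = True,
) -> SelectionScan:
    """Test per-locus allele-frequency differences between temperatures.

    ``long_counts`` has one row per locus x family x temperature with columns
    locus_id, family_id, origin, temperature, major_count, minor_count.
    Families not represented at both temperatures are excluded; a family with
    zero coverage at a locus at either temperature is skipped for that locus.
    """
    df = long_counts[long_counts["temperature"].isin([ambient, heat])]
    if origin != "all":
        df = df[df["origin"] == origin]
    rep = df.groupby("family_id")["temperature"].nunique()
    both = rep.index[rep == 2]
    df = df[df["family_id"].isin(both)]
    if normalize:
        df = _normalize_counts(df)

    df = df.assign(total=lambda d: d["major_count"] + d["minor_count"])
    df = df[df["total"] > 0]
    # keep locus-family cells present at both temperatures
    cell = df.groupby(["locus_id", "family_id"])["temperature"].transform("nunique")
    df = df[cell == 2]

    agg = (df.groupby(["locus_id", "temperature"])[["minor_count", "total"]]
           .sum().unstack("temperature"))
    nfam = (df[df["temperature"] == ambient]
            .groupby("locus_id")["family_id"].nunique())
    agg = agg.loc[nfam.index[nfam >= min_families]]
    if agg.empty:
        return SelectionScan(pd.DataFrame(
            columns=["maf_ambient", "maf_heat", "shift", "p", "p_adj"]), origin, 0)

    k27 = agg[("minor_count", ambient)].to_numpy(dtype=float)
    n27 = agg[("total", ambient)].to_numpy(dtype=float)
    k36 = agg[("minor_count", heat)].to_numpy(dtype=float)
    n36 = agg[("total", heat)].to_numpy(dtype=float)

    # family-mean frequencies (unweighted across families) for the shift
    df = df.assign(freq=lambda d: d["minor_count"] / d["total"])
    fm = (df.pivot_table(index="locus_id", columns="temperature",
                         values="freq", aggfunc="mean")
          .reindex(agg.index))

    def xlogx(x):
        return np.where(x > 0, x * np.log(np.maximum(x, 1e-300)), 0.0)

    def loglik(k, n):
        # profile log-likelihood k log(k/n) + (n-k) log(1-k/n)
        return xlogx(k) + xlogx(n - k) - xlogx(n)

    # closed-form two-level binomial GLM LRT
    ll_full = loglik(k27, n27) + loglik(k36, n36)
    ll_null = loglik(k27 + k36, n27 + n36)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    m = len(agg)
    table = pd.DataFrame({
        "maf_ambient": fm[ambient],
        "maf_heat": fm[heat],
        "shift": fm[heat] - fm[ambient],
        "p": p,
        "p_adj": np.minimum(p * m, 1.0),
    }, index=agg.index)
    return SelectionScan(table=table, origin=origin, n_tested=m)


def summarize_selection(
    scans: dict[str, SelectionScan],
    maf_by_group: pd.DataFrame | None = None,
    fixation_maf: float = FIXATION_MAF,
) -> pd.DataFrame:
    """Per-origin proportion of significant loci and mean |shift| at them.

    When ``maf_by_group`` (index locus_id, one column of mean minor-allele
    frequency per origin group) is supplied, fixation of heat-selected loci
    (group MAF < ``fixation_maf``) is contrasted between groups and the
    PG:IO fixation-likelihood ratio reported in the frame's attrs.
    """
    rows = []
    for origin, scan in scans.items():
        sig = scan.significant
        rows.append({
            "origin": origin,
            "n_tested": scan.n_tested,
            "n_significant": len(sig),
            "prop_significant": len(sig) / scan.n_tested if scan.n_tested else np.nan,
            "mean_abs_shift_significant":
                scan.table.loc[sig, "shift"].abs().mean() if len(sig) else np.nan,
        })
    out = pd.DataFrame(rows)
    if maf_by_group is not None and "all" in scans:
        sig = scans["all"].significant
        sub = maf_by_group.reindex(sig).dropna()
        fixed = (sub < fixation_maf)
        prop = fixed.mean()
        out.attrs["fixation_proportion"] = prop.to_dict()
        if "IO" in prop.index and prop.get("IO", 0) > 0:
            out.attrs["pg_io_fixation_ratio"] = float(
                prop.get("PG", np.nan) / prop["IO"])
        else:
            out.attrs["pg_io_fixation_ratio"] = float("nan")
    return out


class PCAFilterError(ValueError):
    """Fewer than two loci pass the PCA filters."""


def hybrid_shift_pca(
    maf_matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    selection_p_adj: pd.Series,
    pca_alpha: float = PCA_ALPHA,
    max_missing: float = PCA_MISSING,
) -> pd.DataFrame:
    """PCA of pooled MAFs at heat-selected loci, for all family x T samples.

    Loci are filtered to Bonferroni-adjusted p < ``pca_alpha`` from the
    hybrid-subset selection scan and to less than ``max_missing`` missing
    data across samples; remaining missing values are imputed with the
    origin-group mean (hybrids by the hybrid group itself).  Columns are
    centred and samples projected onto the top two components with a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive).
    """
    sig_loci = selection_p_adj.index[selection_p_adj < pca_alpha]
    loci = maf_matrix.columns.intersection(sig_loci)
    if len(loci) < 2:
        raise PCAFilterError(
            f"only {len(loci)} loci pass adjusted p < {pca_alpha}")
    sub = maf_matrix.loc[:, loci]
    keep = sub.isna().mean(axis=0) < max_missing
    sub = sub.loc[:, keep]
    if sub.shape[1] < 2:
        raise PCAFilterError(
            f"only {sub.shape[1]} loci pass the {max_missing:.0%} missing filter")

    origin = sample_meta.set_index("sample_id")["origin"].reindex(sub.index)
    imputed = sub.copy()
    for grp, idx in origin.groupby(origin).groups.items():
        block = sub.loc[idx]
        imputed.loc[idx] = block.fillna(block.mean(axis=0))
    # any column still missing (group entirely missing): overall mean
    imputed = imputed.fillna(sub.mean(axis=0))

    X = imputed.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :2] * S[:2]
    for j in range(2):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            coords[:, j] *= -1.0
            Vt[j] *= -1.0
    var = S ** 2 / (S ** 2).sum()
    out = pd.DataFrame(coords, index=sub.index, columns=["PC1", "PC2"])
    out["origin"] = origin
    out.attrs["explained_variance_ratio"] = var[:2].tolist()
    out.attrs["n_loci"] = sub.shape[1]
    return out


def centroid_shift(
    coords: pd.DataFrame,
    sample_meta: pd.DataFrame,
    heat: float = 36.0,
    ambient: float = 27.0,
) -> dict:
    """Distance of hybrid centroids (per temperature) to the PG centroid.

    A negative ``delta`` (heat centroid closer than ambient) indicates the
    surviving hybrid pools moved toward the hot-origin purebreds.
    """
    meta = sample_meta.set_index("sample_id").reindex(coords.index)
    pts = coords[["PC1", "PC2"]].to_numpy()

    def centroid(mask):
        return pts[mask.to_numpy()].mean(axis=0)

    pg = centroid(meta["origin"] == "PG")
    hyb27 = centroid((meta["origin"] == "PGxIO") & (meta["temperature"] == ambient))
    hyb36 = centroid((meta["origin"] == "PGxIO") & (meta["temperature"] == heat))
    d27 = float(np.linalg.norm(hyb27 - pg))
    d36 = float(np.linalg.norm(hyb36 - pg))
    return {"dist_ambient": d27, "dist_heat": d36, "delta": d36 - d27,
            "moved_toward_pg": d36 < d27}
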