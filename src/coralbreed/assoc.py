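"""Per-SNP association between baseline allele frequencies and heat survival.

For each locus the ambient (27 degC) pooled minor-allele frequency across
families is related to the family's alive/dead counts at 36 degC by a
binomial logistic regression with parental origin as a fixed covariate; the
MAF slope is tested by likelihood-ratio.  A Pearson correlation R between
MAF and the raw survival proportion classifies loci: |R| >= 0.5 is "strong".
Parental genotypes are then scored for the proportion of beneficial alleles
(the allele whose higher frequency predicts higher survival) and correlated
with paternal performance, and paternal genotypes at strong loci are
clustered.

The per-locus GLMs are fitted by a Newton/IRLS solver batched across loci
sharing a missingness pattern, which makes genome-scale scans fast; it is
numerically the same fit as a conventional single-locus GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

STRONG_R = 0.5
ALPHA = 0.05
MIN_FAMILIES = 3
MIN_SHARED_LOCI = 10


def _fit_glm_batch(
    C: np.ndarray, mafs: np.ndarray, alive: np.ndarray, n: np.ndarray,
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for binomial GLM alive/n ~ C + maf, per locus.

    ``C`` is the shared (families x q) covariate matrix (intercept + origin
    dummies), ``mafs`` is (loci x families).  Returns (deviance_full,
    deviance_null) per locus, where the null model omits the MAF column.
    """
    L, nf = mafs.shape
    q = C.shape[1]
    p_dim = q + 1

    def deviance(eta):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(alive > 0, alive * np.log(alive / (n * mu)), 0.0)
            dead = n - alive
            term2 = np.where(dead > 0, dead * np.log(dead / (n * (1 - mu))), 0.0)
        return 2.0 * (term1 + term2).sum(axis=-1)

    # null model: shared across loci (no MAF column)
    beta0 = np.zeros(q)
    for _ in range(max_iter):
        eta = C @ beta0
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu) + 1e-12
        z = eta + (alive - n * mu) / w
        WC = C * w[:, None]
        beta_new = np.linalg.solve(C.T @ WC, WC.T @ z)
        if np.max(np.abs(beta_new - beta0)) < tol:
            beta0 = beta_new
            break
        beta0 = beta_new
    dev_null = float(deviance(C @ beta0))

    # full model, batched over loci
    B = np.zeros((L, p_dim))
    B[:, :q] = beta0
    active = np.ones(L, dtype=bool)
    for _ in range(max_iter):
        eta = B[:, :q] @ C.T + B[:, q:q + 1] * mafs      # (L, nf)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu) + 1e-12
        z = eta + (alive - n * mu) / w
        # build per-locus design products via einsum
        H = np.empty((L, p_dim, p_dim))
        H[:, :q, :q] = np.einsum("ni,ln,nj->lij", C, w, C)
        cm = np.einsum("ni,ln,ln->li", C, w, mafs)
        H[:, :q, q] = cm
        H[:, q, :q] = cm
        H[:, q, q] = np.einsum("ln,ln->l", w * mafs, mafs)
        g = np.empty((L, p_dim))
        g[:, :q] = np.einsum("ni,ln,ln->li", C, w, z)
        g[:, q] = np.einsum("ln,ln->l", w * mafs, z)
        try:
            B_new = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            H += 1e-8 * np.eye(p_dim)[None]
            B_new = np.linalg.solve(H, g[..., None])[..., 0]
        delta = np.max(np.abs(B_new - B), axis=1)
        B = B_new
        active = delta >= tol
        if not active.any():
            break
    eta = B[:, :q] @ C.T + B[:, q:q + 1] * mafs
    dev_full = deviance(eta)
    return dev_full, np.full(L, dev_null)


@dataclass
class AssocScan:
    """Result of the genome-wide MAF vs survival association scan."""

    table: pd.DataFrame          # per-locus statistics
    n_tested: int                # Bonferroni m: loci actually tested

    def classified(self, klass: str) -> pd.Index:
        return self.table.index[self.table["class"] == klass]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["p_adj"] < ALPHA]

    def summary(self) -> dict:
        t = self.table
        return {
            "n_tested": self.n_tested,
            "n_strong": int((t["class"] == "strong").sum()),
            "n_moderate_weak": int((t["class"] == "moderate_weak").sum()),
            "frac_strong": float((t["class"] == "strong").mean()),
            "frac_moderate_weak": float((t["class"] == "moderate_weak").mean()),
            "n_significant": int((t["p_adj"] < ALPHA).sum()),
        }


def classification_fractions(n_strong: int, n_moderate_weak: int, n_tested: int) -> dict:
    """Fractions of tested SNPs in each predictive class, as percentages."""
    return {
        "strong_pct": 100.0 * n_strong / n_tested,
        "moderate_weak_pct": 100.0 * n_moderate_weak / n_tested,
    }


def scan_survival_association(
    ambient_maf: pd.DataFrame,
    survival: pd.DataFrame,
    allele_table: pd.DataFrame | None = None,
    strong_r: float = STRONG_R,
    alpha: float = ALPHA,
    min_families: int = MIN_FAMILIES,
) -> AssocScan:
    """Associate ambient pooled MAFs with family heat survival, per locus.

    ``ambient_maf`` is a families x loci MAF matrix (index: family_id);
    ``survival`` has one row per family with columns family_id, origin,
    n_start, n_alive_60h at 36 degC.  Loci with fewer than ``min_families``
    non-missing frequencies or with a constant MAF are reported as class
    ``none`` with p = 1.  Bonferroni adjustment uses the number of loci
    actually tested.
    """
    surv = survival.set_index("family_id")
    fams = [f for f in ambient_maf.index if f in surv.index]
    maf = ambient_maf.loc[fams]
    alive = surv.loc[fams, "n_alive_60h"].to_numpy(dtype=float)
    n = surv.loc[fams, "n_start"].to_numpy(dtype=float)
    prop = alive / n
    origin = pd.get_dummies(surv.loc[fams, "origin"], drop_first=True)
    C = np.column_stack([np.ones(len(fams)), origin.to_numpy(dtype=float)])

    loci = maf.columns
    M = maf.to_numpy(dtype=float).T            # loci x families
    obs = ~np.isnan(M)
    testable = (obs.sum(axis=1) >= min_families)
    const = np.nanstd(np.where(obs, M, np.nan), axis=1) == 0
    testable &= ~const

    p = np.ones(len(loci))
    slope = np.full(len(loci), np.nan)
    R = np.full(len(loci), np.nan)

    # Pearson R per locus on observed families
    for pattern in np.unique(obs[testable], axis=0):
        sel = testable & (obs == pattern).all(axis=1)
        if not sel.any():
            continue
        cols = pattern
        if cols.sum() < min_families:
            continue
        sub = M[np.ix_(sel, cols)]
        y = prop[cols]
        sx = sub.std(axis=1)
        sy = y.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((sub - sub.mean(axis=1, keepdims=True)) @ (y - y.mean())
                 / (sub.shape[1] * sx * sy))
        R[sel] = r
        dev_full, dev_null = _fit_glm_batch(
            C[cols], sub, alive[cols], n[cols])
        lrt = np.maximum(dev_null - dev_full, 0.0)
        p[sel] = stats.chi2.sf(lrt, df=1)

    m = int(testable.sum())
    p_adj = np.minimum(p * m, 1.0)
    p_adj[~testable] = 1.0

    klass = np.where(np.abs(R) >= strong_r, "strong",
                     np.where(p_adj < alpha, "moderate_weak", "none"))
    klass[~testable] = "none"

    table = pd.DataFrame({
        "R": R, "p": np.where(testable, p, 1.0), "p_adj": p_adj,
        "class": klass, "tested": testable,
    }, index=loci)
    if allele_table is not None:
        al = allele_table.set_index("locus_id")
        table["minor_allele"] = al["minor_allele"].reindex(loci)
        table["major_allele"] = al["major_allele"].reindex(loci)
        # positive R: higher minor-allele frequency predicts higher survival
        table["beneficial_allele"] = np.where(
            np.isnan(R), None,
            np.where(R > 0, table["minor_allele"], table["major_allele"]))
    return AssocScan(table=table, n_tested=m)


def score_parent(
    genotypes: pd.Series,
    beneficial_is_alt: pd.Series,
) -> float:
    """Mean beneficial-allele proportion for one parent over significant loci.

    ``genotypes`` holds distance-from-reference scores (0, 0.5, 1, NaN) at
    the significant loci; ``beneficial_is_alt`` is True where the beneficial
    allele is the alternate (non-reference) allele.  Two, one and zero copies
    of the beneficial allele score 1, 0.5 and 0; the mean skips missing
    genotypes and is missing when every locus is missing.
    """
    loci = genotypes.index.intersection(beneficial_is_alt.index)
    g = genotypes.loc[loci].astype(float)
    flip = ~beneficial_is_alt.loc[loci].astype(bool)
    scores = g.where(~flip, 1.0 - g)
    if scores.notna().sum() == 0:
        return float("nan")
    return float(scores.mean())


def score_parents(
    parent_matrix: pd.DataFrame,
    scan: AssocScan,
    registry: pd.DataFrame,
    loci: pd.Index | None = None,
) -> pd.DataFrame:
    """Beneficial-allele proportion per parent at the significant loci.

    ``loci`` defaults to the scan's Bonferroni-significant set.  The
    beneficial allele per locus comes from the scan; the registry maps it to
    reference/alternate so distance-from-reference genotypes can be scored.
    """
    if loci is None:
        loci = scan.significant
    loci = pd.Index(loci).intersection(parent_matrix.columns)
    if len(loci) == 0:
        raise ValueError("no significant loci overlap the parent matrix")
    reg = registry.set_index("locus_id")
    beneficial = scan.table.loc[loci, "beneficial_allele"]
    beneficial_is_alt = beneficial.eq(reg["alt_base"].reindex(loci))
    rows = []
    for pid, g in parent_matrix.loc[:, loci].iterrows():
        s = score_parent(g, beneficial_is_alt)
        rows.append({"parent_id": pid, "n_loci_scored": int(g.notna().sum()),
                     "beneficial_proportion": s})
    return pd.DataFrame(rows)


def correlate_parent_performance(
    scores: pd.DataFrame,
    sire_index_means: pd.Series,
    exclude: list[str] | None = None,
) -> dict:
    """Pearson correlation of paternal beneficial-allele proportion vs performance.

    ``sire_index_means`` is the per-sire mean survival index; ``exclude``
    names sires to drop (e.g. an outlier represented by a single cross).
    """
    s = scores.set_index("parent_id")["beneficial_proportion"]
    common = s.index.intersection(sire_index_means.index)
    if exclude:
        common = common.difference(exclude)
    x = s.loc[common].dropna()
    y = sire_index_means.loc[x.index].dropna()
    x = x.loc[y.index]
    if len(x) < 3:
        raise ValueError(f"need >=3 sires after exclusions, have {len(x)}")
    r, p = stats.pearsonr(x, y)
    return {"R": float(r), "p": float(p), "n": int(len(x)),
            "excluded": list(exclude or [])}


def cluster_paternal_genotypes(
    parent_matrix: pd.DataFrame,
    loci: pd.Index,
    min_shared: int = MIN_SHARED_LOCI,
) -> dict:
    """Pairwise genotype correlation at strong loci + average-linkage clustering.

    Correlations use shared non-missing loci per pair; pairs sharing fewer
    than ``min_shared`` loci are flagged low-confidence.  Clustering is
    average linkage on (1 - correlation) with deterministic leaf order
    (parents sorted by id before linkage; scipy's ordering is then
    reproducible).
    """
    sub = parent_matrix.loc[sorted(parent_matrix.index), loci].astype(float)
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("need >=2 parents and >=2 loci")
    corr = sub.T.corr(min_periods=2)
    shared = (~sub.isna()).astype(float) @ (~sub.isna()).T.astype(float)
    low_conf = [
        (a, b) for i, a in enumerate(corr.index) for b in corr.index[i + 1:]
        if shared.loc[a, b] < min_shared
    ]
    if low_conf:
        log.warning("%d parent pairs share <%d loci; correlations are "
                    "low-confidence", len(low_conf), min_shared)
    dist = 1.0 - corr.fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [corr.index[i] for i in hierarchy.leaves_list(Z)]
    return {"correlation": corr, "linkage": Z, "leaf_order": order,
            "low_confidence_pairs": low_conf}


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a newick dendrogram string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
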