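"""Gene-level GO enrichment of loci implicated by the association/selection scans.

Study genes are those containing at least one significant intragenic locus;
the background is genes containing at least one tested intragenic locus.
Each GO term is tested with a one-sided hypergeometric tail (classic Fisher),
and called significant when p < 0.05 and the term occurs at least 5 times in
the background set.  No multiple-testing correction is applied across terms.
True-path propagation to ancestor terms is applied when an ontology graph is
supplied; otherwise terms are treated flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

P_THRESHOLD = 0.05
MIN_BACKGROUND = 5


@dataclass(frozen=True)
class GeneAnnotationMap:
    """Locus -> gene (intragenic only) and gene -> GO-term assignments."""

    locus_to_gene: dict[str, str]
    gene_to_terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        bad = [t for terms in self.gene_to_terms.values() for t in terms
               if not (t.startswith("GO:") and t[3:].isdigit() and len(t) == 10)]
        if bad:
            raise ValueError(f"malformed GO term ids: {sorted(set(bad))[:5]}")

    @classmethod
    def from_frames(cls, locus_gene: pd.DataFrame,
                    gene_terms: pd.DataFrame) -> "GeneAnnotationMap":
        """Build from a locus_id/gene_id frame and a gene_id/terms frame
        (terms comma-separated)."""
        l2g = dict(zip(locus_gene["locus_id"], locus_gene["gene_id"]))
        g2t = {
            row["gene_id"]: frozenset(
                t.strip() for t in str(row["terms"]).split(",") if t.strip())
            for _, row in gene_terms.iterrows()
        }
        return cls(locus_to_gene=l2g, gene_to_terms=g2t)


def genes_from_loci(
    significant_loci: list[str],
    tested_loci: list[str],
    annotation: GeneAnnotationMap,
) -> tuple[set[str], set[str]]:
    """Map significant and tested loci to study and background gene sets.

    Intergenic loci (no gene assignment) are dropped with a logged count.
    """
    def to_genes(loci):
        genes, dropped = set(), 0
        for locus in loci:
            gene = annotation.locus_to_gene.get(locus)
            if gene is None:
                dropped += 1
            else:
                genes.add(gene)
        return genes, dropped

    study, n_inter_study = to_genes(significant_loci)
    background, n_inter_bg = to_genes(tested_loci)
    log.info("intergenic loci dropped: %d study, %d background",
             n_inter_study, n_inter_bg)
    if not study:
        raise ValueError("study gene set is empty")
    background |= study
    return study, background


def _propagate(terms: frozenset[str], ancestors: dict[str, set[str]]) -> set[str]:
    out = set(terms)
    for t in terms:
        out |= ancestors.get(t, set())
    return out


def fisher_enrichment(
    study: set[str],
    background: set[str],
    annotation: GeneAnnotationMap,
    ontology=None,
    p_threshold: float = P_THRESHOLD,
    min_background: int = MIN_BACKGROUND,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of GO terms in the study set.

    ``ontology`` may be a networkx DiGraph with child -> parent edges (e.g.
    loaded by obonet), in which case gene annotations are propagated to
    ancestor terms before testing.  Terms absent from the background are
    skipped.  p = P(X >= observed) with X ~ Hypergeom(N, K, n).
    """
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    ancestors: dict[str, set[str]] = {}
    if ontology is not None:
        import networkx as nx
        ancestors = {t: set(nx.descendants(ontology, t))
                     for t in ontology.nodes}

    def annot(gene):
        terms = annotation.gene_to_terms.get(gene, frozenset())
        return _propagate(terms, ancestors) if ancestors else terms

    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for t in annot(gene):
            term_bg[t] = term_bg.get(t, 0) + 1
    for gene in study:
        for t in annot(gene):
            term_study[t] = term_study.get(t, 0) + 1

    N, n = len(background), len(study)
    rows = []
    for term, K in sorted(term_bg.items()):
        k = term_study.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term, "study_count": k, "background_count": K,
            "p": p,
            "significant": (p < p_threshold) and (K >= min_background),
        })
    return pd.DataFrame(rows)
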