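"""Table schemas, validated readers/writers, and VCF export.

Interchange is TSV/CSV with explicit headers.  Writers are byte-stable for a
fixed input: rows are sorted on the key columns and floats formatted at six
significant digits.  Readers validate the header against the schema and name
the offending column or row on failure.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SCHEMAS: dict[str, dict] = {
    "survival": {
        "columns": ["family_id", "dam_id", "sire_id", "origin", "temperature",
                    "plate", "n_start", "n_alive_60h"],
        "dtypes": {"temperature": float, "plate": int,
                   "n_start": int, "n_alive_60h": int},
        "sep": ",", "sort": ["family_id", "temperature", "plate"],
    },
    "field_survival": {
        "columns": ["family_id", "origin", "n_deployed", "n_survivors"],
        "dtypes": {"n_deployed": int, "n_survivors": int},
        "sep": ",", "sort": ["family_id"],
    },
    "counts": {
        "columns": ["locus_id", "sample_id", "A", "C", "G", "T"],
        "dtypes": {"A": int, "C": int, "G": int, "T": int},
        "sep": "\t", "sort": ["locus_id", "sample_id"],
    },
    "registry": {
        "columns": ["locus_id", "contig", "position", "ref_base", "alt_base",
                    "gene_id"],
        "dtypes": {"position": int},
        "sep": "\t", "sort": ["locus_id"],
    },
    "gene_terms": {
        "columns": ["gene_id", "terms"],
        "dtypes": {},
        "sep": "\t", "sort": ["gene_id"],
    },
}


class SchemaError(ValueError):
    """Header or cell contents do not match the declared schema."""


def _float_fmt(x: float) -> str:
    return f"{x:.6g}"


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a table deterministically under a named schema."""
    spec = SCHEMAS[schema]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing columns {missing}")
    out = df[spec["columns"]].sort_values(spec["sort"], kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=spec["sep"], index=False, float_format="%.6g",
               lineterminator="\n")
    log.info("wrote %s (%d rows, sha256 %s)", path, len(out),
             hashlib.sha256(path.read_bytes()).hexdigest()[:12])


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a table written under a named schema."""
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=spec["sep"])
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, dtype in spec["dtypes"].items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise SchemaError(
                f"{path}: column {col!r} malformed near line {row}: {exc}"
            ) from exc
    log.info("read %s (%d rows)", path, len(df))
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 index_name: str = "sample_id") -> None:
    """Write a samples x loci matrix TSV with deterministic ordering."""
    out = matrix.sort_index().sort_index(axis=1)
    out.index.name = index_name
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def export_vcf(
    genotypes: pd.DataFrame, registry: pd.DataFrame, path: str | Path,
) -> None:
    """Export a ParentGenotypeMatrix as a minimal VCFv4.2 (GT field only).

    Distance-from-reference scores map to GT: 0 -> 0/0, 0.5 -> 0/1,
    1 -> 1/1, missing -> ./.  Registry positions are 0-based internally and
    written 1-based here.
    """
    reg = registry.set_index("locus_id")
    samples = list(genotypes.index)
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for locus in sorted(genotypes.columns):
            r = reg.loc[locus]
            gts = [gt_map.get(genotypes.at[s, locus], "./.") for s in samples]
            fh.write(f"{r['contig']}\t{int(r['position']) + 1}\t{locus}\t"
                     f"{r['ref_base']}\t{r['alt_base']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
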