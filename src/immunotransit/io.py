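"""Readers and writers for the cohort bundle and pathway files.

A cohort bundle on disk is a MatrixMarket count matrix (genes in rows, cells
in columns) with tab-separated annotation tables alongside it:

* ``counts.mtx`` — sparse integer UMI counts;
* ``genes.tsv`` — one gene symbol per row (header ``gene``);
* ``cell_meta.tsv`` — per-cell annotations;
* ``clonotypes.csv`` — optional CSV with ``barcode,chain,cdr3_aa,patient,timepoint``;
* ``survival.tsv`` — optional per-patient survival table.

Pathway definitions use the tab-separated GMT dialect
(``name<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import CohortDataset, PathwaySet
from .errors import FormatError, ValidationError

__all__ = ["load_cohort", "save_cohort", "read_gmt", "BUNDLE_FILES"]

BUNDLE_FILES = {
    "counts": "counts.mtx",
    "genes": "genes.tsv",
    "cell_meta": "cell_meta.tsv",
    "clonotypes": "clonotypes.csv",
    "survival": "survival.tsv",
}


def load_cohort(
    mtx_path: str | Path,
    genes_path: str | Path,
    cellmeta_path: str | Path,
    clonotype_path: str | Path | None = None,
    survival_path: str | Path | None = None,
) -> CohortDataset:
    """Read a cohort bundle from disk and validate it.

    Raises
    ------
    FormatError
        If the matrix dimensions disagree with the annotation tables.
    ValidationError
        If any data-model invariant fails (duplicate barcodes, unknown
        timepoints, negative counts, ...).
    """
    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot read MatrixMarket file {mtx_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene" not in genes.columns:
        raise FormatError(f"{genes_path} must have a 'gene' column")
    cell_meta = pd.read_csv(
        cellmeta_path,
        sep="\t",
        dtype={"barcode": str, "patient": str},
        float_precision="round_trip",
    )
    if len(genes) != counts.shape[0]:
        raise FormatError(
            f"gene table has {len(genes)} rows but matrix has {counts.shape[0]} rows"
        )
    if len(cell_meta) != counts.shape[1]:
        raise FormatError(
            f"cell_meta has {len(cell_meta)} rows but matrix has {counts.shape[1]} columns"
        )
    clonotypes = None
    if clonotype_path is not None:
        clonotypes = pd.read_csv(clonotype_path, dtype=str)
    survival = None
    if survival_path is not None:
        survival = pd.read_csv(
            survival_path,
            sep="\t",
            dtype={"patient": str, "arm": str},
            float_precision="round_trip",
        )
    return CohortDataset(
        counts=counts,
        gene_ids=genes["gene"].tolist(),
        cell_meta=cell_meta,
        clonotypes=clonotypes,
        survival=survival,
    )


def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort bundle; returns the paths written, keyed as in BUNDLE_FILES.

    Lossless for integer counts: ``load_cohort`` on the result reproduces the
    dataset field by field.  Optional tables are simply omitted when absent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mtx = out / BUNDLE_FILES["counts"]
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(dataset.counts), field="integer")
    paths["counts"] = mtx
    genes = out / BUNDLE_FILES["genes"]
    pd.DataFrame({"gene": dataset.gene_ids}).to_csv(genes, sep="\t", index=False)
    paths["genes"] = genes
    meta = out / BUNDLE_FILES["cell_meta"]
    dataset.cell_meta.to_csv(meta, sep="\t", index=False)
    paths["cell_meta"] = meta
    if dataset.clonotypes is not None:
        p = out / BUNDLE_FILES["clonotypes"]
        dataset.clonotypes.to_csv(p, index=False)
        paths["clonotypes"] = p
    if dataset.survival is not None:
        p = out / BUNDLE_FILES["survival"]
        dataset.survival.to_csv(p, sep="\t", index=False)
        paths["survival"] = p
    return paths


def load_cohort_dir(bundle_dir: str | Path) -> CohortDataset:
    """Read a bundle written by :func:`save_cohort` from its directory."""
    d = Path(bundle_dir)
    clono = d / BUNDLE_FILES["clonotypes"]
    surv = d / BUNDLE_FILES["survival"]
    return load_cohort(
        d / BUNDLE_FILES["counts"],
        d / BUNDLE_FILES["genes"],
        d / BUNDLE_FILES["cell_meta"],
        clonotype_path=clono if clono.exists() else None,
        survival_path=surv if surv.exists() else None,
    )


def read_gmt(path: str | Path) -> PathwaySet:
    """Parse a GMT pathway file into a :class:`PathwaySet`.

    The description column is dropped; duplicate genes within a set are
    de-duplicated preserving first occurrence; duplicate pathway names are a
    validation error.
    """
    pathways = PathwaySet()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, _description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    if not pathways:
        raise FormatError(f"{path}: no pathways found")
    return pathways
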