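"""Shared data model for the longitudinal PBMC cohort.

A :class:`CohortDataset` bundles a raw UMI count matrix (genes x cells) with
per-cell metadata (patient, treatment arm, survival group, protocol visit,
cell type, subcluster, optional 2-D embedding), an optional TCR clonotype
table, and an optional per-patient survival table.  All downstream stages
consume this object.

Timepoints form a closed vocabulary of the eight protocol visits
(pre-procedure plus pembrolizumab cycles 1, 2, 4, 6, 9, 17 and 34); unknown
labels are rejected so that timepoint ordering is always well defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = [
    "Arm",
    "SurvivalGroup",
    "Timepoint",
    "Chain",
    "TIMEPOINT_ORDER",
    "CD8_SUBTYPES",
    "CohortDataset",
    "PathwaySet",
    "validate_clonotypes",
    "validate_survival",
]


class Arm(str, Enum):
    """Treatment arm: non-LITT surgery or LITT, each followed by pembrolizumab."""

    NLS_PEM = "NLS_PEM"
    LITT_PEM = "LITT_PEM"


class SurvivalGroup(str, Enum):
    """Three-way cohort: control arm, and LITT patients below/above median OS."""

    NLS_PEM = "NLS_PEM"
    LITT_LT_MOS = "LITT_LT_MOS"
    LITT_GT_MOS = "LITT_GT_MOS"


class Timepoint(str, Enum):
    PRE = "PRE"
    C1 = "C1"
    C2 = "C2"
    C4 = "C4"
    C6 = "C6"
    C9 = "C9"
    C17 = "C17"
    C34 = "C34"


class Chain(str, Enum):
    TRA = "TRA"
    TRB = "TRB"


#: Protocol visit order, used wherever timepoints must be sorted.
TIMEPOINT_ORDER: tuple[str, ...] = tuple(tp.value for tp in Timepoint)

#: CD8+ T-cell functional-state vocabulary used by the simulator and the
#: transition analyses: central memory, memory precursor effector, effector
#: memory, effector, cycling, stem-like exhausted, exhausted.
CD8_SUBTYPES: tuple[str, ...] = (
    "CD8_CM",
    "CD8_MPEC",
    "CD8_EM",
    "CD8_EFF",
    "CD8_CYC",
    "CD8_SLEX",
    "CD8_EXH",
)

_CDR3_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

_CELL_META_REQUIRED = (
    "barcode",
    "patient",
    "arm",
    "survival_group",
    "timepoint",
    "cell_type",
    "subcluster",
)

_CLONOTYPE_COLUMNS = ("barcode", "chain", "cdr3_aa", "patient", "timepoint")
_SURVIVAL_COLUMNS = ("patient", "os_months", "event", "age", "arm")


def _check_enum(values: pd.Series, enum_cls: type[Enum], what: str) -> None:
    allowed = {e.value for e in enum_cls}
    bad = set(values.unique()) - allowed
    if bad:
        raise ValidationError(
            f"unknown {what} label(s) {sorted(map(str, bad))}; allowed: {sorted(allowed)}"
        )


def validate_clonotypes(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Validate a clonotype table (barcode, chain, cdr3_aa, patient, timepoint).

    CDR3 sequences must be uppercase strings over the 20 standard amino
    acids, and (barcode, chain) must be unique within a patient-timepoint.
    """
    missing = set(_CLONOTYPE_COLUMNS) - set(clonotypes.columns)
    if missing:
        raise ValidationError(f"clonotype table missing column(s) {sorted(missing)}")
    clonotypes = clonotypes.loc[:, list(_CLONOTYPE_COLUMNS)].reset_index(drop=True)
    _check_enum(clonotypes["chain"], Chain, "chain")
    _check_enum(clonotypes["timepoint"], Timepoint, "timepoint")
    bad = ~clonotypes["cdr3_aa"].astype(str).str.match(_CDR3_RE)
    if bad.any():
        examples = clonotypes.loc[bad, "cdr3_aa"].head(3).tolist()
        raise ValidationError(f"invalid CDR3 amino-acid sequence(s), e.g. {examples}")
    dup = clonotypes.duplicated(subset=["patient", "timepoint", "barcode", "chain"])
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate (barcode, chain) pairs within a patient-timepoint"
        )
    return clonotypes


def validate_survival(survival: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (patient, os_months, event, age, arm)."""
    missing = set(_SURVIVAL_COLUMNS) - set(survival.columns)
    if missing:
        raise ValidationError(f"survival table missing column(s) {sorted(missing)}")
    survival = survival.loc[:, list(_SURVIVAL_COLUMNS)].reset_index(drop=True)
    if survival["patient"].duplicated().any():
        raise ValidationError("duplicate patient in survival table")
    _check_enum(survival["arm"], Arm, "arm")
    if not (survival["os_months"].to_numpy(dtype=float) > 0).all():
        raise ValidationError("os_months must be positive")
    if not (survival["age"].to_numpy(dtype=float) > 0).all():
        raise ValidationError("age must be positive")
    survival["event"] = survival["event"].astype(bool)
    return survival


@dataclass
class CohortDataset:
    """Raw counts plus annotations for one longitudinal cohort.

    Parameters
    ----------
    counts
        Sparse non-negative integer matrix, genes in rows, cells in columns
        (10x orientation).
    gene_ids
        Ordered, unique gene symbols, one per count-matrix row.
    cell_meta
        One row per cell with columns ``barcode, patient, arm,
        survival_group, timepoint, cell_type, subcluster`` and optionally
        ``embed_x, embed_y`` (2-D display embedding).
    clonotypes
        Optional table of TCR contigs per cell barcode.
    survival
        Optional per-patient overall-survival table.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    clonotypes: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[1] == 0 or self.counts.shape[0] == 0:
            raise ValidationError("empty cohort: counts matrix has a zero dimension")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integers (raw UMI)")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} matrix rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        meta = self.cell_meta
        missing = set(_CELL_META_REQUIRED) - set(meta.columns)
        if missing:
            raise ValidationError(f"cell_meta missing column(s) {sorted(missing)}")
        if len(meta) != self.counts.shape[1]:
            raise ValidationError(
                f"cell_meta has {len(meta)} rows for {self.counts.shape[1]} matrix columns"
            )
        if meta["barcode"].duplicated().any():
            raise ValidationError("duplicate cell barcodes")
        _check_enum(meta["arm"], Arm, "arm")
        _check_enum(meta["survival_group"], SurvivalGroup, "survival_group")
        _check_enum(meta["timepoint"], Timepoint, "timepoint")
        self.cell_meta = meta.reset_index(drop=True)
        if self.clonotypes is not None:
            self.clonotypes = validate_clonotypes(self.clonotypes)
        if self.survival is not None:
            self.survival = validate_survival(self.survival)
            known = set(self.survival["patient"])
            orphans = set(meta["patient"].unique()) - known
            if orphans:
                raise ValidationError(
                    f"cells for patient(s) {sorted(orphans)} absent from survival table"
                )

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def has_embedding(self) -> bool:
        return {"embed_x", "embed_y"} <= set(self.cell_meta.columns)

    def gene_index(self, genes: list[str] | str) -> np.ndarray:
        """Row indices for the requested gene symbols (error on absence)."""
        if isinstance(genes, str):
            genes = [genes]
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"gene(s) not in dataset: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CohortDataset":
        """New dataset restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValidationError("cell mask length mismatch")
        if not mask.any():
            raise ValidationError("cell subset is empty")
        meta = self.cell_meta.loc[mask].reset_index(drop=True)
        clono = None
        if self.clonotypes is not None:
            keep = self.clonotypes["barcode"].isin(set(meta["barcode"]))
            clono = self.clonotypes.loc[keep].reset_index(drop=True)
        return CohortDataset(
            counts=self.counts[:, mask],
            gene_ids=list(self.gene_ids),
            cell_meta=meta,
            clonotypes=clono,
            survival=None if self.survival is None else self.survival.copy(),
        )

    def equals(self, other: "CohortDataset") -> bool:
        """Field-by-field equality (counts compared exactly)."""
        if self.gene_ids != other.gene_ids:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        a, b = self.cell_meta, other.cell_meta
        if not a.columns.equals(b.columns) or not a.reset_index(drop=True).equals(
            b.reset_index(drop=True)
        ):
            return False
        for mine, theirs in ((self.clonotypes, other.clonotypes), (self.survival, other.survival)):
            if (mine is None) != (theirs is None):
                return False
            if mine is not None and not mine.reset_index(drop=True).equals(
                theirs.reset_index(drop=True)
            ):
                return False
        return True


class PathwaySet(dict):
    """Mapping of pathway name to an ordered, de-duplicated gene list."""

    def __setitem__(self, name: str, genes: list[str]) -> None:
        if name in self:
            raise ValidationError(f"duplicate pathway name {name!r}")
        if not genes:
            raise ValidationError(f"pathway {name!r} has an empty gene list")
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        super().__setitem__(name, list(seen))
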