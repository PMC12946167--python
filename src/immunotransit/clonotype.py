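"""TCR clonotype collapsing, Simpson diversity and clone-fate tracking.

Clones are defined by exact CDR3 amino-acid identity (cells sharing a
sequence collapse into one clone).  Diversity per patient and visit is the
Simpson index

    D = 1 - sum_i p_i^2,

the probability that two randomly drawn cells belong to different clones;
D = 0 for a monoclonal repertoire and clonal expansion lowers D.  Diversity
ratios between visits, cohort t-tests, clone-fate tables from a source CD8
cluster, and a chi-square test of target-distribution independence across
cohorts complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortDataset, validate_clonotypes
from .errors import AnalysisError

__all__ = [
    "CloneDistribution",
    "collapse_clones",
    "simpson_index",
    "diversity_ratio",
    "diversity_table",
    "compare_diversity",
    "clone_fate",
    "CloneFateTable",
    "chi_square_independence",
]

logger = logging.getLogger(__name__)


@dataclass
class CloneDistribution:
    """Collapsed clone sizes for one patient-timepoint repertoire."""

    counts: pd.Series  # clone CDR3 -> positive integer cell count

    def __post_init__(self) -> None:
        if (self.counts <= 0).any():
            raise AnalysisError("clone counts must be positive")

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float) / self.counts.sum()


def _dedupe_contigs(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """One contig per (patient, timepoint, barcode, chain): keep the first."""
    return clonotypes.drop_duplicates(subset=["patient", "timepoint", "barcode", "chain"])


def collapse_clones(
    clonotypes: pd.DataFrame,
    chain: str = "TRB",
    barcodes: set[str] | None = None,
) -> dict[tuple[str, str], CloneDistribution]:
    """Collapse cells sharing a CDR3 amino-acid sequence into clones.

    Returns one :class:`CloneDistribution` per (patient, timepoint).
    ``barcodes`` optionally restricts to a cell subset (e.g. CD8 T cells).
    An empty requested chain yields an empty result with a warning.
    """
    clonotypes = validate_clonotypes(clonotypes)
    sub = clonotypes[clonotypes["chain"] == chain]
    if barcodes is not None:
        sub = sub[sub["barcode"].isin(barcodes)]
    if sub.empty:
        logger.warning("no cells with chain %s in the clonotype table", chain)
        return {}
    sub = _dedupe_contigs(sub)
    out: dict[tuple[str, str], CloneDistribution] = {}
    for (patient, tp), grp in sub.groupby(["patient", "timepoint"], observed=True):
        counts = grp["cdr3_aa"].value_counts().sort_index()
        out[(patient, tp)] = CloneDistribution(counts=counts)
    return out


def simpson_index(dist: CloneDistribution) -> float:
    """Simpson diversity D = 1 - sum p_i^2, in [0, 1 - 1/n_clones]."""
    if dist.n_clones == 0:
        raise AnalysisError("empty clone distribution")
    p = dist.proportions
    return float(1.0 - np.sum(p**2))


def diversity_ratio(dist_a: CloneDistribution, dist_b: CloneDistribution) -> float:
    """D_B / D_A between two visits; >1 means diversification, <1 expansion.

    A monoclonal baseline (D_A = 0) makes the ratio undefined.
    """
    d_a = simpson_index(dist_a)
    if d_a == 0:
        raise AnalysisError("monoclonal baseline repertoire: diversity ratio undefined")
    return simpson_index(dist_b) / d_a


def diversity_table(
    dataset: CohortDataset,
    chain: str = "TRB",
    cell_type: str = "CD8_T",
) -> pd.DataFrame:
    """Per patient-timepoint Simpson diversity restricted to one cell type."""
    if dataset.clonotypes is None:
        raise AnalysisError("dataset has no clonotype table")
    meta = dataset.cell_meta
    barcodes = set(meta.loc[meta["cell_type"] == cell_type, "barcode"])
    dists = collapse_clones(dataset.clonotypes, chain=chain, barcodes=barcodes)
    groups = meta.drop_duplicates("patient").set_index("patient")["survival_group"]
    rows = [
        {
            "patient": patient,
            "timepoint": tp,
            "survival_group": groups.get(patient),
            "n_clones": d.n_clones,
            "n_cells": d.n_cells,
            "simpson": simpson_index(d),
        }
        for (patient, tp), d in sorted(dists.items())
    ]
    return pd.DataFrame(rows)


def compare_diversity(
    table: pd.DataFrame,
    tp_a: str,
    tp_b: str,
) -> dict[str, object]:
    """Diversity ratios D(tp_b)/D(tp_a) per patient plus cohort t-tests.

    Two-sample t-tests compare mean ratios between cohorts; within each
    cohort a paired two-sided t-test compares the two visits directly.
    Patients with a zero-diversity baseline are excluded with a warning.
    """
    wide = table.pivot_table(index="patient", columns="timepoint", values="simpson")
    groups = table.drop_duplicates("patient").set_index("patient")["survival_group"]
    ok = wide[[tp_a, tp_b]].notna().all(axis=1)
    zero = ok & (wide[tp_a] == 0)
    if zero.any():
        logger.warning("excluding %d patient(s) with monoclonal baseline", int(zero.sum()))
        ok &= ~zero
    ratios = (wide.loc[ok, tp_b] / wide.loc[ok, tp_a]).rename("diversity_ratio")
    per_patient = pd.DataFrame({"diversity_ratio": ratios, "survival_group": groups[ok]})
    pairwise = []
    labels = sorted(per_patient["survival_group"].unique())
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            a = per_patient.loc[per_patient["survival_group"] == g1, "diversity_ratio"]
            b = per_patient.loc[per_patient["survival_group"] == g2, "diversity_ratio"]
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b)
            pairwise.append(
                {"group_a": g1, "group_b": g2, "t": float(t), "p_value": float(p)}
            )
    paired = []
    for g in labels:
        sel = ok & (groups == g)
        if sel.sum() < 2:
            continue
        t, p = stats.ttest_rel(wide.loc[sel, tp_a], wide.loc[sel, tp_b])
        paired.append({"group": g, "t": float(t), "p_value": float(p)})
    return {
        "per_patient": per_patient,
        "between_cohorts": pd.DataFrame(pairwise),
        "within_cohort_paired": pd.DataFrame(paired),
    }


# ---------------------------------------------------------------------------
# clone fate
# ---------------------------------------------------------------------------


@dataclass
class CloneFateTable:
    """Target-subtype counts of source-cluster clones, one column per cohort."""

    counts: pd.DataFrame  # rows: target subtype, columns: cohort

    @property
    def fractions(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            raise AnalysisError("cohort column with zero total in clone-fate table")
        return self.counts / sums


def clone_fate(
    dataset: CohortDataset,
    source_cluster: str,
    tp_a: str,
    tp_b: str,
    cohorts: list[str] | None = None,
    chain: str = "TRB",
) -> CloneFateTable:
    """Track clones seeded in a source CD8 subtype from one visit to the next.

    A clone belongs to the source set of a patient if at least one of its
    cells sits in ``source_cluster`` at ``tp_a``.  All cells of those clones
    observed at ``tp_b`` are tallied by their CD8 subtype, pooled by cohort.
    Clones absent at the later visit contribute nothing.
    """
    if dataset.clonotypes is None:
        raise AnalysisError("dataset has no clonotype table")
    meta = dataset.cell_meta
    if cohorts is None:
        cohorts = sorted(meta["survival_group"].unique())
    contigs = _dedupe_contigs(
        dataset.clonotypes[dataset.clonotypes["chain"] == chain]
    )
    cells = meta.merge(contigs[["barcode", "cdr3_aa"]], on="barcode", how="inner")
    counts: dict[str, pd.Series] = {}
    any_source = False
    for cohort in cohorts:
        coh = cells[cells["survival_group"] == cohort]
        src = coh[(coh["timepoint"] == tp_a) & (coh["subcluster"] == source_cluster)]
        if src.empty:
            continue
        any_source = True
        src_clones = set(zip(src["patient"], src["cdr3_aa"]))
        tgt = coh[coh["timepoint"] == tp_b]
        hit = tgt[[p_c in src_clones for p_c in zip(tgt["patient"], tgt["cdr3_aa"])]]
        if hit.empty:
            continue
        counts[cohort] = hit["subcluster"].value_counts()
    if not any_source:
        logger.warning("no source clones in cluster %s at %s", source_cluster, tp_a)
        return CloneFateTable(counts=pd.DataFrame())
    table = pd.DataFrame(counts).fillna(0).astype(int).sort_index()
    return CloneFateTable(counts=table)


def chi_square_independence(
    fate_table: CloneFateTable | pd.DataFrame,
    continuity_correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square test of target-distribution independence of cohort.

    Rows with all-zero counts are dropped; expected counts below 5 trigger a
    warning.  Returns (statistic, degrees of freedom, p-value).
    """
    table = fate_table.counts if isinstance(fate_table, CloneFateTable) else fate_table
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.size == 0:
        raise AnalysisError("contingency table must be 2-D and non-empty")
    obs = obs[obs.sum(axis=1) > 0]
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise AnalysisError("degenerate contingency table (needs >= 2 rows and columns)")
    result = stats.chi2_contingency(obs, correction=continuity_correction)
    if (result.expected_freq < 5).any():
        logger.warning(
            "%d expected count(s) below 5; chi-square approximation may be poor",
            int((result.expected_freq < 5).sum()),
        )
    return float(result.statistic), int(result.dof), float(result.pvalue)
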