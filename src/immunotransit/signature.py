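"""Signature construction: two-group z-scores, preranked GSEA, pathway
activity ratios and composite per-patient activity scores.

The z statistic contrasts mean per-patient log2 fold-changes between long-
and short-surviving patients gene by gene,

    z = (xbar_L - xbar_S) / sqrt(SD_L^2/n_L + SD_S^2/n_S),

with sample (n-1) standard deviations; positive z means higher induction in
long survivors.  Genes ranked by descending z feed a weighted
Kolmogorov-Smirnov enrichment score whose null is generated by permuting
gene labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datamodel import CohortDataset, PathwaySet
from .errors import AnalysisError
from .preprocess import rc_normalize
from .pseudobulk import PatientFoldChangeTable

__all__ = [
    "group_zscore",
    "rank_genes",
    "gsea_es",
    "gsea_permutation",
    "GseaResult",
    "mean_pathway_expression",
    "signal_change",
    "signal_change_table",
    "composite_score",
    "SignatureScore",
]

logger = logging.getLogger(__name__)


def group_zscore(zinput: pd.DataFrame) -> pd.Series:
    """Per-gene z from group summary statistics.

    ``zinput`` columns: mean_log2fc_long, mean_log2fc_short, sd_long,
    sd_short, n_long, n_short (index: gene).  Genes whose z is undefined
    (zero standard error) are dropped and reported via a warning.
    """
    required = {
        "mean_log2fc_long",
        "mean_log2fc_short",
        "sd_long",
        "sd_short",
        "n_long",
        "n_short",
    }
    missing = required - set(zinput.columns)
    if missing:
        raise AnalysisError(f"z-score input missing column(s) {sorted(missing)}")
    if (zinput[["n_long", "n_short"]] < 2).any().any():
        raise AnalysisError("need n >= 2 patients per group for the z-score")
    if (zinput[["sd_long", "sd_short"]] < 0).any().any():
        raise AnalysisError("negative standard deviation")
    se = np.sqrt(
        zinput["sd_long"] ** 2 / zinput["n_long"]
        + zinput["sd_short"] ** 2 / zinput["n_short"]
    )
    z = (zinput["mean_log2fc_long"] - zinput["mean_log2fc_short"]) / se
    bad = ~np.isfinite(z)
    if bad.any():
        logger.warning("dropping %d gene(s) with undefined z", int(bad.sum()))
    return z[~bad]


def zscore_from_fc_table(fc: PatientFoldChangeTable, long_patients: list[str]) -> pd.Series:
    """Convenience: build the group z-score directly from a fold-change table."""
    cols = fc.log2fc.columns
    long_cols = [c for c in cols if c in set(long_patients)]
    short_cols = [c for c in cols if c not in set(long_patients)]
    if len(long_cols) < 2 or len(short_cols) < 2:
        raise AnalysisError("need >= 2 patients in each survival group")
    tbl = pd.DataFrame(
        {
            "mean_log2fc_long": fc.log2fc[long_cols].mean(axis=1),
            "mean_log2fc_short": fc.log2fc[short_cols].mean(axis=1),
            "sd_long": fc.log2fc[long_cols].std(axis=1, ddof=1),
            "sd_short": fc.log2fc[short_cols].std(axis=1, ddof=1),
            "n_long": len(long_cols),
            "n_short": len(short_cols),
        }
    )
    return group_zscore(tbl)


def rank_genes(z: pd.Series) -> pd.Series:
    """Descending-z ranked list; ties broken lexicographically by gene id."""
    z = z[np.isfinite(z)]
    order = sorted(z.index, key=lambda g: (-z[g], g))
    return z.loc[order]


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _running_sum(values: np.ndarray, member: np.ndarray, weight_p: float) -> np.ndarray:
    n = values.size
    n_hit = int(member.sum())
    if n_hit == 0:
        raise AnalysisError("gene set has no overlap with the ranked list")
    if n_hit == n:
        raise AnalysisError("gene set covers the whole ranked list (no misses)")
    w = np.abs(values) ** weight_p
    hit_w = np.where(member, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = member.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~member) / (n - n_hit)
    return np.cumsum(steps)


def _extremum(curve: np.ndarray) -> float:
    """Maximal deviation from zero; a tie (to 1e-9) resolves to the positive
    side, making the score independent of summation order."""
    hi, lo = float(curve.max()), float(curve.min())
    return hi if hi >= -lo - 1e-9 else lo


def gsea_es(
    ranked: pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running-sum curve.

    Hits increment in proportion to |z|**p (normalized), misses decrement by
    1/(N - N_hit); the ES is the extremum of maximal deviation from zero.
    """
    values = ranked.to_numpy(dtype=float)
    member = ranked.index.isin(set(gene_set))
    curve = _running_sum(values, member, weight_p)
    return _extremum(curve), curve


@dataclass
class GseaResult:
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    fwer_p: float
    n_perm: int

    def __post_init__(self) -> None:
        if self.es != 0 and np.sign(self.nes) != np.sign(self.es):
            raise AnalysisError("NES sign must match ES sign")


def gsea_permutation(
    ranked: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> GseaResult:
    """Permutation GSEA for one gene set via gene-label permutation.

    The null is generated by drawing random same-size gene sets from the
    ranked list.  The nominal p is one-sided in the direction of the observed
    ES among same-sign null scores; NES divides the ES by the mean magnitude
    of same-sign null scores.  With a single gene set the max-statistic FWER
    and the standard preranked FDR q reduce to estimates from the same null
    (documented limitation).
    """
    if n_perm < 100:
        raise AnalysisError("n_perm must be >= 100")
    values = ranked.to_numpy(dtype=float)
    member = ranked.index.isin(set(gene_set))
    n, n_hit = values.size, int(member.sum())
    curve = _running_sum(values, member, weight_p)
    es = _extremum(curve)
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    base = np.zeros(n, dtype=bool)
    base[:n_hit] = True
    for i in range(n_perm):
        perm = base[rng.permutation(n)]
        null_es[i] = _extremum(_running_sum(values, perm, weight_p))
    same = null_es >= 0 if es >= 0 else null_es <= 0
    n_same = int(same.sum())
    if n_same == 0:
        p = 1.0 / (n_perm + 1)
        nes = es  # no same-sign null mass; leave ES unscaled
    else:
        extreme = int((np.abs(null_es[same]) >= abs(es)).sum())
        p = max(extreme, 1) / n_same if extreme else 1.0 / (n_same + 1)
        mean_same = np.abs(null_es[same]).mean()
        nes = es / mean_same if mean_same > 0 else es
    # single-set preranked procedure: q and FWER estimated from the same
    # max-statistic null distribution
    extreme_any = int((np.abs(null_es) >= abs(es)).sum())
    fwer = extreme_any / n_perm if extreme_any else 1.0 / (n_perm + 1)
    return GseaResult(
        es=es,
        nes=float(nes),
        p_nominal=float(min(p, 1.0)),
        fdr_q=float(min(p, 1.0)),
        fwer_p=float(min(fwer, 1.0)),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# pathway activity ratios
# ---------------------------------------------------------------------------


def mean_pathway_expression(
    dataset: CohortDataset,
    pathway_genes: list[str],
    cell_mask: np.ndarray,
    rc: sp.spmatrix | None = None,
) -> float:
    """Mean RC-normalized expression of the pathway genes over the cells in
    ``cell_mask``; NaN with a warning when the subpopulation is empty."""
    present = [g for g in pathway_genes if g in set(dataset.gene_ids)]
    if not present:
        raise AnalysisError("no pathway gene present in the dataset")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        logger.warning("empty subpopulation for pathway mean; returning NaN")
        return float("nan")
    if rc is None:
        rc = rc_normalize(dataset)
    rows = dataset.gene_index(present)
    block = sp.csr_matrix(rc)[rows][:, cell_mask]
    return float(np.asarray(block.todense()).mean())


def signal_change(mean_a: float, mean_b: float) -> float:
    """Pathway activity ratio between consecutive visits: mean_B / mean_A."""
    if not mean_a > 0:
        raise AnalysisError("mean expression at timepoint A must be positive")
    return float(mean_b) / float(mean_a)


def signal_change_table(
    dataset: CohortDataset,
    pathways: PathwaySet,
    cell_types: list[str],
    tp_a: str,
    tp_b: str,
) -> pd.DataFrame:
    """Per patient/pathway/subpopulation activity ratios plus arm labels.

    Patients with zero baseline activity are excluded with a warning.  A
    two-sided Wilcoxon rank-sum comparing arms and (when applicable) a paired
    Wilcoxon signed-rank comparing the two visits within arm are appended by
    :func:`compare_signal_change`.
    """
    meta = dataset.cell_meta
    rc = rc_normalize(dataset)
    rows = []
    for pw_name, genes in pathways.items():
        for ct in cell_types:
            for patient in sorted(meta["patient"].unique()):
                base = (meta["patient"] == patient) & (meta["cell_type"] == ct)
                mask_a = (base & (meta["timepoint"] == tp_a)).to_numpy()
                mask_b = (base & (meta["timepoint"] == tp_b)).to_numpy()
                if not mask_a.any() or not mask_b.any():
                    continue
                mean_a = mean_pathway_expression(dataset, genes, mask_a, rc=rc)
                mean_b = mean_pathway_expression(dataset, genes, mask_b, rc=rc)
                if not mean_a > 0:
                    logger.warning(
                        "patient %s: zero baseline %s activity, excluded", patient, pw_name
                    )
                    continue
                arm = meta.loc[meta["patient"] == patient, "arm"].iloc[0]
                rows.append(
                    {
                        "pathway": pw_name,
                        "cell_type": ct,
                        "patient": patient,
                        "arm": arm,
                        "mean_expr_a": mean_a,
                        "mean_expr_b": mean_b,
                        "signal_change": signal_change(mean_a, mean_b),
                    }
                )
    return pd.DataFrame(rows)


def compare_signal_change(table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of activity ratios between arms, per
    pathway and subpopulation."""
    out = []
    for (pw, ct), grp in table.groupby(["pathway", "cell_type"]):
        arms = sorted(grp["arm"].unique())
        if len(arms) != 2:
            continue
        a = grp.loc[grp["arm"] == arms[0], "signal_change"]
        b = grp.loc[grp["arm"] == arms[1], "signal_change"]
        stat, p = stats.ranksums(a, b)
        out.append(
            {"pathway": pw, "cell_type": ct, "arm_a": arms[0], "arm_b": arms[1],
             "n_a": len(a), "n_b": len(b), "statistic": stat, "p_value": p}
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------


@dataclass
class SignatureScore:
    """Per-patient mean z-scored signature fold-change with a median split."""

    scores: pd.Series  # patient -> score
    groups: pd.Series  # patient -> "high" / "low"

    def __post_init__(self) -> None:
        n_high = int((self.groups == "high").sum())
        n_low = int((self.groups == "low").sum())
        ties = int((self.scores == self.scores.median()).sum())
        # ties at the median all go "low", which is the only sanctioned imbalance
        if len(self.scores) % 2 == 0 and abs(n_high - n_low) > max(1, ties):
            raise AnalysisError("median split unbalanced")


def composite_score(
    fc_table: PatientFoldChangeTable,
    signature_genes: list[str],
) -> SignatureScore:
    """Mean over signature genes of gene-wise z-scored per-patient log2FC.

    Patients at or below the median score are labelled "low" (deterministic,
    conservative for the high-activity hypothesis).
    """
    missing = set(signature_genes) - set(fc_table.zscored.index)
    if missing:
        raise AnalysisError(f"signature gene(s) absent from table: {sorted(missing)[:5]}")
    if fc_table.zscored.shape[1] < 4:
        raise AnalysisError("median split needs at least 4 patients")
    scores = fc_table.zscored.loc[list(signature_genes)].mean(axis=0)
    median = scores.median()
    groups = pd.Series(np.where(scores > median, "high", "low"), index=scores.index)
    return SignatureScore(scores=scores, groups=groups)
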