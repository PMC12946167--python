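"""Pseudo-bulk aggregation and negative-binomial differential expression.

Single-cell counts are summed per patient and visit into bulk-style samples,
normalized by trimmed-mean-of-M-values (TMM) factors, and tested gene by
gene with a negative-binomial GLM (log link, effective-library-size offsets)
under a paired ``~ patient + timepoint`` design.  A common dispersion is
estimated across genes by maximizing the Cox-Reid adjusted profile
likelihood, and the visit effect is tested with a likelihood-ratio test
against chi-square(1); Benjamini-Hochberg FDRs are appended.

The model follows the statsmodels idiom: :class:`PseudobulkDEModel` is built
from a :class:`PseudobulkMatrix` and ``fit()`` returns :class:`DEResults`
with the per-gene table and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CohortDataset, TIMEPOINT_ORDER
from .errors import AnalysisError, ValidationError

__all__ = [
    "PseudobulkMatrix",
    "DEResults",
    "PseudobulkDEModel",
    "aggregate_pseudobulk",
    "tmm_norm_factors",
    "fit_nb_lrt",
    "top_k_by_fdr",
    "per_patient_log2fc",
    "PatientFoldChangeTable",
]

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


@dataclass
class PseudobulkMatrix:
    """Genes x samples integer counts with per-sample metadata and TMM factors."""

    counts: np.ndarray
    sample_meta: pd.DataFrame  # columns: patient, timepoint, n_cells
    gene_ids: list[str]
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("pseudobulk counts must be 2-D")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError("gene_ids length mismatch")
        if len(self.sample_meta) != self.counts.shape[1]:
            raise ValidationError("sample_meta length mismatch")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def effective_lib_sizes(self) -> np.ndarray:
        factors = self.norm_factors if self.norm_factors is not None else 1.0
        return self.lib_sizes * factors


def aggregate_pseudobulk(
    dataset: CohortDataset,
    cell_type: str,
    timepoints: tuple[str, str],
    min_cells: int = 10,
    patients: list[str] | None = None,
) -> PseudobulkMatrix:
    """Sum raw counts over cells per (patient, timepoint) for one cell type.

    Samples with fewer than ``min_cells`` cells are dropped with a warning;
    patients left without both requested visits are excluded.  Fewer than two
    usable patients is an error.
    """
    meta = dataset.cell_meta
    keep = (meta["cell_type"] == cell_type) & meta["timepoint"].isin(timepoints)
    if patients is not None:
        keep &= meta["patient"].isin(patients)
    if not keep.any():
        raise AnalysisError(f"no {cell_type!r} cells at timepoints {timepoints}")
    idx = np.flatnonzero(keep.to_numpy())
    sub_meta = meta.iloc[idx]
    counts = sp.csc_matrix(dataset.counts)[:, idx]
    cols, rows_meta = [], []
    for (patient, tp), cell_rows in sorted(
        sub_meta.groupby(["patient", "timepoint"], observed=True).indices.items()
    ):
        n = len(cell_rows)
        if n < min_cells:
            logger.warning(
                "dropping pseudobulk sample %s/%s: %d < %d cells", patient, tp, n, min_cells
            )
            continue
        cols.append(np.asarray(counts[:, cell_rows].sum(axis=1)).ravel())
        rows_meta.append({"patient": patient, "timepoint": tp, "n_cells": n})
    sample_meta = pd.DataFrame(rows_meta)
    if sample_meta.empty:
        raise AnalysisError("no pseudobulk samples pass the min_cells filter")
    complete = sample_meta.groupby("patient")["timepoint"].nunique() == len(set(timepoints))
    usable = set(complete.index[complete])
    dropped = set(sample_meta["patient"]) - usable
    if dropped:
        logger.warning("excluding patient(s) without both visits: %s", sorted(dropped))
    keep_cols = sample_meta["patient"].isin(usable).to_numpy()
    sample_meta = sample_meta.loc[keep_cols].reset_index(drop=True)
    if sample_meta["patient"].nunique() < 2:
        raise AnalysisError("fewer than 2 usable patients for pseudobulk DE")
    mat = np.stack([c for c, k in zip(cols, keep_cols) if k], axis=1)
    return PseudobulkMatrix(counts=mat, sample_meta=sample_meta, gene_ids=list(dataset.gene_ids))


def tmm_norm_factors(
    pseudobulk: PseudobulkMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile (of count/library)
    is closest to the mean upper-quartile.  Per sample, genes positive in
    both it and the reference contribute an M (log2 ratio) and an A (mean
    log2 abundance); the most extreme ``trim_m`` (resp. ``trim_a``) fraction
    on each side of M (resp. A) is discarded and the factor is 2**mean(M).
    """
    counts = pseudobulk.counts if isinstance(pseudobulk, PseudobulkMatrix) else np.asarray(pseudobulk)
    counts = counts.astype(float)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise AnalysisError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise AnalysisError("sample with zero total counts")
    props = counts / lib
    uq = np.array([np.quantile(props[counts[:, j] > 0, j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        both = (counts[:, j] > 0) & (counts[:, ref] > 0)
        pj, pr = props[both, j], props[both, ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        n = m.size
        if n == 0:
            continue
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (
            (rank_m > n * trim_m)
            & (rank_m <= n * (1 - trim_m))
            & (rank_a > n * trim_a)
            & (rank_a <= n * (1 - trim_a))
        )
        if keep.any():
            factors[j] = 2.0 ** m[keep].mean()
    factors /= np.exp(np.mean(np.log(factors)))
    if isinstance(pseudobulk, PseudobulkMatrix):
        pseudobulk.norm_factors = factors
    return factors


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _irls_nb(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB GLM with log link; returns (beta, mu, converged)."""
    n, p = design.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.5)) - offset.mean()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = design @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        var = mu + alpha * mu**2
        w = mu**2 / var
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
        if not np.isfinite(beta_new).all():
            return beta, mu, False
        beta = beta_new
        mu = np.exp(np.clip(design @ beta + offset, -30, 30))
        ll = _nb_loglik(y, mu, alpha)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll
    return beta, mu, converged


def _design_matrix(sample_meta: pd.DataFrame, design: str) -> tuple[np.ndarray, int]:
    """Build the design from a ``~ patient + timepoint`` style formula.

    Returns the matrix and the column index of the timepoint effect (last
    timepoint level vs first, in protocol order).
    """
    terms = [t.strip() for t in design.lstrip("~ ").split("+") if t.strip()]
    if "timepoint" not in terms:
        raise AnalysisError("design must include a timepoint term")
    order = {tp: i for i, tp in enumerate(TIMEPOINT_ORDER)}
    cols = [np.ones(len(sample_meta))]
    names = ["intercept"]
    for term in terms:
        if term == "timepoint":
            continue
        levels = sorted(sample_meta[term].unique())
        for lv in levels[1:]:
            cols.append((sample_meta[term] == lv).to_numpy(float))
            names.append(f"{term}[{lv}]")
    tps = sorted(sample_meta["timepoint"].unique(), key=order.__getitem__)
    if len(tps) != 2:
        raise AnalysisError(f"timepoint effect needs exactly 2 visits, got {tps}")
    cols.append((sample_meta["timepoint"] == tps[1]).to_numpy(float))
    names.append(f"timepoint[{tps[1]}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise AnalysisError("rank-deficient design matrix")
    if x.shape[0] - x.shape[1] < 1:
        raise AnalysisError("no residual degrees of freedom")
    return x, x.shape[1] - 1


@dataclass
class DEResults:
    """Per-gene DE table with the fitted common dispersion.

    ``table`` columns: log2fc (visit effect), lr_stat, p_value, fdr,
    converged; index is the gene id, in input order.
    """

    table: pd.DataFrame
    dispersion: float
    design: str
    n_samples: int

    def __post_init__(self) -> None:
        t = self.table
        ok = t["p_value"].notna()
        if ok.any() and (t.loc[ok, "fdr"] < t.loc[ok, "p_value"] - 1e-12).any():
            raise ValidationError("FDR below p-value")

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("fdr").head(top)
        lines = [
            "Pseudo-bulk NB GLM likelihood-ratio test",
            f"  design: {self.design}   samples: {self.n_samples}   "
            f"genes: {len(self.table)}   common dispersion: {self.dispersion:.4g}",
            f"  genes at FDR<0.05: {int((self.table['fdr'] < 0.05).sum())}",
            "",
            t.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class PseudobulkDEModel:
    """NB GLM differential-expression model over a pseudo-bulk matrix.

    Parameters
    ----------
    pseudobulk
        Aggregated counts; TMM factors are computed if absent.
    design
        Additive formula over sample metadata columns; the timepoint term is
        the tested effect (last visit vs first, paired within patient when
        ``patient`` is included).
    """

    def __init__(self, pseudobulk: PseudobulkMatrix, design: str = "~ patient + timepoint"):
        self.pseudobulk = pseudobulk
        self.design = design
        if pseudobulk.norm_factors is None:
            tmm_norm_factors(pseudobulk)
        self.design_matrix, self._tp_col = _design_matrix(pseudobulk.sample_meta, design)
        self.offset = np.log(pseudobulk.effective_lib_sizes())

    # -- dispersion ---------------------------------------------------------

    def _apl(self, alpha: float, gene_rows: np.ndarray) -> float:
        """Cox-Reid adjusted profile log-likelihood summed over genes."""
        x = self.design_matrix
        total = 0.0
        for g in gene_rows:
            y = self.pseudobulk.counts[g].astype(float)
            _, mu, _ = _irls_nb(y, x, self.offset, alpha)
            w = mu**2 / (mu + alpha * mu**2)
            xtwx = x.T @ (x * w[:, None])
            sign, logdet = np.linalg.slogdet(xtwx)
            if sign <= 0:
                return -np.inf
            total += _nb_loglik(y, mu, alpha) - 0.5 * logdet
        return total

    def estimate_dispersion(self, max_genes: int = 200) -> float:
        """Common dispersion maximizing the Cox-Reid APL across genes."""
        counts = self.pseudobulk.counts
        expressed = np.flatnonzero(counts.sum(axis=1) > 0)
        if expressed.size == 0:
            raise AnalysisError("no expressed genes")
        if expressed.size > max_genes:
            pick = np.linspace(0, expressed.size - 1, max_genes).astype(int)
            expressed = expressed[pick]
        res = optimize.minimize_scalar(
            lambda la: -self._apl(10.0**la, expressed),
            bounds=(-6.0, 1.0),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return float(10.0 ** res.x)

    # -- fitting ------------------------------------------------------------

    def fit(self, dispersion: float | None = None) -> DEResults:
        """Fit full and timepoint-dropped models per gene; LRT vs chi2(1)."""
        if dispersion is None:
            dispersion = self.estimate_dispersion()
        x_full = self.design_matrix
        x_red = np.delete(x_full, self._tp_col, axis=1)
        counts = self.pseudobulk.counts
        n_genes = counts.shape[0]
        log2fc = np.full(n_genes, np.nan)
        lr = np.full(n_genes, np.nan)
        pval = np.full(n_genes, np.nan)
        conv = np.zeros(n_genes, dtype=bool)
        for g in range(n_genes):
            y = counts[g].astype(float)
            if y.sum() == 0:
                log2fc[g], lr[g], pval[g], conv[g] = 0.0, 0.0, 1.0, True
                continue
            beta_f, mu_f, ok_f = _irls_nb(y, x_full, self.offset, dispersion)
            beta_r, mu_r, ok_r = _irls_nb(y, x_red, self.offset, dispersion)
            if not (ok_f and ok_r):
                logger.warning("gene %d: IRLS did not converge; p set to NA", g)
                continue
            ll_f = _nb_loglik(y, mu_f, dispersion)
            ll_r = _nb_loglik(y, mu_r, dispersion)
            stat = max(0.0, 2.0 * (ll_f - ll_r))
            log2fc[g] = beta_f[self._tp_col] / _LN2
            lr[g] = stat
            pval[g] = stats.chi2.sf(stat, df=1)
            conv[g] = True
        fdr = np.full(n_genes, np.nan)
        ok = np.isfinite(pval)
        if ok.any():
            fdr[ok] = multipletests(pval[ok], method="fdr_bh")[1]
        table = pd.DataFrame(
            {"log2fc": log2fc, "lr_stat": lr, "p_value": pval, "fdr": fdr, "converged": conv},
            index=pd.Index(self.pseudobulk.gene_ids, name="gene"),
        )
        return DEResults(
            table=table,
            dispersion=float(dispersion),
            design=self.design,
            n_samples=counts.shape[1],
        )


def fit_nb_lrt(
    pseudobulk: PseudobulkMatrix,
    design: str = "~ patient + timepoint",
    dispersion: float | None = None,
) -> DEResults:
    """Functional entry point: build the model and fit it."""
    return PseudobulkDEModel(pseudobulk, design=design).fit(dispersion=dispersion)


def top_k_by_fdr(de_result: DEResults | pd.DataFrame, k: int = 500) -> list[str]:
    """Gene ids with the smallest FDR; ties broken by |log2fc| then gene id."""
    if k <= 0:
        raise AnalysisError("k must be positive")
    table = de_result.table if isinstance(de_result, DEResults) else de_result
    if table.empty:
        raise AnalysisError("empty DE result")
    t = table[table["p_value"].notna()].reset_index()
    t["_neg_abs_fc"] = -t["log2fc"].abs()
    t = t.sort_values(["fdr", "_neg_abs_fc", "gene"], kind="mergesort")
    if len(t) < k:
        logger.warning("only %d genes tested; returning all for k=%d", len(t), k)
    return t["gene"].head(min(k, len(t))).tolist()


@dataclass
class PatientFoldChangeTable:
    """Genes x patients log2 fold-changes plus a gene-wise z-scored copy."""

    log2fc: pd.DataFrame
    zscored: pd.DataFrame

    def order_columns_by(self, values: pd.Series) -> "PatientFoldChangeTable":
        """Reorder patient columns, e.g. by survival time."""
        cols = values.loc[self.log2fc.columns].sort_values().index.tolist()
        return PatientFoldChangeTable(self.log2fc[cols], self.zscored[cols])


def per_patient_log2fc(
    dataset: CohortDataset,
    gene_set: list[str],
    cell_type: str,
    tp_a: str,
    tp_b: str,
    pseudocount: float = 1.0,
    min_cells: int = 10,
    patients: list[str] | None = None,
) -> PatientFoldChangeTable:
    """Per-patient log2((CPM_B + pc) / (CPM_A + pc)) on pseudo-bulk CPM.

    Patients missing either visit are excluded with a warning.  The z-scored
    copy standardizes each gene across patients (sd 0 rows stay 0).
    """
    pb = aggregate_pseudobulk(dataset, cell_type, (tp_a, tp_b), min_cells=min_cells, patients=patients)
    gene_rows = [pb.gene_ids.index(g) for g in gene_set]
    cpm = pb.counts / pb.lib_sizes * 1e6
    meta = pb.sample_meta
    cols = {}
    for patient in sorted(meta["patient"].unique()):
        ia = np.flatnonzero((meta["patient"] == patient) & (meta["timepoint"] == tp_a))
        ib = np.flatnonzero((meta["patient"] == patient) & (meta["timepoint"] == tp_b))
        a = cpm[gene_rows, ia[0]]
        b = cpm[gene_rows, ib[0]]
        cols[patient] = np.log2((b + pseudocount) / (a + pseudocount))
    fc = pd.DataFrame(cols, index=pd.Index(gene_set, name="gene"))
    sd = fc.std(axis=1, ddof=1)
    z = fc.sub(fc.mean(axis=1), axis=0)
    nz = sd > 0
    z.loc[nz] = z.loc[nz].div(sd[nz], axis=0)
    return PatientFoldChangeTable(log2fc=fc, zscored=z)
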