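"""Pseudo-bulk aggregation, TMM, the NB GLM LRT and fold-change tables."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats

from immunotransit import (
    CohortDataset,
    PseudobulkDEModel,
    PseudobulkMatrix,
    aggregate_pseudobulk,
    fit_nb_lrt,
    per_patient_log2fc,
    tmm_norm_factors,
    top_k_by_fdr,
)
from immunotransit.errors import AnalysisError


def _pb(counts, patients, timepoints):
    meta = pd.DataFrame({"patient": patients, "timepoint": timepoints, "n_cells": 50})
    return PseudobulkMatrix(
        counts=np.asarray(counts),
        sample_meta=meta,
        gene_ids=[f"g{i}" for i in range(np.asarray(counts).shape[0])],
    )


class TestAggregate:
    def test_summation(self):
        counts = np.array([[1, 0, 4], [2, 1, 0]])
        meta = pd.DataFrame(
            {
                "barcode": ["a", "b", "c"],
                "patient": "P1",
                "arm": "LITT_PEM",
                "survival_group": "LITT_GT_MOS",
                "timepoint": "PRE",
                "cell_type": "mono",
                "subcluster": "m0",
            }
        )
        meta2 = pd.concat([meta, meta.assign(barcode=["d", "e", "f"], timepoint="C1"),
                           meta.assign(barcode=["g", "h", "i"], patient="P2"),
                           meta.assign(barcode=["j", "k", "l"], patient="P2", timepoint="C1")],
                          ignore_index=True)
        ds = CohortDataset(
            sp.csr_matrix(np.tile(counts, (1, 4))), ["g0", "g1"], meta2
        )
        pb = aggregate_pseudobulk(ds, "mono", ("PRE", "C1"), min_cells=1)
        assert pb.counts.shape == (2, 4)
        col = pb.counts[:, 0]
        assert col.tolist() == [5, 3]
        # conservation
        assert pb.counts.sum() == ds.counts.sum()

    def test_matches_groupby_oracle(self, small_cohort):
        pb = aggregate_pseudobulk(
            small_cohort, "non_classical_monocyte", ("PRE", "C1"), min_cells=1
        )
        dense = small_cohort.counts.toarray()
        meta = small_cohort.cell_meta
        for j, row in pb.sample_meta.iterrows():
            sel = (
                (meta["patient"] == row["patient"])
                & (meta["timepoint"] == row["timepoint"])
                & (meta["cell_type"] == "non_classical_monocyte")
            ).to_numpy()
            assert np.array_equal(pb.counts[:, j], dense[:, sel].sum(axis=1))

    def test_too_few_patients_rejected(self, small_cohort):
        with pytest.raises(AnalysisError):
            aggregate_pseudobulk(
                small_cohort, "non_classical_monocyte", ("PRE", "C1"),
                min_cells=10, patients=["GT01"],
            )


class TestTmm:
    def test_identical_samples(self):
        c = np.tile(np.arange(1, 21)[:, None], (1, 2))
        assert np.allclose(tmm_norm_factors(c), [1.0, 1.0])

    def test_pure_depth_difference(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 200) + 1
        c = np.column_stack([a, 2 * a])
        assert np.allclose(tmm_norm_factors(c), [1.0, 1.0], atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(20, size=(300, 5)) + 1
        f = tmm_norm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_trimmed_mean_oracle_five_genes(self):
        """Two-sample TMM agrees with an explicit sort-and-trim evaluation."""
        c = np.array([[10, 30], [20, 20], [30, 35], [40, 45], [100, 400]], dtype=float)
        f = tmm_norm_factors(c, trim_m=0.2, trim_a=0.0)
        lib = c.sum(axis=0)
        # reference is sample 0 here (computed by the documented UQ rule)
        m = np.log2((c[:, 1] / lib[1]) / (c[:, 0] / lib[0]))
        order = np.argsort(m)
        kept = m[order][1:-1]  # trim 20% (=1 gene) from each M tail
        expected = 2.0 ** kept.mean()
        expected_pair = np.array([1 / np.sqrt(expected), np.sqrt(expected)])
        assert np.allclose(f, expected_pair, rtol=1e-12)

    def test_zero_sample_rejected(self):
        with pytest.raises(AnalysisError, match="zero"):
            tmm_norm_factors(np.array([[0, 1], [0, 2]]))


class TestNbGlm:
    def test_null_gene_flat(self):
        counts = np.vstack([np.full(8, 100), np.full(8, 250)])
        pb = _pb(counts, np.repeat(["p1", "p2", "p3", "p4"], 2), ["PRE", "C1"] * 4)
        res = fit_nb_lrt(pb, dispersion=0.05)
        assert res.table["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res.table["p_value"].iloc[0] > 0.99

    def test_poisson_limit_oracle(self):
        """At vanishing dispersion the NB LRT approaches the Poisson GLM LRT."""
        rng = np.random.default_rng(3)
        counts = rng.poisson(150, size=(10, 8))
        counts[0] *= np.tile([1, 3], 4)  # one strong visit effect
        pb = _pb(counts, np.repeat(["p1", "p2", "p3", "p4"], 2), ["PRE", "C1"] * 4)
        model = PseudobulkDEModel(pb)
        res = model.fit(dispersion=1e-8)
        x_full = model.design_matrix
        x_red = np.delete(x_full, -1, axis=1)
        for g in range(10):
            y = counts[g].astype(float)
            llf = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=model.offset).fit().llf
            llr = sm.GLM(y, x_red, family=sm.families.Poisson(), offset=model.offset).fit().llf
            p_oracle = stats.chi2.sf(2 * (llf - llr), 1)
            p_mine = res.table["p_value"].iloc[g]
            assert p_mine == pytest.approx(p_oracle, rel=0.1, abs=1e-12)

    def test_nb_coefficients_match_statsmodels(self):
        alpha = 0.2
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 0.05, size=(3, 10))
        pb = _pb(counts, np.repeat(["p1", "p2", "p3", "p4", "p5"], 2), ["PRE", "C1"] * 5)
        model = PseudobulkDEModel(pb)
        res = model.fit(dispersion=alpha)
        y = counts[0].astype(float)
        sm_fit = sm.GLM(
            y, model.design_matrix,
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=model.offset,
        ).fit()
        assert res.table["log2fc"].iloc[0] == pytest.approx(
            sm_fit.params[-1] / np.log(2), abs=1e-4
        )

    def test_rank_deficient_design_rejected(self):
        counts = np.ones((2, 4), dtype=int) * 10
        pb = _pb(counts, ["p1", "p1", "p2", "p2"], ["PRE", "PRE", "C1", "C1"])
        # patient and timepoint confounded -> collinear design
        with pytest.raises(AnalysisError, match="rank"):
            PseudobulkDEModel(pb)

    def test_bh_fdr_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(80, size=(60, 8))
        pb = _pb(counts, np.repeat(["p1", "p2", "p3", "p4"], 2), ["PRE", "C1"] * 4)
        res = fit_nb_lrt(pb, dispersion=0.05)
        p = res.table["p_value"].to_numpy()
        # brute-force Benjamini-Hochberg step-up
        n = p.size
        order = np.argsort(p)
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        assert np.allclose(res.table["fdr"].to_numpy(), q, atol=1e-12)
        assert (res.table["fdr"] >= res.table["p_value"] - 1e-12).all()


class TestTopK:
    def _result_like(self, fdr, log2fc, genes):
        return pd.DataFrame(
            {"log2fc": log2fc, "lr_stat": 1.0, "p_value": fdr, "fdr": fdr},
            index=pd.Index(genes, name="gene"),
        )

    def test_ordering(self):
        t = self._result_like([0.5, 0.01, 0.2], [1, 1, 1], ["a", "b", "c"])
        assert top_k_by_fdr(t, k=2) == ["b", "c"]

    def test_tie_broken_by_abs_fc_then_name(self):
        t = self._result_like([0.1, 0.1, 0.1], [0.5, -2.0, 0.5], ["a", "b", "c"])
        assert top_k_by_fdr(t, k=2) == ["b", "a"]

    def test_k_bound_and_validation(self):
        t = self._result_like([0.1, 0.2], [1, 1], ["a", "b"])
        assert len(top_k_by_fdr(t, k=500)) == 2
        with pytest.raises(AnalysisError):
            top_k_by_fdr(t, k=0)


class TestPatientFoldChange:
    def test_equal_cpm_gives_zero_and_zscore_rows(self, small_cohort):
        fc = per_patient_log2fc(
            small_cohort,
            list(small_cohort.gene_ids[:50]),
            "non_classical_monocyte",
            "PRE",
            "C1",
            min_cells=1,
        )
        z = fc.zscored
        sd = fc.log2fc.std(axis=1, ddof=1)
        nz = sd > 0
        assert np.allclose(z.loc[nz].mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.loc[nz].std(axis=1, ddof=1), 1, atol=1e-12)

    def test_doubling_limit(self):
        # two patients, both visits, CPM doubles -> log2fc -> 1 as pc -> 0
        counts = np.array([[100, 200, 100, 200], [900, 800, 900, 800]])
        meta = pd.DataFrame(
            {
                "barcode": list("abcd"),
                "patient": ["P1", "P1", "P2", "P2"],
                "arm": "LITT_PEM",
                "survival_group": "LITT_GT_MOS",
                "timepoint": ["PRE", "C1", "PRE", "C1"],
                "cell_type": "mono",
                "subcluster": "m0",
            }
        )
        ds = CohortDataset(sp.csr_matrix(counts), ["g0", "g1"], meta)
        fc = per_patient_log2fc(ds, ["g0"], "mono", "PRE", "C1",
                                pseudocount=1e-9, min_cells=1)
        assert np.allclose(fc.log2fc.loc["g0"], 1.0, atol=1e-6)
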