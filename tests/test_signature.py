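"""Group z-scores, ranking, GSEA, pathway activity and composite scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from immunotransit import (
    composite_score,
    group_zscore,
    gsea_es,
    gsea_permutation,
    mean_pathway_expression,
    rank_genes,
    signal_change,
)
from immunotransit.pseudobulk import PatientFoldChangeTable
from immunotransit.errors import AnalysisError

from conftest import make_toy_dataset


def _zinput(xl, xs, sl, ss, nl=4, ns=4, genes=None):
    idx = genes or [f"g{i}" for i in range(len(np.atleast_1d(xl)))]
    return pd.DataFrame(
        {
            "mean_log2fc_long": np.atleast_1d(xl),
            "mean_log2fc_short": np.atleast_1d(xs),
            "sd_long": np.atleast_1d(sl),
            "sd_short": np.atleast_1d(ss),
            "n_long": nl,
            "n_short": ns,
        },
        index=idx,
    )


class TestZScore:
    def test_hand_value(self):
        z = group_zscore(_zinput(2.0, 1.0, 1.0, 1.0, nl=4, ns=4))
        assert z.iloc[0] == pytest.approx(1.0 / np.sqrt(0.5), abs=1e-5)

    def test_equal_means_zero(self):
        z = group_zscore(_zinput(1.3, 1.3, 0.7, 0.4))
        assert z.iloc[0] == 0.0

    def test_antisymmetry_random(self):
        rng = np.random.default_rng(0)
        n = 1000
        tbl = _zinput(
            rng.normal(size=n), rng.normal(size=n),
            rng.uniform(0.1, 2, n), rng.uniform(0.1, 2, n),
            nl=7, ns=5,
        )
        swapped = tbl.rename(
            columns={
                "mean_log2fc_long": "mean_log2fc_short",
                "mean_log2fc_short": "mean_log2fc_long",
                "sd_long": "sd_short",
                "sd_short": "sd_long",
                "n_long": "n_short",
                "n_short": "n_long",
            }
        )
        assert np.allclose(group_zscore(tbl), -group_zscore(swapped), atol=1e-12)

    def test_undefined_z_dropped(self):
        tbl = _zinput([1.0, 1.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0])
        z = group_zscore(tbl)
        assert list(z.index) == ["g1"]


class TestRank:
    def test_sort_and_ties(self):
        z = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0})
        assert list(rank_genes(z).index) == ["b", "c", "a"]
        z = pd.Series({"b": 1.0, "a": 1.0})
        assert list(rank_genes(z).index) == ["a", "b"]

    def test_non_finite_filtered(self):
        z = pd.Series({"a": 1.0, "b": np.nan, "c": -1.0})
        assert len(rank_genes(z)) == 2


def _brute_force_es(values, member, p=1.0):
    """Independent walk: explicit per-step accumulation, max |deviation|,
    positive side preferred on an exact tie."""
    n = len(values)
    nh = sum(member)
    denom = sum(abs(v) ** p for v, m in zip(values, member) if m)
    hi = lo = run = 0.0
    for v, m in zip(values, member):
        if m:
            run += abs(v) ** p / denom
        else:
            run -= 1.0 / (n - nh)
        hi, lo = max(hi, run), min(lo, run)
    return hi if hi >= -lo - 1e-9 else lo


class TestGseaEs:
    def test_top_heavy_set_positive_and_matches_oracle(self):
        ranked = pd.Series(
            np.ones(10), index=[f"g{i}" for i in range(10)]
        )
        ranked.iloc[:] = 1.0
        gene_set = ["g0", "g1", "g2"]
        es, curve = gsea_es(ranked, gene_set)
        member = [g in gene_set for g in ranked.index]
        assert es > 0
        assert es == pytest.approx(_brute_force_es(ranked.tolist(), member), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = 20
            vals = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(vals, index=[f"g{i}" for i in range(n)])
            size = rng.integers(2, 10)
            gene_set = list(rng.choice(ranked.index, size=size, replace=False))
            es, _ = gsea_es(ranked, gene_set)
            member = [g in set(gene_set) for g in ranked.index]
            assert es == pytest.approx(_brute_force_es(vals, member), abs=1e-12)

    def test_reversal_negates_equal_weight(self):
        ranked = pd.Series(np.ones(12), index=[f"g{i}" for i in range(12)])
        gene_set = ["g0", "g1", "g2"]
        es_fwd, _ = gsea_es(ranked, gene_set, weight_p=0.0)
        rev = ranked.iloc[::-1]
        es_rev, _ = gsea_es(rev, gene_set, weight_p=0.0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_degenerate_full_set_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(AnalysisError, match="whole ranked list"):
            gsea_es(ranked, ["a", "b"])
        with pytest.raises(AnalysisError, match="no overlap"):
            gsea_es(ranked, ["zzz"])


class TestGseaPermutation:
    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        ranked = rank_genes(
            pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        )
        gs = [f"g{i}" for i in range(0, 40, 4)]
        r1 = gsea_permutation(ranked, gs, n_perm=200, seed=5)
        r2 = gsea_permutation(ranked, gs, n_perm=200, seed=5)
        assert (r1.p_nominal, r1.nes) == (r2.p_nominal, r2.nes)

    def test_power_on_strong_gradient(self):
        rng = np.random.default_rng(3)
        vals = np.sort(np.abs(rng.normal(0, 3, 200)))[::-1]
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(200)])
        gs = list(ranked.index[:20])  # top decile
        r = gsea_permutation(ranked, gs, n_perm=1000, seed=1)
        assert r.p_nominal <= 0.01
        assert np.sign(r.nes) == np.sign(r.es) == 1.0

    def test_min_permutations(self):
        ranked = pd.Series([1.0, 0.5, -1.0], index=list("abc"))
        with pytest.raises(AnalysisError, match="n_perm"):
            gsea_permutation(ranked, ["a"], n_perm=50)


class TestPathwayActivity:
    def test_mean_matches_double_loop(self, small_cohort):
        genes = list(small_cohort.gene_ids[:7])
        mask = (small_cohort.cell_meta["cell_type"] == "CD8_T").to_numpy()
        got = mean_pathway_expression(small_cohort, genes, mask)
        from immunotransit.preprocess import rc_normalize

        rc = rc_normalize(small_cohort).toarray()
        rows = [small_cohort.gene_ids.index(g) for g in genes]
        acc = [rc[r, j] for r in rows for j in np.flatnonzero(mask)]
        assert got == pytest.approx(np.mean(acc), abs=1e-9)

    def test_singleton_pathway(self, small_cohort):
        gene = small_cohort.gene_ids[0]
        mask = np.zeros(small_cohort.n_cells, dtype=bool)
        mask[:5] = True
        from immunotransit.preprocess import rc_normalize

        rc = rc_normalize(small_cohort).toarray()
        got = mean_pathway_expression(small_cohort, [gene], mask)
        assert got == pytest.approx(rc[0, :5].mean(), abs=1e-9)

    def test_signal_change_basic(self):
        assert signal_change(5.0, 5.0) == 1.0
        assert signal_change(3.0, 6.0) == 2.0
        with pytest.raises(AnalysisError):
            signal_change(0.0, 1.0)

    def test_wilcoxon_null_calibration(self):
        """Rank-sum on identically distributed arm ratios is non-significant
        in at least 90% of null replicates."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            a = rng.lognormal(0, 0.3, 8)
            b = rng.lognormal(0, 0.3, 9)
            if stats.ranksums(a, b).pvalue > 0.05:
                hits += 1
        assert hits >= 90


class TestCompositeScore:
    def _table(self, z):
        z = pd.DataFrame(z)
        return PatientFoldChangeTable(log2fc=z.copy(), zscored=z)

    def test_direct_two_gene(self):
        z = pd.DataFrame(
            [[-1.0, 1.0, -0.5, 0.5]], columns=list("abcd"), index=["g0"]
        )
        score = composite_score(self._table(z), ["g0"])
        assert score.scores.tolist() == [-1.0, 1.0, -0.5, 0.5]
        assert score.groups.tolist() == ["low", "high", "low", "high"]

    def test_tie_goes_low(self):
        z = pd.DataFrame(np.zeros((2, 4)), columns=list("abcd"), index=["g0", "g1"])
        score = composite_score(self._table(z), ["g0", "g1"])
        assert (score.groups == "low").all()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        z = pd.DataFrame(
            rng.normal(size=(6, 5)), columns=list("abcde"),
            index=[f"g{i}" for i in range(6)],
        )
        genes = [f"g{i}" for i in range(6)]
        s1 = composite_score(self._table(z), genes)
        s2 = composite_score(self._table(z), genes[::-1])
        assert np.allclose(s1.scores, s2.scores)

    def test_too_few_patients(self):
        z = pd.DataFrame([[0.0, 1.0]], columns=["a", "b"], index=["g0"])
        with pytest.raises(AnalysisError, match="4 patients"):
            composite_score(self._table(z), ["g0"])
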