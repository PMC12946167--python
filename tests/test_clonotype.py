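"""Clone collapsing, Simpson diversity, fate tracking and chi-square tests."""

import numpy as np
import pandas as pd
import pytest

from immunotransit import (
    CloneDistribution,
    chi_square_independence,
    clone_fate,
    collapse_clones,
    diversity_ratio,
    simpson_index,
)
from immunotransit.clonotype import compare_diversity, diversity_table
from immunotransit.errors import AnalysisError, ValidationError


def _clono(cdr3s, patient="P1", tp="C1", chain="TRB"):
    return pd.DataFrame(
        {
            "barcode": [f"{patient}_{tp}_{i}" for i in range(len(cdr3s))],
            "chain": chain,
            "cdr3_aa": cdr3s,
            "patient": patient,
            "timepoint": tp,
        }
    )


def _dist(counts):
    return CloneDistribution(counts=pd.Series(counts))


class TestCollapse:
    def test_grouping(self):
        dists = collapse_clones(_clono(["CASSA", "CASSA", "CASSG"]))
        d = dists[("P1", "C1")]
        assert d.counts.to_dict() == {"CASSA": 2, "CASSG": 1}

    def test_lowercase_rejected(self):
        with pytest.raises(ValidationError):
            collapse_clones(_clono(["cassa"]))

    def test_missing_chain_empty_with_warning(self):
        assert collapse_clones(_clono(["CASSA"]), chain="TRA") == {}

    def test_idempotent(self):
        table = _clono(["CASSA", "CASSA", "CASSG", "CASSG", "CASSG"])
        d1 = collapse_clones(table)[("P1", "C1")]
        rebuilt = _clono(
            [c for c, n in d1.counts.items() for _ in range(int(n))]
        )
        d2 = collapse_clones(rebuilt)[("P1", "C1")]
        assert d1.counts.equals(d2.counts)


class TestSimpson:
    def test_monoclonal_zero(self):
        assert simpson_index(_dist({"A": 7})) == 0.0

    def test_two_equal_clones(self):
        assert simpson_index(_dist({"A": 5, "G": 5})) == pytest.approx(0.5)

    def test_matches_pairwise_collision_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200)[:200]:
            k = int(rng.integers(2, 50))
            counts = rng.integers(1, 20, size=k)
            d = _dist({f"C{i}": int(c) for i, c in enumerate(counts)})
            labels = np.repeat(np.arange(k), counts)
            collision = (labels[:, None] == labels[None, :]).mean()
            assert simpson_index(d) == pytest.approx(1.0 - collision, abs=1e-12)

    def test_bounds_and_uniform_maximum(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(2, 30))
            counts = rng.integers(1, 30, size=k)
            d = simpson_index(_dist({f"C{i}": int(c) for i, c in enumerate(counts)}))
            assert 0.0 <= d <= 1.0 - 1.0 / k + 1e-12
        k = 10
        assert simpson_index(
            _dist({f"C{i}": 4 for i in range(k)})
        ) == pytest.approx(1 - 1 / k)


class TestDiversityRatio:
    def test_identity(self):
        d = _dist({"A": 3, "G": 5})
        assert diversity_ratio(d, d) == 1.0

    def test_expansion_lowers_ratio(self):
        before = _dist({f"C{i}": 10 for i in range(10)})
        after = _dist({"C0": 91, **{f"C{i}": 1 for i in range(1, 10)}})
        assert diversity_ratio(before, after) < 1.0
        # both Simpson values check out directly
        assert simpson_index(before) == pytest.approx(0.9)
        p = np.array([91] + [1] * 9) / 100
        assert simpson_index(after) == pytest.approx(1 - np.sum(p**2))

    def test_monoclonal_baseline_rejected(self):
        with pytest.raises(AnalysisError, match="monoclonal"):
            diversity_ratio(_dist({"A": 5}), _dist({"A": 2, "G": 2}))


class TestCloneFate:
    def test_recovery_and_fraction_sums(self, small_cohort):
        fate = clone_fate(small_cohort, "CD8_CM", "PRE", "C1")
        fr = fate.fractions
        assert np.allclose(fr.sum(axis=0), 1.0, atol=1e-12)
        gt = fr["LITT_GT_MOS"]
        assert gt.get("CD8_EFF", 0) > 0.3  # programmed flow dominates

    def test_source_only_clone_stays(self):
        meta = pd.DataFrame(
            {
                "barcode": ["b1", "b2"],
                "patient": "P1",
                "arm": "LITT_PEM",
                "survival_group": "LITT_GT_MOS",
                "timepoint": ["PRE", "C1"],
                "cell_type": "CD8_T",
                "subcluster": "CD8_CM",
            }
        )
        import scipy.sparse as sp
        from immunotransit import CohortDataset

        clono = pd.DataFrame(
            {
                "barcode": ["b1", "b2"],
                "chain": "TRB",
                "cdr3_aa": "CASSA",
                "patient": "P1",
                "timepoint": ["PRE", "C1"],
            }
        )
        ds = CohortDataset(
            sp.csr_matrix(np.ones((2, 2), dtype=int)), ["g0", "g1"], meta, clonotypes=clono
        )
        fate = clone_fate(ds, "CD8_CM", "PRE", "C1")
        assert fate.fractions["LITT_GT_MOS"].loc["CD8_CM"] == 1.0

    def test_absent_clone_contributes_nothing(self, small_cohort):
        # a source cluster with no matching clones yields an empty table
        fate = clone_fate(small_cohort, "NO_SUCH_CLUSTER", "PRE", "C1")
        assert fate.counts.empty


class TestChiSquare:
    def test_flat_table(self):
        stat, df, p = chi_square_independence(pd.DataFrame([[10, 10], [10, 10]]))
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        # explicit Pearson evaluation: E = 12.5 everywhere,
        # 4 * (7.5^2 / 12.5) = 18.0 with df 1
        stat, df, _ = chi_square_independence(pd.DataFrame([[20, 5], [5, 20]]))
        assert df == 1
        assert stat == pytest.approx(18.0, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 40, size=(5, 3))
        s1, *_ = chi_square_independence(pd.DataFrame(t))
        s2, *_ = chi_square_independence(pd.DataFrame(t[::-1, ::-1]))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(AnalysisError, match="degenerate"):
            chi_square_independence(pd.DataFrame([[1, 2]]))


class TestCohortComparison:
    def test_ttest_null_calibration(self):
        """Two-sample t on equal-diversity cohorts: type-I error near 0.05."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a = rng.normal(0.9, 0.03, 5)
            b = rng.normal(0.9, 0.03, 7)
            from scipy import stats

            if stats.ttest_ind(a, b).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_diversity_tables_and_tests(self, small_cohort):
        table = diversity_table(small_cohort)
        assert {"patient", "timepoint", "simpson"} <= set(table.columns)
        out = compare_diversity(table, "C1", "C2")
        assert not out["per_patient"].empty
        assert {"group_a", "group_b", "p_value"} <= set(out["between_cohorts"].columns)
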