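"""CPM, low-expression filtering, DE stand-in, normalisation, coverage."""

import numpy as np
import pandas as pd
import pytest

from g4ltr import (
    aggregate_coverage,
    cpm,
    de_test,
    filter_low_expression,
    gen_count_matrix,
    normalization_factors,
)

from _oracle import bh_adjust
from conftest import make_hit


def _matrix(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


class TestCpm:
    def test_definition(self):
        m = _matrix({"a": [10, 0], "b": [999990, 1000000]})
        c = cpm(m)
        assert c.loc["a", "s0"] == pytest.approx(10.0)
        assert c.loc["a", "s1"] == 0.0
        assert c.loc["b", "s1"] == pytest.approx(1e6)

    def test_fractional_counts_admissible(self):
        m = _matrix({"a": [0.5], "b": [999999.5]})
        assert cpm(m).loc["a", "s0"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        m = _matrix({"a": [3, 8], "b": [7, 2]})
        assert np.allclose(cpm(m).values, cpm(m * 13).values)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(_matrix({"a": [1, 0], "b": [1, 0]}))


class TestFilter:
    def _with_cpm(self, vectors):
        """Matrix whose per-sample CPM equals the given vectors (each
        library padded to a 1e6 total by a filler element)."""
        df = pd.DataFrame(vectors).T
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        filler = 1e6 - df.sum(axis=0)
        df.loc["_filler"] = filler
        return df

    def test_all_above_retained(self):
        m = self._with_cpm({"a": [100] * 6})
        retained, _ = filter_low_expression(m)
        assert "a" in retained

    def test_three_below_removed(self):
        m = self._with_cpm({"a": [10, 10, 10, 100, 100, 100]})
        retained, filtered = filter_low_expression(m)
        assert "a" in filtered and "a" not in retained

    def test_two_below_retained(self):
        m = self._with_cpm({"a": [10, 10, 100, 100, 100, 100]})
        retained, _ = filter_low_expression(m)
        assert "a" in retained

    def test_conventional_keep_rule_flag(self):
        # 2 samples >= 45: removed by keep_high(min_samples=3), kept by
        # the literal rule only when fewer than 3 fall below
        m = self._with_cpm({"a": [50, 50, 10, 10, 10, 10]})
        assert "a" in filter_low_expression(m, rule="remove_low")[1]
        assert "a" in filter_low_expression(m, rule="keep_high")[1]
        m2 = self._with_cpm({"b": [50, 50, 50, 10, 10, 10]})
        assert "b" in filter_low_expression(m2, rule="keep_high")[0]

    def test_sample_order_invariance(self):
        m = self._with_cpm({"a": [10, 100, 10, 100, 10, 100]})
        shuffled = m[["s3", "s0", "s5", "s2", "s1", "s4"]]
        assert filter_low_expression(m)[0] == filter_low_expression(shuffled)[0]


class TestNormalizationFactors:
    def test_equal_libraries_give_unit_factors(self):
        m = _matrix({"a": [100, 100], "b": [50, 50]})
        for method in ("tmm", "total"):
            f = normalization_factors(m, method=method)
            assert np.allclose(f.values, 1.0)

    def test_total_method_ratio(self):
        m = _matrix({"a": [100, 200], "b": [100, 200]})
        f = normalization_factors(m, method="total")
        assert f["s0"] / f["s1"] == pytest.approx(2.0)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_tmm_resists_composition_bias(self):
        """10% of elements 8-fold up in one library: TMM factors stay
        closer to 1:1 than total-count factors."""
        rng = np.random.default_rng(1)
        base = rng.lognormal(np.log(200), 0.8, size=500)
        lib2 = base.copy()
        lib2[:50] *= 8
        m = pd.DataFrame({"s0": base, "s1": lib2})
        tmm = normalization_factors(m, method="tmm")
        total = normalization_factors(m, method="total")
        assert abs(np.log(tmm["s0"] / tmm["s1"])) < abs(
            np.log(total["s0"] / total["s1"])
        )

    def test_single_library_rejected(self):
        with pytest.raises(ValueError):
            normalization_factors(_matrix({"a": [1]}))


class TestDeTest:
    def _groups(self, n):
        g = {f"T{i}": "treated" for i in range(n)}
        g.update({f"C{i}": "control" for i in range(n)})
        return g

    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(100, size=50)
        data = {f"T{i}": vals for i in range(3)} | {f"C{i}": vals for i in range(3)}
        m = pd.DataFrame(data, index=[f"te{i}" for i in range(50)])
        res = de_test(m, self._groups(3))
        assert np.allclose(res["lfc"], 0.0)
        assert set(res["status"]) == {"not_DE"}

    def test_bh_adjustment_matches_textbook_oracle(self):
        """External p-values pass through BH exactly as the p*m/rank +
        cumulative-min recipe demands; fdr >= p always."""
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.poisson(100, size=(10, 6)),
            index=[f"te{i}" for i in range(10)],
            columns=list(self._groups(3)),
        )
        pvals = pd.Series(
            [0.001, 0.8, 0.04, 0.04, 0.2, 0.9, 0.011, 0.33, 0.05, 0.6],
            index=m.index,
        )
        res = de_test(m, self._groups(3), external_pvalues=pvals)
        assert np.allclose(res["fdr"].values, bh_adjust(pvals.tolist()))
        assert (res["fdr"] >= res["p"] - 1e-12).all()

    def test_filtered_elements_carried_through(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            rng.poisson(100, size=(5, 6)),
            index=[f"te{i}" for i in range(5)],
            columns=list(self._groups(3)),
        )
        res = de_test(m, self._groups(3), retained=["te0", "te1"])
        assert res.loc["te4", "status"] == "filtered"
        assert np.isnan(res.loc["te4", "p"])

    def test_empty_group_rejected(self):
        m = pd.DataFrame({"T0": [1], "T1": [2], "T2": [3]}, index=["a"])
        with pytest.raises(ValueError):
            de_test(m, {"T0": "treated", "T1": "treated", "T2": "treated"})

    def test_small_groups_rejected_by_default(self):
        m, groups, _ = gen_count_matrix(n_te=20, n_per_group=1, seed=0)
        with pytest.raises(ValueError, match="at least 3"):
            de_test(m, groups)

    def test_planted_eightfold_changes_recovered(self):
        m, groups, truth = gen_count_matrix(
            n_te=500, n_per_group=4, de_frac=0.05, true_lfc=3.0, seed=9
        )
        res = de_test(m, groups)
        called = set(res.index[res["status"].isin(["DE_up", "DE_down"])])
        tp = len(called & set(truth.de_true_lfc))
        assert tp / len(truth.de_true_lfc) >= 0.8
        # signs agree with planted direction
        for te, lfc in truth.de_true_lfc.items():
            if te in called:
                expect = "DE_up" if lfc > 0 else "DE_down"
                assert res.loc[te, "status"] == expect


class TestCoverage:
    def test_identical_libraries_unit_factors(self):
        cov = np.arange(10.0)
        prof = aggregate_coverage([cov, cov], [1.0, 1.0])
        assert np.allclose(prof.coverage, cov)

    def test_zero_factor_silences_library(self):
        c1, c2 = np.full(5, 3.0), np.full(5, 100.0)
        prof = aggregate_coverage([c1, c2], [2.0, 0.0])
        assert np.allclose(prof.coverage, c1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            aggregate_coverage([np.zeros(5), np.zeros(6)], [1.0, 1.0])

    def test_factor_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_coverage([np.zeros(5)], [1.0, 1.0])

    def test_g4_overlay_positions(self):
        prof = aggregate_coverage(
            [np.zeros(100)], [1.0], hits=[make_hit("te", 10, "-")]
        )
        assert prof.g4_positions == ((10, "-"),)
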