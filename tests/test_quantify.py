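import numpy as np
import pandas as pd
import pytest
import shapely
from scipy import stats

from tmespat.errors import ConfigError, DataError
from tmespat.phenotype import assign_phenotypes, call_hla1_status
from tmespat.quantify import (
    cmh_test,
    coefficient_of_variation,
    correlogram,
    export_heatmap,
    fov_ratios,
    welch_compare,
)

from conftest import make_cells

MARKERS = ("S100", "HLA1", "CD3", "CD20", "CD8", "PD1", "CD4", "FOXP3")


def counts_table(per_fov):
    """per_fov: {fov: {class: n}}; builds a phenotyped + HLA-called table."""
    marker_for = {"CD3": "CD3", "CD20": "CD20"}
    rows = []
    for fov, spec in per_fov.items():
        for lab, n in spec.items():
            for _ in range(n):
                intens = {m: 5.0 for m in MARKERS}
                if lab in ("HLA1pos", "HLA1neg", "Tumor"):
                    intens["S100"] = 100.0
                    intens["HLA1"] = 100.0 if lab == "HLA1pos" else 5.0
                elif lab == "CD8PD1":
                    intens.update(CD3=100.0, CD8=100.0, PD1=100.0, HLA1=100.0)
                elif lab == "CD4FOXP3":
                    intens.update(CD4=100.0, FOXP3=100.0, HLA1=100.0)
                else:
                    # immune cells ubiquitously express HLA-1 (internal control)
                    intens[marker_for[lab]] = 100.0
                    intens["HLA1"] = 100.0
                rows.append({"fov_id": fov, "x": float(len(rows)), "y": 0.0, **intens})
    df = {k: [r[k] for r in rows] for k in rows[0]}
    t = make_cells(df, markers=MARKERS)
    t.data["cell_id"] = [f"c{i}" for i in range(len(rows))]
    # need >=1 CD3 cell overall as HLA internal control
    return call_hla1_status(assign_phenotypes(t))


class TestFovRatios:
    def test_basic_ratio_arithmetic(self):
        t = counts_table({"F1": {"HLA1pos": 4, "HLA1neg": 6, "CD3": 5}})
        r = fov_ratios(t)
        assert r.loc["F1", "hla1pos_tumor_over_tumor"] == pytest.approx(0.4)
        assert r.loc["F1", "cd3_over_tumor"] == pytest.approx(0.5)

    def test_zero_denominator_missing_not_infinite(self):
        t = counts_table({"F1": {"CD3": 5}})
        r = fov_ratios(t)
        assert np.isnan(r.loc["F1", "cd3_over_tumor"])
        assert np.isfinite(r.loc["F1", "cd20_over_immune"])

    def test_immune_denominator(self):
        t = counts_table({"F1": {"CD3": 2, "CD20": 1, "CD8PD1": 1, "CD4FOXP3": 1, "HLA1pos": 1}})
        r = fov_ratios(t)
        assert r.loc["F1", "cd20_over_immune"] == pytest.approx(1 / 5)

    def test_region_restriction_monotone(self):
        t = counts_table({"F1": {"HLA1pos": 5, "CD3": 5}})
        whole = fov_ratios(t)
        region = shapely.box(-1, -1, 3.5, 1)  # first few cells only
        inside = fov_ratios(t, region=region)
        for col in whole.columns:
            if col.startswith("n_"):
                assert inside.loc["F1", col] <= whole.loc["F1", col]

    def test_ambiguous_cells_never_counted(self):
        t = counts_table({"F1": {"CD3": 2, "Tumor": 2}})
        # make one cell CD3+CD20+ ambiguous
        t.data.loc[0, "CD20"] = 100.0
        t2 = call_hla1_status(assign_phenotypes(
            make_cells({c: t.data[c].tolist() for c in t.data.columns}, markers=MARKERS)))
        r = fov_ratios(t2)
        assert r.loc["F1", "n_CD3"] == 1


class TestCorrelogram:
    def test_self_correlation_and_perfect_pair(self):
        ratios = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]},
                              index=pd.Index(["F1", "F2", "F3"], name="fov_id"))
        res = correlogram(ratios, min_n=3)
        assert res.r.loc["a", "a"] == 1.0 and res.flag.loc["a", "a"] == "significant"
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.flag.loc["a", "b"] == "significant"

    def test_insufficient_data_flag(self):
        ratios = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        res = correlogram(ratios, min_n=3)
        assert res.flag.loc["a", "b"] == "insufficient_data"
        assert np.isnan(res.r.loc["a", "b"])

    def test_not_significant_flag_and_symmetry(self, rng):
        ratios = pd.DataFrame({"a": rng.uniform(size=10), "b": rng.uniform(size=10),
                               "c": rng.uniform(size=10)})
        res = correlogram(ratios)
        pd.testing.assert_frame_equal(res.r, res.r.T)
        flags = set(res.flag.to_numpy().ravel())
        assert flags <= {"significant", "not_significant", "insufficient_data"}
        off = res.flag.loc["a", "b"]
        assert off == ("significant" if res.p.loc["a", "b"] <= 0.05 else "not_significant")

    def test_complete_case_handling(self):
        ratios = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan], "b": [2.0, 4.0, 6.0, 1.0]})
        res = correlogram(ratios, min_n=3)
        assert res.n.loc["a", "b"] == 3
        assert res.r.loc["a", "b"] == pytest.approx(1.0)


class TestCV:
    def test_constant_vector_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_case(self):
        # {1,2,3}: sample sd 1, mean 2 -> CV 0.5
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        v = rng.uniform(1, 5, size=20)
        assert coefficient_of_variation(7.3 * v) == pytest.approx(coefficient_of_variation(v))

    def test_degenerate_cases_missing(self):
        assert np.isnan(coefficient_of_variation([1.0]))
        assert np.isnan(coefficient_of_variation([-1.0, 1.0]))  # mean 0


def cmh_oracle(tables):
    """Hand-written CMH chi-square over 2x2xK tables (no correction):
    (sum_k a_k - sum_k E_k)^2 / sum_k V_k with the standard hypergeometric
    mean and variance per stratum."""
    num = 0.0
    var = 0.0
    for tab in tables:
        a = tab[0, 0]
        r1, r2 = tab[0].sum(), tab[1].sum()
        c1, c2 = tab[:, 0].sum(), tab[:, 1].sum()
        n = tab.sum()
        num += a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n ** 2 * (n - 1))
    stat = num ** 2 / var
    return stat, stats.chi2.sf(stat, 1)


def expand(tables):
    """Turn per-stratum 2x2 counts into unit-level outcome/group/stratum."""
    outcome, group, stratum = [], [], []
    for k, tab in enumerate(tables):
        for gi in (0, 1):
            for oi in (0, 1):
                m = int(tab[gi, oi])
                outcome += [oi] * m
                group += [gi] * m
                stratum += [k] * m
    return outcome, group, stratum


class TestCMH:
    def test_null_case(self):
        tables = [np.array([[10, 10], [20, 20]]), np.array([[5, 5], [5, 5]])]
        res = cmh_test(*expand(tables))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_single_stratum_reduces_to_score_chi2(self):
        # one stratum: CMH = (n-1)/n * Pearson chi-square of the 2x2 table
        tab = np.array([[12, 5], [3, 14]])
        res = cmh_test(*expand([tab]))
        chi2 = stats.chi2_contingency(tab, correction=False).statistic
        n = tab.sum()
        assert res.statistic == pytest.approx((n - 1) / n * chi2)

    def test_matches_hand_formula_on_random_tables(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 5))
            tables = [rng.integers(1, 20, size=(2, 2)).astype(float) for _ in range(k)]
            res = cmh_test(*expand(tables))
            stat, p = cmh_oracle(tables)
            assert res.statistic == pytest.approx(stat, rel=1e-9)
            assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_stratum_order_invariant(self, rng):
        tables = [rng.integers(1, 15, size=(2, 2)).astype(float) for _ in range(4)]
        a = cmh_test(*expand(tables)).statistic
        b = cmh_test(*expand(list(reversed(tables)))).statistic
        assert a == pytest.approx(b)

    def test_degenerate_stratum_dropped_with_warning(self):
        tables = [np.array([[10, 2], [3, 9]]), np.array([[4, 4], [0, 0]])]
        with pytest.warns(UserWarning, match="degenerate"):
            res = cmh_test(*expand(tables))
        assert res.n_strata == 1 and res.n_dropped == 1


class TestWelch:
    def test_identical_groups(self):
        res = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_separated_groups(self):
        res = welch_compare([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert abs(res.statistic) > 50 and res.pvalue < 1e-4

    def test_hand_computed_3v3(self):
        # A={1,2,3}, B={2,4,8}: t = -8/sqrt(31), df = 1922/793 (Satterthwaite)
        res = welch_compare([1.0, 2.0, 3.0], [2.0, 4.0, 8.0])
        assert res.statistic == pytest.approx(-8 / np.sqrt(31), rel=1e-12)
        assert res.df == pytest.approx(1922 / 793, rel=1e-12)
        assert res.pvalue == pytest.approx(2 * stats.t.sf(8 / np.sqrt(31), 1922 / 793), rel=1e-9)

    def test_zero_variance_conventions(self):
        assert welch_compare([2.0, 2.0], [2.0, 2.0]).pvalue == 1.0
        assert welch_compare([3.0, 3.0], [2.0, 2.0]).pvalue == 0.0


class TestExportHeatmap:
    def test_round_trip_and_missing_preserved(self, tmp_path):
        ratios = pd.DataFrame({"a": [0.5, np.nan], "b": [1.0, 2.0], "n_Tumor": [3, 4]},
                              index=pd.Index(["F1", "F2"], name="fov_id"))
        csv, png = export_heatmap(ratios, tmp_path / "m.csv", tmp_path / "m.png")
        back = pd.read_csv(csv, index_col=0)
        assert list(back.columns) == ["a", "b"]  # count columns not part of the matrix
        assert np.isnan(back.loc["F2", "a"]) and back.loc["F2", "b"] == 2.0
        assert png.exists() and png.stat().st_size > 0
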