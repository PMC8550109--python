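import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fecalmethods import ComparisonMode, generate_manifest
from fecalmethods.icc import ICCModel, classify_icc, evaluate_features, spearman
from fecalmethods.simulate import SimulationParams, simulate_metabolome


def brute_force_two_way_anova(y):
    """Independent oracle: explicit-loop two-way ANOVA without interaction."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = 0.0
    for s in range(n):
        ss_rows += k * (y[s].mean() - grand) ** 2
    ss_cols = 0.0
    for i in range(k):
        ss_cols += n * (y[:, i].mean() - grand) ** 2
    ss_tot = 0.0
    for s in range(n):
        for i in range(k):
            ss_tot += (y[s, i] - grand) ** 2
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return icc, ms_rows, ms_err


class TestICCModel:
    def test_perfect_agreement(self):
        assert ICCModel([[1, 1], [2, 2], [3, 3]]).fit().icc == pytest.approx(1.0)

    def test_constant_shift_is_consistent(self):
        res = ICCModel([[1, 2], [2, 3], [3, 4]]).fit()
        assert res.icc == pytest.approx(1.0)

    def test_hand_computed_instance(self):
        res = ICCModel([[1, 1], [2, 3], [3, 2]]).fit()
        assert res.ms_rows == pytest.approx(1.5)
        assert res.ms_error == pytest.approx(0.5)
        assert res.icc == pytest.approx(0.5)
        assert res.f_stat == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2, 2)
        assert res.category == "FAIR_GOOD"

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.standard_normal((8, 2)) + rng.standard_normal((8, 1))
            res = ICCModel(y).fit()
            icc, msr, mse = brute_force_two_way_anova(y)
            assert abs(res.icc - icc) < 1e-10
            assert abs(res.ms_rows - msr) < 1e-10
            assert abs(res.ms_error - mse) < 1e-10

    def test_matches_reference_implementation(self):
        """Cross-check against pingouin's single-measures consistency ICC (ICC3)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        y = rng.standard_normal((10, 2)) + 2 * rng.standard_normal((10, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["a", "b"], 10),
                "score": y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref3 = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        res = ICCModel(y).fit()
        assert res.icc == pytest.approx(ref3["ICC"], abs=1e-9)
        assert res.p_value == pytest.approx(ref3["pval"], abs=1e-9)

    def test_degenerate_all_identical(self):
        with pytest.warns(UserWarning, match="identical"):
            res = ICCModel([[1.0, 1.0], [1.0, 1.0]]).fit()
        assert np.isnan(res.icc)

    def test_n2_estimate_without_p(self):
        res = ICCModel([[1.0, 2.0], [3.0, 5.0]]).fit()
        assert np.isfinite(res.icc)
        assert np.isnan(res.p_value)

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="finite"):
            ICCModel([[1.0, np.nan], [2.0, 3.0]])

    @given(
        shift=st.floats(-10, 10),
        scale=st.floats(0.1, 10),
        offset=st.floats(-5, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariance_properties(self, shift, scale, offset):
        """ICC unchanged by shifting one column or jointly rescaling both."""
        rng = np.random.default_rng(7)
        y = rng.standard_normal((8, 2)) + rng.standard_normal((8, 1))
        base = ICCModel(y).fit().icc
        shifted = y.copy()
        shifted[:, 1] += shift
        assert ICCModel(shifted).fit().icc == pytest.approx(base, abs=1e-9)
        assert ICCModel(scale * y + offset).fit().icc == pytest.approx(base, abs=1e-9)

    def test_bounded_for_k2(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            icc = ICCModel(rng.standard_normal((6, 2))).fit().icc
            assert -1.0 - 1e-12 <= icc <= 1.0 + 1e-12

    def test_summary_renders(self):
        s = ICCModel([[1, 1], [2, 3], [3, 2]], metric="shannon").fit().summary()
        assert "ICC" in s and "shannon" in s


class TestClassify:
    @pytest.mark.parametrize(
        "icc,cat",
        [(0.39, "POOR"), (0.4, "FAIR_GOOD"), (0.7499, "FAIR_GOOD"), (0.75, "EXCELLENT"), (-1.0, "POOR"), (1.0, "EXCELLENT")],
    )
    def test_thresholds(self, icc, cat):
        assert classify_icc(icc) == cat

    def test_na_propagates(self):
        assert np.isnan(classify_icc(np.nan))

    def test_monotone(self):
        order = {"POOR": 0, "FAIR_GOOD": 1, "EXCELLENT": 2}
        cats = [order[classify_icc(x)] for x in np.linspace(-1, 1, 41)]
        assert cats == sorted(cats)


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_midrank_hand_example(self):
        rho, _ = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.9487, abs=1e-4)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)


@pytest.fixture(scope="module")
def logged():
    man = generate_manifest(8)
    p = SimulationParams(n_features=80, sigma_t=0.0, delta_t=0.0, sigma_e=0.05,
                         lod=0.0, adduct_dup_frac=0.0, n_qc=0, seed=21)
    met = simulate_metabolome(man, p)
    return man, np.log(met.data[met.study_columns])


class TestEvaluateFeatures:
    def test_zero_drift_stability_near_one(self, logged):
        man, data = logged
        res = evaluate_features(data, man, ComparisonMode("STABILITY", "OMNIGENE"))
        assert res.median_icc >= 0.9

    def test_feature_subset_single_row(self, logged):
        man, data = logged
        res = evaluate_features(data, man, ComparisonMode("STABILITY", "OMNIGENE"),
                                feature_subset=[data.index[0]])
        assert len(res.table) == 1

    def test_summary_matches_direct_quantiles(self, logged):
        man, data = logged
        res = evaluate_features(data, man, ComparisonMode("RELIABILITY", "ETOH95"))
        assert res.median_icc == pytest.approx(res.table["icc"].median())
        q1, q3 = res.iqr_icc
        assert (q1, q3) == pytest.approx((res.table["icc"].quantile(0.25), res.table["icc"].quantile(0.75)))

    def test_constant_feature_yields_na_row(self, logged):
        man, data = logged
        data = data.copy()
        data.iloc[0] = 3.14
        res = evaluate_features(data, man, ComparisonMode("STABILITY", "OMNIGENE"))
        assert np.isnan(res.table["icc"].iloc[0])
        assert res.n_na == 1

    def test_rows_agree_with_iccmodel(self, logged):
        man, data = logged
        from fecalmethods.design import select_pairs

        comp = ComparisonMode("CONCORDANCE", "RNALATER")
        res = evaluate_features(data, man, comp)
        pairs = select_pairs(man, comp)
        f = data.index[5]
        y = np.column_stack([data.loc[f, pairs["evaluated"]], data.loc[f, pairs["reference"]]])
        single = ICCModel(y).fit()
        assert res.table.loc[f, "icc"] == pytest.approx(single.icc, abs=1e-12)
        assert res.table.loc[f, "p"] == pytest.approx(single.p_value, abs=1e-12)

    def test_null_permutation_mean_near_zero(self):
        """Breaking the subject links (per-feature derangements of one column)
        drives the mean ICC over many features to zero (up to the O(1/n)
        finite-sample bias of the estimator, hence n = 50 subjects here)."""
        rng = np.random.default_rng(5)
        man = generate_manifest(50)
        p = SimulationParams(n_features=400, lod=0.0, adduct_dup_frac=0.0, n_qc=0, seed=30)
        met = simulate_metabolome(man, p)
        data = np.log(met.data[met.study_columns])
        from fecalmethods.design import select_pairs

        comp = ComparisonMode("STABILITY", "OMNIGENE")
        pairs = select_pairs(man, comp)
        a = data[pairs["evaluated"]].to_numpy()
        b = data[pairs["reference"]].to_numpy()
        n = b.shape[1]
        for i in range(b.shape[0]):  # cyclic shift: no subject keeps its partner
            b[i] = np.roll(b[i], int(rng.integers(1, n)))
        from fecalmethods.icc import _icc_vectorized

        out = _icc_vectorized(a, b)
        assert abs(out["icc"].mean()) < 0.1
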