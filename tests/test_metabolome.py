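import numpy as np
import pandas as pd
import pytest

from fecalmethods.metabolome import (
    collapse_adducts,
    detectability,
    filter_qc_missing,
    impute_and_log,
    overlap_with_reference,
    qc_rsd,
    restrict_by_detectability,
)
from fecalmethods.tables import MetaboliteMatrix


def _matrix(rows, qc_cols, annotations=None):
    df = pd.DataFrame(rows).T
    return MetaboliteMatrix(df, qc_columns=qc_cols, annotations=annotations)


class TestQcRsd:
    def test_constant_qc_zero_rsd(self):
        m = _matrix({"f1": {"QC1": 5.0, "QC2": 5.0, "QC3": 5.0}}, ["QC1", "QC2", "QC3"])
        assert qc_rsd(m).rsd["f1"] == 0.0

    def test_hand_rsd(self):
        m = _matrix({"f1": {"QC1": 1.0, "QC2": 2.0, "QC3": 3.0}}, ["QC1", "QC2", "QC3"])
        assert qc_rsd(m).rsd["f1"] == pytest.approx(0.5)

    def test_single_present_qc_undefined(self):
        m = _matrix({"f1": {"QC1": 1.0, "QC2": np.nan, "s1": 2.0}}, ["QC1", "QC2"])
        prof = qc_rsd(m)
        assert np.isnan(prof.rsd["f1"])
        assert prof.qc_missing_fraction["f1"] == 0.5

    def test_requires_qc_columns(self):
        with pytest.raises(ValueError):
            qc_rsd(_matrix({"f1": {"s1": 1.0}}, []))


class TestCollapseAdducts:
    def _annotated(self, rsd_vals):
        rows = {
            fid: {"QC1": v, "QC2": v * (1 + r), "s1": 10.0}
            for fid, (v, r) in rsd_vals.items()
        }
        ann = pd.DataFrame(
            {"name": ["m1"] * len(rows), "class": ["lipid"] * len(rows), "adduct_group": ["g1"] * len(rows)},
            index=list(rows),
        )
        return _matrix(rows, ["QC1", "QC2"], annotations=ann)

    def test_lowest_rsd_wins(self):
        m = self._annotated({"fa": (10.0, 0.2), "fb": (10.0, 0.1)})
        out = collapse_adducts(m, qc_rsd(m))
        assert out.feature_ids == ["fb"]

    def test_singleton_group_unchanged(self):
        rows = {"fa": {"QC1": 1.0, "QC2": 1.0, "s1": 2.0}}
        ann = pd.DataFrame({"name": ["m"], "class": ["lipid"], "adduct_group": ["g"]}, index=["fa"])
        m = _matrix(rows, ["QC1", "QC2"], annotations=ann)
        assert collapse_adducts(m, qc_rsd(m)).feature_ids == ["fa"]

    def test_rsd_tie_broken_lexicographically(self):
        m = self._annotated({"fb": (10.0, 0.1), "fa": (10.0, 0.1)})
        assert collapse_adducts(m, qc_rsd(m)).feature_ids == ["fa"]

    def test_all_undefined_rsd_falls_back_to_fewest_missing(self):
        rows = {
            "fa": {"QC1": 1.0, "QC2": np.nan, "s1": np.nan, "s2": 3.0},
            "fb": {"QC1": 1.0, "QC2": np.nan, "s1": 2.0, "s2": 3.0},
        }
        ann = pd.DataFrame({"name": ["m", "m"], "class": ["x", "x"], "adduct_group": ["g", "g"]},
                           index=["fa", "fb"])
        m = _matrix(rows, ["QC1", "QC2"], annotations=ann)
        assert collapse_adducts(m, qc_rsd(m)).feature_ids == ["fb"]

    def test_never_increases_feature_count(self, metabolite_matrix):
        out = collapse_adducts(metabolite_matrix, qc_rsd(metabolite_matrix))
        assert len(out.feature_ids) == metabolite_matrix.annotations["adduct_group"].nunique()
        assert len(out.feature_ids) <= len(metabolite_matrix.feature_ids)


class TestQcMissingFilter:
    @pytest.mark.parametrize("n_missing,kept", [(3, False), (2, True), (0, True)])
    def test_strict_half_boundary(self, n_missing, kept):
        vals = {f"QC{i}": (np.nan if i <= n_missing else 5.0) for i in range(1, 5)}
        vals["s1"] = 1.0
        m = _matrix({"f1": vals}, [f"QC{i}" for i in range(1, 5)])
        out = filter_qc_missing(m, max_missing=0.5)
        assert ("f1" in out.feature_ids) is kept


class TestDetectability:
    def _design(self):
        from fecalmethods import generate_manifest

        return generate_manifest(8)

    def test_fraction_of_subjects(self, manifest8):
        # feature present for exactly 4 of 8 subjects in ETOH95 (both timepoints)
        cols = manifest8.records[manifest8.records["method"] == "ETOH95"]["sample_id"]
        data = {}
        for c in manifest8.sample_ids:
            data[c] = 10.0
        row = pd.Series(data)
        present_subjects = {"S01", "S02", "S03", "S04"}
        for c in cols:
            if c[:3] not in present_subjects:
                row[c] = np.nan
        m = MetaboliteMatrix(row.to_frame("f1").T)
        rep = detectability(m, manifest8)
        assert rep.fractions.loc["f1", "ETOH95"] == 0.5
        assert rep.fractions.loc["f1", "GS"] == 1.0

    def test_seven_of_eight_counts_at_80_not_100(self, manifest8):
        row = pd.Series({c: 10.0 for c in manifest8.sample_ids})
        for c in manifest8.sample_ids:
            if c.startswith("S08_RNALATER"):
                row[c] = np.nan
        m = MetaboliteMatrix(row.to_frame("f1").T)
        rep = detectability(m, manifest8)
        assert rep.fractions.loc["f1", "RNALATER"] == 0.875
        counts = rep.level_counts()
        assert counts.loc["RNALATER", ">=80%"] == 1
        assert counts.loc["RNALATER", ">=100%"] == 0

    def test_level_counts_monotone(self, metabolite_matrix, manifest8):
        counts = detectability(metabolite_matrix, manifest8).level_counts((0.5, 0.8, 1.0))
        arr = counts.to_numpy()
        assert (np.diff(arr, axis=1) <= 0).all()

    def test_restrict_levels(self, metabolite_matrix, manifest8):
        rep = detectability(metabolite_matrix, manifest8)
        full = restrict_by_detectability(metabolite_matrix, rep, "ETOH95", 0.0)
        assert full.feature_ids == metabolite_matrix.feature_ids
        strict = restrict_by_detectability(metabolite_matrix, rep, "ETOH95", 1.0)
        assert set(strict.feature_ids) == rep.feature_set("ETOH95", 1.0)
        mid = restrict_by_detectability(metabolite_matrix, rep, "ETOH95", 0.8)
        assert set(mid.feature_ids) == rep.feature_set("ETOH95", 0.8)


class TestImputeAndLog:
    def test_half_minimum_rule(self):
        m = _matrix({"f1": {"s1": 10.0, "s2": 20.0, "s3": np.nan}}, [])
        out = impute_and_log(m, scope=["s1", "s2", "s3"])
        assert out.loc["f1"].tolist() == pytest.approx([1.0, np.log10(20), np.log10(5)])

    def test_no_missing_is_pure_log10(self):
        m = _matrix({"f1": {"s1": 1.0, "s2": 100.0}}, [])
        assert impute_and_log(m).loc["f1"].tolist() == [0.0, 2.0]

    def test_scope_dependence(self):
        m = _matrix({"f1": {"s1": 10.0, "s2": 40.0, "s3": np.nan}}, [])
        wide = impute_and_log(m, scope=["s1", "s2", "s3"])
        narrow = impute_and_log(m, scope=["s2", "s3"])
        assert wide.loc["f1", "s3"] == pytest.approx(np.log10(5))
        assert narrow.loc["f1", "s3"] == pytest.approx(np.log10(20))

    def test_entirely_missing_feature_excluded(self):
        m = _matrix({"f1": {"s1": np.nan, "s2": np.nan, "s3": 5.0}}, [])
        with pytest.warns(UserWarning, match="entirely missing"):
            out = impute_and_log(m, scope=["s1", "s2"])
        assert "f1" not in out.index

    def test_imputed_below_scope_minimum_preserving_order(self, metabolite_matrix):
        scope = metabolite_matrix.study_columns[:16]
        sub = metabolite_matrix.data[scope].dropna(how="all")
        out = impute_and_log(metabolite_matrix, scope=scope)
        mins = np.log10(sub.min(axis=1))
        imputed_mask = sub.isna()
        for f in out.index[:20]:
            if imputed_mask.loc[f].any():
                assert (out.loc[f][imputed_mask.loc[f]] < mins[f]).all()


class TestOverlap:
    def test_printed_counts_reproduced(self):
        shared, pct = overlap_with_reference(1878, 1867, shared=1848)
        assert (shared, pct) == (1848, 99.0)

    def test_identical_sets(self):
        s = {"a", "b", "c"}
        assert overlap_with_reference(s, s) == (3, 100.0)

    def test_disjoint_sets(self):
        assert overlap_with_reference({"a"}, {"b", "c"}) == (0, 0.0)

    def test_half_up_rounding(self):
        # 179/200 = 89.5 exactly; half-up keeps 89.5; 1/3 -> 33.3
        assert overlap_with_reference(0, 200, shared=179)[1] == 89.5
        assert overlap_with_reference(0, 3, shared=1)[1] == 33.3

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_with_reference({"a"}, set())


def test_pipeline_order_is_idempotent(metabolite_matrix):
    """Re-running collapse + QC filter on its own output changes nothing."""
    prof = qc_rsd(metabolite_matrix)
    once = filter_qc_missing(collapse_adducts(metabolite_matrix, prof), 0.5)
    prof2 = qc_rsd(once)
    twice = filter_qc_missing(collapse_adducts(once, prof2), 0.5)
    assert once.feature_ids == twice.feature_ids
    assert once.data.equals(twice.data)
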