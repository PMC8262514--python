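"""Variance-ratio conversions, plausibility screen, and database round trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intakevar import (
    RatioDatabaseEntry,
    VarianceRatio,
    components_to_ratios,
    convert_ratio,
    flag_implausible,
    read_ratio_database,
    write_ratio_database,
)
from intakevar.ratios import InfiniteAlphaError, RatioConversionError


class TestConvertRatio:
    @pytest.mark.parametrize(
        "kind,value,target,expected",
        [
            ("wiv_to_biv", 10.0, "wiv_to_total", 10.0 / 11.0),
            ("wiv_to_total", 0.5, "wiv_to_biv", 1.0),
            ("cv_ratio", 1.2, "wiv_to_biv", 1.44),
            ("cv_ratio", 1.2, "wiv_to_total", 1.44 / 2.44),
            ("wiv_to_biv", 0.0, "wiv_to_total", 0.0),
        ],
    )
    def test_table_conversions(self, kind, value, target, expected):
        out = convert_ratio(VarianceRatio(kind, value), target)
        assert out.kind == target
        assert out.value == pytest.approx(expected, abs=1e-12)

    def test_alpha_ten_rounds_to_091(self):
        """WIV:BIV of 10 is the WIV:total 0.91 screening cutoff."""
        beta = convert_ratio(VarianceRatio("wiv_to_biv", 10.0),
                             "wiv_to_total").value
        assert round(beta, 2) == 0.91

    def test_identity_conversion(self):
        r = VarianceRatio("wiv_to_total", 0.37, source="x")
        out = convert_ratio(r, "wiv_to_total")
        assert out == r and out is not r

    def test_round_trip_beta(self):
        beta = 0.37
        alpha = convert_ratio(VarianceRatio("wiv_to_total", beta),
                              "wiv_to_biv")
        back = convert_ratio(alpha, "wiv_to_total")
        assert back.value == pytest.approx(beta, abs=1e-15)

    def test_cv_ratio_not_recoverable(self):
        with pytest.raises(RatioConversionError, match="not invertible"):
            convert_ratio(VarianceRatio("wiv_to_biv", 2.0), "cv_ratio")

    def test_beta_one_gives_infinite_alpha(self):
        with pytest.raises(InfiniteAlphaError, match="infinite alpha"):
            convert_ratio(VarianceRatio("wiv_to_total", 1.0), "wiv_to_biv")

    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, beta):
        alpha = convert_ratio(VarianceRatio("wiv_to_total", beta),
                              "wiv_to_biv")
        back = convert_ratio(alpha, "wiv_to_total")
        assert abs(back.value - beta) < 1e-12

    def test_beta_monotone_in_alpha(self):
        alphas = np.linspace(0, 50, 400)
        betas = [convert_ratio(VarianceRatio("wiv_to_biv", a),
                               "wiv_to_total").value for a in alphas]
        assert all(0 <= b < 1 for b in betas)
        assert np.all(np.diff(betas) > 0)


class TestComponentsToRatios:
    def test_direct_formula(self):
        out = components_to_ratios(0.5, 0.25)
        assert out["beta"] == pytest.approx(2.0 / 3.0)
        assert out["alpha"] == pytest.approx(2.0)
        assert out["flags"] == []

    def test_zero_between_variance(self):
        out = components_to_ratios(0.3, 0.0)
        assert out["beta"] == 1.0
        assert math.isinf(out["alpha"])
        assert "infinite_alpha" in out["flags"]

    def test_negative_between_variance_not_truncated(self):
        """A negative BIV estimate yields beta > 1, flagged, never clipped."""
        out = components_to_ratios(0.52, -0.02)
        assert out["beta"] == pytest.approx(1.04)
        assert "implausible" in out["flags"]
        assert "negative_between_variance" in out["flags"]

    def test_no_variance_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            components_to_ratios(0.0, 0.0)

    @given(st.floats(min_value=1e-6, max_value=10.0),
           st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_convert_ratio(self, s_w2, s_b2):
        direct = components_to_ratios(s_w2, s_b2)
        via = convert_ratio(VarianceRatio("wiv_to_biv", direct["alpha"]),
                            "wiv_to_total")
        assert abs(direct["beta"] - via.value) < 1e-12


class TestFlagImplausible:
    @pytest.mark.parametrize(
        "kind,value,expected",
        [
            ("wiv_to_total", 0.95, True),
            ("wiv_to_total", 0.68, False),
            ("wiv_to_total", 1.04, True),
            ("wiv_to_biv", 10.5, True),
            ("wiv_to_biv", 9.9, False),
            ("cv_ratio", 3.5, True),  # alpha = 12.25
        ],
    )
    def test_cutoff(self, kind, value, expected):
        flagged, reason = flag_implausible(VarianceRatio(kind, value))
        assert flagged is expected
        if expected:
            assert reason

    def test_out_of_range_reason(self):
        flagged, reason = flag_implausible(VarianceRatio("wiv_to_total", 1.04))
        assert flagged and "out-of-range" in reason

    def test_configurable_cutoff(self):
        r = VarianceRatio("wiv_to_biv", 7.0)
        assert not flag_implausible(r)[0]
        assert flag_implausible(r, alpha_cutoff=5.0)[0]


class TestRatioDatabase:
    def _entries(self):
        return [
            RatioDatabaseEntry(
                country="Cameroon", setting="mixed",
                population_group="WRA", nutrient="zinc", method="24HR",
                n_subjects=537, n_days=2,
                ratios=[VarianceRatio("wiv_to_total", 0.74, "survey")]),
            RatioDatabaseEntry(
                country="Bangladesh", setting="rural",
                population_group="WRA", nutrient="folate",
                method="weighed record", n_subjects=463, n_days=2,
                ratios=[VarianceRatio("wiv_to_biv", 2.1, "survey")]),
            RatioDatabaseEntry(
                country="", setting="urban", population_group="children",
                nutrient="vitamin_a", method="24HR", n_subjects=None,
                n_days=None,
                ratios=[VarianceRatio("cv_ratio", 1.3, "pub")]),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "db.csv"
        entries = self._entries()
        write_ratio_database(entries, path)
        back = read_ratio_database(path)
        assert len(back) == 3
        for orig, rt in zip(entries, back):
            assert rt.nutrient == orig.nutrient
            assert rt.population_group == orig.population_group
            assert rt.n_subjects == orig.n_subjects
            assert rt.ratios[0].kind == orig.ratios[0].kind
            assert rt.ratios[0].value == pytest.approx(orig.ratios[0].value)
        # second round trip is identity on parsed fields
        path2 = tmp_path / "db2.csv"
        write_ratio_database(back, path2)
        assert read_ratio_database(path2) == back

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("country,setting,nutrient,beta\nX,rural,zinc,0.5\n")
        with pytest.raises(ValueError, match="population_group"):
            read_ratio_database(path)

    def test_missing_ratio_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("nutrient,population_group\nzinc,WRA\n")
        with pytest.raises(ValueError, match="ratio"):
            read_ratio_database(path)

    def test_disagreeing_alpha_beta_warns(self, tmp_path):
        # beta consistent with alpha=2 is 2/3; 0.5 disagrees
        path = tmp_path / "db.csv"
        path.write_text(
            "nutrient,population_group,alpha,beta\nzinc,WRA,2.0,0.5\n")
        with pytest.warns(UserWarning, match="disagree"):
            entries = read_ratio_database(path)
        assert len(entries[0].ratios) == 2

    def test_consistent_alpha_beta_no_warning(self, tmp_path):
        path = tmp_path / "db.csv"
        beta = 2.0 / 3.0
        path.write_text(
            f"nutrient,population_group,alpha,beta\nzinc,WRA,2.0,{beta!r}\n")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            read_ratio_database(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_ratio_database(path) == []

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text("nutrient,population_group,beta,season\n"
                        "zinc,WRA,0.6,harvest\n")
        entries = read_ratio_database(path)
        assert entries[0].extra["season"] == "harvest"


class TestVarianceRatioInvariants:
    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            VarianceRatio("wiv_to_biv", -0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            VarianceRatio("nope", 0.5)

    def test_frozen(self):
        r = VarianceRatio("wiv_to_total", 0.5)
        with pytest.raises(Exception):
            r.value = 0.6
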