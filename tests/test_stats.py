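"""Cohort statistics against closed-form and hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retmetrics.cohort import generate_cohort
from retmetrics.normative import default_normative_config
from retmetrics.stats import (DEFAULT_QUARTILES, QuartileBands, build_tables,
                              pearson_with_covariate, quartile_anova,
                              sex_ttest, snellen_to_logmar, summarize)


def table_from(ages, sexes, values, metric="m"):
    n = len(ages)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "age": ages, "sex": sexes,
        "bcva_snellen": ["20/20"] * n,
        "spherical_equivalent": [0.0] * n,
        "laterality": ["OD"] * n,
        metric: values,
    })


class TestSummarize:
    def test_identical_rows_have_zero_sd(self):
        t = table_from([30] * 5, ["M", "F", "M", "F", "F"], [7.0] * 5)
        s = summarize(t)
        assert s.loc["m", "sd"] == 0
        assert s.loc["m", "min"] == s.loc["m", "max"] == s.loc["m", "mean"] == 7

    def test_hand_computed_values(self):
        vals = [2.0, 4.0, 4.0, 4.0, 5.0]
        t = table_from([20, 30, 40, 50, 60], ["M"] * 3 + ["F"] * 2, vals)
        s = summarize(t)
        assert s.loc["m", "mean"] == pytest.approx(3.8)
        # sum of squared deviations: 3.24+0.04*3+1.44 = 4.8; sd = sqrt(4.8/4)
        assert s.loc["m", "sd"] == pytest.approx(math.sqrt(1.2))

    def test_sex_group_filter(self):
        t = table_from([20, 30, 40, 50], ["M", "M", "F", "F"],
                       [1.0, 3.0, 10.0, 20.0])
        assert summarize(t, group="M").loc["m", "mean"] == 2.0
        assert summarize(t, group="F").loc["m", "mean"] == 15.0


class TestPearson:
    def test_metric_equal_to_covariate_gives_r_one(self):
        t = table_from([10, 20, 30, 40], ["M", "F"] * 2, [10, 20, 30, 40])
        assert pearson_with_covariate(t, "m", "age").r_value == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        t = table_from(x, ["M", "F"] * 2 + ["M"], y)
        res = pearson_with_covariate(t, "m", "age")
        # closed-form oracle: r = cov / (sd_x sd_y), p from t on n-2 df
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert res.r_value == pytest.approx(r_oracle)
        t_stat = r_oracle * math.sqrt(3) / math.sqrt(1 - r_oracle ** 2)
        from scipy import stats as sps
        p_oracle = 2 * sps.t.sf(abs(t_stat), df=3)
        assert res.p_value == pytest.approx(p_oracle)

    def test_zero_variance_is_an_error_not_nan(self):
        t = table_from([10, 20, 30], ["M", "F", "M"], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="variance"):
            pearson_with_covariate(t, "m", "age")

    def test_bcva_covariate_uses_logmar(self):
        t = table_from([10, 20, 30, 40], ["M", "F"] * 2, [1.0, 2.0, 3.0, 4.0])
        t["bcva_snellen"] = ["20/20", "20/25", "20/30", "20/40"]
        res = pearson_with_covariate(t, "m", "bcva_logmar")
        assert res.r_value > 0.9  # worsening acuity tracks the metric here

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 80, 30)
        y = rng.normal(size=30) + 0.05 * x
        t1 = table_from(x, ["M", "F"] * 15, y)
        t2 = table_from(x, ["M", "F"] * 15, a * y + b)
        r1 = pearson_with_covariate(t1, "m", "age").r_value
        r2 = pearson_with_covariate(t2, "m", "age").r_value
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestSexTTest:
    def test_identical_groups_give_p_one(self):
        t = table_from([20, 30, 40, 50], ["M", "M", "F", "F"],
                       [5.0, 7.0, 5.0, 7.0])
        res = sex_ttest(t, "m")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_vs_three_textbook_formula(self):
        males, females = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        t = table_from([20] * 6, ["M"] * 3 + ["F"] * 3, males + females)
        res = sex_ttest(t, "m")
        # pooled: s2 = (sum sq dev M + F) / 4; t = (2 - 5) / sqrt(s2 * 2/3)
        s2 = (2.0 + 26.0) / 4.0
        t_oracle = (2.0 - 5.0) / math.sqrt(s2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_oracle)
        from scipy import stats as sps
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t_oracle), df=4))

    def test_relabel_symmetry(self):
        t = table_from([20] * 6, ["M"] * 3 + ["F"] * 3,
                       [1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        swapped = t.assign(sex=t["sex"].map({"M": "F", "F": "M"}))
        assert sex_ttest(t, "m").p_value == pytest.approx(
            sex_ttest(swapped, "m").p_value)

    def test_welch_flavor_available(self):
        t = table_from([20] * 6, ["M"] * 3 + ["F"] * 3,
                       [1.0, 2.0, 3.0, 2.0, 4.0, 9.0])
        assert sex_ttest(t, "m", equal_var=False).test_name == "t_welch"


class TestQuartileAnova:
    def test_identical_groups_give_f_zero(self):
        ages = [20, 40, 60, 80] * 3
        t = table_from(ages, ["M", "F"] * 6, [5.0] * 12)
        res = quartile_anova(t, "m")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_band_anova_equals_squared_t(self):
        ages = [20, 25, 22, 60, 65, 70]
        vals = [1.0, 2.0, 3.0, 4.0, 6.0, 9.0]
        t = table_from(ages, ["M"] * 3 + ["F"] * 3, vals)
        bands = QuartileBands(((10, 30), (51, 85)))
        res = quartile_anova(t, "m", bands)
        t_by_age = sex_ttest(t, "m")  # same 3-vs-3 split by construction
        assert res.statistic == pytest.approx(t_by_age.statistic ** 2)
        assert res.p_value == pytest.approx(t_by_age.p_value)

    def test_hand_computed_two_band_decomposition(self):
        ages = [20, 25, 60, 65]
        vals = [1.0, 3.0, 5.0, 9.0]
        t = table_from(ages, ["M", "F", "M", "F"], vals)
        res = quartile_anova(t, "m", QuartileBands(((10, 30), (51, 85))))
        # between SS = 2*(2-4.5)^2 + 2*(7-4.5)^2 = 25; within SS = 2 + 8
        f_oracle = (25.0 / 1) / (10.0 / 2)
        assert res.statistic == pytest.approx(f_oracle)

    def test_out_of_band_subjects_excluded(self):
        ages = [20, 25, 60, 65, 100]
        vals = [1.0, 3.0, 5.0, 9.0, 999.0]
        t = table_from(ages, ["M", "F", "M", "F", "M"], vals)
        res = quartile_anova(t, "m", QuartileBands(((10, 30), (51, 85))))
        assert res.n == 4

    def test_default_bands_match_published_quartiles(self):
        assert DEFAULT_QUARTILES.bands == ((10, 30), (31, 50), (51, 70),
                                           (71, 85))


@pytest.mark.parametrize("snellen,expected", [
    ("20/20", 0.0),
    ("20/40", 0.3010299957),
    ("20/15", -0.1249387366),
])
def test_snellen_to_logmar(snellen, expected):
    assert snellen_to_logmar(snellen) == pytest.approx(expected, abs=1e-6)


def test_snellen_parse_error():
    with pytest.raises(ValueError, match="Snellen"):
        snellen_to_logmar("hand motion")


class TestBuildTables:
    def test_renders_on_synthetic_cohort_with_sane_means(self):
        cfg = default_normative_config()
        t = generate_cohort(cfg, n=167, seed=0)
        tables = build_tables(t)
        summary = tables["cohort_summary"]
        for m in cfg.metrics:
            se = m.sd / np.sqrt(167)
            assert summary.loc[m.name, "mean"] == pytest.approx(
                m.mean, abs=3.5 * se)
        assert set(tables) == {"cohort_summary", "correlations", "age_bands"}
        assert (tables["correlations"]["covariate"] == "age").all()

    def test_empty_metric_column_omitted_with_warning(self):
        t = generate_cohort(default_normative_config(), n=30, seed=1)
        t["ez_rpe_central_um"] = np.nan
        with pytest.warns(UserWarning, match="ez_rpe_central_um"):
            tables = build_tables(t)
        assert "ez_rpe_central_um" not in tables["cohort_summary"].index
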