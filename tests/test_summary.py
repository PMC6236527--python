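"""Descriptive and comparative statistics, with brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gwtrace.datamodel import ValidationError, WellSummary
from gwtrace.summary import (
    anova_oneway,
    area_mean,
    detection_frequency,
    exceedance,
    metropolis_mean,
    paired_seasonal_ttest,
    pearson_r,
    summarize_records,
)
from gwtrace.io import read_records_csv


def _summary(well, mean, analyte="arsenic", scope="overall", area="residential"):
    return WellSummary(well, analyte, scope, mean=mean, sd=0.0, n=3, area=area)


class TestMeans:
    def test_metropolis_means_match_study(self, summaries):
        assert metropolis_mean(summaries, "arsenic")[0] == pytest.approx(2.32, abs=0.005)
        assert metropolis_mean(summaries, "antimony")[0] == pytest.approx(24.9, abs=0.05)
        assert metropolis_mean(summaries, "selenium")[0] == pytest.approx(22.5, abs=0.05)

    def test_single_well_identity(self):
        mean, sd = metropolis_mean([_summary("W1", 5.0)], "arsenic")
        assert mean == 5.0 and sd == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            metropolis_mean([], "arsenic")

    @pytest.mark.parametrize(
        "area, analyte, expected",
        [
            ("commercial", "arsenic", 11.82),
            ("agricultural", "arsenic", 0.0),
            ("industrial", "antimony", 26.9),  # (26.3+26.8+30.3+24.2)/4
            ("residential", "antimony", 24.545833333333334),
        ],
    )
    def test_area_means(self, summaries, area, analyte, expected):
        assert area_mean(summaries, analyte, area) == pytest.approx(expected, rel=1e-9)

    def test_unknown_area_rejected(self, summaries):
        with pytest.raises(ValidationError):
            area_mean(summaries, "arsenic", "suburban")

    def test_metropolis_mean_is_well_count_weighted_area_mean(self, summaries, study):
        counts = {}
        for area in study.areas.values():
            counts[area] = counts.get(area, 0) + 1
        for analyte in ("arsenic", "antimony", "selenium"):
            weighted = sum(
                counts[a] * area_mean(summaries, analyte, a) for a in counts
            ) / sum(counts.values())
            assert metropolis_mean(summaries, analyte)[0] == pytest.approx(
                weighted, rel=1e-12
            )


class TestDetectionAndExceedance:
    def test_detection_frequencies_match_study(self, summaries):
        assert detection_frequency(summaries, "arsenic") == pytest.approx(6 / 35)
        assert detection_frequency(summaries, "antimony") == 1.0
        assert detection_frequency(summaries, "arsenic", scope="wet") == 0.0

    @pytest.mark.parametrize(
        "analyte, limit, scope, inclusive, n_exceeding",
        [
            ("antimony", 20, "overall", False, 26),
            ("antimony", 20, "dry", False, 35),
            ("selenium", 40, "overall", False, 4),
            ("selenium", 40, "dry", True, 11),  # 31.4%, needs >= at the 40.0 well
            ("arsenic", 10, "overall", False, 2),
        ],
    )
    def test_exceedance_counts(self, summaries, analyte, limit, scope, inclusive, n_exceeding):
        rep = exceedance(summaries, analyte, limit, scope=scope, inclusive=inclusive)
        assert rep.n_wells == 35
        assert rep.n_exceeding == n_exceeding
        assert rep.fraction == n_exceeding / 35

    def test_nonpositive_limit_rejected(self, summaries):
        with pytest.raises(ValidationError):
            exceedance(summaries, "antimony", 0.0)

    def test_monotone_in_limit_and_inclusiveness(self, summaries):
        """Exceedance fraction never increases with the limit; >= is never
        below > at the same limit."""
        for analyte in ("arsenic", "antimony", "selenium"):
            fractions = [
                exceedance(summaries, analyte, limit).fraction
                for limit in (1, 5, 10, 20, 40, 80)
            ]
            assert all(a >= b for a, b in zip(fractions, fractions[1:]))
            for limit in (10, 20, 40):
                assert (
                    exceedance(summaries, analyte, limit, inclusive=True).fraction
                    >= exceedance(summaries, analyte, limit).fraction
                )


class TestPearson:
    def test_perfect_lines(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        data=st.lists(
            st.floats(min_value=-50, max_value=50), min_size=4, max_size=12, unique=True
        ),
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance(self, data, a, b):
        y = [2 * x + 1 + ((-1) ** i) * 0.5 for i, x in enumerate(data)]
        r = pearson_r(data, y)
        assert pearson_r([a * x + b for x in data], y) == pytest.approx(r, abs=1e-9)
        assert pearson_r([-a * x + b for x in data], y) == pytest.approx(-r, abs=1e-9)


class TestPairedSeasonalTTest:
    def test_antimony_dry_season_significantly_higher(self, summaries):
        res = paired_seasonal_ttest(summaries, "antimony")
        assert res.significant
        assert res.statistic > 0  # dry minus wet
        assert res.df == 34

    def test_identical_seasons_give_t_zero(self):
        rows = []
        for i, value in enumerate([3.0, 5.0, 7.0, 9.0]):
            for scope in ("wet", "dry"):
                rows.append(
                    WellSummary(f"W{i}", "arsenic", scope, mean=value, sd=0.0, n=3)
                )
        res = paired_seasonal_ttest(rows, "arsenic")
        assert res.statistic == 0.0 and res.p_value == 1.0 and not res.significant

    def test_constant_nonzero_differences_degenerate(self):
        rows = []
        for i in range(4):
            rows.append(WellSummary(f"W{i}", "arsenic", "wet", mean=1.0 + i, sd=0.0, n=3))
            rows.append(WellSummary(f"W{i}", "arsenic", "dry", mean=2.0 + i, sd=0.0, n=3))
        with pytest.warns(RuntimeWarning):
            res = paired_seasonal_ttest(rows, "arsenic")
        assert res.p_value == 0.0 and res.significant

    def test_too_few_pairs_rejected(self):
        rows = [
            WellSummary("W0", "arsenic", s, mean=1.0 + (s == "dry"), sd=0.0, n=3)
            for s in ("wet", "dry")
        ]
        with pytest.raises(ValidationError):
            paired_seasonal_ttest(rows, "arsenic")

    def test_matches_direct_formula_on_small_sample(self):
        """Brute-force oracle: t = mean(d) / (sd(d)/sqrt(n)) on 5 pairs."""
        wet = [1.0, 4.0, 2.5, 3.0, 6.0]
        dry = [2.0, 3.5, 4.0, 5.5, 7.0]
        rows = []
        for i, (w, d) in enumerate(zip(wet, dry)):
            rows.append(WellSummary(f"W{i}", "selenium", "wet", mean=w, sd=0.0, n=3))
            rows.append(WellSummary(f"W{i}", "selenium", "dry", mean=d, sd=0.0, n=3))
        res = paired_seasonal_ttest(rows, "selenium")
        d = np.array(dry) - np.array(wet)
        t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_direct, abs=1e-12)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_direct), len(d) - 1), abs=1e-12
        )


class TestAnova:
    def test_hand_computed_example(self):
        f, df1, df2, p, ssb, ssw = anova_oneway([(1, 2, 3), (4, 5, 6)])
        assert (f, df1, df2) == (13.5, 1, 4)
        assert ssb == 13.5 and ssw == 4.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc, 1.0, size=8) for loc in (0.0, 0.4, 1.1)]
        f, df1, df2, p, *_ = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=n) for n in (5, 9, 4, 7)]
        _, _, _, _, ssb, ssw = anova_oneway(groups)
        pooled = np.concatenate(groups)
        ss_total = ((pooled - pooled.mean()) ** 2).sum()
        assert ssb + ssw == pytest.approx(ss_total, rel=1e-12)

    def test_constant_groups_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([(2.0, 2.0), (2.0, 2.0)])

    def test_exchangeable_groups_not_significant(self):
        rng = np.random.default_rng(3)
        pooled = rng.normal(size=30)
        rng.shuffle(pooled)
        f, _, _, p, *_ = anova_oneway(np.split(pooled, 3))
        assert p > 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([(1.0,), (2.0, 3.0)])


class TestSummarizeRecords:
    def test_balanced_campaign_round_trip(self, tmp_path):
        """Monthly records → summaries: overall mean is the mean of the two
        seasonal means, pooled SD uses n−1, min/max cover all months."""
        lines = ["well_id,area,season,month_index,analyte,conc_ugL"]
        wet, dry = [2.0, 4.0, 6.0], [10.0, 12.0, 14.0]
        for m, v in enumerate(wet, 1):
            lines.append(f"GW1,residential,wet,{m},antimony,{v}")
        for m, v in enumerate(dry, 1):
            lines.append(f"GW1,residential,dry,{m},antimony,{v}")
        path = tmp_path / "c.csv"
        path.write_text("\n".join(lines) + "\n")
        out = {s.scope: s for s in summarize_records(read_records_csv(path))}
        assert out["overall"].mean == pytest.approx((np.mean(wet) + np.mean(dry)) / 2)
        assert out["overall"].sd == pytest.approx(np.std(wet + dry, ddof=1))
        assert out["overall"].n == 6
        assert (out["overall"].min, out["overall"].max) == (2.0, 14.0)
        assert out["wet"].mean == 4.0 and out["dry"].mean == 12.0
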