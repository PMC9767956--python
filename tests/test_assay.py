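"""ELISA analytics: background, titers, normalisation, outliers,
regression, ANOVA and kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from resurf.assay import (
    AssayDataError,
    anova_hypersensitivity,
    background_subtract,
    binding_distance_regression,
    endpoint_titer,
    grubbs_critical,
    grubbs_outlier,
    his_normalize,
    kinetic_relvmax,
    normalize_to_wt,
    pick_working_dilution,
)


def wells(rows):
    base = {"plate_id": "P1", "sample_id": "s", "antigen_id": "WT",
            "dilution": 300.0, "replicate": 1, "role": "experimental"}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestBackgroundSubtract:
    def test_mean_background_subtracted(self):
        df = wells([
            {"role": "secondary_only", "od450": 0.05},
            {"role": "secondary_only", "od450": 0.07},
            {"od450": 0.50},
        ])
        out = background_subtract(df)
        assert out.loc[out.role == "experimental", "od450"].iloc[0] == pytest.approx(0.44)

    def test_negative_clamps_to_zero(self):
        df = wells([
            {"role": "secondary_only", "od450": 0.06},
            {"od450": 0.04},
        ])
        out = background_subtract(df)
        assert out.loc[out.role == "experimental", "od450"].iloc[0] == 0.0
        out2 = background_subtract(df, clamp_negative=False)
        assert out2.loc[out2.role == "experimental", "od450"].iloc[0] == pytest.approx(-0.02)

    def test_plates_are_independent(self):
        df = wells([
            {"role": "secondary_only", "od450": 0.10},
            {"od450": 0.50},
            {"plate_id": "P2", "role": "secondary_only", "od450": 0.30},
            {"plate_id": "P2", "od450": 0.50},
        ])
        out = background_subtract(df)
        vals = out[out.role == "experimental"].set_index("plate_id")["od450"]
        assert vals["P1"] == pytest.approx(0.40)
        assert vals["P2"] == pytest.approx(0.20)

    def test_missing_background_wells(self):
        with pytest.raises(AssayDataError):
            background_subtract(wells([{"od450": 0.5}]))


def series(sig_by_dil, **kw):
    rows = []
    for d, v in sig_by_dil.items():
        for rep, x in enumerate(v if isinstance(v, (list, tuple)) else [v]):
            rows.append({"dilution": float(d), "replicate": rep + 1,
                         "od450": float(x), **kw})
    return wells(rows)


class TestEndpointTiter:
    DILS = [300, 3000, 30000, 300000, 1000000]

    def test_high_titer_through_one_million(self):
        s = series({d: 1.0 for d in self.DILS})
        c = series({d: 0.05 for d in self.DILS}, role="healthy_control")
        t = endpoint_titer(s, c)
        assert t.titer == 1000000

    def test_all_below_threshold_is_undetected(self):
        s = series({d: 0.1 for d in self.DILS})
        c = series({d: 0.05 for d in self.DILS}, role="healthy_control")
        t = endpoint_titer(s, c)
        assert t.titer is None and not t.detected

    def test_exactly_three_fold_counts(self):
        s = series({300: 0.15, 3000: 0.01})
        c = series({300: 0.05, 3000: 0.05}, role="healthy_control")
        t = endpoint_titer(s, c)
        assert t.titer == 300
        assert t.fold_over_control == pytest.approx(3.0)

    def test_monotone_under_signal_scaling(self):
        rng = np.random.default_rng(0)
        sig = {d: float(x) for d, x in zip(self.DILS, rng.uniform(0.05, 1.0, 5))}
        c = series({d: 0.05 for d in self.DILS}, role="healthy_control")
        prev = -np.inf
        for scale in (0.5, 1.0, 2.0, 5.0, 20.0):
            t = endpoint_titer(series({d: v * scale for d, v in sig.items()}), c)
            cur = -1 if t.titer is None else t.titer
            assert cur >= prev
            prev = cur

    def test_zero_control_uses_floor(self):
        s = series({300: 0.2})
        c = series({300: 0.0}, role="healthy_control")
        t = endpoint_titer(s, c, control_floor=0.01)
        assert t.titer == 300 and t.fold_over_control == pytest.approx(20.0)

    def test_empty_series_rejected(self):
        with pytest.raises(AssayDataError):
            endpoint_titer(series({}), series({300: 0.05}))


class TestWorkingDilution:
    def test_picks_eighty_percent_point(self):
        s = series({100: 1.0, 300: 0.8, 900: 0.4, 2700: 0.1})
        assert pick_working_dilution(s) == 300

    def test_tie_goes_to_more_dilute(self):
        s = series({100: 1.0, 300: 0.82, 900: 0.78})
        assert pick_working_dilution(s) == 900

    def test_fraction_one_picks_peak(self):
        s = series({100: 1.0, 300: 0.5, 900: 0.2})
        assert pick_working_dilution(s, fraction=1.0) == 100

    def test_flat_zero_rejected(self):
        with pytest.raises(AssayDataError):
            pick_working_dilution(series({100: 0.0, 300: 0.0, 900: 0.0}))


class TestNormalisation:
    def test_percent_of_wt(self):
        pct = normalize_to_wt({"WT": 1.0, "v1": 0.5, "v2": 0.0}, "WT")
        assert pct == {"WT": 100.0, "v1": 50.0, "v2": 0.0}

    def test_nonpositive_wt_rejected(self):
        with pytest.raises(AssayDataError):
            normalize_to_wt({"WT": 0.0, "v1": 0.5}, "WT")

    def test_his_factor_doubles_under_half_coating(self):
        out = his_normalize({"WT": 100.0, "v1": 40.0},
                            {"WT": 1.0, "v1": 0.5}, "WT")
        assert out["v1"] == pytest.approx(80.0)
        assert out["WT"] == pytest.approx(100.0)

    def test_unit_factors_change_nothing(self):
        pct = {"WT": 100.0, "v1": 33.0}
        out = his_normalize(pct, {"WT": 2.0, "v1": 2.0}, "WT")
        assert out == pytest.approx(pct)

    def test_common_plate_gain_cancels(self):
        means = {"WT": 1.0, "v1": 0.6, "v2": 0.3}
        his = {"WT": 0.9, "v1": 0.8, "v2": 0.7}
        base = his_normalize(normalize_to_wt(means, "WT"), his, "WT")
        gained = his_normalize(
            normalize_to_wt({k: 3.7 * v for k, v in means.items()}, "WT"),
            {k: 3.7 * v for k, v in his.items()}, "WT")
        for k in means:
            assert gained[k] == pytest.approx(base[k])


class TestGrubbs:
    def test_planted_outlier_flagged(self):
        vals = [1.0, 1.1, 0.9, 1.0, 5.0]
        x = np.asarray(vals)
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        assert g == pytest.approx(1.7877, abs=1e-3)
        assert grubbs_critical(5, 0.05) == pytest.approx(1.715, abs=1e-3)
        assert grubbs_outlier(vals) == [4]

    def test_constant_vector_flags_nothing(self):
        assert grubbs_outlier([2.0, 2.0, 2.0, 2.0]) == []

    def test_small_sample_rejected(self):
        with pytest.raises(AssayDataError):
            grubbs_outlier([1.0, 2.0])

    @given(st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
    def test_equidistant_triple_never_flagged(self, scale, shift):
        # for n=3 equidistant values G = 1 < G_crit(3) ~ 1.154 always
        vals = [shift - scale, shift, shift + scale]
        assert grubbs_outlier(vals) == []

    def test_null_flag_rate_matches_alpha(self):
        rng = np.random.default_rng(2024)
        n, reps = 8, 10000
        x = rng.standard_normal((reps, n))
        g = np.max(np.abs(x - x.mean(axis=1, keepdims=True)), axis=1) / x.std(
            axis=1, ddof=1
        )
        rate = float(np.mean(g > grubbs_critical(n, 0.05)))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_iterative_removal(self):
        vals = [1.0, 1.05, 0.95, 1.0, 1.02, 0.98, 30.0, 6.0]
        flagged = grubbs_outlier(vals, iterate=True)
        assert set(flagged) == {6, 7}


class TestRegression:
    def test_exact_line(self):
        r = binding_distance_regression([(0, 100), (10, 90), (20, 80)])
        assert r.slope == pytest.approx(-1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_x_is_singular(self):
        with pytest.raises(AssayDataError):
            binding_distance_regression([(5, 1), (5, 2), (5, 3)])

    def test_too_few_points(self):
        with pytest.raises(AssayDataError):
            binding_distance_regression([(0, 1), (1, 2)])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(7)
        x = np.arange(10.0)
        ps = []
        for _ in range(2000):
            y = rng.standard_normal(10)
            ps.append(binding_distance_regression(list(zip(x, y))).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def score_frame(groups):
    rows = []
    for g, scores in groups.items():
        for i, s in enumerate(scores):
            rows.append({"mouse_id": f"{g}{i}", "group": g, "day": 21, "score": s})
    return pd.DataFrame(rows)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        df = score_frame({"wt": [2, 3, 2, 3], "v": [2, 3, 2, 3]})
        out = anova_hypersensitivity(df, "wt")
        assert out.loc[0, "F"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        df = score_frame({"wt": [4, 3, 4, 3, 4], "v": [1, 0, 1, 2, 0]})
        out = anova_hypersensitivity(df, "wt")
        a = df[df.group == "v"]["score"]
        b = df[df.group == "wt"]["score"]
        t = stats.ttest_ind(a, b, equal_var=True)
        assert out.loc[0, "F"] == pytest.approx(t.statistic**2)
        assert out.loc[0, "p_value"] == pytest.approx(t.pvalue)

    def test_invalid_scores_rejected(self):
        df = score_frame({"wt": [2, 7], "v": [1, 1]})
        with pytest.raises(AssayDataError):
            anova_hypersensitivity(df, "wt")

    def test_holm_adjustment_is_monotone(self):
        df = score_frame({"wt": [4, 4, 3, 4], "a": [0, 1, 0, 1],
                          "b": [3, 4, 3, 4], "c": [2, 1, 2, 1]})
        out = anova_hypersensitivity(df, "wt", holm=True)
        assert (out["p_holm"] >= out["p_value"] - 1e-12).all()


class TestRelVmax:
    def test_linear_signal_recovers_slope(self):
        t = np.arange(0, 40, 2.0)
        assert kinetic_relvmax(t, 3.5 * t + 1.0) == pytest.approx(3.5)

    def test_saturating_curve_uses_early_phase(self):
        t = np.arange(0, 60, 2.0)
        y = np.minimum(10.0 * t, 100.0)  # linear then flat
        assert kinetic_relvmax(t, y) == pytest.approx(10.0)

    def test_relative_to_reference(self):
        t = np.arange(0, 40, 2.0)
        assert kinetic_relvmax(t, 5.0 * t, reference_vmax=10.0) == pytest.approx(0.5)

    def test_too_few_points(self):
        with pytest.raises(AssayDataError):
            kinetic_relvmax([0, 2], [0, 1], window=5)
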