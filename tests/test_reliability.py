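import numpy as np
import pytest

from pacemetrics.reliability import (
    icc_2_1,
    icc_3_1,
    icc_interpretation,
    measurement_matrix,
    reliability_report,
    reliability_table,
    rm_anova,
    sem,
    typical_error_cv,
)

M32 = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])


def brute_force_ss(x):
    """Independent sum-of-squares decomposition by explicit loops."""
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    return ssr, ssc, sst - ssr - ssc


class TestRMAnova:
    def test_identical_columns(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        a = rm_anova(x)
        assert a.f == 0.0 and a.p == 1.0

    def test_hand_oracle_3x2(self):
        a = rm_anova(M32)
        assert a.ms_rows == pytest.approx(4.5)
        assert a.ms_cols == pytest.approx(6.0)
        assert a.ms_error == pytest.approx(0.5)
        assert a.f == pytest.approx(12.0)
        assert (a.df_cols, a.df_error) == (1, 2)
        # SST 16 = SSR 9 + SSC 6 + SSE 1
        assert a.ss_total == pytest.approx(16.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n, k = rng.integers(3, 9), rng.integers(2, 6)
            x = rng.normal(0, 1, (n, k))
            a = rm_anova(x)
            ssr, ssc, sse = brute_force_ss(x)
            assert a.ss_rows == pytest.approx(ssr, rel=1e-10)
            assert a.ss_cols == pytest.approx(ssc, rel=1e-10)
            assert a.ss_error == pytest.approx(sse, rel=1e-9, abs=1e-12)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (12, 4)) + rng.normal(0, 0.5, (12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "day": np.tile(np.arange(4), 12),
                "y": x.ravel(),
            }
        )
        res = pg.rm_anova(
            data=long, dv="y", within="day", subject="subject", correction=False
        )
        a = rm_anova(x)
        assert a.f == pytest.approx(float(res["F"].iloc[0]), rel=1e-9)
        assert a.p == pytest.approx(float(res["p_unc"].iloc[0]), rel=1e-9)

    def test_degenerate_zero_error_variance(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])  # pure row+col
        with pytest.warns(UserWarning, match="infinite"):
            a = rm_anova(x)
        assert np.isinf(a.f) and a.p == 0.0

    def test_rejects_incomplete(self):
        with pytest.raises(ValueError):
            rm_anova(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestICC:
    def test_perfect_repeatability(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        icc, lo, hi = icc_3_1(x)
        assert icc == pytest.approx(1.0)

    def test_closed_form_3x2(self):
        icc, lo, hi = icc_3_1(M32)
        assert icc == pytest.approx((4.5 - 0.5) / (4.5 + 0.5))
        assert lo <= icc <= hi

    @pytest.mark.parametrize(
        "form,pg_type", [("3,1", "ICC(C,1)"), ("2,1", "ICC(A,1)")]
    )
    def test_matches_pingouin(self, form, pg_type):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(17)
        x = rng.normal(2.7, 0.3, (15, 1)) + rng.normal(0, 0.08, (15, 4))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 4),
                "rater": np.tile(np.arange(4), 15),
                "y": x.ravel(),
            }
        )
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="y"
        ).set_index("Type")
        fn = icc_3_1 if form == "3,1" else icc_2_1
        icc, lo, hi = fn(x)
        assert icc == pytest.approx(float(res.loc[pg_type, "ICC"]), abs=1e-9)
        want_lo, want_hi = res.loc[pg_type, "CI95"]  # rounded to 2 dp
        assert lo == pytest.approx(float(want_lo), abs=6e-3)
        assert hi == pytest.approx(float(want_hi), abs=6e-3)

    def test_consistency_invariances(self):
        rng = np.random.default_rng(31)
        x = rng.normal(5, 1, (10, 4))
        icc, _, _ = icc_3_1(x)
        shifted = x.copy()
        shifted[:, 2] += 3.0  # uniform day shift
        icc_shift, _, _ = icc_3_1(shifted)
        assert icc_shift == pytest.approx(icc, rel=1e-10)
        icc_scaled, _, _ = icc_3_1(2.5 * x)
        assert icc_scaled == pytest.approx(icc, rel=1e-10)

    def test_variance_component_recovery(self):
        # subject + noise model: ICC(3,1) estimates var_s / (var_s + var_e)
        rng = np.random.default_rng(2024)
        var_s, var_e = 1.0, 0.25
        subj = rng.normal(0, np.sqrt(var_s), (200, 1))
        day = rng.normal(0, 0.1, (1, 4))
        x = subj + day + rng.normal(0, np.sqrt(var_e), (200, 4))
        icc, lo, hi = icc_3_1(x)
        assert icc == pytest.approx(var_s / (var_s + var_e), abs=0.05)
        assert lo < var_s / (var_s + var_e) < hi


class TestSemAndCV:
    def test_sem_limits(self):
        x = np.array([[1.0, 1.1], [2.0, 2.1], [3.0, 3.2]])
        assert sem(x, icc=1.0) == 0.0
        resid = x - x.mean(axis=0, keepdims=True)
        pooled = np.sqrt((resid**2).sum() / (x.size - x.shape[1]))
        assert sem(x, icc=0.0) == pytest.approx(pooled)

    def test_sem_formula(self):
        # pooled sd 0.35 with ICC 0.92 gives 0.35*sqrt(0.08) ~ 0.099
        rng = np.random.default_rng(1)
        x = rng.normal(2.7, 0.36, (20, 4))
        resid = x - x.mean(axis=0, keepdims=True)
        pooled = np.sqrt((resid**2).sum() / (x.size - x.shape[1]))
        assert sem(x, icc=0.92) == pytest.approx(pooled * np.sqrt(0.08))

    def test_typical_error_cv_identical_columns(self):
        x = np.array([[2.5, 2.5], [2.8, 2.8], [3.1, 3.1]])
        cv, transform = typical_error_cv(x)
        assert cv == pytest.approx(0.0, abs=1e-9)
        assert transform == "log"

    def test_uniform_day_ratio_gives_zero(self):
        # day 2 exactly 5% faster for everyone: pure column effect on the
        # log scale, absorbed by the day term
        rng = np.random.default_rng(6)
        d1 = rng.uniform(2.3, 3.2, 15)
        x = np.column_stack([d1, d1 * 1.05])
        cv, transform = typical_error_cv(x)
        assert transform == "log"
        assert cv == pytest.approx(0.0, abs=1e-9)

    def test_known_log_noise_level(self):
        # multiplicative noise with sd ~3% should come back as CV% ~ 3
        rng = np.random.default_rng(44)
        base = rng.uniform(2.3, 3.2, (400, 1))
        x = base * np.exp(rng.normal(0, 0.03, (400, 4)))
        cv, transform = typical_error_cv(x)
        assert transform == "log"
        assert cv == pytest.approx(3.0, abs=0.3)

    def test_raw_fallback_for_nonpositive_values(self):
        x = np.array([[1.0, -0.5], [2.0, 1.5], [3.0, 2.5]])
        cv, transform = typical_error_cv(x)
        assert transform == "raw"
        assert np.isfinite(cv) and cv >= 0


class TestReport:
    def test_interpretation_bands(self):
        assert icc_interpretation(0.2) == "poor"
        assert icc_interpretation(0.5) == "moderate"
        assert icc_interpretation(0.75) == "good"
        assert icc_interpretation(0.9) == "excellent"

    def test_full_report_on_synthetic_cohort(self, default_variables):
        stats_list = reliability_report(default_variables)
        assert [s.variable for s in stats_list] == [
            "ms", "cv", "cs", "csf", "acs", "pr", "mrs", "split_32_10"
        ]
        by_var = {s.variable: s for s in stats_list}
        # stationary generator: no real day effect on mean speed
        assert by_var["ms"].p_value > 0.05
        # mean speed dominated by stable between-runner differences
        assert by_var["ms"].icc > 0.9
        assert by_var["ms"].interpretation == "excellent"
        for s in stats_list:
            assert s.icc_ci_low <= s.icc <= s.icc_ci_high
            assert s.sem >= 0 and s.cv_percent >= 0
            assert 0 <= s.p_value <= 1
        # signed variables can go negative -> raw path allowed; MS must log
        assert by_var["ms"].transform_used == "log"
        df = reliability_table(stats_list)
        assert len(df) == 8 and "day4_mean" in df.columns

    def test_degenerate_zero_variance_variable_flagged(self):
        import pandas as pd

        rows = []
        for rid in ("a", "b", "c"):
            for day in (1, 2):
                rows.append(
                    {"runner_id": rid, "day": day,
                     "ms": {"a": 2.5, "b": 2.7, "c": 2.9}[rid], "cv": 0.0}
                )
        df = pd.DataFrame(rows)
        stats_list = reliability_report(df, variable_names=("ms", "cv"))
        by_var = {s.variable: s for s in stats_list}
        assert np.isnan(by_var["cv"].icc)
        assert "zero variance" in by_var["cv"].interpretation
        assert by_var["ms"].icc == pytest.approx(1.0)

    def test_measurement_matrix_rejects_incomplete(self, default_variables):
        df = default_variables.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            measurement_matrix(df, "ms")

    def test_unknown_icc_form(self, default_variables):
        with pytest.raises(ValueError):
            reliability_report(default_variables, icc_form="1,1")
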