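"""Tests of the repeated-measures model, divergence rule, and KW/Dunn."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socmetrics.exceptions import DegenerateDataError
from socmetrics.stats import (
    ci_divergence_day,
    describe_widths,
    fit_lmm,
    kruskal_dunn,
    significance_stars,
    validate_cohort,
)
from socmetrics.synthetic import generate_cohort


def cohort_frame(rows):
    return pd.DataFrame(rows, columns=["chip_id", "group", "day", "width_um"])


class TestValidateCohort:
    def test_duplicate_chip_day_rejected(self):
        df = cohort_frame(
            [("c1", "g", 2, 1.0), ("c1", "g", 2, 2.0)]
        )
        with pytest.raises(ValueError):
            validate_cohort(df)

    def test_chip_in_two_groups_rejected(self):
        df = cohort_frame([("c1", "a", 2, 1.0), ("c1", "b", 3, 2.0)])
        with pytest.raises(ValueError):
            validate_cohort(df)


class TestFitLmm:
    def test_single_cell_reduces_to_sample_mean(self):
        df = cohort_frame(
            [(f"c{i}", "control", 2, w) for i, w in enumerate([1290.0, 1300.0, 1310.0])]
        )
        fit = fit_lmm(df)
        pred = fit.predictions.iloc[0]
        assert pred["mean_um"] == pytest.approx(1300.0)
        assert pred["ci_upper_um"] - pred["mean_um"] == pytest.approx(
            pred["mean_um"] - pred["ci_lower_um"]
        )
        # REML variance of {1290,1300,1310} is 100 -> se = sqrt(100/3)
        assert pred["se_um"] == pytest.approx(np.sqrt(100.0 / 3.0))

    def test_balanced_complete_equals_closed_form(self, small_cohort_design):
        cohort = generate_cohort(small_cohort_design(seed=21))
        fit = fit_lmm(cohort)
        for (g, d), grp in cohort.groupby(["group", "day"]):
            assert fit.cell_mean(g, d) == pytest.approx(
                grp["width_um"].mean(), abs=1e-4
            )
        wide = cohort.pivot(index="chip_id", columns="day", values="width_um")
        groups = cohort.drop_duplicates("chip_id").set_index("chip_id")["group"]
        centered = wide.groupby(groups.reindex(wide.index)).transform(
            lambda v: v - v.mean()
        )
        pooled = centered.T @ centered / (len(wide) - 2)
        assert np.allclose(fit.covariance.to_numpy(), pooled.to_numpy(), atol=1e-3)

    def test_monotone_dropout_fit_matches_r_gls_reml(self, small_cohort_design, tmp_path):
        """Cross-check against nlme::gls (unstructured covariance, REML)."""
        design = small_cohort_design(
            seed=31,
            dropout_schedule={"control": (8, 8, 6, 5), "co-culture": (12, 11, 10, 8)},
        )
        cohort = generate_cohort(design)
        csv = tmp_path / "cohort.csv"
        cohort.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            d$day <- factor(d$day); d$group <- factor(d$group)
            m <- gls(width_um ~ group*day, data=d,
                     correlation=corSymm(form=~as.integer(day)|chip_id),
                     weights=varIdent(form=~1|day), method="REML",
                     control=glsControl(maxIter=200, msMaxIter=200))
            newd <- expand.grid(group=levels(d$group), day=levels(d$day))
            X <- model.matrix(~group*day, newd)
            out <- data.frame(group=newd$group, day=newd$day,
                              mean=predict(m, newd),
                              se=sqrt(diag(X %*% vcov(m) %*% t(X))))
            write.csv(out, "{tmp_path / 'r_pred.csv'}", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        r_pred = pd.read_csv(tmp_path / "r_pred.csv")
        fit = fit_lmm(cohort)
        merged = fit.predictions.merge(r_pred, on=["group", "day"])
        assert len(merged) == 8
        assert np.allclose(merged["mean_um"], merged["mean"], atol=0.05)
        assert np.allclose(merged["se_um"], merged["se"], atol=0.05)

    def test_covariance_estimate_is_symmetric_psd(self, small_cohort_design):
        fit = fit_lmm(generate_cohort(small_cohort_design(seed=5)))
        sigma = fit.covariance.to_numpy()
        assert np.allclose(sigma, sigma.T)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)

    def test_ci_bounds_bracket_mean(self, small_cohort_design):
        fit = fit_lmm(generate_cohort(small_cohort_design(seed=6)))
        p = fit.predictions
        assert (p["ci_lower_um"] <= p["mean_um"]).all()
        assert (p["mean_um"] <= p["ci_upper_um"]).all()


class TestDivergence:
    def predictions(self, rows):
        return pd.DataFrame(
            rows, columns=["group", "day", "ci_lower_um", "ci_upper_um"]
        )

    def test_identical_predictions_never_diverge(self):
        rows = [(g, d, 1290.0, 1310.0) for g in ("a", "b") for d in (2, 3, 5)]
        res = ci_divergence_day(self.predictions(rows))
        assert res.first_divergence_day is None
        assert all(res.overlap_by_day.values())

    def test_reported_day6_interval_bounds_separate(self):
        # Day-6 bounds as printed for the two conditions; earlier days overlap.
        rows = [
            ("control", 5, 1280.0, 1400.0),
            ("co-culture", 5, 1250.0, 1290.0),
            ("control", 6, 1283.53, 1394.714),
            ("co-culture", 6, 1247.35, 1276.41),
        ]
        res = ci_divergence_day(self.predictions(rows))
        assert res.first_divergence_day == 6
        assert res.overlap_by_day == {5: True, 6: False}

    def test_touching_intervals_count_as_overlap(self):
        rows = [("a", 2, 1200.0, 1250.0), ("b", 2, 1250.0, 1300.0)]
        res = ci_divergence_day(self.predictions(rows))
        assert res.first_divergence_day is None

    def test_days_before_divergence_all_overlap(self):
        rows = []
        for d in (2, 3, 5, 6, 7):
            sep = d >= 6
            rows.append(("a", d, 1300.0, 1320.0))
            rows.append(("b", d, 1330.0 if sep else 1310.0, 1350.0))
        res = ci_divergence_day(self.predictions(rows))
        assert res.first_divergence_day == 6
        assert all(res.overlap_by_day[d] for d in (2, 3, 5))

    def test_single_group_rejected(self):
        rows = [("a", 2, 1.0, 2.0)]
        with pytest.raises(ValueError):
            ci_divergence_day(self.predictions(rows))


class TestKruskalDunn:
    def test_hand_computed_h_statistic(self):
        res = kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        # H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) with rank sums 3, 7, 11
        assert res.h_statistic == pytest.approx(4.571, abs=5e-4)

    def test_two_groups_h_equals_z_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        res = kruskal_dunn({"a": a, "b": b})
        z = res.pairwise["z"].iloc[0]
        assert res.h_statistic == pytest.approx(z**2, rel=1e-9)

    @given(
        scale=st.floats(min_value=0.1, max_value=50.0),
        shift=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_rank_invariance_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(12)
        groups = {k: rng.normal(i, 1, 7) for i, k in enumerate("abc")}
        base = kruskal_dunn(groups)
        cubed = kruskal_dunn(
            {k: (scale * v + shift) ** 3 for k, v in groups.items()}
        )
        assert cubed.h_statistic == pytest.approx(base.h_statistic, rel=1e-9)
        assert np.allclose(cubed.pairwise["z"], base.pairwise["z"])

    def test_all_identical_observations_rejected(self):
        with pytest.raises(DegenerateDataError):
            kruskal_dunn({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})

    def test_adjusted_p_never_below_unadjusted_and_stars_consistent(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(3 * i, 1, 12) for i, k in enumerate("abcd")}
        res = kruskal_dunn(groups)
        pw = res.pairwise
        assert (pw["p_adjusted"] >= pw["p_unadjusted"] - 1e-15).all()
        for _, row in pw.iterrows():
            assert row["stars"] == significance_stars(row["p_adjusted"])

    def test_tie_heavy_data_matches_scipy_h(self):
        groups = {"a": [1, 1, 2, 2], "b": [2, 2, 3, 3], "c": [3, 3, 1, 4]}
        from scipy.stats import kruskal

        res = kruskal_dunn(groups)
        h, _ = kruskal(*groups.values())
        assert res.h_statistic == pytest.approx(h)


class TestDescribeWidths:
    def test_hand_arithmetic(self):
        df = cohort_frame(
            [(f"c{i}", "control", 2, w) for i, w in enumerate([1290.0, 1300.0, 1310.0])]
        )
        out = describe_widths(df)
        assert out["mean_um"].iloc[0] == pytest.approx(1300.0)
        assert out["sd_um"].iloc[0] == pytest.approx(10.0)

    def test_single_chip_cell_sd_undefined(self):
        df = cohort_frame([("c0", "control", 2, 1295.0)])
        out = describe_widths(df)
        assert out["mean_um"].iloc[0] == 1295.0
        assert np.isnan(out["sd_um"].iloc[0])

    def test_agrees_with_direct_recomputation(self, small_cohort_design):
        cohort = generate_cohort(small_cohort_design(seed=8))
        out = describe_widths(cohort).set_index(["group", "day"])
        for (g, d), grp in cohort.groupby(["group", "day"]):
            v = grp["width_um"]
            assert out.loc[(g, d), "mean_um"] == pytest.approx(v.mean())
            assert out.loc[(g, d), "sd_um"] == pytest.approx(v.std(ddof=1))
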