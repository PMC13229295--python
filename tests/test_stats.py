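import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from wristmotion import stats as ws


def three_group_table(rng, n=30, shift=(0.0, 0.0, 0.0), metric="m0", n_metrics=1):
    """Lognormal metric table with per-class multiplicative shifts."""
    rows = []
    classes = [("control", 1), ("dmd", 1), ("dmd", 0)]
    for (group, amb), s in zip(classes, shift):
        for _ in range(n):
            rows.append(
                dict(
                    group=group,
                    ambulatory=amb,
                    **{
                        (metric if k == 0 else f"m{k}"): float(rng.lognormal(s, 0.4))
                        for k in range(n_metrics)
                    },
                )
            )
    df = pd.DataFrame(rows)
    df["participant_id"] = [f"P{i}" for i in range(len(df))]
    df["visit"] = 1
    return df


class TestGroupCompare:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        df = three_group_table(rng, shift=(2.0, 1.0, 0.0))
        res = ws.group_compare(df, metrics=["m0"])
        assert res[0].q_value < 0.01
        assert len(res[0].pairwise_p) == 3
        assert res[0].q_value >= res[0].p_value

    def test_two_group_degrades_to_rank_sum(self):
        rng = np.random.default_rng(1)
        df = three_group_table(rng, shift=(1.0, 0.0, 0.0))
        df = df[df["ambulatory"] == 1]  # drop the non-ambulatory class
        res = ws.group_compare(df, metrics=["m0"])
        assert len(res) == 1
        assert len(res[0].pairwise_p) == 1

    def test_all_missing_metric_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        df = three_group_table(rng)
        df["m0"] = np.nan
        with pytest.warns(UserWarning, match="m0"):
            assert ws.group_compare(df, metrics=["m0"]) == []

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        df = three_group_table(rng, shift=(0.8, 0.4, 0.0))
        p1 = ws.group_compare(df, metrics=["m0"])[0].p_value
        df["m0"] = np.exp(df["m0"])
        p2 = ws.group_compare(df, metrics=["m0"])[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestMultiplicityAdjustments:
    def test_hand_computed_three_element_inputs(self):
        p = [0.01, 0.02, 0.04]
        _, holm, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm, [0.03, 0.04, 0.04])
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh, [0.03, 0.03, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 10)
        for method in ("holm", "fdr_bh"):
            _, adj, _, _ = multipletests(p, method=method)
            assert (adj >= p - 1e-15).all()


class TestCorrelationMatrix:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": -(x**3)})
        rho, padj = ws.correlation_matrix(df, ["a", "b", "c"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert (padj.to_numpy() >= 0).all()

    def test_constant_variable_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        rho, _ = ws.correlation_matrix(df, ["a", "b"])
        assert math.isnan(rho.loc["a", "b"])

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValueError, match="3 complete rows"):
            ws.correlation_matrix(df, ["a", "b"])


def longitudinal_table(rng, n_participants=100, true_b=-0.5, re_var=0.1, sigma=0.3):
    """100 participants, 183 wear periods, known log-linear effect."""
    rows = []
    for i in range(n_participants):
        b = rng.normal(0, math.sqrt(re_var))
        visits = 2 if i < 83 else 1
        kind = i % 3  # stays ambulatory / stays non-ambulatory / transitions
        for v in range(1, visits + 1):
            nonamb = 1 if kind == 1 else (1 if (kind == 2 and v == 2) else 0)
            y = math.exp(1.0 + true_b * nonamb + b + rng.normal(0, sigma))
            rows.append(
                dict(
                    participant_id=f"P{i}",
                    visit=v,
                    group="dmd",
                    ambulatory=1 - nonamb,
                    counts_per_minute=y,
                )
            )
    return pd.DataFrame(rows)


class TestLoglinearMixed:
    def test_sign_convention_lower_after_loss_is_negative(self):
        rng = np.random.default_rng(5)
        fits = ws.loglinear_mixed(longitudinal_table(rng), metrics=["counts_per_minute"])
        assert fits[0].fixed_effect_b < 0
        assert fits[0].random_intercept_var >= 0
        assert math.isfinite(fits[0].log_likelihood)
        assert fits[0].n_obs == 183

    def test_nonpositive_rows_excluded_and_counted(self):
        rng = np.random.default_rng(6)
        df = longitudinal_table(rng)
        df.loc[df.index[:5], "counts_per_minute"] = 0.0
        fits = ws.loglinear_mixed(df, metrics=["counts_per_minute"])
        assert fits[0].n_excluded_nonpositive == 5
        assert fits[0].n_obs == 178

    def test_null_effect_confidence_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        reps = 100
        for _ in range(reps):
            df = longitudinal_table(rng, n_participants=40, true_b=0.0)
            fit = ws.loglinear_mixed(df, metrics=["counts_per_minute"])[0]
            covered += fit.fixed_effect_p > 0.05
        assert covered / reps >= 0.90


def classifier_table(rng, n=200, separation=4.0):
    jerk = np.concatenate([rng.normal(1.5, 0.3, n // 2), rng.normal(1.5 - separation * 0.3, 0.3, n - n // 2)])
    mf = np.concatenate([rng.normal(3.2, 0.2, n // 2), rng.normal(3.2 + separation * 0.2, 0.2, n - n // 2)])
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    df = pd.DataFrame(dict(jerk=jerk, mean_freq=mf, ambulatory=y, group="dmd"))
    df["participant_id"] = [f"D{i}" for i in range(n)]
    df["visit"] = 1
    return df


class TestBinaryClassifier:
    def test_perfect_separation_flagged_with_unit_discrimination(self):
        df = pd.DataFrame(
            dict(
                jerk=[2.0, 2.1, 2.2, 0.1, 0.2, 0.3],
                mean_freq=[3.0, 3.1, 3.0, 4.5, 4.4, 4.6],
                ambulatory=[1, 1, 1, 0, 0, 0],
            )
        )
        fit = ws.fit_binary_ambulation(df)
        assert fit.separation_flag
        assert fit.auc == 1.0
        assert fit.accuracy == 1.0

    def test_odds_ratios_are_exp_of_coefficients(self):
        rng = np.random.default_rng(8)
        fit = ws.fit_binary_ambulation(classifier_table(rng, separation=2.0))
        for name, coef in fit.coefficients.items():
            assert fit.odds_ratios[name] == pytest.approx(math.exp(coef), rel=1e-12)

    def test_single_class_rejected(self):
        df = classifier_table(np.random.default_rng(0))
        with pytest.raises(ValueError, match="class"):
            ws.fit_binary_ambulation(df[df["ambulatory"] == 1])

    def test_synthetic_cohort_auc(self, cohort_table):
        dmd = cohort_table[cohort_table["group"] == "dmd"]
        fit = ws.fit_binary_ambulation(dmd)
        assert fit.auc >= 0.85


class TestOrdinalClassifier:
    def _table(self, rng, n=40):
        rows = []
        for cls_i, (group, amb, jmu, fmu) in enumerate(
            [("control", 1, 2.0, 3.0), ("dmd", 1, 1.0, 3.6), ("dmd", 0, 0.3, 4.4)]
        ):
            for i in range(n):
                rows.append(
                    dict(
                        participant_id=f"{cls_i}_{i}",
                        visit=1,
                        group=group,
                        ambulatory=amb,
                        jerk=rng.normal(jmu, 0.25),
                        mean_freq=rng.normal(fmu, 0.2),
                    )
                )
        return pd.DataFrame(rows)

    def test_cumulative_probabilities_monotone_in_predictors(self):
        rng = np.random.default_rng(10)
        fit = ws.fit_ordinal_three_class(self._table(rng))
        # higher jerk pushes toward the healthy end, higher frequency away
        assert fit.coefficients["jerk"] < 0 or fit.coefficients["mean_freq"] > 0
        assert set(fit.per_class_auc) == set(ws.CLASS_ORDER)
        assert all(0.5 <= v <= 1.0 for v in fit.per_class_auc.values())

    def test_collapsing_classes_matches_binary_direction(self):
        rng = np.random.default_rng(11)
        df = self._table(rng)
        ordinal = ws.fit_ordinal_three_class(df)
        binary = ws.fit_binary_ambulation(df[df["group"] == "dmd"])
        # ordinal slopes are on severity, binary on P(ambulatory): opposite signs
        assert np.sign(ordinal.coefficients["jerk"]) == -np.sign(
            binary.coefficients["jerk"]
        )

    def test_missing_class_named_in_error(self):
        rng = np.random.default_rng(12)
        df = self._table(rng)
        with pytest.raises(ValueError, match="dmd_non_ambulatory"):
            ws.fit_ordinal_three_class(df[df["ambulatory"] == 1])

    def test_healthy_discrimination_exceeds_nonambulatory(self, cohort_table):
        fit = ws.fit_ordinal_three_class(cohort_table)
        assert (
            fit.per_class_auc["healthy_control"]
            >= fit.per_class_auc["dmd_non_ambulatory"] - 0.05
        )


class TestBootstrapAndExternal:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(13)
        df = classifier_table(rng, n=60, separation=1.5)
        fit = ws.fit_binary_ambulation(df)
        a = ws.bootstrap_validate(fit, df, n_resamples=100, seed=3)
        b = ws.bootstrap_validate(fit, df, n_resamples=100, seed=3)
        assert a.corrected_auc == b.corrected_auc
        assert a.corrected_accuracy == b.corrected_accuracy

    def test_overfit_scenario_correction_shrinks_auc(self):
        rng = np.random.default_rng(14)
        df = classifier_table(rng, n=30, separation=0.4)  # weak signal, small n
        fit = ws.fit_binary_ambulation(df)
        out = ws.bootstrap_validate(fit, df, n_resamples=200, seed=1)
        assert out.corrected_auc < fit.auc

    def test_external_identical_table_matches_training_accuracy(self):
        rng = np.random.default_rng(15)
        df = classifier_table(rng, n=80, separation=2.0)
        fit = ws.fit_binary_ambulation(df)
        acc, preds = ws.external_validate(fit, df)
        assert acc == pytest.approx(fit.accuracy)
        assert preds["misclassified"].sum() == round((1 - acc) * len(df))

    def test_missing_predictor_column_rejected(self):
        rng = np.random.default_rng(16)
        df = classifier_table(rng)
        fit = ws.fit_binary_ambulation(df)
        with pytest.raises(ValueError, match="mean_freq"):
            ws.external_validate(fit, df.drop(columns=["mean_freq"]))


class TestAnalyzeReports:
    def test_full_report_bundle(self, cohort_table):
        res = ws.analyze_reports(cohort_table, seed=1, n_resamples=50)
        assert len(res["group_comparison"]) == 10
        assert res["correlations_rho"].shape == (4, 4)
        assert "binary" in res["classifiers"]
        assert "seed=1" in res["run_log"]
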