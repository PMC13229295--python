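"""Cross-sectional, correlational, longitudinal and predictive statistics.

Operates on a *cohort table*: one row per wear period carrying the ten
movement metrics plus ``participant_id``, ``visit``, ``group``
(control/dmd) and ``ambulatory`` (0/1) labels.  The three analysis classes
are healthy controls, ambulatory DMD and non-ambulatory DMD; cross-sectional
analyses restrict DMD rows to the baseline (first) visit, longitudinal
models use all wear periods.

Implements:

* Kruskal–Wallis omnibus tests per metric with pairwise rank-sum follow-ups
  and Benjamini–Hochberg false-discovery-rate adjustment across metrics;
* Spearman correlation matrices with Holm adjustment of the unique
  off-diagonal p-values;
* log-linear mixed-effects models (random participant intercept, maximum
  likelihood) of each metric on non-ambulatory status;
* a binary logistic classifier of ambulatory status on jerk and mean
  frequency, a proportional-odds ordinal model over the three classes,
  bootstrap optimism correction of discrimination indices, and frozen-
  coefficient external validation.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning
import statsmodels.api as sm

from .metrics import METRIC_COLUMNS

__all__ = [
    "CLASS_ORDER",
    "GroupTestResult",
    "ModelFit",
    "ClassifierFit",
    "attach_class",
    "baseline_table",
    "group_compare",
    "correlation_matrix",
    "loglinear_mixed",
    "fit_binary_ambulation",
    "fit_ordinal_three_class",
    "bootstrap_validate",
    "external_validate",
]

CLASS_ORDER = ["healthy_control", "dmd_ambulatory", "dmd_non_ambulatory"]

#: Predictors of the ambulatory-status classifiers.
CLASSIFIER_PREDICTORS = ["jerk", "mean_freq"]

#: The four primary correlation variables.
PRIMARY_CORR_VARS = ["counts_per_minute", "entropy", "jerk", "mean_freq"]


def attach_class(table: pd.DataFrame) -> pd.DataFrame:
    """Add a 3-level ``cls`` column derived from group and ambulatory labels."""
    out = table.copy()
    cls = np.where(
        out["group"] == "control",
        "healthy_control",
        np.where(out["ambulatory"] == 1, "dmd_ambulatory", "dmd_non_ambulatory"),
    )
    out["cls"] = pd.Categorical(cls, categories=CLASS_ORDER, ordered=True)
    return out


def baseline_table(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict DMD rows to each participant's first observed visit."""
    dmd = table[table["group"] == "dmd"]
    first = dmd.sort_values("visit").groupby("participant_id", sort=False).head(1)
    return pd.concat([table[table["group"] == "control"], first], ignore_index=True)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupTestResult:
    """Per-metric three-class comparison summary."""

    metric: str
    medians: dict[str, float]
    iqrs: dict[str, tuple[float, float]]
    statistic: float
    p_value: float
    q_value: float = math.nan
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def group_compare(table: pd.DataFrame, metrics: list[str] | None = None) -> list[GroupTestResult]:
    """Kruskal–Wallis omnibus per metric across classes, with BH adjustment.

    Requires at least two classes with ≥ 2 observations each.  With exactly
    two classes the omnibus degrades to the pairwise rank-sum test.  Metrics
    with all-missing values are skipped with a warning.
    """
    metrics = metrics if metrics is not None else METRIC_COLUMNS
    tab = attach_class(table) if "cls" not in table.columns else table
    results: list[GroupTestResult] = []
    for metric in metrics:
        groups = {}
        for cls_name, sub in tab.groupby("cls", observed=True):
            vals = sub[metric].dropna().to_numpy()
            if vals.size >= 2:
                groups[str(cls_name)] = vals
        if len(groups) < 2:
            warnings.warn(f"metric {metric!r}: fewer than two usable classes; skipped")
            continue
        samples = list(groups.values())
        if len(samples) == 2:
            stat, p = sps.mannwhitneyu(*samples, alternative="two-sided")
        else:
            stat, p = sps.kruskal(*samples)
        pairwise = {}
        names = list(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                _, pp = sps.mannwhitneyu(
                    groups[names[i]], groups[names[j]], alternative="two-sided"
                )
                pairwise[(names[i], names[j])] = float(pp)
        results.append(
            GroupTestResult(
                metric=metric,
                medians={k: float(np.median(v)) for k, v in groups.items()},
                iqrs={
                    k: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
                    for k, v in groups.items()
                },
                statistic=float(stat),
                p_value=float(p),
                pairwise_p=pairwise,
            )
        )
    if results:
        _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return results


def group_compare_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten group-comparison results into a report table."""
    rows = []
    for r in results:
        row: dict[str, float | str] = {"metric": r.metric}
        for cls_name in CLASS_ORDER:
            if cls_name in r.medians:
                lo, hi = r.iqrs[cls_name]
                row[f"{cls_name}_median"] = r.medians[cls_name]
                row[f"{cls_name}_q1"] = lo
                row[f"{cls_name}_q3"] = hi
        row["statistic"] = r.statistic
        row["p_value"] = r.p_value
        row["q_value"] = r.q_value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations


def correlation_matrix(
    table: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations with Holm-adjusted p-values.

    Returns ``(rho, p_adjusted)`` DataFrames over ``variables`` (default:
    the four primary quantity/quality variables).  The diagonal of ``rho``
    is unity; constant variables yield NaN entries.
    """
    variables = variables if variables is not None else PRIMARY_CORR_VARS
    data = table[variables].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    k = len(variables)
    rho = np.eye(k)
    praw = np.zeros((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data[variables[i]], data[variables[j]]
            if x.nunique() <= 1 or y.nunique() <= 1:
                r, p = math.nan, math.nan
            else:
                r, p = sps.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            praw[i, j] = praw[j, i] = p
            pairs.append((i, j, p))
    finite = [(i, j, p) for i, j, p in pairs if not math.isnan(p)]
    padj = np.full((k, k), math.nan)
    if finite:
        _, adj, _, _ = multipletests([p for _, _, p in finite], method="holm")
        for (i, j, _), a in zip(finite, adj):
            padj[i, j] = padj[j, i] = a
    np.fill_diagonal(padj, 0.0)
    return (
        pd.DataFrame(rho, index=variables, columns=variables),
        pd.DataFrame(padj, index=variables, columns=variables),
    )


# ---------------------------------------------------------------------------
# longitudinal mixed models


@dataclass
class ModelFit:
    """Summary of one log-linear mixed-effects model."""

    metric: str
    fixed_effect_b: float  # slope of non-ambulatory status on log(metric)
    fixed_effect_p: float
    random_intercept_var: float
    log_likelihood: float
    n_obs: int
    n_excluded_nonpositive: int


def loglinear_mixed(
    table: pd.DataFrame, metrics: list[str] | None = None
) -> list[ModelFit]:
    """Fit ``log(metric) ~ non_ambulatory + (1 | participant)`` per metric.

    Maximum-likelihood (not REML) fits so log-likelihoods are comparable
    across fixed-effect specifications.  The fixed-effect slope is on a
    non-ambulatory indicator, so a metric that is *lower* after loss of
    ambulation gets a negative B.  Rows with non-positive metric values are
    excluded (count reported).
    """
    metrics = metrics if metrics is not None else METRIC_COLUMNS
    fits: list[ModelFit] = []
    for metric in metrics:
        sub = table[["participant_id", "ambulatory", metric]].dropna()
        n_bad = int((sub[metric] <= 0).sum())
        sub = sub[sub[metric] > 0]
        if sub["participant_id"].nunique() < 2 or sub["ambulatory"].nunique() < 2:
            continue
        endog = np.log(sub[metric].to_numpy())
        exog = sm.add_constant((1 - sub["ambulatory"].to_numpy()).astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = MixedLM(endog, exog, groups=sub["participant_id"].to_numpy())
            res = model.fit(reml=False)
        fits.append(
            ModelFit(
                metric=metric,
                fixed_effect_b=float(res.fe_params[1]),
                fixed_effect_p=float(res.pvalues[1]),
                random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
                log_likelihood=float(res.llf),
                n_obs=len(sub),
                n_excluded_nonpositive=n_bad,
            )
        )
    return fits


def mixed_model_frame(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": f.metric,
                "fixed_effect_B": f.fixed_effect_b,
                "p_value": f.fixed_effect_p,
                "random_intercept_s2": f.random_intercept_var,
                "log_likelihood": f.log_likelihood,
                "n_obs": f.n_obs,
                "n_excluded_nonpositive": f.n_excluded_nonpositive,
            }
            for f in fits
        ]
    )


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierFit:
    """Fitted ambulatory-status classifier summary."""

    kind: str  # "binary" | "ordinal"
    predictors: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    auc: float
    accuracy: float
    separation_flag: bool = False
    corrected_auc: float = math.nan
    corrected_accuracy: float = math.nan
    n_resamples: int = 0
    per_class_auc: dict[str, float] = field(default_factory=dict)


def _logit_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """MLE logistic coefficients [intercept, slopes...]; flags separation."""
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=False, maxiter=200)
            params = np.asarray(res.params)
            separated = bool(np.abs(params).max() > 1e3) or not np.isfinite(
                params
            ).all()
        except Exception:
            params, separated = None, True
    if params is None or separated:
        # ridge-regularized fallback keeps coefficients finite under
        # complete separation; flagged so reports can say so
        res = sm.Logit(y, exog).fit_regularized(
            disp=False, alpha=0.01, L1_wt=0.0, maxiter=500
        )
        params = np.asarray(res.params)
        separated = True
    return params, separated


def _predict_proba(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    eta = params[0] + x @ params[1:]
    return 1.0 / (1.0 + np.exp(-eta))


def fit_binary_ambulation(
    table: pd.DataFrame, predictors: list[str] | None = None
) -> ClassifierFit:
    """Logistic regression of ambulatory (1) vs non-ambulatory (0) DMD rows.

    Default predictors are jerk and mean frequency.  Reports coefficients,
    per-unit odds ratios, AUC, and accuracy at the 0.5 probability
    threshold.  Complete separation triggers a flagged ridge fallback.
    """
    predictors = predictors if predictors is not None else CLASSIFIER_PREDICTORS
    data = table.dropna(subset=predictors + ["ambulatory"])
    y = data["ambulatory"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both ambulatory classes must be present")
    x = data[predictors].to_numpy(dtype=float)
    params, separated = _logit_fit(x, y)
    proba = _predict_proba(params, x)
    names = ["intercept"] + list(predictors)
    return ClassifierFit(
        kind="binary",
        predictors=list(predictors),
        coefficients=dict(zip(names, params.tolist())),
        odds_ratios={n: float(np.exp(c)) for n, c in zip(names, params.tolist())},
        auc=float(roc_auc_score(y, proba)),
        accuracy=float(((proba >= 0.5) == (y == 1)).mean()),
        separation_flag=separated,
    )


def fit_ordinal_three_class(
    table: pd.DataFrame, predictors: list[str] | None = None
) -> ClassifierFit:
    """Proportional-odds model across the three ordered severity classes.

    Class order (increasing severity): healthy control < ambulatory DMD <
    non-ambulatory DMD.  Reports one-vs-rest AUCs per class and overall
    accuracy of the modal predicted class.
    """
    predictors = predictors if predictors is not None else CLASSIFIER_PREDICTORS
    tab = attach_class(table) if "cls" not in table.columns else table
    data = tab.dropna(subset=predictors + ["cls"])
    present = set(data["cls"].astype(str))
    missing = [c for c in CLASS_ORDER if c not in present]
    if missing:
        raise ValueError(f"ordinal model requires all three classes; missing {missing}")
    y = data["cls"].cat.codes.to_numpy()
    x = data[predictors].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, x, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    k = x.shape[1]
    slopes = np.asarray(res.params[:k])
    probs = res.model.predict(res.params, exog=x)
    pred = probs.argmax(axis=1)
    per_class = {}
    for code, cls_name in enumerate(CLASS_ORDER):
        per_class[cls_name] = float(roc_auc_score((y == code).astype(int), probs[:, code]))
    names = list(predictors)
    return ClassifierFit(
        kind="ordinal",
        predictors=names,
        coefficients=dict(zip(names, slopes.tolist())),
        odds_ratios={n: float(np.exp(c)) for n, c in zip(names, slopes.tolist())},
        auc=float(np.mean(list(per_class.values()))),
        accuracy=float((pred == y).mean()),
        per_class_auc=per_class,
    )


# ---------------------------------------------------------------------------
# validation


def bootstrap_validate(
    fit: ClassifierFit,
    table: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
) -> ClassifierFit:
    """Optimism-corrected AUC and accuracy by the bootstrap refit loop.

    Per resample: refit on a with-replacement resample, evaluate on both the
    resample and the original table; optimism is the mean excess of the
    former over the latter, subtracted from the apparent index.  Degenerate
    resamples (a single class) are redrawn; their count is recorded on the
    returned fit as ``n_redrawn``.
    """
    predictors = fit.predictors
    data = table.dropna(subset=predictors + ["ambulatory"]).reset_index(drop=True)
    y = data["ambulatory"].to_numpy(dtype=float)
    x = data[predictors].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(data)
    opt_auc, opt_acc = [], []
    n_redrawn = 0
    while len(opt_auc) < n_resamples:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            n_redrawn += 1
            continue
        xb = x[idx]
        params, _ = _logit_fit(xb, yb)
        pb = _predict_proba(params, xb)
        po = _predict_proba(params, x)
        opt_auc.append(roc_auc_score(yb, pb) - roc_auc_score(y, po))
        opt_acc.append(
            ((pb >= 0.5) == (yb == 1)).mean() - ((po >= 0.5) == (y == 1)).mean()
        )
    out = dataclasses.replace(fit)
    out.corrected_auc = fit.auc - float(np.mean(opt_auc))
    out.corrected_accuracy = fit.accuracy - float(np.mean(opt_acc))
    out.n_resamples = n_resamples
    out.__dict__["n_redrawn"] = n_redrawn
    return out


def analyze_reports(
    table: pd.DataFrame,
    seed: int = 0,
    n_resamples: int = 1000,
    baseline_only: bool = True,
) -> dict:
    """Run every statistics stage on a metric table; return report frames.

    Cross-sectional stages (group comparison, correlations, classifiers)
    use the baseline-restricted table when ``baseline_only``; the mixed
    models always use all DMD wear periods.
    """
    tab = attach_class(table)
    cross = baseline_table(tab) if baseline_only else tab
    results: dict = {}
    results["group_comparison"] = group_compare_frame(group_compare(cross))
    rho, padj = correlation_matrix(cross, PRIMARY_CORR_VARS)
    results["correlations_rho"] = rho
    results["correlations_p"] = padj
    full_vars = [
        "counts_per_minute",
        "total_counts",
        "counts_per_day",
        "median_accel",
        "sd_accel",
        "peak_accel",
        "entropy",
        "jerk",
        "mean_freq",
        "sd_freq",
    ]
    full_rho, _ = correlation_matrix(cross, full_vars)
    results["correlations_full_rho"] = full_rho

    dmd_all = attach_class(table[table["group"] == "dmd"])
    results["mixed_models"] = mixed_model_frame(loglinear_mixed(dmd_all))

    dmd_baseline = baseline_table(dmd_all) if baseline_only else dmd_all
    classifiers: dict = {}
    if dmd_baseline["ambulatory"].nunique() == 2:
        binary = fit_binary_ambulation(dmd_baseline)
        binary = bootstrap_validate(binary, dmd_baseline, n_resamples=n_resamples, seed=seed)
        classifiers["binary"] = {
            "coefficients": binary.coefficients,
            "odds_ratios": binary.odds_ratios,
            "auc": binary.auc,
            "accuracy": binary.accuracy,
            "corrected_auc": binary.corrected_auc,
            "corrected_accuracy": binary.corrected_accuracy,
            "n_resamples": binary.n_resamples,
            "separation_flag": binary.separation_flag,
        }
    try:
        ordinal = fit_ordinal_three_class(cross)
        classifiers["ordinal"] = {
            "coefficients": ordinal.coefficients,
            "odds_ratios": ordinal.odds_ratios,
            "per_class_auc": ordinal.per_class_auc,
            "accuracy": ordinal.accuracy,
        }
    except ValueError as exc:
        classifiers["ordinal"] = {"error": str(exc)}
    results["classifiers"] = classifiers
    results["run_log"] = (
        f"seed={seed}\nn_resamples={n_resamples}\nbaseline_only={baseline_only}\n"
        f"n_rows={len(table)}\nn_participants={table['participant_id'].nunique()}\n"
        f"n_cross_sectional={len(cross)}\nn_dmd_wears={len(dmd_all)}\n"
    )
    return results


def external_validate(
    fit: ClassifierFit, external: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Apply frozen binary-model coefficients to an external cohort.

    Returns overall accuracy and a per-row frame with predicted
    probabilities, predicted classes and a misclassification flag.
    """
    missing = [p for p in fit.predictors if p not in external.columns]
    if missing:
        raise ValueError(f"external table missing predictor columns {missing}")
    data = external.dropna(subset=fit.predictors + ["ambulatory"]).copy()
    params = np.array(
        [fit.coefficients["intercept"]]
        + [fit.coefficients[p] for p in fit.predictors]
    )
    proba = _predict_proba(params, data[fit.predictors].to_numpy(dtype=float))
    pred = (proba >= 0.5).astype(int)
    data["p_ambulatory"] = proba
    data["predicted"] = pred
    data["misclassified"] = pred != data["ambulatory"].astype(int)
    accuracy = float((~data["misclassified"]).mean())
    return accuracy, data
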