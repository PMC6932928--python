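"""Performance reporting: confusion matrices, micro-average ROC, survival analysis.

Conventions follow the reporting layout this workflow uses: confusion
matrices are hypothesized class (rows) by true class (columns) with
per-class accuracy defined as the correctly classified
fraction of each true-class column; percentages are rounded half-up to two
decimals; the exact 95% CI on overall accuracy is Clopper-Pearson. The
multiclass ROC pools all (sample, class) one-vs-all decisions into a single
binary problem (micro-averaging). Survival reporting covers Kaplan-Meier
curves with the k-group log-rank test, univariate/multivariate Cox tables,
the Kaplan-Meier-based cumulative-case/dynamic-control time-dependent AUC,
and the four-level risk stratification (risk group x early/advanced stage)
with an ordinal trend test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ValidationError
from .prognostic import CoxResult, encode_clinical, fit_cox


def round2(x: float) -> float:
    """Round half-up to two decimals (as printed percentages are)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# classification


@dataclass
class ConfusionSummary:
    """K x K confusion counts with per-class and overall accuracy.

    ``counts`` has hypothesized (predicted) classes as rows and true classes
    as columns; per-class accuracy is diagonal / column total, overall
    accuracy trace / total, both in percent rounded half-up to two decimals.
    ``ci`` is the exact Clopper-Pearson 95% interval on overall accuracy.
    """

    counts: pd.DataFrame
    per_class_accuracy: pd.Series
    overall_accuracy: float
    ci: tuple[float, float]
    n: int
    n_correct: int

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ConfusionSummary":
        counts = counts.astype(int)
        if list(counts.index) != list(counts.columns):
            raise ValidationError("count matrix must be square with matching labels")
        col_tot = counts.sum(axis=0)
        if (col_tot == 0).any():
            raise ValidationError("every true class needs at least one sample")
        diag = pd.Series(np.diag(counts.to_numpy()), index=counts.columns)
        per_class = (100.0 * diag / col_tot).map(round2)
        n = int(counts.to_numpy().sum())
        n_correct = int(diag.sum())
        lo, hi = proportion_confint(n_correct, n, alpha=0.05, method="beta")
        return cls(
            counts=counts,
            per_class_accuracy=per_class,
            overall_accuracy=round2(100.0 * n_correct / n),
            ci=(round2(100.0 * lo), round2(100.0 * hi)),
            n=n,
            n_correct=n_correct,
        )

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, labels=None) -> "ConfusionSummary":
        true_labels = pd.Series(list(true_labels))
        predicted_labels = pd.Series(list(predicted_labels))
        if len(true_labels) != len(predicted_labels):
            raise ValidationError("label vectors must have equal length")
        if labels is None:
            labels = sorted(set(true_labels))
        labels = list(labels)
        outside = set(true_labels) | set(predicted_labels)
        outside -= set(labels)
        if outside:
            raise ValidationError(f"labels outside the class set: {sorted(outside)}")
        counts = pd.crosstab(predicted_labels, true_labels).reindex(
            index=labels, columns=labels, fill_value=0
        )
        counts.index.name = "hypothesized"
        counts.columns.name = "true"
        return cls.from_counts(counts)


def confusion_summary(true_labels, predicted_labels, labels=None) -> ConfusionSummary:
    return ConfusionSummary.from_labels(true_labels, predicted_labels, labels)


@dataclass
class MicroAverageROC:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def micro_average_auc(true_labels, probabilities: pd.DataFrame) -> MicroAverageROC:
    """One-vs-all micro-average ROC/AUC.

    Every (sample, class) pair becomes one binary instance: indicator of the
    true class against the predicted probability for that class. The AUC is
    the rank (Mann-Whitney) statistic of the pooled instances with ties
    counted one half.
    """
    true_labels = pd.Series(list(true_labels))
    if true_labels.nunique() < 2:
        raise ValidationError("micro-average ROC needs at least two observed classes")
    probs = probabilities.to_numpy(dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")
    indicator = np.zeros_like(probs)
    cols = {c: j for j, c in enumerate(probabilities.columns)}
    for i, lab in enumerate(true_labels):
        indicator[i, cols[lab]] = 1.0
    y = indicator.ravel()
    s = probs.ravel()
    fpr, tpr, thr = roc_curve(y, s)
    return MicroAverageROC(auc=float(roc_auc_score(y, s)), fpr=fpr, tpr=tpr, thresholds=thr)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurves:
    """Kaplan-Meier step functions per group plus the k-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk
    statistic: float
    p: float
    df: int


def km_logrank(times, events, groups) -> SurvivalCurves:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(list(groups))
    curves: dict[str, pd.DataFrame] = {}
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    if groups.nunique() < 2:
        return SurvivalCurves(curves=curves, statistic=0.0, p=1.0, df=0)
    res = multivariate_logrank_test(times, groups.to_numpy(), events)
    return SurvivalCurves(
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=int(groups.nunique() - 1),
    )


def _km_survival_at(times, events, t: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.predict(t))


def time_dependent_auc(risk_scores, times, events, horizon: float) -> float:
    """Cumulative-case/dynamic-control AUC at a fixed horizon.

    Kaplan-Meier-based estimator: for each cutoff c,

        sensitivity(c, t) = (1 - S(t | X > c)) P(X > c) / (1 - S(t))
        specificity(c, t) = S(t | X <= c) P(X <= c) / S(t)

    with subgroup survival estimated by Kaplan-Meier; the curve is swept
    over all observed cutoffs and integrated by the trapezoid rule. Returns
    NaN when the overall survival at the horizon is exactly 0 or 1 (the
    case or control population is empty).
    """
    scores = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s_t = _km_survival_at(times, events, horizon)
    if s_t <= 0.0 or s_t >= 1.0:
        return float("nan")

    points = [(1.0, 1.0)]  # cutoff below min: everyone called positive
    for c in np.unique(scores):
        high = scores > c
        low = ~high
        if high.any():
            s_high = _km_survival_at(times[high], events[high], horizon)
            sens = (1.0 - s_high) * high.mean() / (1.0 - s_t)
        else:
            sens = 0.0
        if low.any():
            s_low = _km_survival_at(times[low], events[low], horizon)
            spec = s_low * low.mean() / s_t
        else:
            spec = 0.0
        sens = min(max(sens, 0.0), 1.0)
        spec = min(max(spec, 0.0), 1.0)
        points.append((1.0 - spec, sens))
    points.append((0.0, 0.0))  # cutoff above max: everyone called negative
    # points run from permissive to strict cutoffs; keep that (monotone)
    # ordering rather than re-sorting, which scrambles float-tied FPRs
    pts = np.array(points[::-1])
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def cox_table(
    factors: pd.DataFrame,
    times,
    events,
) -> pd.DataFrame:
    """Univariate and multivariate Cox regression table.

    One univariate fit per factor column and one joint multivariate fit;
    rows are factors, columns the HR, 95% CI and Wald p of each analysis.
    Duplicated (rank-deficient) factor columns are rejected.
    """
    df = factors.copy()
    X = df.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.hstack([X, np.ones((len(X), 1))])) < X.shape[1] + 1:
        raise ValidationError("factor matrix is rank deficient (duplicated factor?)")
    df["os_time"] = np.asarray(times, dtype=float)
    df["os_event"] = np.asarray(events, dtype=int)

    rows = {}
    for col in factors.columns:
        uni = fit_cox(df[["os_time", "os_event", col]], covariates=[col])
        rows[col] = {
            "hr_uni": uni.table.loc[col, "hr"],
            "ci_lower_uni": uni.table.loc[col, "ci_lower"],
            "ci_upper_uni": uni.table.loc[col, "ci_upper"],
            "p_uni": uni.table.loc[col, "p"],
        }
    multi = fit_cox(df, covariates=list(factors.columns))
    for col in factors.columns:
        rows[col].update(
            {
                "hr_multi": multi.table.loc[col, "hr"],
                "ci_lower_multi": multi.table.loc[col, "ci_lower"],
                "ci_upper_multi": multi.table.loc[col, "ci_upper"],
                "p_multi": multi.table.loc[col, "p"],
            }
        )
    out = pd.DataFrame(rows).T
    out.index.name = "risk_factor"
    return out


# ---------------------------------------------------------------------------
# risk stratification


LEVELS = ("G1", "G2", "G3", "G4")


@dataclass
class RiskStratification:
    """Four-level stratification from risk group x early/advanced stage.

    G1 = low risk & stage I/II, G2 = low & III/IV, G3 = high & I/II,
    G4 = high & III/IV. ``hr_table`` gives the adjusted HR of each level
    vs G1 (NaN for empty levels); ``trend_p`` is the Wald p of the ordinal
    0-3 level coding in the adjusted Cox model.
    """

    levels: pd.Series
    hr_table: pd.DataFrame
    trend_p: float
    logrank: SurvivalCurves


def assign_risk_levels(risk_groups: pd.Series, stages: pd.Series) -> pd.Series:
    advanced = stages.map({"I": False, "II": False, "III": True, "IV": True})
    if advanced.isna().any():
        bad = stages[advanced.isna()].unique().tolist()
        raise ValidationError(f"unknown or missing stages: {bad}")
    high = pd.Series(risk_groups) == "high"
    lvl = np.where(
        ~high & ~advanced, "G1", np.where(~high & advanced, "G2",
                                          np.where(high & ~advanced, "G3", "G4"))
    )
    return pd.Series(lvl, index=risk_groups.index, name="risk_level")


def risk_stratify(
    risk_groups: pd.Series,
    annotation: pd.DataFrame,
) -> RiskStratification:
    """Stratify by risk group and stage; adjusted Cox per level plus trend test.

    The adjustment set is age, gender, BMI, smoking and alcohol use (stage
    is part of the level coding and therefore not adjusted for).
    """
    ann = annotation.loc[risk_groups.index]
    levels = assign_risk_levels(risk_groups, ann["ajcc_stage"])
    clinical = encode_clinical(ann, include_stage=False)
    times = pd.to_numeric(ann["os_time"], errors="coerce")
    events = pd.to_numeric(ann["os_event"], errors="coerce")

    df = clinical.copy()
    present = [lv for lv in LEVELS[1:] if (levels == lv).any()]
    for lv in present:
        df[lv] = (levels == lv).astype(float)
    df["os_time"] = times
    df["os_event"] = events
    df = df.dropna()

    hr_rows = {}
    if present and (levels == "G1").any():
        res = fit_cox(df, covariates=list(clinical.columns) + present)
        for lv in LEVELS[1:]:
            if lv in present:
                hr_rows[lv] = res.table.loc[lv, ["hr", "ci_lower", "ci_upper", "p"]].to_dict()
            else:
                hr_rows[lv] = {"hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan}
    else:
        for lv in LEVELS[1:]:
            hr_rows[lv] = {"hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan}
    hr_table = pd.DataFrame(hr_rows).T
    hr_table.index.name = "level_vs_G1"

    # ordinal trend: Wald test of the 0-3 coding in the adjusted model
    df_trend = clinical.copy()
    df_trend["level_ordinal"] = levels.map({lv: i for i, lv in enumerate(LEVELS)}).astype(float)
    df_trend["os_time"] = times
    df_trend["os_event"] = events
    df_trend = df_trend.dropna()
    if df_trend["level_ordinal"].nunique() > 1:
        trend = fit_cox(df_trend, covariates=list(clinical.columns) + ["level_ordinal"])
        trend_p = float(trend.table.loc["level_ordinal", "p"])
    else:
        trend_p = float("nan")

    lr = km_logrank(
        times.loc[levels.index].to_numpy(),
        events.loc[levels.index].to_numpy(dtype=int),
        levels,
    )
    return RiskStratification(levels=levels, hr_table=hr_table, trend_p=trend_p, logrank=lr)
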