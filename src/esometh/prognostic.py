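"""Prognostic risk scoring for esophageal carcinoma from methylation markers.

Pipeline per histology: differentially methylated CpGs (tumor vs normal)
are screened one at a time in a Cox proportional-hazards model adjusted for
age, gender, BMI, smoking, alcohol use and AJCC stage; CpGs whose adjusted
Wald p-value is below 0.05 are candidates for an L1-penalized (lasso) Cox
model. Stability of the lasso selection is assessed over 100 replicates of
subsampling 75% of the patients without replacement, tuning the penalty by
5-fold cross-validated partial-likelihood deviance with the
one-standard-error rule; CpGs selected in strictly more than 30 replicates
form the panel. The final risk score is the linear predictor of an
unpenalized multivariable Cox model refit on the panel, and patients are
split into high- and low-risk groups at the median score (ties at the
median go to the low-risk group).

Unpenalized Cox models use Efron's approximation for tied event times (via
lifelines); the penalized path is solved by the elastic-net coordinate
descent of scikit-survival with the mixing parameter fixed at pure lasso.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.exceptions import ConvergenceWarning as LifelinesConvergenceWarning
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .diagnostic import StabilitySelection
from .exceptions import StratificationError, ValidationError

ADJUSTMENT_COVARIATES = [
    "age",
    "gender_male",
    "bmi",
    "smoking_yes",
    "alcohol_yes",
    "stage_advanced",
]


def encode_clinical(annotation: pd.DataFrame, *, include_stage: bool = True) -> pd.DataFrame:
    """Numeric design columns from the sample-sheet clinical fields.

    gender/smoking/alcohol become 0/1 indicators; AJCC stage becomes the
    advanced-stage indicator (III/IV vs I/II). Rows with missing fields are
    kept as NaN for the caller to exclude and report.
    """
    out = pd.DataFrame(index=annotation.index)
    out["age"] = pd.to_numeric(annotation["age"], errors="coerce")
    out["gender_male"] = annotation["gender"].map({"male": 1.0, "female": 0.0})
    out["bmi"] = pd.to_numeric(annotation["bmi"], errors="coerce")
    out["smoking_yes"] = annotation["smoking"].map({"yes": 1.0, "no": 0.0})
    out["alcohol_yes"] = annotation["alcohol"].map({"yes": 1.0, "no": 0.0})
    if include_stage:
        out["stage_advanced"] = annotation["ajcc_stage"].map(
            {"I": 0.0, "II": 0.0, "III": 1.0, "IV": 1.0}
        )
    return out


@dataclass
class CoxResult:
    """Tidy Cox fit: per-covariate coefficient, HR, 95% CI, Wald p.

    ``table`` is indexed by covariate with columns ``coef``, ``hr``,
    ``ci_lower``, ``ci_upper``, ``p``.
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True


def fit_cox(
    df: pd.DataFrame,
    duration_col: str = "os_time",
    event_col: str = "os_event",
    covariates: list[str] | None = None,
    *,
    robust_fallback_penalizer: float = 0.1,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald inference.

    Requires at least one event and no constant covariate. When the partial
    likelihood is monotone (no finite MLE, e.g. perfect separation) the fit
    is retried with a small ridge penalizer and flagged via
    ``converged=False`` with a warning.
    """
    if covariates is None:
        covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col, *covariates]].dropna()
    if data[event_col].sum() < 1:
        raise ValidationError("need at least one event")
    const = [c for c in covariates if data[c].nunique() <= 1]
    if const:
        raise ValidationError(f"constant covariates: {const}")

    def _fit(penalizer: float) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(data, duration_col=duration_col, event_col=event_col)
        return cph

    converged = True
    try:
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            cph = _fit(0.0)
        if any(issubclass(w.category, LifelinesConvergenceWarning) for w in rec):
            raise ConvergenceError("lifelines reported convergence trouble")
        if not np.all(np.isfinite(cph.params_)) or np.abs(cph.params_).max() > 50:
            raise ConvergenceError("implausibly large coefficient")
    except (ConvergenceError, np.linalg.LinAlgError):
        warnings.warn(
            "monotone or ill-conditioned partial likelihood; "
            f"refit with ridge penalizer {robust_fallback_penalizer}",
            stacklevel=2,
        )
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = _fit(robust_fallback_penalizer)

    s = cph.summary
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        converged=converged,
    )


def independent_prognostic_filter(
    dmcs,
    betas: pd.DataFrame,
    annotation: pd.DataFrame,
    *,
    p_threshold: float = 0.05,
    return_table: bool = False,
):
    """Keep DMCs whose covariate-adjusted Cox Wald p is below the threshold.

    Each candidate CpG is fit in its own Cox model together with age,
    gender, BMI, smoking, alcohol use and advanced stage; the Wald p of the
    CpG term decides retention. Samples with missing clinical fields are
    excluded per fit (counts reported in the optional table).
    """
    dmcs = [g for g in dmcs]
    clinical = encode_clinical(annotation)
    base = pd.concat(
        [annotation[["os_time", "os_event"]].apply(pd.to_numeric, errors="coerce"), clinical],
        axis=1,
    )
    rows = []
    kept: list[str] = []
    for g in dmcs:
        df = base.copy()
        df["cpg"] = betas.loc[g, df.index].to_numpy(dtype=float)
        complete = df.dropna()
        res = fit_cox(
            complete, covariates=["cpg", *ADJUSTMENT_COVARIATES]
        )
        p = float(res.table.loc["cpg", "p"])
        rows.append(
            {
                "cpg_id": g,
                "coef": float(res.table.loc["cpg", "coef"]),
                "hr": float(res.table.loc["cpg", "hr"]),
                "p": p,
                "n_used": res.n,
                "n_excluded": len(df) - res.n,
            }
        )
        if p < p_threshold:
            kept.append(g)
    if return_table:
        return kept, pd.DataFrame(rows).set_index("cpg_id")
    return kept


# ---------------------------------------------------------------------------
# penalized Cox stability selection


def cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                       beta: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector.

    Used to score held-out folds along the penalty path.
    """
    lp = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp_o = lp[order]
    t_o = time[order]
    e_o = event[order]
    # running logsumexp over the risk set (all with time >= t)
    log_risk = np.empty(len(lp_o))
    run_max = -np.inf
    run_sum = 0.0
    for i in range(len(lp_o)):
        if lp_o[i] > run_max:
            run_sum = run_sum * np.exp(run_max - lp_o[i]) + 1.0
            run_max = lp_o[i]
        else:
            run_sum += np.exp(lp_o[i] - run_max)
        log_risk[i] = run_max + np.log(run_sum)
    # ties: all subjects with identical time share the same risk set
    for i in range(len(t_o) - 1, 0, -1):
        if t_o[i - 1] == t_o[i]:
            log_risk[i - 1] = log_risk[i]
    ll = float(np.sum(e_o * (lp_o - log_risk)))
    return ll


def _coxnet_path(X: np.ndarray, y_surv, alphas=None):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        n_alphas=50,
        alpha_min_ratio=0.01,
        max_iter=100000,
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y_surv)
    return model


def _one_se_alpha(alphas: np.ndarray, fold_dev: np.ndarray) -> float:
    """Largest penalty within one SE of the deviance minimum.

    The SE is taken over the per-fold *paired differences* from the best
    penalty. Fold deviances share a large fold-composition component that a
    naive per-penalty SE would count as uncertainty, making the rule
    degenerate (it would almost always return the null model); pairing
    within folds removes that shared component while keeping the rule's
    intent.
    """
    n_folds = np.sum(~np.isnan(fold_dev), axis=0)
    mean_dev = np.nanmean(fold_dev, axis=0)
    best = int(np.nanargmin(mean_dev))
    diff = fold_dev - fold_dev[:, [best]]
    mean_diff = np.nanmean(diff, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_diff = np.nanstd(diff, axis=0, ddof=1) / np.sqrt(np.maximum(n_folds, 1))
    ok = alphas[mean_diff <= se_diff + 1e-12]
    if ok.size == 0:  # degenerate SE (e.g. a single valid fold)
        return float(alphas[best])
    return float(ok.max())


def lasso_cox_stability(
    X: pd.DataFrame,
    times,
    events,
    *,
    n_reps: int = 100,
    subsample_fraction: float = 0.75,
    n_folds: int = 5,
    freq_threshold: int = 30,
    seed: int = 0,
    max_redraws: int = 20,
) -> StabilitySelection:
    """Lasso-Cox selection frequencies over subsampling replicates.

    Per replicate: subsample ``subsample_fraction`` of the patients without
    replacement (redrawn if the subsample or a CV training fold has no
    events), tune the penalty by K-fold cross-validated partial-likelihood
    deviance with the one-SE rule, refit on the subsample at the chosen
    penalty and record the nonzero CpGs. Selection requires frequency
    strictly greater than ``freq_threshold``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    Xv = X.to_numpy(dtype=float)
    n = len(times)
    if events.sum() < n_folds:
        raise StratificationError("too few events for cross-validation")
    rng = np.random.default_rng(seed)
    freq = pd.Series(0, index=X.columns, dtype=int)
    n_sub = int(round(subsample_fraction * n))

    for _rep in range(n_reps):
        for _try in range(max_redraws):
            idx = rng.choice(n, n_sub, replace=False)
            if events[idx].sum() >= n_folds:
                break
        else:
            raise StratificationError("could not draw a subsample with enough events")
        Xi, ti, ei = Xv[idx], times[idx], events[idx]
        mean = Xi.mean(axis=0)
        scale = Xi.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xi = (Xi - mean) / scale
        y_sub = Surv.from_arrays(event=ei.astype(bool), time=ti)

        path = _coxnet_path(Xi, y_sub)
        alphas = np.asarray(path.alphas_)

        fold_dev = np.full((n_folds, len(alphas)), np.nan)
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        # Verweij-van Houwelingen cross-validated partial likelihood:
        # dev_k = -2 [ pll(all; beta_(-k)) - pll(train_k; beta_(-k)) ], which
        # cancels fold-composition variance that would otherwise swamp the
        # one-SE rule.
        for f, (tr, te) in enumerate(kf.split(Xi)):
            if ei[tr].sum() == 0 or ei[te].sum() == 0:
                continue
            y_tr = Surv.from_arrays(event=ei[tr].astype(bool), time=ti[tr])
            m = _coxnet_path(Xi[tr], y_tr, alphas=alphas)
            # the solver may truncate the requested path; match by value
            m_alphas = np.asarray(m.alphas_)
            for j, a in enumerate(alphas):
                jj = np.argmin(np.abs(m_alphas - a))
                if not np.isclose(m_alphas[jj], a, rtol=1e-6, atol=0.0):
                    continue
                beta = m.coef_[:, jj]
                ll_all = cox_partial_loglik(Xi, ti, ei, beta)
                ll_tr = cox_partial_loglik(Xi[tr], ti[tr], ei[tr], beta)
                fold_dev[f, j] = -2.0 * (ll_all - ll_tr)
        valid = ~np.all(np.isnan(fold_dev), axis=0)
        chosen = _one_se_alpha(alphas[valid], fold_dev[:, valid])
        coef = path.coef_[:, int(np.argmin(np.abs(np.asarray(path.alphas_) - chosen)))]
        freq.iloc[np.where(coef != 0)[0]] += 1

    return StabilitySelection(
        frequencies=freq, n_replicates=n_reps, threshold=freq_threshold, strict=True
    )


# ---------------------------------------------------------------------------
# risk score


@dataclass
class PrognosticModel:
    """Refit Cox coefficients, per-sample risk score and median split.

    The risk score is the linear predictor sum(coef_k * beta_k); the cutoff
    is the median score of the fitting cohort and is stored so the model
    can be applied to external samples. Scores equal to the median are
    assigned to the low-risk group.
    """

    cpgs: list[str]
    coefficients: np.ndarray
    cutoff: float
    risk_scores: pd.Series
    groups: pd.Series
    cox: CoxResult | None = None

    def score(self, betas: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.cpgs if g not in betas.index]
        if missing:
            raise ValidationError(f"model CpGs missing from matrix: {missing}")
        vals = betas.loc[self.cpgs].to_numpy(dtype=float).T @ self.coefficients
        return pd.Series(vals, index=betas.columns, name="risk_score")

    def assign_groups(self, scores: pd.Series) -> pd.Series:
        return pd.Series(
            np.where(scores > self.cutoff, "high", "low"),
            index=scores.index,
            name="risk_group",
        )

    def to_json(self, path=None) -> str:
        payload = {
            "cpgs": list(self.cpgs),
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_risk_score(
    selected,
    betas: pd.DataFrame,
    annotation: pd.DataFrame,
) -> PrognosticModel:
    """Unpenalized multivariable Cox on the selected CpGs plus median split."""
    selected = list(selected)
    if not selected:
        raise ValidationError("selected CpG set is empty")
    df = pd.DataFrame(
        {
            "os_time": pd.to_numeric(annotation["os_time"], errors="coerce"),
            "os_event": pd.to_numeric(annotation["os_event"], errors="coerce"),
        },
        index=annotation.index,
    )
    for g in selected:
        df[g] = betas.loc[g, df.index].to_numpy(dtype=float)
    df = df.dropna()
    res = fit_cox(df, covariates=selected)
    coefs = res.table.loc[selected, "coef"].to_numpy(dtype=float)
    scores = pd.Series(
        df[selected].to_numpy(dtype=float) @ coefs, index=df.index, name="risk_score"
    )
    cutoff = float(np.median(scores))
    model = PrognosticModel(
        cpgs=selected,
        coefficients=coefs,
        cutoff=cutoff,
        risk_scores=scores,
        groups=pd.Series(
            np.where(scores > cutoff, "high", "low"), index=scores.index, name="risk_group"
        ),
        cox=res,
    )
    return model
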