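"""Per-CpG differential methylation with empirical-Bayes moderated t-statistics.

The moderated t borrows strength across CpGs by shrinking each probe's
pooled two-sample variance toward a common prior. The prior degrees of
freedom ``d0`` and prior variance ``s0^2`` are fitted by moment matching on
``log s^2`` using digamma/trigamma identities of the scaled-F sampling
distribution of the sample variances, with ``d0`` obtained by Newton
iteration on the trigamma equation. The shrunken variance is the
degrees-of-freedom-weighted average

    s~^2_g = (d0 * s0^2 + d_g * s^2_g) / (d0 + d_g)

and the moderated t is referred to a t distribution with ``d0 + d_g``
degrees of freedom. Statistics are computed on beta-values directly so the
effect size is the familiar delta-beta.

Built on top of this are the tissue-specific marker rule (significant in
all seven pairwise contrasts against the other tissue classes, FDR applied
within each contrast) and the differential-methylation-CpG (DMC) rule
(|delta beta| > 0.2 and BH-FDR < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import HyperparameterError, ValidationError

DEFAULT_FDR = 0.05
DEFAULT_DELTA = 0.2


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise HyperparameterError("trigamma inverse requires a positive target")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching on z = log(s2): the sampling distribution of z given a
    true variance is a shifted log-F, whose mean and variance involve
    digamma and trigamma functions of df/2 and d0/2. CpGs with zero sample
    variance are excluded by the caller. Returns ``d0 = inf`` when the
    observed spread of z is no larger than the sampling spread (complete
    shrinkage to a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise HyperparameterError(
            "need at least two CpGs with positive variance to fit the prior; "
            "check that both groups vary at some probes"
        )
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1))
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        half_d0 = _trigamma_inverse(rhs)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


@dataclass
class ModeratedTFit:
    """Moderated-t results for one two-group comparison.

    ``table`` is indexed by CpG id with columns ``delta_beta`` (mean_a -
    mean_b), ``s2`` (pooled variance), ``s2_post`` (shrunken variance),
    ``t`` (moderated t), ``p_raw`` and ``p_bh``. ``prior_df``/``prior_var``
    are the fitted empirical-Bayes hyperparameters, ``residual_df`` the
    per-CpG pooled degrees of freedom (n_a + n_b - 2).
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: float
    n_a: int
    n_b: int


def moderated_t(matrix: pd.DataFrame, group_a, group_b) -> ModeratedTFit:
    """Empirical-Bayes moderated two-sample t for every CpG row.

    ``group_a``/``group_b`` are disjoint collections of sample (column)
    ids, each of size >= 2. BH adjustment is applied across CpGs within
    this comparison.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least two samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")

    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    delta = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p_raw": p,
            "p_bh": bh_adjust(p),
        },
        index=matrix.index,
    )
    return ModeratedTFit(
        table=table,
        prior_df=d0,
        prior_var=s0_sq,
        residual_df=float(df),
        n_a=na,
        n_b=nb,
    )


@dataclass
class TissueSpecificMarkers:
    """Per-class tissue-specific marker sets and their union.

    A CpG is specific to a target class when its BH-adjusted p-value is
    below the FDR threshold in every pairwise comparison of that class
    against each of the other tissue classes.
    """

    per_class: dict[str, list[str]]
    fdr_threshold: float

    @property
    def union(self) -> set[str]:
        return {g for ids in self.per_class.values() for g in ids}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target_class": cls, "cpg_id": g}
            for cls, ids in self.per_class.items()
            for g in ids
        ]
        return pd.DataFrame(rows, columns=["target_class", "cpg_id"])


def tissue_specific_markers(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    *,
    target_classes=None,
    all_classes=None,
    min_per_class: int = 2,
) -> TissueSpecificMarkers:
    """Markers significant in all pairwise contrasts against the other classes.

    For each target class, one moderated-t comparison is run against each
    of the remaining classes, with BH applied within each comparison across
    CpGs; the class marker set is the intersection of the per-comparison
    significant sets. ``annotation`` must carry a ``tissue_class`` column
    for the matrix samples.
    """
    from .simulate import CLASSES, ESOPHAGEAL_CLASSES

    if all_classes is None:
        all_classes = list(CLASSES)
    if target_classes is None:
        target_classes = [c for c in ESOPHAGEAL_CLASSES if c in all_classes]

    groups = {
        cls: annotation.index[annotation["tissue_class"] == cls].tolist()
        for cls in all_classes
    }
    groups = {c: [s for s in ids if s in matrix.columns] for c, ids in groups.items()}
    lacking = [c for c, ids in groups.items() if len(ids) < min_per_class]
    if lacking:
        raise ValidationError(
            f"classes with fewer than {min_per_class} samples: {lacking}"
        )

    per_class: dict[str, list[str]] = {}
    for target in target_classes:
        sig: pd.Index | None = None
        for other in all_classes:
            if other == target:
                continue
            fit = moderated_t(matrix, groups[target], groups[other])
            hits = fit.table.index[fit.table["p_bh"] < fdr_threshold]
            sig = hits if sig is None else sig.intersection(hits)
            if len(sig) == 0:
                break
        keep = matrix.index.intersection(sig if sig is not None else [])
        per_class[target] = keep.tolist()
    return TissueSpecificMarkers(per_class=per_class, fdr_threshold=fdr_threshold)


def select_dmc(
    fit: ModeratedTFit,
    delta_threshold: float = DEFAULT_DELTA,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[str]:
    """Differentially methylated CpGs: |delta beta| > threshold and FDR < threshold.

    Both inequalities are strict.
    """
    t = fit.table
    keep = (t["delta_beta"].abs() > delta_threshold) & (t["p_bh"] < fdr_threshold)
    return t.index[keep].tolist()
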