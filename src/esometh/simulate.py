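"""Synthetic 450K-like methylation datasets with planted diagnostic and prognostic signal.

The generator emulates the structure of an Illumina HumanMethylation450
beta-value study of the esophagus and its adjacent organs: eight tissue
classes (normal squamous esophagus, Barrett's esophagus, the two esophageal
carcinoma histologies, plus head-and-neck and stomach tumor/normal pairs),
a bimodal baseline beta distribution, tissue-specific CpGs shifted in
exactly one class, optional "contaminant-mimicking" decoy CpGs shifted in an
esophageal class *and* in an adjacent-organ class, and survival times drawn
from an exponential proportional-hazards model driven by planted prognostic
CpGs.

Beta values are produced by adding Gaussian noise on the logit scale to a
class-specific mean beta and mapping back through the inverse logit, which
keeps every value inside (0, 1) while preserving the planted mean-shift
parameterization to good approximation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigurationError, ConsistencyError

#: The eight tissue classes of the study design.
CLASSES: tuple[str, ...] = (
    "NSE",
    "BE",
    "EAC",
    "ESCC",
    "HNSC",
    "HNSC-normal",
    "STAD",
    "STAD-normal",
)

#: The four esophageal classes targeted by the diagnostic classifier.
ESOPHAGEAL_CLASSES: tuple[str, ...] = ("NSE", "BE", "EAC", "ESCC")

#: Classes treated as tumors (receive an AJCC stage and carry the planted
#: tumor-vs-normal shift at prognostic CpGs).
TUMOR_CLASSES: tuple[str, ...] = ("EAC", "ESCC", "HNSC", "STAD")

#: Adjacent-organ partner used when planting a contaminant-mimicking decoy
#: for each esophageal class (squamous classes pair with HNSC, columnar with
#: STAD, mirroring the histologic resemblance that motivates the design).
DECOY_PARTNER: dict[str, str] = {
    "NSE": "HNSC",
    "BE": "STAD",
    "EAC": "STAD",
    "ESCC": "HNSC",
}

AJCC_STAGES: tuple[str, ...] = ("I", "II", "III", "IV")


def _default_counts() -> dict[str, int]:
    return {c: 50 for c in CLASSES}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_cpgs:
        Total number of CpG rows (planted + background).
    n_per_class:
        Samples per tissue class; all eight classes must be present with a
        positive count.
    n_specific_per_class:
        Planted tissue-specific CpGs for each of the four esophageal classes.
    delta:
        Mean beta shift of a planted CpG in its target class, in [0, 1)
        (0 yields a signal-free dataset).
    noise_sd:
        Within-class dispersion on the logit scale.
    n_decoys_per_class:
        Contaminant-mimicking CpGs per esophageal class, shifted identically
        in the esophageal class and in its adjacent-organ partner.
    n_prognostic:
        Planted survival-associated CpGs (variable across tumor samples).
    cox_betas:
        Planted log-hazard coefficient per prognostic CpG (per unit beta).
    prognostic_noise_sd:
        Logit-scale dispersion of prognostic CpGs; larger than ``noise_sd``
        so the risk score has patient-to-patient spread.
    baseline_hazard:
        Exponential baseline event rate (per time unit).
    censor_rate:
        Independent exponential censoring rate; 0 disables censoring.
    missing_rate:
        Fraction of beta entries masked to NaN (0 by default).
    seed:
        Seed for all randomness; identical configs give identical datasets.
    """

    n_cpgs: int = 500
    n_per_class: Mapping[str, int] = field(default_factory=_default_counts)
    n_specific_per_class: int = 3
    delta: float = 0.3
    noise_sd: float = 0.9
    n_decoys_per_class: int = 0
    n_prognostic: int = 3
    cox_betas: tuple[float, ...] = (1.5, 1.5, 1.5)
    prognostic_noise_sd: float = 1.5
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cpgs <= 0:
            raise ConfigurationError("n_cpgs must be positive")
        missing = set(CLASSES) - set(self.n_per_class)
        if missing:
            raise ConfigurationError(f"n_per_class missing classes: {sorted(missing)}")
        for cls, n in self.n_per_class.items():
            if n <= 0:
                raise ConfigurationError(f"n_per_class[{cls!r}] must be positive, got {n}")
        if not (0.0 <= self.delta < 1.0):
            raise ConfigurationError(f"delta must lie in [0, 1), got {self.delta}")
        if self.noise_sd < 0 or self.prognostic_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        if self.n_prognostic != len(self.cox_betas):
            raise ConfigurationError(
                f"cox_betas has {len(self.cox_betas)} entries for "
                f"n_prognostic={self.n_prognostic}"
            )
        n_planted = (
            len(ESOPHAGEAL_CLASSES) * (self.n_specific_per_class + self.n_decoys_per_class)
            + self.n_prognostic
        )
        if n_planted > self.n_cpgs:
            raise ConfigurationError(f"{n_planted} planted CpGs exceed n_cpgs={self.n_cpgs}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of the planted signal.

    ``specific_cpgs`` maps each esophageal class to its planted
    tissue-specific CpG ids; ``decoy_cpgs`` maps each esophageal class to
    the contaminant-mimicking ids (also shifted in the adjacent-organ
    partner); ``prognostic_cpgs`` maps CpG id to its planted log-hazard
    coefficient.
    """

    specific_cpgs: dict[str, list[str]]
    decoy_cpgs: dict[str, list[str]]
    prognostic_cpgs: dict[str, float]

    @property
    def all_specific(self) -> set[str]:
        return {g for ids in self.specific_cpgs.values() for g in ids}

    @property
    def all_decoys(self) -> set[str]:
        return {g for ids in self.decoy_cpgs.values() for g in ids}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


# Beta means are clipped away from 0/1 so the logit is finite and a +/-delta
# shift stays inside the unit interval.
_MEAN_LO, _MEAN_HI = 0.03, 0.97
_PROGNOSTIC_NORMAL_MEAN = 0.15
_PROGNOSTIC_TUMOR_MEAN = 0.50


def _class_mean_model(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Class-mean beta matrix (CpG x class) plus the planted truth.

    Seeded only by ``config.seed`` (stream 0), so independently sampled
    cohorts — e.g. an external validation set drawn with a different cohort
    seed — share the same underlying signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    ids = _cpg_ids(config.n_cpgs)

    # Bimodal baseline: mixture of logit-normals concentrated near 0.1/0.9.
    comp = rng.random(config.n_cpgs) < 0.5
    mu_logit = np.where(
        comp,
        rng.normal(logit(0.1), 0.4, config.n_cpgs),
        rng.normal(logit(0.9), 0.4, config.n_cpgs),
    )
    base = np.clip(expit(mu_logit), _MEAN_LO, _MEAN_HI)

    # Planted markers start from the concentrated hypo-/hypermethylated ends
    # (narrow spread), as marker CpGs of comparable effect do; this keeps the
    # planted signal strength homogeneous across markers.
    n_marker_rows = len(ESOPHAGEAL_CLASSES) * (
        config.n_specific_per_class + config.n_decoys_per_class
    )
    side = rng.random(n_marker_rows) < 0.5
    marker_base = np.clip(
        expit(
            np.where(
                side,
                rng.normal(logit(0.12), 0.15, n_marker_rows),
                rng.normal(logit(0.88), 0.15, n_marker_rows),
            )
        ),
        _MEAN_LO,
        _MEAN_HI,
    )
    base[:n_marker_rows] = marker_base

    means = np.tile(base[:, None], (1, len(CLASSES)))
    col = {c: j for j, c in enumerate(CLASSES)}

    specific: dict[str, list[str]] = {}
    decoys: dict[str, list[str]] = {}
    row = 0
    for cls in ESOPHAGEAL_CLASSES:
        rows = list(range(row, row + config.n_specific_per_class))
        row += config.n_specific_per_class
        specific[cls] = [ids[r] for r in rows]
        for r in rows:
            direction = 1.0 if base[r] < 0.5 else -1.0
            means[r, col[cls]] = np.clip(
                base[r] + direction * config.delta, 0.01, 0.99
            )
    for cls in ESOPHAGEAL_CLASSES:
        rows = list(range(row, row + config.n_decoys_per_class))
        row += config.n_decoys_per_class
        decoys[cls] = [ids[r] for r in rows]
        partner = DECOY_PARTNER[cls]
        for r in rows:
            direction = 1.0 if base[r] < 0.5 else -1.0
            shifted = np.clip(base[r] + direction * config.delta, 0.01, 0.99)
            means[r, col[cls]] = shifted
            means[r, col[partner]] = shifted

    prognostic: dict[str, float] = {}
    for k in range(config.n_prognostic):
        r = row + k
        prognostic[ids[r]] = float(config.cox_betas[k])
        for cls in CLASSES:
            means[r, col[cls]] = (
                _PROGNOSTIC_TUMOR_MEAN if cls in TUMOR_CLASSES else _PROGNOSTIC_NORMAL_MEAN
            )

    frame = pd.DataFrame(means, index=ids, columns=list(CLASSES))
    truth = SimulationTruth(
        specific_cpgs=specific, decoy_cpgs=decoys, prognostic_cpgs=prognostic
    )
    return frame, truth


def simulate_betas(
    config: SimulationConfig,
    *,
    cohort_seed: int | None = None,
    n_per_class: Mapping[str, int] | None = None,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw a beta matrix and sample sheet (without survival fields).

    ``cohort_seed`` seeds the per-sample noise independently of the planted
    mean structure; two cohorts drawn from the same config but different
    cohort seeds carry the same signal in fresh samples. ``n_per_class``
    optionally overrides the per-class sample counts (classes omitted from
    the override are skipped entirely), which is how validation cohorts
    restricted to the esophageal classes are produced.
    """
    config.validate()
    counts = dict(config.n_per_class if n_per_class is None else n_per_class)
    for cls, n in counts.items():
        if cls not in CLASSES:
            raise ConfigurationError(f"unknown class {cls!r}")
        if n <= 0:
            raise ConfigurationError(f"count for {cls!r} must be positive")

    means, truth = _class_mean_model(config)
    seed = config.seed if cohort_seed is None else cohort_seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, seed]))

    sample_ids: list[str] = []
    classes: list[str] = []
    blocks: list[np.ndarray] = []
    prog_rows = [means.index.get_loc(g) for g in truth.prognostic_cpgs]
    sd = np.full(config.n_cpgs, config.noise_sd)
    sd[prog_rows] = config.prognostic_noise_sd

    i = 0
    for cls in CLASSES:
        if cls not in counts:
            continue
        n = counts[cls]
        mu = logit(means[cls].to_numpy())[:, None]
        noise = rng.normal(0.0, 1.0, size=(config.n_cpgs, n)) * sd[:, None]
        blocks.append(expit(mu + noise))
        for _ in range(n):
            sample_ids.append(f"{sample_prefix}{i:04d}")
            classes.append(cls)
            i += 1

    values = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    matrix = pd.DataFrame(values, index=means.index, columns=sample_ids)

    n_total = len(sample_ids)
    cls_arr = pd.Series(classes, index=sample_ids, name="tissue_class")
    is_tumor = cls_arr.isin(TUMOR_CLASSES)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue_class": classes,
            "cohort": "train",
            "age": rng.integers(40, 81, n_total),
            "gender": rng.choice(["male", "female"], n_total),
            "bmi": rng.uniform(18.0, 35.0, n_total).round(1),
            "smoking": rng.choice(["yes", "no"], n_total),
            "alcohol": rng.choice(["yes", "no"], n_total),
            "ajcc_stage": rng.choice(AJCC_STAGES, n_total),
            "os_time": np.nan,
            "os_event": np.nan,
        }
    ).set_index("sample_id", drop=False)
    sheet.index.name = None
    sheet.loc[~is_tumor.to_numpy(), "ajcc_stage"] = np.nan
    return matrix, sheet, truth


def simulate_survival(
    config: SimulationConfig,
    betas: pd.DataFrame,
    truth: SimulationTruth,
    annotation: pd.DataFrame,
    *,
    cohort_seed: int | None = None,
) -> pd.DataFrame:
    """Fill ``os_time`` / ``os_event`` from an exponential proportional-hazards model.

    The linear predictor is the sum of planted coefficient times beta over
    the prognostic CpGs, centered at the planted tumor mean so the baseline
    hazard refers to an average tumor sample. Censoring is an independent
    exponential; the observed time is the minimum of event and censoring
    time and is strictly positive.
    """
    missing = [g for g in truth.prognostic_cpgs if g not in betas.index]
    if missing:
        raise ConsistencyError(f"prognostic CpGs absent from matrix: {missing}")
    seed = config.seed if cohort_seed is None else cohort_seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, seed]))

    samples = annotation.index
    lp = np.zeros(len(samples))
    for g, b in truth.prognostic_cpgs.items():
        lp += b * (betas.loc[g, samples].to_numpy(dtype=float) - _PROGNOSTIC_TUMOR_MEAN)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, len(samples))
    else:
        t_cens = np.full(len(samples), np.inf)
    out = annotation.copy()
    out["os_time"] = np.minimum(t_event, t_cens)
    out["os_event"] = (t_event <= t_cens).astype(int)
    return out


def simulate_dataset(
    config: SimulationConfig,
    *,
    cohort_seed: int | None = None,
    n_per_class: Mapping[str, int] | None = None,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Full dataset: beta matrix, sample sheet with survival, planted truth."""
    matrix, sheet, truth = simulate_betas(
        config,
        cohort_seed=cohort_seed,
        n_per_class=n_per_class,
        sample_prefix=sample_prefix,
    )
    sheet = simulate_survival(config, matrix, truth, sheet, cohort_seed=cohort_seed)
    return matrix, sheet, truth


def simulate_probe_annotation(
    cpg_ids, *, seed: int = 0, frac_xy: float = 0.0
) -> pd.DataFrame:
    """Minimal probe annotation table for a set of CpG ids.

    Chromosomes are drawn uniformly from the autosomes unless ``frac_xy``
    requests a fraction of sex-chromosome probes (useful for exercising the
    X/Y exclusion filter).
    """
    rng = np.random.default_rng(seed)
    cpg_ids = list(cpg_ids)
    n = len(cpg_ids)
    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], n).astype(object)
    if frac_xy > 0:
        idx = rng.choice(n, max(1, int(round(frac_xy * n))), replace=False)
        chroms[idx] = rng.choice(["chrX", "chrY"], len(idx))
    return pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene_symbol": [f"GENE{i % 97}" for i in range(n)],
            "chromosome": chroms,
            "genomic_coordinate": rng.integers(1, 2_000_000_00, n),
            "relation_to_island": rng.choice(
                ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"], n
            ),
            "refgene_group": rng.choice(
                ["Body", "TSS200", "TSS1500", "5'UTR", "3'UTR", "1stExon"], n
            ),
        }
    ).set_index("cpg_id", drop=False)
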