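"""Reading, writing and validation of beta matrices, sample sheets and probe tables.

File formats are plain TSV/CSV with a header row (gzip-transparent through
pandas). A beta matrix is stored with CpG ids as the first column and one
column per sample; the sample sheet carries one row per sample with the
clinical fields used downstream.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, ValidationError

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "tissue_class",
    "cohort",
    "age",
    "gender",
    "bmi",
    "smoking",
    "alcohol",
    "ajcc_stage",
    "os_time",
    "os_event",
]


def compute_beta(meth_intensity, unmeth_intensity):
    """Beta-value from methylated/unmethylated probe intensities.

    beta = M / (M + U), the plain ratio without a stabilizing offset.
    Where both intensities are zero the result is NaN (missing), not an
    error. Accepts scalars or arrays; negative intensities are rejected.
    """
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValidationError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def validate_beta_matrix(matrix: pd.DataFrame) -> None:
    """Check id uniqueness and the [0, 1] range (NaN allowed as missing)."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate CpG ids: {dups[:5]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    vals = matrix.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {vals[r, c]:g} outside [0, 1] at CpG "
            f"{matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )


def filter_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    snp_list: Iterable[str] = (),
    crossreactive_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Remove probes on chrX/chrY, SNP-associated probes and cross-reactive probes.

    The exclusion lists are user-supplied id collections (possibly empty).
    Row order of the survivors is preserved; the operation is idempotent.
    """
    missing = matrix.index.difference(annotation.index)
    if len(missing) > 0:
        raise AnnotationError(
            f"CpGs missing from annotation: {missing[:5].tolist()}"
        )
    chrom = annotation.loc[matrix.index, "chromosome"].astype(str)
    drop = chrom.isin(SEX_CHROMOSOMES)
    drop |= matrix.index.isin(set(snp_list))
    drop |= matrix.index.isin(set(crossreactive_list))
    return matrix.loc[~drop]


def drop_incomplete_probes(matrix: pd.DataFrame, *, impute_median: bool = False) -> pd.DataFrame:
    """Handle missing betas before marker discovery.

    Default is complete-case: any CpG with a missing value is dropped.
    With ``impute_median=True`` missing entries are replaced by the probe's
    median across samples instead (probes missing everywhere are dropped).
    """
    if not impute_median:
        return matrix.dropna(axis=0)
    med = matrix.median(axis=1)
    out = matrix.T.fillna(med).T
    return out.dropna(axis=0)


def _read_table(path) -> pd.DataFrame:
    name = str(path).removesuffix(".gz")
    return pd.read_csv(path, sep="," if name.endswith(".csv") else "\t")


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cpg_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path) -> pd.DataFrame:
    df = _read_table(path)
    return df.set_index(df.columns[0])


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = _read_table(path)
    if "sample_id" not in sheet.columns:
        raise ValidationError("sample sheet lacks a 'sample_id' column")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dups[:5]}")
    out = sheet.set_index("sample_id", drop=False)
    out.index.name = None
    return out


def read_probe_annotation(path) -> pd.DataFrame:
    ann = _read_table(path)
    if "cpg_id" not in ann.columns:
        raise ValidationError("probe annotation lacks a 'cpg_id' column")
    out = ann.set_index("cpg_id", drop=False)
    return out


def load_dataset(
    matrix_path, sample_sheet_path, annotation_path=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Load and reconcile a beta matrix, sample sheet and optional probe table.

    Sample columns and sheet rows must agree exactly; any mismatch is
    reported with the offending ids. Beta values outside [0, 1] raise a
    validation error naming the CpG and sample.
    """
    matrix = read_beta_matrix(matrix_path)
    sheet = read_sample_sheet(sample_sheet_path)
    validate_beta_matrix(matrix)

    extra_sheet = sheet.index.difference(matrix.columns)
    extra_matrix = pd.Index(matrix.columns).difference(sheet.index)
    if len(extra_sheet) or len(extra_matrix):
        raise ValidationError(
            "sample sheet and matrix disagree: "
            f"only in sheet {extra_sheet.tolist()[:5]}, "
            f"only in matrix {extra_matrix.tolist()[:5]}"
        )
    sheet = sheet.loc[matrix.columns]

    annotation = None
    if annotation_path is not None:
        annotation = read_probe_annotation(annotation_path)
        missing = matrix.index.difference(annotation.index)
        if len(missing):
            raise AnnotationError(
                f"CpGs missing from annotation: {missing[:5].tolist()}"
            )
    return matrix, sheet, annotation
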