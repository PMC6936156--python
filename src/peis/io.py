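"""Reading, validation and pre-filtering of methylation cohort inputs.

Three tabular inputs describe a paired tumor/normal cohort:

* a beta-value matrix (rows = CpG sites, columns = samples, values in [0, 1]
  or missing), TSV or CSV, first column = site ids, header = sample ids;
* a CpG annotation giving each site a chromosome and a 1-based position,
  either a 3-column TSV (site_id, chromosome, position) or a 4-column BED
  (chrom, start, end, site_id; 0-based half-open, converted on read);
* a sample design TSV with columns patient_id, tumor_sample_id,
  normal_sample_id pairing each patient's two samples.

All coordinates are held internally as 1-based point positions so that
genomic distances are plain integer differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"chrx", "chry", "x", "y"}

DESIGN_COLUMNS = ["patient_id", "tumor_sample_id", "normal_sample_id"]


@dataclass(frozen=True)
class PairedBeta:
    """Beta values aligned into tumor and normal matrices with one column
    per patient (same patient order in both) and no missing values."""

    tumor: pd.DataFrame
    normal: pd.DataFrame

    @property
    def site_ids(self) -> pd.Index:
        return self.tumor.index

    @property
    def patients(self) -> pd.Index:
        return self.tumor.columns

    @property
    def n_patients(self) -> int:
        return self.tumor.shape[1]


def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "csv" if str(path).lower().endswith(".csv") else "tsv"


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a beta matrix; rows = CpG sites, columns = samples.

    Missing values (empty cells or NA) are kept as NaN and handled later by
    :func:`qc_filter` / :func:`align_pairs`.  Any non-missing value outside
    [0, 1] is rejected with the offending site and sample named.
    """
    sep = "," if _infer_dialect(path, dialect) == "csv" else "\t"
    try:
        # round_trip parsing keeps write/read bit-exact
        beta = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no sites (empty file)") from None
    if beta.shape[0] == 0:
        raise ParseError(f"{path}: no sites")
    if beta.shape[1] == 0:
        raise ParseError(f"{path}: no samples (malformed header?)")
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    if beta.index.duplicated().any():
        dup = beta.index[beta.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate site id {dup!r}")
    if beta.columns.duplicated().any():
        dup = beta.columns[beta.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    try:
        beta = beta.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric beta value ({exc})") from None
    bad = (beta < 0) | (beta > 1)
    if bad.any().any():
        stacked = bad.stack()
        site, sample = stacked[stacked].index[0]
        raise ParseError(
            f"{path}: beta value out of [0, 1] at site {site!r}, sample {sample!r}"
        )
    return beta


def write_beta_matrix(beta: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    sep = "," if _infer_dialect(path, dialect) == "csv" else "\t"
    beta.to_csv(path, sep=sep, index_label="site_id")


def read_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a CpG annotation into a frame indexed by site_id with columns
    ``chromosome`` and ``position`` (1-based).

    BED input (0-based half-open) is converted to a 1-based point
    position = start + 1.
    """
    if format is None:
        format = "bed" if str(path).lower().endswith(".bed") else "tsv"
    if format == "bed":
        raw = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chromosome", "start", "end", "site_id"],
            usecols=[0, 1, 2, 3],
        )
        annot = pd.DataFrame(
            {
                "site_id": raw["site_id"].astype(str),
                "chromosome": raw["chromosome"].astype(str),
                "position": raw["start"].astype(int) + 1,
            }
        )
    elif format == "tsv":
        raw = pd.read_csv(path, sep="\t")
        missing = {"site_id", "chromosome", "position"} - set(raw.columns)
        if missing:
            raise ParseError(f"{path}: missing annotation column(s) {sorted(missing)}")
        annot = raw[["site_id", "chromosome", "position"]].copy()
        annot["site_id"] = annot["site_id"].astype(str)
        annot["chromosome"] = annot["chromosome"].astype(str)
        annot["position"] = annot["position"].astype(int)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if annot["site_id"].duplicated().any():
        dup = annot.loc[annot["site_id"].duplicated(), "site_id"].iloc[0]
        raise ParseError(f"{path}: duplicate site id {dup!r}")
    if (annot["position"] < 1).any():
        raise ParseError(f"{path}: position < 1")
    return annot.set_index("site_id")


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.reset_index().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (patient_id, tumor_sample_id, normal_sample_id)."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ParseError(f"{path}: missing design column(s) {sorted(missing)}")
    design = design[DESIGN_COLUMNS]
    if design["patient_id"].duplicated().any():
        dup = design.loc[design["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ParseError(f"{path}: patient {dup!r} appears more than once")
    tumors = set(design["tumor_sample_id"].dropna())
    normals = set(design["normal_sample_id"].dropna())
    if tumors & normals:
        raise ParseError(
            f"{path}: sample(s) {sorted(tumors & normals)} listed as both tumor and normal"
        )
    return design


def qc_filter(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    drop_sex_chromosomes: bool = True,
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Apply the cohort-level pre-filters.

    Sites missing from the annotation are dropped with a warning; sites on
    the sex chromosomes are removed when ``drop_sex_chromosomes`` is set
    (chrX/chrY/X/Y, case-insensitive); sites whose missing fraction across
    samples exceeds ``max_missing_fraction`` are removed.  Any missing values
    that survive here are resolved later by complete-case dropping in
    :func:`align_pairs`.
    """
    unannotated = beta.index.difference(annotation.index)
    if len(unannotated) > 0:
        warnings.warn(
            f"dropping {len(unannotated)} site(s) absent from the annotation",
            stacklevel=2,
        )
        beta = beta.drop(index=unannotated)
    if drop_sex_chromosomes:
        chroms = annotation.loc[beta.index, "chromosome"].str.lower()
        beta = beta.loc[~chroms.isin(SEX_CHROMOSOMES)]
    if beta.shape[0] > 0:
        missing_frac = beta.isna().mean(axis=1)
        beta = beta.loc[missing_frac <= max_missing_fraction]
    if beta.shape[0] == 0:
        raise DataError("all sites removed by QC filtering")
    return beta


def align_pairs(beta: pd.DataFrame, design: pd.DataFrame) -> PairedBeta:
    """Split the beta matrix into patient-aligned tumor and normal matrices.

    Design rows with a null/empty sample id are skipped with a warning
    (patient lacks one of the two samples); a non-null sample id absent from
    the matrix is an error.  Sites with any missing value in either matrix
    are dropped (complete-case per site), so paired tests downstream always
    see complete pairs.
    """
    rows = []
    for rec in design.itertuples(index=False):
        if pd.isna(rec.tumor_sample_id) or pd.isna(rec.normal_sample_id):
            warnings.warn(
                f"patient {rec.patient_id!r} lacks a tumor or normal sample; skipped",
                stacklevel=2,
            )
            continue
        for sid in (rec.tumor_sample_id, rec.normal_sample_id):
            if sid not in beta.columns:
                raise DataError(f"design references sample {sid!r} absent from the beta matrix")
        rows.append(rec)
    if not rows:
        raise DataError("no complete tumor/normal pairs in the design")
    patients = [r.patient_id for r in rows]
    tumor = beta[[r.tumor_sample_id for r in rows]].copy()
    normal = beta[[r.normal_sample_id for r in rows]].copy()
    tumor.columns = patients
    normal.columns = patients
    complete = ~(tumor.isna().any(axis=1) | normal.isna().any(axis=1))
    if not complete.all():
        logger.info("dropping %d site(s) with missing values among paired samples",
                    int((~complete).sum()))
    tumor, normal = tumor.loc[complete], normal.loc[complete]
    if tumor.shape[0] == 0:
        raise DataError("no complete-case sites remain after pairing")
    return PairedBeta(tumor=tumor, normal=normal)
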