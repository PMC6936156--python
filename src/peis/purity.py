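"""Tumor purity as the kernel-density mode of transformed beta values.

Bulk tumor methylation at an informative site is a mixture: with tumor-cell
fraction (purity) p and a site that is fully methylated in tumor cells but
unmethylated in the contaminating normal cells, the observed beta is close
to p.  Hypo-methylated informative sites mirror this at 1 - beta.  After
transforming every informative site onto the same scale (hyper: beta,
hypo: 1 - beta) the transformed values of a sample pile up around the
sample's purity, and the purity is read off as the argmax (mode) of a
Gaussian kernel density estimate over [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["PurityEstimate", "transform_betas", "estimate_purity", "estimate_cohort"]

DEFAULT_GRID_SIZE = 1001
DEFAULT_MIN_SITES = 10


@dataclass
class PurityEstimate:
    """Per-sample purity with KDE diagnostics.

    ``bandwidth`` is the kernel standard deviation actually used (NaN for the
    degenerate all-identical bypass); ``grid``/``density`` are retained for
    plotting when requested.
    """

    sample_id: str | None
    purity: float
    n_sites_used: int
    bandwidth: float
    grid: np.ndarray | None = field(default=None, repr=False)
    density: np.ndarray | None = field(default=None, repr=False)


def transform_betas(sample_betas: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Map beta values onto the purity scale: hyper -> beta, hypo -> 1 - beta."""
    betas = np.asarray(sample_betas, dtype=float)
    directions = np.asarray(directions)
    if betas.shape != directions.shape:
        raise DataError("betas and directions differ in length")
    bad = set(np.unique(directions)) - {"hyper", "hypo"}
    if bad:
        raise ValueError(f"unknown direction label(s) {sorted(bad)}")
    return np.where(directions == "hypo", 1.0 - betas, betas)


def estimate_purity(
    values: np.ndarray,
    bandwidth: str | float = "silverman",
    grid_size: int = DEFAULT_GRID_SIZE,
    min_sites: int = DEFAULT_MIN_SITES,
    sample_id: str | None = None,
    keep_density: bool = False,
) -> PurityEstimate:
    """Gaussian-KDE mode of transformed values on a uniform grid over [0, 1].

    ``bandwidth`` is either a rule name understood by scipy's gaussian_kde
    ("silverman", the default, or "scott") or a fixed numeric kernel standard
    deviation.  The density is evaluated on ``grid_size`` equispaced points;
    argmax ties resolve to the lower grid point, so the estimate is fully
    deterministic.  All values identical bypasses the KDE (its variance would
    be zero) and returns that value directly.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < min_sites:
        raise DataError(
            f"need at least {min_sites} informative-site values, got {values.size}"
        )
    if np.all(values == values[0]):
        return PurityEstimate(
            sample_id=sample_id,
            purity=float(np.clip(values[0], 0.0, 1.0)),
            n_sites_used=int(values.size),
            bandwidth=float("nan"),
        )
    if isinstance(bandwidth, str):
        kde = stats.gaussian_kde(values, bw_method=bandwidth)
    else:
        # scipy's bw_method scalar is a factor multiplying the data std;
        # convert so `bandwidth` is the kernel sd itself.
        sd = values.std(ddof=1)
        kde = stats.gaussian_kde(values, bw_method=float(bandwidth) / sd)
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid)
    purity = float(grid[int(np.argmax(density))])
    return PurityEstimate(
        sample_id=sample_id,
        purity=purity,
        n_sites_used=int(values.size),
        bandwidth=float(np.sqrt(kde.covariance[0, 0])),
        grid=grid if keep_density else None,
        density=density if keep_density else None,
    )


def estimate_cohort(
    tumor_beta: pd.DataFrame,
    informative: pd.DataFrame,
    bandwidth: str | float = "silverman",
    grid_size: int = DEFAULT_GRID_SIZE,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Estimate purity for every tumor sample (column of ``tumor_beta``).

    ``informative`` is the selected-site frame (indexed by site_id, with a
    ``direction`` column).  Informative sites absent from the matrix are
    skipped with a warning; per-sample missing values are dropped.  A sample
    with fewer usable values than ``min_sites`` is flagged with a NaN purity
    rather than aborting the cohort.

    Returns a frame with columns sample_id, purity, n_sites_used, bandwidth.
    """
    if informative.empty:
        raise DataError("informative site set is empty")
    present = informative.index.intersection(tumor_beta.index)
    if len(present) < len(informative):
        warnings.warn(
            f"{len(informative) - len(present)} informative site(s) absent "
            "from the beta matrix; skipped",
            stacklevel=2,
        )
    if len(present) == 0:
        raise DataError("no informative sites present in the beta matrix")
    sub = tumor_beta.loc[present]
    directions = informative.loc[present, "direction"].to_numpy()

    rows = []
    for sample_id in tumor_beta.columns:
        betas = sub[sample_id].to_numpy(dtype=float)
        ok = ~np.isnan(betas)
        values = transform_betas(betas[ok], directions[ok])
        try:
            est = estimate_purity(
                values, bandwidth=bandwidth, grid_size=grid_size,
                min_sites=min_sites, sample_id=str(sample_id),
            )
        except DataError:
            warnings.warn(
                f"sample {sample_id!r} has fewer than {min_sites} usable "
                "informative sites; purity set to NaN",
                stacklevel=2,
            )
            est = PurityEstimate(
                sample_id=str(sample_id), purity=float("nan"),
                n_sites_used=int(ok.sum()), bandwidth=float("nan"),
            )
        rows.append(
            {
                "sample_id": est.sample_id,
                "purity": est.purity,
                "n_sites_used": est.n_sites_used,
                "bandwidth": est.bandwidth,
            }
        )
    return pd.DataFrame(rows)
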