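"""Integrated mean/variance signal scores for CpG sites (stage-1 statistic).

For each CpG site the paired tumor/normal cohort yields two p-values: a
two-sided paired Student-T test on the mean methylation difference, and a
one-sided F test for the tumor variance exceeding the normal variance
(differential variability is itself a tumor signal).  Each p-value is mapped
to a non-negative normal-quantile signal

    m = max(0, Phi^-1(1 - p_mean)),    v = max(0, Phi^-1(1 - p_var)),

and the two signals are merged into one signed score

    S = sign(T) * (lambda * v + (1 - lambda) * m),    lambda = v / (m + v),

a convex combination weighted toward the LARGER of the two signals, so that
(m, v) = (0, 38) scores 38 and (14.9, 14.9) scores 14.9.  The sign comes
from the paired-T statistic: positive = hyper-methylated in tumor, negative
= hypo-methylated.  Sites with both signals zero (both p >= 0.5) or with a
degenerate test carry no usable signal and are marked untestable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateTestError
from .io import PairedBeta

__all__ = [
    "paired_t_test",
    "variance_f_test",
    "p_to_signal",
    "integrate_signal",
    "score_all_sites",
    "write_signal_table",
]

SIGNAL_COLUMNS = ["t", "p_mean", "p_var", "m", "v", "lam", "sign", "score", "testable"]


def paired_t_test(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student-T test on tumor - normal differences.

    Returns ``(t, p_two_sided)`` with t = mean(d) / (sd(d)/sqrt(n)) using the
    sample standard deviation (n-1 denominator).  Zero variance of the
    differences makes the statistic undefined and raises
    :class:`DegenerateTestError` so the caller can mark the site untestable.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise DataError("tumor and normal vectors differ in length")
    n = tumor.size
    if n < 2:
        raise DataError(f"paired T test needs n >= 2 pairs, got {n}")
    d = tumor - normal
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTestError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(min(p, 1.0))


def variance_f_test(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """One-sided F test of tumor variance exceeding normal variance.

    F = var(tumor)/var(normal) (sample variances); p is the upper tail of the
    F distribution with (n_t - 1, n_n - 1) degrees of freedom.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size < 2 or normal.size < 2:
        raise DataError("variance F test needs >= 2 observations per group")
    var_n = normal.var(ddof=1)
    if var_n == 0.0:
        raise DegenerateTestError("zero variance in normal samples")
    f = tumor.var(ddof=1) / var_n
    p = stats.f.sf(f, dfn=tumor.size - 1, dfd=normal.size - 1)
    return float(f), float(p)


def p_to_signal(p) -> float | np.ndarray:
    """Map a p-value in (0, 1] to the clamped normal quantile max(0, Phi^-1(1-p)).

    Computed through the inverse survival function so that extreme p (down to
    1e-320) does not lose precision through 1 - p.  p >= 0.5 maps to 0.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr > 1.0):
        raise ValueError("p-value must lie in (0, 1]")
    signal = np.maximum(0.0, stats.norm.isf(p_arr))
    return float(signal) if np.isscalar(p) or p_arr.ndim == 0 else signal


def integrate_signal(m: float, v: float, t_sign: int, pairing: str = "variance") -> float:
    """Combine mean and variance signals into the signed site score.

    ``pairing="variance"`` (default) weights toward the larger signal:
    score = sign * (lambda*v + (1-lambda)*m) with lambda = v/(m+v).
    ``pairing="literal"`` applies lambda to the mean signal instead
    (score = sign * (lambda*m + (1-lambda)*v)), kept for comparison.
    """
    if m < 0 or v < 0:
        raise ValueError("signals must be non-negative")
    if m == 0.0 and v == 0.0:
        raise DegenerateTestError("both signals zero: site carries no signal")
    if t_sign not in (1, -1):
        raise ValueError("t_sign must be +1 or -1")
    lam = v / (m + v)
    if pairing == "variance":
        combined = lam * v + (1.0 - lam) * m
    elif pairing == "literal":
        combined = lam * m + (1.0 - lam) * v
    else:
        raise ValueError(f"unknown lambda pairing {pairing!r}")
    return t_sign * combined


def score_all_sites(pb: PairedBeta, lambda_pairing: str = "variance") -> pd.DataFrame:
    """Score every site of a complete-case paired cohort (vectorised).

    Returns a frame indexed by site_id with columns t, p_mean, p_var, m, v,
    lam, sign, score and testable.  Sites whose paired differences have zero
    variance, whose normal variance is zero, or whose two signals are both
    zero get ``testable = False`` and a NaN score; they are excluded from
    downstream selection.
    """
    tumor = pb.tumor.to_numpy(dtype=float)
    normal = pb.normal.to_numpy(dtype=float)
    n_sites, n = tumor.shape
    if n_sites == 0:
        raise DataError("no sites to score")
    if n < 2:
        raise DataError("need >= 2 patients for paired testing")

    d = tumor - normal
    sd_d = d.std(axis=1, ddof=1)
    var_t = tumor.var(axis=1, ddof=1)
    var_n = normal.var(axis=1, ddof=1)
    computable = (sd_d > 0.0) & (var_n > 0.0)

    t_stat = np.full(n_sites, np.nan)
    p_mean = np.full(n_sites, np.nan)
    p_var = np.full(n_sites, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat[computable] = d.mean(axis=1)[computable] / (sd_d[computable] / np.sqrt(n))
        p_mean[computable] = np.minimum(
            1.0, 2.0 * stats.t.sf(np.abs(t_stat[computable]), df=n - 1)
        )
        p_var[computable] = stats.f.sf(
            var_t[computable] / var_n[computable], dfn=n - 1, dfd=n - 1
        )

    m = np.full(n_sites, np.nan)
    v = np.full(n_sites, np.nan)
    m[computable] = np.maximum(0.0, stats.norm.isf(p_mean[computable]))
    v[computable] = np.maximum(0.0, stats.norm.isf(p_var[computable]))

    testable = computable & ((m > 0.0) | (v > 0.0))
    sign = np.where(t_stat >= 0.0, 1, -1)

    lam = np.full(n_sites, np.nan)
    score = np.full(n_sites, np.nan)
    tm, tv = m[testable], v[testable]
    tlam = tv / (tm + tv)
    lam[testable] = tlam
    if lambda_pairing == "variance":
        combined = tlam * tv + (1.0 - tlam) * tm
    elif lambda_pairing == "literal":
        combined = tlam * tm + (1.0 - tlam) * tv
    else:
        raise ValueError(f"unknown lambda pairing {lambda_pairing!r}")
    score[testable] = sign[testable] * combined

    return pd.DataFrame(
        {
            "t": t_stat,
            "p_mean": p_mean,
            "p_var": p_var,
            "m": m,
            "v": v,
            "lam": lam,
            "sign": sign,
            "score": score,
            "testable": testable,
        },
        index=pb.site_ids.copy(),
    )


def write_signal_table(signals: pd.DataFrame, path) -> None:
    """Export a signal table as TSV (site_id, t, p_mean, p_var, m, v, lambda, sign, score, testable)."""
    out = signals.rename(columns={"lam": "lambda"})
    out.to_csv(path, sep="\t", index_label="site_id")
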