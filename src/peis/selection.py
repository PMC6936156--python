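"""Neighbor-corrected score finalisation and informative-site selection.

Methylation at nearby CpG sites is strongly correlated, so a site's evidence
is reinforced (or eroded) by its genomic neighbors.  Each testable site's
base score S is corrected by the influence of its two nearest testable
neighbors on the same chromosome within a strict 1000-bp window:

    f_S = S + sum_n alpha_n * S_n,    alpha = 1 - distance / window,

a linear distance decay that vanishes at the window edge.  The top-k sites
by |f_S| form the informative set used for purity estimation; hypo-methylated
sites carry negative scores, so ranking by magnitude keeps both directions.

Two simpler selectors are provided as baselines for comparison: ranking by
the paired-T p-value alone, and a variance (F-test) filter followed by the
paired-T ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import PairedBeta
from .scoring import score_all_sites

__all__ = [
    "NeighborHit",
    "influence_ratio",
    "find_neighbors",
    "finalize_scores",
    "select_top",
    "select_ttest_only",
    "select_f_and_t",
    "write_informative_tsv",
    "write_informative_bed",
]


@dataclass(frozen=True)
class NeighborHit:
    neighbor_site_id: str
    distance: int
    alpha: float


def influence_ratio(distance: float, window: float = 1000.0) -> float:
    """Linear distance decay alpha = 1 - distance/window, strictly in (0, 1)."""
    if not 0 < distance < window:
        raise ValueError(f"distance must lie strictly in (0, {window}), got {distance}")
    return 1.0 - distance / window


def _neighbor_candidates(positions: np.ndarray, order: np.ndarray, pos: int,
                         window: int) -> np.ndarray:
    """Indices (into the original array) of sites with 0 < |p - pos| < window,
    sorted by (distance, position)."""
    sorted_pos = positions[order]
    lo = np.searchsorted(sorted_pos, pos - window, side="right")
    hi = np.searchsorted(sorted_pos, pos + window, side="left")
    cand = order[lo:hi]
    dist = np.abs(positions[cand] - pos)
    keep = dist > 0
    cand, dist = cand[keep], dist[keep]
    rank = np.lexsort((positions[cand], dist))
    return cand[rank]


def find_neighbors(
    annotation: pd.DataFrame,
    site_id: str,
    window: int = 1000,
    max_neighbors: int = 2,
    eligible: set[str] | None = None,
) -> list[NeighborHit]:
    """Up to ``max_neighbors`` nearest same-chromosome sites within the window.

    Strict window: a site exactly ``window`` bp away is excluded, as is a
    site at distance 0.  Equidistant ties are broken by ascending position.
    ``eligible`` optionally restricts which sites may serve as neighbors.
    """
    if site_id not in annotation.index:
        raise DataError(f"site {site_id!r} is not annotated")
    chrom = annotation.loc[site_id, "chromosome"]
    pos = int(annotation.loc[site_id, "position"])
    block = annotation[annotation["chromosome"] == chrom]
    if eligible is not None:
        block = block[block.index.isin(eligible) | (block.index == site_id)]
    block = block[block.index != site_id]
    positions = block["position"].to_numpy(dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    cand = _neighbor_candidates(positions, order, pos, window)[:max_neighbors]
    return [
        NeighborHit(
            neighbor_site_id=str(block.index[i]),
            distance=int(abs(positions[i] - pos)),
            alpha=influence_ratio(abs(positions[i] - pos), window),
        )
        for i in cand
    ]


def finalize_scores(
    signals: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 1000,
    neighbor_mode: str = "two_nearest",
    max_neighbors: int = 2,
) -> pd.DataFrame:
    """Neighbor-correct the base score of every testable site.

    Only testable sites receive a final score and only testable sites may
    donate influence (untestable sites carry no real signal and would
    otherwise promote non-differential neighbors).  ``neighbor_mode`` is
    ``"two_nearest"`` (default) or ``"all_in_window"``, which sums the
    influence of every in-window testable site.

    Returns a frame indexed by site_id with columns chromosome, position,
    base_score, neighbor_sum, final_score, n_neighbors, sign and
    neighbor_contributions (list of (neighbor_site_id, alpha*S) pairs).
    """
    if neighbor_mode not in ("two_nearest", "all_in_window"):
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")
    testable = signals[signals["testable"]]
    if testable.empty:
        raise DataError("no testable sites to finalize")
    unannotated = testable.index.difference(annotation.index)
    if len(unannotated) > 0:
        raise DataError(
            f"{len(unannotated)} testable site(s) missing from the annotation, "
            f"e.g. {unannotated[0]!r}"
        )
    ann = annotation.loc[testable.index]
    scores = testable["score"].to_numpy(dtype=float)
    signs = testable["sign"].to_numpy()
    site_ids = np.asarray(testable.index, dtype=object)
    positions = ann["position"].to_numpy(dtype=np.int64)

    limit = None if neighbor_mode == "all_in_window" else max_neighbors
    neighbor_sum = np.zeros(len(testable))
    contributions: list[list[tuple[str, float]]] = [[] for _ in range(len(testable))]
    n_neighbors = np.zeros(len(testable), dtype=int)

    for chrom, block in ann.groupby("chromosome", sort=False):
        idx = ann.index.get_indexer(block.index)
        chrom_pos = positions[idx]
        order = np.argsort(chrom_pos, kind="stable")
        for local_i, global_i in enumerate(idx):
            cand = _neighbor_candidates(chrom_pos, order, chrom_pos[local_i], window)
            cand = cand[cand != local_i][:limit]
            contrib = []
            total = 0.0
            for c in cand:
                gi = idx[c]
                alpha = 1.0 - abs(chrom_pos[c] - chrom_pos[local_i]) / window
                w = alpha * scores[gi]
                contrib.append((str(site_ids[gi]), w))
                total += w
            neighbor_sum[global_i] = total
            contributions[global_i] = contrib
            n_neighbors[global_i] = len(contrib)

    return pd.DataFrame(
        {
            "chromosome": ann["chromosome"].to_numpy(),
            "position": positions,
            "base_score": scores,
            "neighbor_sum": neighbor_sum,
            "final_score": scores + neighbor_sum,
            "n_neighbors": n_neighbors,
            "sign": signs,
            "neighbor_contributions": contributions,
        },
        index=testable.index.copy(),
    )


def _rank_and_take(df: pd.DataFrame, key: np.ndarray, k: int) -> pd.DataFrame:
    """Order by ascending key then (chromosome, position) and take the top k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tmp = df.assign(_key=key)
    tmp = tmp.sort_values(["_key", "chromosome", "position"], kind="stable")
    return tmp.drop(columns="_key").head(min(k, len(tmp)))


def select_top(final_scores: pd.DataFrame, k: int = 1000, ranking: str = "absolute") -> pd.DataFrame:
    """Top-k informative sites from neighbor-corrected scores.

    ``ranking="absolute"`` (default) orders by |final_score| descending so
    hyper (positive) and hypo (negative) sites compete on magnitude;
    ``ranking="signed"`` orders by the signed score descending.  Ties break
    deterministically by (chromosome, position).
    """
    if final_scores.empty:
        raise DataError("no scored sites to select from")
    f = final_scores["final_score"].to_numpy(dtype=float)
    if ranking == "absolute":
        key = -np.abs(f)
    elif ranking == "signed":
        key = -f
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    top = _rank_and_take(final_scores, key, k)
    return pd.DataFrame(
        {
            "chromosome": top["chromosome"],
            "position": top["position"],
            "score": top["final_score"],
            "direction": np.where(top["sign"] > 0, "hyper", "hypo"),
        },
        index=top.index,
    )


def _baseline_frame(signals: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    usable = signals[signals["p_mean"].notna()]
    if usable.empty:
        raise DataError("no testable sites")
    missing = usable.index.difference(annotation.index)
    if len(missing) > 0:
        raise DataError(f"{len(missing)} site(s) missing from the annotation")
    ann = annotation.loc[usable.index]
    return usable.assign(chromosome=ann["chromosome"], position=ann["position"])


def select_ttest_only(pb: PairedBeta, annotation: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    """Baseline selector: rank by the two-sided paired-T p-value alone."""
    df = _baseline_frame(score_all_sites(pb), annotation)
    top = _rank_and_take(df, df["p_mean"].to_numpy(), k)
    return pd.DataFrame(
        {
            "chromosome": top["chromosome"],
            "position": top["position"],
            "score": top["p_mean"],
            "direction": np.where(top["sign"] > 0, "hyper", "hypo"),
        },
        index=top.index,
    )


def select_f_and_t(
    pb: PairedBeta,
    annotation: pd.DataFrame,
    k: int = 1000,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Baseline selector: F-test variance filter, then paired-T ranking."""
    df = _baseline_frame(score_all_sites(pb), annotation)
    df = df[df["p_var"] < p_threshold]
    if df.empty:
        raise DataError(f"no sites pass the F-test filter at p < {p_threshold}")
    top = _rank_and_take(df, df["p_mean"].to_numpy(), k)
    return pd.DataFrame(
        {
            "chromosome": top["chromosome"],
            "position": top["position"],
            "score": top["p_mean"],
            "direction": np.where(top["sign"] > 0, "hyper", "hypo"),
        },
        index=top.index,
    )


def write_informative_tsv(informative: pd.DataFrame, path) -> None:
    out = informative.rename(columns={"score": "final_score"})
    out.to_csv(path, sep="\t", index_label="site_id")


def write_informative_bed(informative: pd.DataFrame, path) -> None:
    """4-column BED: chrom, start (0-based), end, site_id."""
    bed = pd.DataFrame(
        {
            "chrom": informative["chromosome"],
            "start": informative["position"].astype(int) - 1,
            "end": informative["position"].astype(int),
            "name": informative.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
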