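"""Synthetic paired tumor/normal methylation cohorts with known truth.

The generator emulates the mixture structure the purity estimator assumes: a
bulk tumor sample is a blend of tumor cells (fraction p, the purity) and
contaminating normal cells, so at an informative site with pure-tumor mean
mu_t and normal mean mu_n the expected tumor beta is

    E[beta_tumor] = p * mu_t + (1 - p) * mu_n,

while background sites share one mean between tumor and normal.  Observed
beta values are Beta-distributed around their mean with a single precision
knob kappa (shape a = mu*kappa, b = (1-mu)*kappa), matching the bounded
support and heteroscedastic noise of array beta values.  Informative hyper
sites have low normal / high pure-tumor means; hypo sites are the mirror
image.  A configurable fraction of informative sites is laid out in close
pairs (within 1000 bp) so the neighbor-correlation correction is exercised;
the rest, and all background sites, sit more than 2000 bp from any
informative site.

Everything is reproducible from the config seed, and a truth table (per-
patient purity, per-site label and means) accompanies every cohort so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import write_annotation, write_beta_matrix

__all__ = ["SimulationConfig", "TruthTable", "SimulatedCohort", "simulate_cohort",
           "evaluate_recovery", "write_cohort"]

_LATTICE_STEP = 3000        # min spacing between informative units (bp)
_ISOLATION_BP = 2000        # background keeps this far from informative sites
_EPS = 1e-9                 # clip generated betas strictly inside (0, 1)


@dataclass
class SimulationConfig:
    """Cohort-generator settings.

    ``purity`` is either a (low, high) uniform range or an explicit
    per-patient list; ``noise_precision`` is the Beta precision kappa (> 2;
    larger = less measurement noise); ``cluster_fraction`` is the share of
    informative sites placed in pairs within 1000 bp of each other.  With
    ``common_noise`` the same uniform deviate per site drives every sample's
    Beta draw (through the quantile function), so two patients' tumor
    columns differ only through their purity — useful for monotonicity
    checks.
    """

    n_patients: int = 30
    n_sites: int = 20_000
    n_informative_hyper: int = 500
    n_informative_hypo: int = 500
    purity: tuple[float, float] | list[float] = (0.3, 0.9)
    noise_precision: float = 150.0
    hyper_normal_mean_range: tuple[float, float] = (0.02, 0.08)
    hyper_tumor_mean_range: tuple[float, float] = (0.92, 0.98)
    background_mean_range: tuple[float, float] = (0.1, 0.9)
    cluster_fraction: float = 0.5
    cluster_spacing: tuple[int, int] = (100, 900)
    chromosomes: tuple[str, ...] = ("chr1", "chr2")
    chromosome_length: int = 10_000_000
    common_noise: bool = False
    seed: int = 2019

    def validate(self) -> None:
        if self.n_informative_hyper + self.n_informative_hypo > self.n_sites:
            raise ValueError("more informative sites than total sites")
        if self.noise_precision <= 2:
            raise ValueError("noise_precision (kappa) must exceed 2")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        for lo, hi in (self.hyper_normal_mean_range, self.hyper_tumor_mean_range,
                       self.background_mean_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("mean ranges must lie within (0, 1)")
        p = np.asarray(self.purity, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("purities must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth: per-patient purity and per-site generative parameters."""

    purity: pd.Series                 # indexed by tumor sample id
    sites: pd.DataFrame               # site_id -> label, mu_normal, mu_tumor_pure
    patients: pd.DataFrame            # patient_id, tumor_sample_id, normal_sample_id, purity


@dataclass
class SimulatedCohort:
    beta: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame
    truth: TruthTable
    config: SimulationConfig = field(repr=False, default=None)


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out site coordinates; returns (chrom array, pos array, label array).

    Informative sites occupy lattice anchors >= 3000 bp apart (pairs get a
    partner 100-900 bp away); background sites fill the rest of the two
    chromosomes by rejection sampling, at least 2000 bp from any informative
    site.
    """
    n_inf = cfg.n_informative_hyper + cfg.n_informative_hypo
    n_pairs = int(round(cfg.cluster_fraction * n_inf)) // 2
    n_isolated = n_inf - 2 * n_pairs
    n_units = n_pairs + n_isolated
    n_background = cfg.n_sites - n_inf

    lattice = []
    for ci, _ in enumerate(cfg.chromosomes):
        pts = np.arange(_LATTICE_STEP, cfg.chromosome_length - _LATTICE_STEP,
                        _LATTICE_STEP, dtype=np.int64)
        lattice.append(np.stack([np.full(pts.size, ci, dtype=np.int64), pts], axis=1))
    lattice = np.concatenate(lattice) if lattice else np.empty((0, 2), dtype=np.int64)
    if n_units > len(lattice):
        raise DataError(
            f"cannot place {n_units} informative units on "
            f"{len(lattice)} lattice anchors; enlarge the chromosomes"
        )
    anchors = lattice[rng.choice(len(lattice), size=n_units, replace=False)]

    inf_chrom = [anchors[:, 0]]
    inf_pos = [anchors[:, 1]]
    if n_pairs > 0:
        lo, hi = cfg.cluster_spacing
        offsets = rng.integers(lo, hi + 1, size=n_pairs)
        inf_chrom.append(anchors[:n_pairs, 0])
        inf_pos.append(anchors[:n_pairs, 1] + offsets)
    inf_chrom = np.concatenate(inf_chrom)
    inf_pos = np.concatenate(inf_pos)

    # background: uniform, rejected within 2000 bp of informative sites
    bg_chrom_list, bg_pos_list = [], []
    taken = {ci: np.sort(inf_pos[inf_chrom == ci]) for ci in range(len(cfg.chromosomes))}
    seen = set(zip(inf_chrom.tolist(), inf_pos.tolist()))
    need = n_background
    attempts = 0
    while need > 0:
        attempts += 1
        if attempts > 200:
            raise DataError("cannot place background sites; chromosome too crowded")
        ci = rng.integers(0, len(cfg.chromosomes), size=2 * need)
        pos = rng.integers(1, cfg.chromosome_length, size=2 * need)
        for c, p in zip(ci, pos):
            if need == 0:
                break
            t = taken[int(c)]
            j = np.searchsorted(t, p)
            near = False
            if j < len(t) and t[j] - p < _ISOLATION_BP:
                near = True
            if j > 0 and p - t[j - 1] < _ISOLATION_BP:
                near = True
            if near or (int(c), int(p)) in seen:
                continue
            seen.add((int(c), int(p)))
            bg_chrom_list.append(int(c))
            bg_pos_list.append(int(p))
            need -= 1

    chrom_idx = np.concatenate([inf_chrom, np.asarray(bg_chrom_list, dtype=np.int64)])
    pos = np.concatenate([inf_pos, np.asarray(bg_pos_list, dtype=np.int64)])
    labels = np.array(
        ["informative"] * n_inf + ["background"] * n_background, dtype=object
    )
    return chrom_idx, pos, labels


def simulate_cohort(cfg: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate a paired cohort, its annotation, design and truth table."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    chrom_idx, pos, labels = _place_sites(cfg, rng)
    n_sites = cfg.n_sites
    n_inf = cfg.n_informative_hyper + cfg.n_informative_hypo

    # hyper/hypo assignment among informative sites
    directions = np.array(
        ["informative_hyper"] * cfg.n_informative_hyper
        + ["informative_hypo"] * cfg.n_informative_hypo, dtype=object,
    )
    rng.shuffle(directions)
    labels = labels.copy()
    labels[:n_inf] = directions

    # per-site generative means
    mu_normal = rng.uniform(*cfg.background_mean_range, size=n_sites)
    mu_tumor = mu_normal.copy()
    hyper = labels == "informative_hyper"
    hypo = labels == "informative_hypo"
    mu_normal[hyper] = rng.uniform(*cfg.hyper_normal_mean_range, size=int(hyper.sum()))
    mu_tumor[hyper] = rng.uniform(*cfg.hyper_tumor_mean_range, size=int(hyper.sum()))
    mu_normal[hypo] = 1.0 - rng.uniform(*cfg.hyper_normal_mean_range, size=int(hypo.sum()))
    mu_tumor[hypo] = 1.0 - rng.uniform(*cfg.hyper_tumor_mean_range, size=int(hypo.sum()))

    # per-patient purity
    if isinstance(cfg.purity, tuple):
        purities = rng.uniform(cfg.purity[0], cfg.purity[1], size=cfg.n_patients)
    else:
        purities = np.asarray(cfg.purity, dtype=float)
        if purities.size != cfg.n_patients:
            raise ValueError("explicit purity list length must equal n_patients")

    kappa = cfg.noise_precision
    mu_mix = purities[None, :] * mu_tumor[:, None] + (1.0 - purities[None, :]) * mu_normal[:, None]
    a_mix, b_mix = mu_mix * kappa, (1.0 - mu_mix) * kappa
    a_n, b_n = mu_normal * kappa, (1.0 - mu_normal) * kappa
    if cfg.common_noise:
        # one uniform deviate per site drives every patient's tumor draw, so
        # tumor columns differ only through purity; normals stay independent
        u_t = rng.uniform(size=n_sites)
        tumor = stats.beta.ppf(u_t[:, None], a_mix, b_mix)
    else:
        tumor = rng.beta(a_mix, b_mix)
    normal = rng.beta(a_n[:, None], b_n[:, None], size=(n_sites, cfg.n_patients))
    tumor = np.clip(tumor, _EPS, 1.0 - _EPS)
    normal = np.clip(normal, _EPS, 1.0 - _EPS)

    # assemble in genomic order for tidy outputs
    order = np.lexsort((pos, chrom_idx))
    width = len(str(n_sites))
    site_ids = np.array([f"cg{i + 1:0{width}d}" for i in range(n_sites)], dtype=object)
    chroms = np.asarray(cfg.chromosomes, dtype=object)[chrom_idx[order]]

    patients = [f"P{j + 1:02d}" for j in range(cfg.n_patients)]
    tumor_ids = [f"{p}-T" for p in patients]
    normal_ids = [f"{p}-N" for p in patients]
    beta = pd.DataFrame(
        np.concatenate([tumor[order], normal[order]], axis=1),
        index=pd.Index(site_ids, name="site_id"),
        columns=tumor_ids + normal_ids,
    )
    annotation = pd.DataFrame(
        {"chromosome": chroms, "position": pos[order]},
        index=pd.Index(site_ids, name="site_id"),
    )
    design = pd.DataFrame(
        {"patient_id": patients, "tumor_sample_id": tumor_ids,
         "normal_sample_id": normal_ids}
    )
    truth = TruthTable(
        purity=pd.Series(purities, index=tumor_ids, name="purity"),
        sites=pd.DataFrame(
            {"label": labels[order], "mu_normal": mu_normal[order],
             "mu_tumor_pure": mu_tumor[order]},
            index=pd.Index(site_ids, name="site_id"),
        ),
        patients=pd.DataFrame(
            {"patient_id": patients, "tumor_sample_id": tumor_ids,
             "normal_sample_id": normal_ids, "purity": purities}
        ),
    )
    return SimulatedCohort(beta=beta, annotation=annotation, design=design,
                           truth=truth, config=cfg)


def evaluate_recovery(estimates: pd.DataFrame, truth: TruthTable) -> dict:
    """Score estimated purities against the truth table.

    ``estimates`` is the frame produced by purity estimation (columns
    sample_id, purity).  The estimate and truth sample-id sets must match
    exactly; rows are aligned by id.  Returns mean absolute error, bias
    (mean signed error) and the per-sample table.
    """
    est = estimates.set_index("sample_id")["purity"]
    if set(est.index) != set(truth.purity.index):
        raise DataError("estimate sample ids do not match the truth table")
    true = truth.purity.loc[est.index]
    err = est - true
    table = pd.DataFrame(
        {"true_purity": true, "estimated_purity": est, "error": err}
    )
    return {
        "mae": float(err.abs().mean()),
        "bias": float(err.mean()),
        "table": table,
    }


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the TSV inputs the tool reads, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "annotation": outdir / "annotation.tsv",
        "design": outdir / "design.tsv",
        "truth_purity": outdir / "truth_purity.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_annotation(cohort.annotation, paths["annotation"])
    cohort.design.to_csv(paths["design"], sep="\t", index=False)
    cohort.truth.patients.to_csv(paths["truth_purity"], sep="\t", index=False)
    cohort.truth.sites.to_csv(paths["truth_sites"], sep="\t", index_label="site_id")
    return paths
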