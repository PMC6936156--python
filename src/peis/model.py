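"""Model/Results interface tying the two-stage purity workflow together.

:class:`PeisModel` holds a cohort (beta matrix, CpG annotation, tumor/normal
pairing) plus the method settings; :meth:`PeisModel.fit` runs QC, per-site
signal scoring, neighbor correction, informative-site selection and
per-sample kernel-density purity estimation, returning a
:class:`PeisResults` that carries every intermediate table and a
``summary()`` report.

>>> from peis import PeisModel, simulate_cohort
>>> cohort = simulate_cohort(n_sites=2000, n_informative_hyper=100,
...                          n_informative_hypo=100, seed=7)
>>> res = PeisModel(cohort.beta, cohort.annotation, cohort.design, k=200).fit()
>>> res.purity["purity"].between(0, 1).all()
True
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, purity, scoring, selection
from .errors import DataError

__all__ = ["PeisModel", "PeisResults"]

SELECTORS = ("peis", "ttest", "f_and_t")


class PeisModel:
    """Tumor-purity estimator for a paired tumor/normal methylation cohort.

    Parameters
    ----------
    beta : DataFrame
        Beta-value matrix, sites x samples, values in [0, 1] or NaN.
    annotation : DataFrame
        Indexed by site_id with columns ``chromosome`` and ``position``
        (1-based).
    design : DataFrame
        Columns patient_id, tumor_sample_id, normal_sample_id.
    window_bp, k, neighbor_mode, ranking
        Stage-2 settings: neighbor window (strict, bp), informative-set
        size, ``two_nearest``/``all_in_window`` neighbor mode and
        ``absolute``/``signed`` ranking.
    selector : {"peis", "ttest", "f_and_t"}
        Informative-site selector; the latter two are hypothesis-test-only
        baselines.
    lambda_pairing : {"variance", "literal"}
        Which signal the lambda weight multiplies when merging the mean and
        variance quantile signals.
    bandwidth : str or float
        KDE bandwidth rule ("silverman"/"scott") or a fixed kernel sd.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        annotation: pd.DataFrame,
        design: pd.DataFrame,
        *,
        window_bp: int = 1000,
        k: int = 1000,
        neighbor_mode: str = "two_nearest",
        ranking: str = "absolute",
        selector: str = "peis",
        lambda_pairing: str = "variance",
        bandwidth: str | float = "silverman",
        drop_sex_chromosomes: bool = True,
        max_missing_fraction: float = 0.2,
        min_sites: int = purity.DEFAULT_MIN_SITES,
        grid_size: int = purity.DEFAULT_GRID_SIZE,
    ) -> None:
        if selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}, got {selector!r}")
        self.beta = beta
        self.annotation = annotation
        self.design = design
        self.window_bp = window_bp
        self.k = k
        self.neighbor_mode = neighbor_mode
        self.ranking = ranking
        self.selector = selector
        self.lambda_pairing = lambda_pairing
        self.bandwidth = bandwidth
        self.drop_sex_chromosomes = drop_sex_chromosomes
        self.max_missing_fraction = max_missing_fraction
        self.min_sites = min_sites
        self.grid_size = grid_size

    @classmethod
    def from_files(
        cls,
        beta_path: str | Path,
        annotation_path: str | Path,
        design_path: str | Path,
        **kwargs,
    ) -> "PeisModel":
        """Build a model straight from the TSV/CSV/BED inputs."""
        return cls(
            io.read_beta_matrix(beta_path),
            io.read_annotation(annotation_path),
            io.read_design(design_path),
            **kwargs,
        )

    def fit(self) -> "PeisResults":
        """Run the full two-stage workflow and return the results."""
        filtered = io.qc_filter(
            self.beta,
            self.annotation,
            drop_sex_chromosomes=self.drop_sex_chromosomes,
            max_missing_fraction=self.max_missing_fraction,
        )
        paired = io.align_pairs(filtered, self.design)

        if self.selector == "peis":
            signals = scoring.score_all_sites(paired, lambda_pairing=self.lambda_pairing)
            final = selection.finalize_scores(
                signals, self.annotation, window=self.window_bp,
                neighbor_mode=self.neighbor_mode,
            )
            informative = selection.select_top(final, k=self.k, ranking=self.ranking)
        elif self.selector == "ttest":
            signals = scoring.score_all_sites(paired, lambda_pairing=self.lambda_pairing)
            final = None
            informative = selection.select_ttest_only(paired, self.annotation, k=self.k)
        else:
            signals = scoring.score_all_sites(paired, lambda_pairing=self.lambda_pairing)
            final = None
            informative = selection.select_f_and_t(paired, self.annotation, k=self.k)
        if informative.empty:
            raise DataError("informative site set is empty")

        tumor_ids = [s for s in self.design["tumor_sample_id"].dropna()
                     if s in filtered.columns]
        tumor_beta = filtered[tumor_ids]
        purities = purity.estimate_cohort(
            tumor_beta, informative, bandwidth=self.bandwidth,
            grid_size=self.grid_size, min_sites=self.min_sites,
        )
        return PeisResults(
            model=self,
            paired=paired,
            site_signals=signals,
            final_scores=final,
            informative_sites=informative,
            purity=purities,
        )


@dataclass
class PeisResults:
    """Fitted two-stage results: per-site tables and per-sample purities."""

    model: PeisModel = field(repr=False)
    paired: io.PairedBeta = field(repr=False)
    site_signals: pd.DataFrame = field(repr=False)
    final_scores: pd.DataFrame | None = field(repr=False)
    informative_sites: pd.DataFrame
    purity: pd.DataFrame

    @property
    def n_testable_sites(self) -> int:
        return int(self.site_signals["testable"].sum())

    def summary(self) -> str:
        """Plain-text report of the fit: cohort shape, selection and purities."""
        m = self.model
        pur = self.purity["purity"]
        lines = [
            "PEIS tumor-purity estimation",
            "=" * 60,
            f"Patients (pairs):        {self.paired.n_patients}",
            f"Sites tested:            {len(self.site_signals)}",
            f"Sites testable:          {self.n_testable_sites}",
            f"Selector:                {m.selector}",
            f"Informative sites (k):   {len(self.informative_sites)}",
            f"  hyper-methylated:      {(self.informative_sites['direction'] == 'hyper').sum()}",
            f"  hypo-methylated:       {(self.informative_sites['direction'] == 'hypo').sum()}",
            f"Neighbor window:         {m.window_bp} bp ({m.neighbor_mode})",
            f"KDE bandwidth:           {m.bandwidth}",
            "-" * 60,
            f"Purity: mean {pur.mean():.3f}  median {pur.median():.3f}  "
            f"range [{pur.min():.3f}, {pur.max():.3f}]  (n = {len(pur)})",
            "-" * 60,
            self.purity.to_string(index=False,
                                  float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    def sample_density(self, sample_id: str) -> purity.PurityEstimate:
        """Re-estimate one sample keeping the full density grid for plotting."""
        present = self.informative_sites.index.intersection(self.model.beta.index)
        betas = self.model.beta.loc[present, sample_id].to_numpy(dtype=float)
        directions = self.informative_sites.loc[present, "direction"].to_numpy()
        ok = ~np.isnan(betas)
        values = purity.transform_betas(betas[ok], directions[ok])
        return purity.estimate_purity(
            values, bandwidth=self.model.bandwidth, grid_size=self.model.grid_size,
            min_sites=self.model.min_sites, sample_id=sample_id, keep_density=True,
        )

    def plot_density(self, sample_id: str, ax=None):
        """Plot a sample's transformed-beta KDE with the purity mode marked."""
        import matplotlib.pyplot as plt

        est = self.sample_density(sample_id)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(est.grid, est.density, lw=1.5)
        ax.axvline(est.purity, color="crimson", ls="--",
                   label=f"purity = {est.purity:.3f}")
        ax.set_xlabel("transformed beta")
        ax.set_ylabel("density")
        ax.set_title(f"{sample_id} ({est.n_sites_used} informative sites)")
        ax.legend()
        return ax

    def to_tsv(self, outdir: str | Path) -> dict[str, Path]:
        """Write the signal, informative-site and purity tables as TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "signals": outdir / "site_signals.tsv",
            "informative_tsv": outdir / "informative_sites.tsv",
            "informative_bed": outdir / "informative_sites.bed",
            "purity": outdir / "purity.tsv",
        }
        scoring.write_signal_table(self.site_signals, paths["signals"])
        selection.write_informative_tsv(self.informative_sites, paths["informative_tsv"])
        selection.write_informative_bed(self.informative_sites, paths["informative_bed"])
        self.purity.to_csv(paths["purity"], sep="\t", index=False)
        return paths
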