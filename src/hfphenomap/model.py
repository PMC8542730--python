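"""Model/Results interface to the full phenotype-clustering analysis.

:class:`PhenomapModel` is built from a patient-level DataFrame (or CSV) and
holds the analysis configuration; ``fit()`` runs eligibility exclusions,
complete-case filtering, rhythm stratification, feature encoding, embedding,
gap-statistic model selection and per-cluster treatment-effect estimation,
returning a :class:`PhenomapResults` that carries the selected clustering,
its diagnostics and the effect table, with stability validation, LOTO
validation, cluster profiling and radar plotting as methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import prep
from .cluster import (
    GapResult,
    ClusterSolution,
    canonicalise_by_risk,
    cluster_profile,
    select_model,
)
from .effects import cluster_effect_table
from .embed import EmbeddingPipeline, VaeConfig
from .loto import LotoResult, leave_one_trial_out
from .stability import StabilityResult, bootstrap_stability

__all__ = ["PhenomapModel", "PhenomapResults"]


class PhenomapModel:
    """Phenotype clustering of one rhythm stratum of a pooled trial cohort.

    Parameters
    ----------
    data:
        Patient-level table (one row per randomised participant) with the
        raw columns produced by the cohort generator / loader.
    stratum:
        ``"SR"`` or ``"AF"``.
    d_grid, k_grid:
        Candidate latent dimensions and cluster numbers for the
        gap-statistic sweep.
    method:
        ``"hierarchical"`` (Ward, the primary backend) or ``"kmeanspp"``.
    embedding:
        ``"vae"`` or ``"pca"``.
    B:
        Number of reference datasets per gap evaluation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        stratum: str = "SR",
        d_grid: Sequence[int] = tuple(range(2, 13)),
        k_grid: Sequence[int] = tuple(range(2, 11)),
        method: str = "hierarchical",
        embedding: str = "vae",
        vae_config: VaeConfig | None = None,
        B: int = 50,
    ):
        if stratum not in ("SR", "AF"):
            raise ValueError("stratum must be 'SR' or 'AF'")
        self.data = data
        self.stratum = stratum
        self.d_grid = list(d_grid)
        self.k_grid = list(k_grid)
        self.method = method
        self.embedding_source = embedding
        self.vae_config = vae_config
        self.B = B

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PhenomapModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, seed: int = 0) -> "PhenomapResults":
        table, X, report = prep.prepare_stratum(self.data, self.stratum)
        template = EmbeddingPipeline(
            source=self.embedding_source,
            d=self.d_grid[0],
            config=self.vae_config,
        )
        gap_result, solution, pipeline, emb = select_model(
            X,
            self.d_grid,
            self.k_grid,
            method=self.method,
            B=self.B,
            seed=seed,
            embedding=template,
        )
        labels, order = canonicalise_by_risk(
            solution.labels, table["death"].to_numpy()
        )
        solution.labels = labels
        solution.centroids = solution.centroids[order]
        names = {i: f"{self.stratum}{i + 1}" for i in range(solution.k)}
        effects = cluster_effect_table(table, labels, cluster_names=names)
        return PhenomapResults(
            model=self,
            seed=seed,
            table=table,
            features=X,
            embedding=emb,
            pipeline=pipeline,
            gap_result=gap_result,
            solution=solution,
            cluster_names=names,
            effects_=effects,
            prep_report=report,
        )


@dataclass
class PhenomapResults:
    """Fitted clustering, diagnostics and per-cluster treatment effects."""

    model: PhenomapModel
    seed: int
    table: pd.DataFrame
    features: prep.FeatureMatrix
    embedding: object
    pipeline: EmbeddingPipeline
    gap_result: GapResult
    solution: ClusterSolution
    cluster_names: dict
    effects_: pd.DataFrame
    prep_report: dict
    stability_: StabilityResult | None = None
    loto_: LotoResult | None = None

    @property
    def labels_(self) -> np.ndarray:
        return self.solution.labels

    @property
    def d_(self) -> int:
        return self.gap_result.best[0]

    @property
    def k_(self) -> int:
        return self.gap_result.best[1]

    # ------------------------------------------------------------ validation

    def bootstrap_stability(
        self, n_boot: int = 100, frac: float = 0.8, seed: int | None = None,
        refit_embedding: bool = True,
    ) -> StabilityResult:
        """Bootstrap weighted-Jaccard stability at the selected (d*, k*)."""
        self.stability_ = bootstrap_stability(
            self.features,
            self.labels_,
            d=self.d_,
            k=self.k_,
            method=self.solution.method,
            embedding=self.pipeline.clone(),
            fitted_pipeline=self.pipeline,
            n_boot=n_boot,
            frac=frac,
            seed=self.seed + 1 if seed is None else seed,
            refit_embedding=refit_embedding,
        )
        return self.stability_

    def leave_one_trial_out(
        self, seed: int | None = None, n_perm: int = 1000
    ) -> LotoResult:
        """Leave-one-trial-out external validation at the selected (d*, k*)."""
        self.loto_ = leave_one_trial_out(
            self.table,
            d=self.d_,
            k=self.k_,
            method=self.solution.method,
            embedding=self.pipeline.clone(),
            full_labels=self.labels_,
            seed=self.seed + 2 if seed is None else seed,
            n_perm=n_perm,
        )
        return self.loto_

    # ------------------------------------------------------------- reporting

    def cluster_profiles(self) -> pd.DataFrame:
        """Radar-plot profile table (cluster medians scaled to cohort)."""
        prof = cluster_profile(self.table, self.labels_)
        prof["cluster"] = prof["cluster"].map(self.cluster_names)
        return prof

    def plot_radar(self, outdir=None):
        """Render one radar figure per cluster; see :mod:`hfphenomap.plotting`."""
        from .plotting import render_radar

        return render_radar(self.cluster_profiles(), outdir=outdir)

    def summary(self) -> str:
        g = self.gap_result
        lines = [
            "Phenotype clustering of beta-blocker trial cohort",
            "=" * 58,
            f"Stratum: {self.model.stratum}    patients: {len(self.table)}",
            f"Embedding: {self.model.embedding_source}    "
            f"clustering: {self.solution.method}",
            f"Selected latent dimension d* = {self.d_}, clusters k* = {self.k_}"
            f"  (gap = {g.best_gap():.3f}, B = {g.B})",
        ]
        if g.weak_structure:
            lines.append("WARNING: weak structure — max gap within 2 SE of "
                         "the smallest-k gap")
        idx = self.solution.internal_indices
        if idx:
            lines.append(
                "Internal indices: silhouette={silhouette:.3f}  "
                "Calinski-Harabasz={calinski_harabasz:.1f}  "
                "Davies-Bouldin={davies_bouldin:.3f}".format(**idx)
            )
        lines.append("")
        lines.append("Per-cluster all-cause mortality (intention to treat):")
        cols = ["cluster", "deaths_placebo", "n_placebo", "deaths_bb", "n_bb",
                "or", "or_lo", "or_hi", "p_value", "nnt"]
        show = self.effects_[[c for c in cols if c in self.effects_.columns]]
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(show.to_string(index=False))
        if self.stability_ is not None:
            s = self.stability_
            lines.append(
                f"\nBootstrap stability: mean weighted Jaccard "
                f"{s.mean:.3f} (SD {s.sd:.3f}) vs random {s.random_mean:.3f} "
                f"(SD {s.random_sd:.3f}); KS p = {s.ks_p:.2g}"
            )
        if self.loto_ is not None:
            l = self.loto_
            lines.append(
                f"LOTO validation: iteration ARI {l.mean_ari_iteration:.3f} "
                f"(SD {l.sd_ari_iteration:.3f}); prediction ARI "
                f"{l.mean_ari_prediction:.3f} (SD {l.sd_ari_prediction:.3f}); "
                f"permutation p = {l.permutation_p:.4f}"
            )
        return "\n".join(lines)
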