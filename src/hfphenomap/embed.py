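"""Dimensionality reduction of the encoded feature matrix.

Two backends behind one interface: the mixed-likelihood VAE (nonlinear,
per-column gaussian/bernoulli likelihoods) and a linear PCA baseline.
Clustering always consumes deterministic coordinates — VAE posterior means
or PCA scores — never latent samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .prep import FeatureMatrix
from .vae import MixedVae, VaeConfig

__all__ = ["Embedding", "EmbeddingPipeline", "fit_vae", "encode_mean", "fit_pca",
           "VaeConfig"]


@dataclass
class Embedding:
    """Per-patient latent coordinates of dimension d."""

    coords: np.ndarray
    source: str  # "vae" | "pca"
    d: int
    training_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")
        if self.coords.shape[1] != self.d:
            raise ValueError("coords width does not match d")


def fit_vae(X: FeatureMatrix, config: VaeConfig) -> MixedVae:
    """Train the VAE on a complete, standardised feature matrix."""
    kinds = [k for _, k in X.schema]
    model = MixedVae(kinds, config)
    model.fit(X.values)
    return model


def encode_mean(embedder: MixedVae, X: FeatureMatrix) -> Embedding:
    """Posterior-mean coordinates for ``X`` under a fitted VAE."""
    if X.p != embedder.p:
        raise ValueError(
            f"feature matrix has {X.p} columns, embedder expects {embedder.p}"
        )
    coords = embedder.encode_mean(X.values)
    return Embedding(
        coords=coords,
        source="vae",
        d=embedder.config.latent_dim,
        training_log=list(embedder.training_log),
    )


class _PcaEmbedder:
    """Thin PCA wrapper with a fixed sign convention (largest-magnitude
    loading positive per component)."""

    def __init__(self, d: int):
        self.d = d
        self._pca = PCA(n_components=d, svd_solver="full")
        self._signs: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "_PcaEmbedder":
        n, p = values.shape
        rank = min(n - 1 if n > 1 else 1, p)
        if self.d > rank:
            raise ValueError(f"d={self.d} exceeds data rank {rank}")
        self._pca.fit(values)
        comp = self._pca.components_
        flip_idx = np.argmax(np.abs(comp), axis=1)
        self._signs = np.sign(comp[np.arange(len(comp)), flip_idx])
        self._signs[self._signs == 0] = 1.0
        return self

    def encode_mean(self, values: np.ndarray) -> np.ndarray:
        return self._pca.transform(values) * self._signs

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_


def fit_pca(X: FeatureMatrix, d: int) -> Embedding:
    """First ``d`` principal-component scores of the feature matrix."""
    emb = _PcaEmbedder(d).fit(X.values)
    return Embedding(coords=emb.encode_mean(X.values), source="pca", d=d)


class EmbeddingPipeline:
    """Fit-and-transform facade used by model selection, the bootstrap and
    leave-one-trial-out validation.

    ``source`` chooses the backend ("vae" or "pca"); ``d`` the latent
    dimension.  ``fit`` trains on a FeatureMatrix with a given seed (the seed
    is ignored by PCA, which is deterministic); ``transform`` maps any
    schema-compatible FeatureMatrix into the fitted latent space.
    """

    def __init__(self, source: str = "vae", d: int = 9,
                 config: VaeConfig | None = None):
        if source not in ("vae", "pca"):
            raise ValueError(f"unknown embedding source {source!r}")
        self.source = source
        self.d = d
        self.config = config
        self._embedder = None

    def clone(self, d: int | None = None) -> "EmbeddingPipeline":
        d = self.d if d is None else d
        cfg = self.config
        if cfg is not None:
            cfg = VaeConfig(**{**cfg.__dict__, "latent_dim": d})
        return EmbeddingPipeline(self.source, d, cfg)

    def fit(self, X: FeatureMatrix, seed: int = 0) -> Embedding:
        if self.source == "pca":
            self._embedder = _PcaEmbedder(self.d).fit(X.values)
            return Embedding(coords=self._embedder.encode_mean(X.values),
                             source="pca", d=self.d)
        cfg = self.config or VaeConfig()
        cfg = VaeConfig(**{**cfg.__dict__, "latent_dim": self.d, "seed": seed})
        self._embedder = MixedVae([k for _, k in X.schema], cfg).fit(X.values)
        return encode_mean(self._embedder, X)

    def transform(self, X: FeatureMatrix) -> np.ndarray:
        if self._embedder is None:
            raise RuntimeError("pipeline is not fitted")
        return self._embedder.encode_mean(X.values)
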