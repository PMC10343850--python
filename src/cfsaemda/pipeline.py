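"""End-to-end pipeline: stacked-autoencoder compression + cascade forest.

Features are standardized (zero mean, unit variance per column, fitted on the
training data) before autoencoder training.  This weights every feature
equally in the reconstruction objective — without it the objective is
dominated by the high-variance similarity blocks and the codes discard the
low-variance adjacency structure that carries most of the association signal.

The standardizer and the autoencoder stack are fitted on the training
features only; any later data is transformed with the frozen pair before
cascade prediction, so the compression step never sees evaluation samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import CascadeConfig, CascadeModel, fit_cascade, predict_proba
from .sae import EncoderStack, encode, fit_sae

__all__ = ["SAEConfig", "PipelineConfig", "FittedPipeline", "fit_pipeline", "pipeline_scores"]


@dataclass
class SAEConfig:
    dims: tuple[int, ...] = (1024, 512, 256)
    epochs: int = 100
    batch: int = 128
    lr: float = 1e-3


@dataclass
class PipelineConfig:
    """Hyperparameters of both stages plus the single run seed."""

    sae: SAEConfig = field(default_factory=SAEConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    seed: int = 0


@dataclass
class FittedPipeline:
    stack: EncoderStack
    model: CascadeModel
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize with the frozen training statistics, then encode."""
        X = np.asarray(X, dtype=float)
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        return encode(self.stack, X)


def fit_pipeline(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig, seed_offset: int = 0
) -> FittedPipeline:
    """Standardize X, fit the autoencoder, then the cascade on the codes.

    ``seed_offset`` lets protocol drivers (e.g. CV folds) derive distinct but
    reproducible seeds from the one configured seed.
    """
    seed = config.seed + 104729 * seed_offset
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through centred
    Xs = (X - mean) / scale
    batch = min(config.sae.batch, Xs.shape[0])
    stack = fit_sae(
        Xs,
        dims=config.sae.dims,
        epochs=config.sae.epochs,
        batch=batch,
        lr=config.sae.lr,
        seed=seed,
    )
    Z = encode(stack, Xs)
    cascade_cfg = CascadeConfig(**{**config.cascade.__dict__, "seed": seed})
    model = fit_cascade(Z, y, cascade_cfg)
    return FittedPipeline(stack=stack, model=model, feature_mean=mean, feature_scale=scale)


def pipeline_scores(fitted: FittedPipeline, X: np.ndarray) -> np.ndarray:
    """Scores in [0,1] for new feature rows."""
    return predict_proba(fitted.model, fitted.transform(X))
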