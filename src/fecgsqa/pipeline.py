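"""End-to-end orchestration of the quality-assessment pipeline.

Glue over the library modules: synthesize a labeled dataset, preprocess,
render spectrograms, train the autoencoder on high-quality images only,
extract the 12 features, select the top 5 by MCFS, balance, train and
label the SOM, classify and report.  The train = test protocol is the
unsupervised-clustering evaluation convention.

Desk-scale defaults (64x64 spectrograms, a modest number of autoencoder
epochs) keep a full run tractable on one CPU; the layer stack and all
statistical machinery are identical at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (ClassificationReport, classification_report,
                       fhr_improvement_experiment)
from .feature_select import MCFSResult, mcfs_scores, select_top
from .features import EntropyParams, build_feature_matrix
from .preprocess import make_spectrogram
from .som_classifier import (SOMModel, balance_dataset, classify,
                             label_neurons, train_som)
from .spectrogram_ae import AEArchitecture, AEModel, ae_mse_batch, build_ae, train_ae
from .synthetic_fecg import QualityLevel, generate_mixed_recording, \
    generate_quality_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_quality_pipeline",
           "run_fhr_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of a full pipeline run."""

    n_per_class: int = 271
    seed: int = 0
    image_size: int = 64          # desk-scale; 128 at full scale
    ae_epochs: int = 8
    ae_batch_size: int = 64
    ae_learning_rate: float = 1e-3
    top_k: int = 5
    som_grid: tuple = (8, 8)
    som_learning_rate: float = 0.5
    som_iterations: int = 100_000
    mcfs_clusters: int = 3
    mcfs_neighbors: int = 5
    entropy_params: EntropyParams = field(default_factory=EntropyParams)


@dataclass
class PipelineResult:
    """Artifacts and metrics of one pipeline run."""

    config: PipelineConfig
    features: pd.DataFrame            # all segments x 12 features
    labels: list
    ae: AEModel
    mcfs: MCFSResult
    selected: list
    balanced_X: pd.DataFrame
    balanced_labels: list
    som: SOMModel
    predictions: list
    report: ClassificationReport


def run_quality_pipeline(config: PipelineConfig | None = None,
                         **overrides) -> PipelineResult:
    """Run the whole unsupervised quality-assessment pipeline once."""
    if config is None:
        config = PipelineConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=4)

    segments, labels = generate_quality_dataset(
        config.n_per_class, seed=int(seeds[0]))
    spectrograms = [make_spectrogram(s, size=config.image_size)
                    for s in segments]

    high_specs = [sp for sp, lab in zip(spectrograms, labels)
                  if lab == QualityLevel.HIGH]
    arch = AEArchitecture(image_size=config.image_size)
    ae = build_ae(arch, seed=int(seeds[1]))
    ae = train_ae(ae, high_specs, epochs=config.ae_epochs,
                  batch_size=config.ae_batch_size,
                  learning_rate=config.ae_learning_rate, seed=int(seeds[1]))

    X = build_feature_matrix(segments, spectrograms=None, ae=None,
                             params=config.entropy_params)
    X["AE_MSE"] = ae_mse_batch(ae, spectrograms)

    mcfs = mcfs_scores(X, n_clusters=config.mcfs_clusters,
                       n_neighbors=config.mcfs_neighbors)
    selected = select_top(mcfs, k=config.top_k)

    balanced = balance_dataset(X[selected], labels, seed=int(seeds[2]))
    som = train_som(balanced.X, grid=config.som_grid,
                    learning_rate_initial=config.som_learning_rate,
                    iterations=config.som_iterations, seed=int(seeds[3]))
    som = label_neurons(som, balanced.X, balanced.labels, seed=int(seeds[3]))

    predictions = classify(som, balanced.X)
    report = classification_report(balanced.labels, predictions)
    return PipelineResult(
        config=config, features=X, labels=labels, ae=ae, mcfs=mcfs,
        selected=selected, balanced_X=balanced.X,
        balanced_labels=balanced.labels, som=som,
        predictions=predictions, report=report)


def run_fhr_experiment(artifacts: PipelineResult, n_recordings: int = 5,
                       low_fraction: float = 0.3, seed: int = 0):
    """FHR-improvement experiment on fresh mixed-quality recordings.

    Returns ``(no_removal, with_removal, info)``; ``info`` carries the
    injected and evaluated-subset LOW fractions.
    """
    rng = np.random.default_rng(seed)
    recordings = [
        generate_mixed_recording(low_fraction=low_fraction,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)))
        for _ in range(n_recordings)]
    injected = float(np.mean([
        np.mean([lab == QualityLevel.LOW for lab in r.meta["block_labels"]])
        for r in recordings]))
    no_removal, with_removal, info = fhr_improvement_experiment(
        recordings, artifacts.som, artifacts.ae, artifacts.selected,
        entropy_params=artifacts.config.entropy_params)
    info["injected_low_fraction"] = injected
    return no_removal, with_removal, info
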