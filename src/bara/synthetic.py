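"""Synthetic multi-batch expression collections with known ground truth.

Emulates the structure of a cross-study microarray collection: several
datasets (each its own batch), two biological groups of equal size, a
minority of group-informative genes, per-gene additive batch offsets and
optional multiplicative batch factors, plus Gaussian measurement noise.

Generative model, per gene g, dataset d, sample i:

    value = (mu_g + effect * [g informative and group B] + eps) * exp(gamma_dg) + beta_dg

with mu_g ~ N(baseline_mean, baseline_sd^2) shared across datasets,
beta_dg ~ N(0, batch_shift_sd^2), gamma_dg ~ N(0, batch_scale_sd^2) and
eps ~ N(0, noise_sd^2).  All latent draws are recorded so tests can score
estimators against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import Dataset

# Default condition: 4 datasets of 2x25 samples, 2000 genes of which 100
# carry a group effect of 2 units against unit noise, additive per-gene
# batch shifts of sd 2, no multiplicative batch component.  Baselines mimic
# log2-intensity scale of processed arrays.


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_informative: int = 100
    samples_per_group: int = 25
    n_datasets: int = 4
    effect_size: float = 2.0
    batch_shift_sd: float = 2.0
    batch_scale_sd: float = 0.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_informative", "samples_per_group", "n_datasets"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_informative > self.n_genes:
            raise ParameterError("n_informative cannot exceed n_genes")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class SimulationTruth:
    """Latent parameters behind a simulated collection."""

    mu: pd.Series
    beta: pd.DataFrame  # datasets x genes, additive offsets
    gamma: pd.DataFrame  # datasets x genes, log scale factors
    informative_genes: list
    noise_free: dict = field(repr=False)  # dataset name -> samples x genes expected values


@dataclass
class SimulatedCollection:
    """List-like collection of datasets plus their generating truth."""

    datasets: list
    truth: SimulationTruth = field(repr=False)
    config: SimulationConfig = field(repr=False, default=None)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return len(self.datasets)

    def __getitem__(self, i):
        return self.datasets[i]


def simulate_collection(config: SimulationConfig | None = None, **overrides) -> SimulatedCollection:
    """Generate an annotated multi-dataset collection.

    Bit-identical for a given config (single RNG stream, fixed draw order:
    baselines, informative-gene subset, then per dataset offsets, scale
    factors and noise).
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise ParameterError("pass either a config object or keyword overrides, not both")
    rng = np.random.default_rng(np.random.SeedSequence(int(config.rng_seed)))

    genes = [f"g{j:04d}" for j in range(config.n_genes)]
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    informative = sorted(
        rng.choice(config.n_genes, size=config.n_informative, replace=False).tolist()
    )
    inf_mask = np.zeros(config.n_genes)
    inf_mask[informative] = 1.0

    n_per = config.samples_per_group
    groups = np.array(["A"] * n_per + ["B"] * n_per)
    group_effect = (groups == "B").astype(float)[:, None] * inf_mask[None, :] * config.effect_size

    datasets = []
    beta_rows, gamma_rows, noise_free = [], [], {}
    for d in range(config.n_datasets):
        name = f"d{d}"
        beta = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        gamma = rng.normal(0.0, config.batch_scale_sd, size=config.n_genes)
        eps = rng.normal(0.0, config.noise_sd, size=(2 * n_per, config.n_genes))
        signal = mu[None, :] + group_effect
        values = (signal + eps) * np.exp(gamma)[None, :] + beta[None, :]

        sample_ids = [f"{name}_s{i:03d}" for i in range(2 * n_per)]
        matrix = pd.DataFrame(values, index=sample_ids, columns=genes)
        annotations = pd.DataFrame(
            {"group": groups, "batch": name, "is_reference": False}, index=sample_ids
        )
        datasets.append(Dataset(name=name, matrix=matrix, annotations=annotations))
        beta_rows.append(pd.Series(beta, index=genes, name=name))
        gamma_rows.append(pd.Series(gamma, index=genes, name=name))
        noise_free[name] = pd.DataFrame(
            signal * np.exp(gamma)[None, :] + beta[None, :], index=sample_ids, columns=genes
        )

    truth = SimulationTruth(
        mu=pd.Series(mu, index=genes),
        beta=pd.DataFrame(beta_rows),
        gamma=pd.DataFrame(gamma_rows),
        informative_genes=[genes[j] for j in informative],
        noise_free=noise_free,
    )
    return SimulatedCollection(datasets=datasets, truth=truth, config=config)


def holdout_truth(collection: SimulatedCollection) -> SimulationTruth:
    """Latent parameter record of a simulated collection (for oracle tests)."""
    if not isinstance(collection, SimulatedCollection):
        raise ParameterError("holdout_truth expects a collection from simulate_collection")
    return collection.truth
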