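"""Generation of balanced one-way random-effects datasets.

Datasets follow Y_ij = mu + a_i + e_ij with independent cluster effects
a_i and residuals e_ij.  Two cluster-effect families are supported:

``normal``
    a_i ~ Normal(0, sigma_T^2).
``gamma``
    a_i = G - alpha*beta with G ~ Gamma(shape=alpha, scale=beta) and
    beta = sqrt(sigma_T^2 / alpha), so that Var(a_i) = alpha beta^2 =
    sigma_T^2 and E[a_i] = 0.  With the default alpha = 1.67 the effect
    distribution is markedly right-skewed (skewness 2/sqrt(alpha) ~ 1.55).
    Centering leaves every ICC estimate unchanged (location invariance)
    but keeps the overall mean truthful.

Residuals are Normal(0, sigma_e^2) in both families.  The variance
components are parameterised through the intraclass correlation:
sigma_T^2 = total_variance * rho and sigma_e^2 = total_variance * (1 - rho),
with total_variance = 1000 and mu = 10 by default, mimicking typical
reliability-study measurement scales.

Reproducibility: replicate ``r`` of a configuration with master seed ``s``
draws from ``numpy``'s ``SeedSequence(s, spawn_key=(r,))``, so replicates
form non-overlapping, order-independent substreams and a (seed,
replicate_index, config) triple always produces the identical dataset.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Literal

import numpy as np

from .anova import MeasurementTable
from .exceptions import IccError

__all__ = ["SimConfig", "gen_dataset", "draw_cluster_effects"]

Dist = Literal["normal", "gamma"]

#: Cluster-count grid used throughout the bias study.
DEFAULT_N_CLUSTERS = (10, 30, 50)
#: Observations per cluster in the bias study.
DEFAULT_CLUSTER_SIZE = 10
#: True ICC grid of the bias study.
DEFAULT_RHOS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SimConfig:
    """One simulation cell of the bias study.

    Parameters
    ----------
    n_clusters
        Number of clusters/targets n (study grid: 10, 30, 50).
    cluster_size
        Observations per cluster k (fixed at 10 in the study).
    rho
        True intraclass correlation, in [0, 1).
    total_variance
        sigma_T^2 + sigma_e^2; fixed at 1000 in the study.
    mu
        Overall mean; fixed at 10 in the study.
    dist
        Cluster-effect family, ``"normal"`` or ``"gamma"``.
    gamma_shape
        Shape alpha of the gamma effects (study value 1.67).
    reps
        Monte-Carlo replicates per cell (study value 5000).
    seed
        Master seed for the cell's random substreams.
    """

    n_clusters: int
    rho: float
    cluster_size: int = DEFAULT_CLUSTER_SIZE
    total_variance: float = 1000.0
    mu: float = 10.0
    dist: Dist = "normal"
    gamma_shape: float = 1.67
    reps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise IccError(f"need at least 2 clusters, got {self.n_clusters}")
        if self.cluster_size < 2:
            raise IccError(
                f"need at least 2 observations per cluster, got {self.cluster_size}"
            )
        if not 0.0 <= self.rho < 1.0:
            raise IccError(
                f"rho must lie in [0, 1) (rho = 1 implies sigma_e^2 = 0), got {self.rho}"
            )
        if self.total_variance <= 0:
            raise IccError(f"total_variance must be positive, got {self.total_variance}")
        if self.dist not in ("normal", "gamma"):
            raise IccError(f"unknown distribution {self.dist!r}")
        if self.gamma_shape <= 0:
            raise IccError(f"gamma_shape must be positive, got {self.gamma_shape}")
        if self.reps < 1:
            raise IccError(f"reps must be at least 1, got {self.reps}")

    @property
    def sigma2_between(self) -> float:
        """Cluster-effect variance sigma_T^2 = total_variance * rho."""
        return self.total_variance * self.rho

    @property
    def sigma2_within(self) -> float:
        """Residual variance sigma_e^2 = total_variance * (1 - rho)."""
        return self.total_variance * (1.0 - self.rho)

    @property
    def gamma_scale(self) -> float:
        """Gamma scale beta = sqrt(sigma_T^2 / alpha), so alpha beta^2 = sigma_T^2."""
        return math.sqrt(self.sigma2_between / self.gamma_shape)

    @property
    def true_F(self) -> float:
        """Population variance ratio F = rho / (1 - rho)."""
        return self.rho / (1.0 - self.rho)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def _rng_for(cfg: SimConfig, replicate_index: int) -> np.random.Generator:
    if replicate_index < 0:
        raise IccError(f"replicate_index must be non-negative, got {replicate_index}")
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(replicate_index,))
    return np.random.default_rng(ss)


def draw_cluster_effects(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` cluster effects a_i with mean 0 and variance sigma_T^2."""
    s2t = cfg.sigma2_between
    if cfg.dist == "normal":
        return rng.normal(0.0, math.sqrt(s2t), size=size)
    beta = cfg.gamma_scale
    if beta == 0.0:
        return np.zeros(size)
    return rng.gamma(cfg.gamma_shape, beta, size=size) - cfg.gamma_shape * beta

def gen_dataset(cfg: SimConfig, replicate_index: int) -> MeasurementTable:
    """Generate one balanced dataset for replicate ``replicate_index``.

    Returns a long-format table of n_clusters * cluster_size rows with
    integer cluster labels 0 .. n_clusters-1.  The output is a
    deterministic function of (cfg.seed, replicate_index, cfg); distinct
    replicate indices use independent random substreams.
    """
    rng = _rng_for(cfg, replicate_index)
    n, k = cfg.n_clusters, cfg.cluster_size
    a = draw_cluster_effects(cfg, rng, n)
    e = rng.normal(0.0, math.sqrt(cfg.sigma2_within), size=(n, k))
    y = cfg.mu + a[:, None] + e
    return MeasurementTable(
        cluster_ids=np.repeat(np.arange(n), k), values=y.ravel()
    )
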