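"""Monte-Carlo bias study of the ICC estimators.

Runs a factorial design -- cluster-effect distribution x number of
clusters x true ICC -- and reports, per cell, the Monte-Carlo mean of the
conventional estimator rho_hat, the variant rho_tilde and the
bias-corrected rho_bc, together with percent bias

    pct_bias = 100 * (mean_estimate - rho_true) / rho_true

and the Monte-Carlo standard error of each mean.  All three estimators
are evaluated on the same simulated dataset within a replicate (common
random numbers), so their comparison shares sampling noise.

The default grid is 2 distributions x {10, 30, 50} clusters x
rho in {0.1, ..., 0.9}, k = 10 observations per cluster, 5000 replicates
per cell.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anova import estimate_all
from .exceptions import IccError
from .simulate import (
    DEFAULT_CLUSTER_SIZE,
    DEFAULT_N_CLUSTERS,
    DEFAULT_RHOS,
    SimConfig,
    gen_dataset,
)

__all__ = [
    "StudyResult",
    "percent_bias",
    "run_cell",
    "run_study",
    "default_grid",
    "results_to_dataframe",
    "format_table",
    "plot_bias",
]


def percent_bias(mean_est: float, rho_true: float) -> float:
    """Percent bias 100 * (mean_est - rho_true) / rho_true; rho_true > 0."""
    if rho_true <= 0:
        raise IccError(f"percent bias undefined for rho_true = {rho_true}")
    return 100.0 * (mean_est - rho_true) / rho_true


@dataclass(frozen=True)
class StudyResult:
    """Aggregated Monte-Carlo results for one simulation cell."""

    dist: str
    n_clusters: int
    cluster_size: int
    rho_true: float
    reps: int
    mean_rho_hat: float
    mean_rho_tilde: float
    mean_rho_bc: float
    pct_bias_hat: float
    pct_bias_tilde: float
    pct_bias_bc: float
    mc_se_hat: float
    mc_se_tilde: float
    mc_se_bc: float
    n_small_F_branch: int

    def to_dict(self) -> dict:
        return asdict(self)


def run_cell(cfg: SimConfig, *, branch_threshold: float = 0.4) -> StudyResult:
    """Simulate one cell: ``cfg.reps`` datasets, all estimators on each.

    Every replicate contributes to every mean; an estimation failure in
    any replicate (possible only for measure-zero events such as SSE = 0)
    aborts the cell rather than silently dropping the replicate, which
    would bias the averages.

    Raises
    ------
    IccError
        before simulating, if the design has n(k-1) <= 4 so that the
        bias-corrected estimator is not computable.
    """
    if cfg.n_clusters * (cfg.cluster_size - 1) <= 4:
        raise IccError(
            "bias-corrected estimator not computable: design "
            f"n={cfg.n_clusters}, k={cfg.cluster_size} has n(k-1) <= 4"
        )
    if cfg.rho <= 0:
        raise IccError("bias study requires rho_true > 0 (percent bias undefined at 0)")

    rho_hat = np.empty(cfg.reps)
    rho_til = np.empty(cfg.reps)
    rho_bc = np.empty(cfg.reps)
    n_small = 0
    with warnings.catch_warnings():
        # negative F_hat draws are routine in low-rho cells; the per-dataset
        # warning is for interactive use, not for Monte-Carlo loops
        warnings.simplefilter("ignore", UserWarning)
        for r in range(cfg.reps):
            est = estimate_all(
                gen_dataset(cfg, r), branch_threshold=branch_threshold
            )
            rho_hat[r] = est.rho_hat
            rho_til[r] = est.rho_tilde
            rho_bc[r] = est.rho_bc
            n_small += est.branch_used == "small_F"

    def _se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    return StudyResult(
        dist=cfg.dist,
        n_clusters=cfg.n_clusters,
        cluster_size=cfg.cluster_size,
        rho_true=cfg.rho,
        reps=cfg.reps,
        mean_rho_hat=float(rho_hat.mean()),
        mean_rho_tilde=float(rho_til.mean()),
        mean_rho_bc=float(rho_bc.mean()),
        pct_bias_hat=percent_bias(float(rho_hat.mean()), cfg.rho),
        pct_bias_tilde=percent_bias(float(rho_til.mean()), cfg.rho),
        pct_bias_bc=percent_bias(float(rho_bc.mean()), cfg.rho),
        mc_se_hat=_se(rho_hat),
        mc_se_tilde=_se(rho_til),
        mc_se_bc=_se(rho_bc),
        n_small_F_branch=n_small,
    )


def _cell_key(cfg: SimConfig) -> str:
    return (
        f"{cfg.dist}|n={cfg.n_clusters}|k={cfg.cluster_size}|rho={cfg.rho!r}"
        f"|tv={cfg.total_variance!r}|mu={cfg.mu!r}|a={cfg.gamma_shape!r}"
        f"|reps={cfg.reps}"
    )


def _cell_seed(master_seed: int, cfg: SimConfig) -> int:
    # content-addressed substream: the same cell gets the same seed
    # regardless of its position in the grid, so shuffling the grid or
    # running cells in parallel cannot change any result
    key = zlib.crc32(_cell_key(cfg).encode())
    return int(np.random.SeedSequence(master_seed, spawn_key=(key,)).generate_state(1)[0])


def run_study(
    grid: Sequence[SimConfig],
    seed: int | None = None,
    *,
    branch_threshold: float = 0.4,
) -> list[StudyResult]:
    """Run every cell of a study grid.

    If ``seed`` is given, each cell's random substream is derived from it
    and from the cell's own parameters, so results are deterministic and
    independent of grid order; otherwise each config's own ``seed`` is
    used.  Duplicate cells are run (and warned about): with a master seed
    they reproduce identical results.
    """
    grid = list(grid)
    if not grid:
        raise IccError("empty study grid")
    keys = [_cell_key(c) for c in grid]
    if len(set(keys)) < len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        warnings.warn(f"duplicate cells in grid: {dupes}; running all", stacklevel=2)
    results = []
    for cfg in grid:
        if seed is not None:
            cfg = cfg.with_seed(_cell_seed(seed, cfg))
        results.append(run_cell(cfg, branch_threshold=branch_threshold))
    return results


def default_grid(
    dists: Iterable[str] = ("gamma", "normal"),
    n_clusters: Iterable[int] = DEFAULT_N_CLUSTERS,
    rhos: Iterable[float] = DEFAULT_RHOS,
    cluster_size: int = DEFAULT_CLUSTER_SIZE,
    reps: int = 5000,
    **kwargs,
) -> list[SimConfig]:
    """The full factorial bias-study grid (2 x 3 x 9 = 54 cells by default)."""
    return [
        SimConfig(
            n_clusters=n, rho=r, cluster_size=cluster_size, dist=d, reps=reps, **kwargs
        )
        for d in dists
        for n in n_clusters
        for r in rhos
    ]


def results_to_dataframe(results: Iterable[StudyResult]) -> pd.DataFrame:
    """Tidy frame: one row per cell, columns as in :class:`StudyResult`."""
    return pd.DataFrame([r.to_dict() for r in results])


def format_table(results: Iterable[StudyResult], dist: str) -> str:
    """Render the cells of one distribution as a fixed-width report table.

    Columns mirror the study's reporting layout: mean estimate of each
    estimator followed by its percent bias rounded to one decimal place.
    """
    rows = sorted(
        (r for r in results if r.dist == dist),
        key=lambda r: (r.n_clusters, r.rho_true),
    )
    lines = [
        f"Simulation results, {dist} cluster effects",
        f"{'Clusters':>8} {'ICC':>5} | {'rho_hat':>8} {'rho_til':>8} {'rho_bc':>8} "
        f"| {'%bias':>6} {'%bias':>6} {'%bias':>6}",
    ]
    last_n = None
    for r in rows:
        n_lbl = f"{r.n_clusters:>8}" if r.n_clusters != last_n else " " * 8
        last_n = r.n_clusters
        lines.append(
            f"{n_lbl} {r.rho_true:>5.1f} | {r.mean_rho_hat:>8.4f} "
            f"{r.mean_rho_tilde:>8.4f} {r.mean_rho_bc:>8.4f} | "
            f"{r.pct_bias_hat:>6.1f} {r.pct_bias_tilde:>6.1f} {r.pct_bias_bc:>6.1f}"
        )
    return "\n".join(lines)


def plot_bias(results: Iterable[StudyResult], path: str) -> None:
    """Plot percent bias of rho_hat and rho_bc against true rho, per distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    dists = sorted({r.dist for r in results})
    fig, axes = plt.subplots(1, len(dists), figsize=(5 * len(dists), 4), squeeze=False)
    for ax, dist in zip(axes[0], dists):
        for n in sorted({r.n_clusters for r in results if r.dist == dist}):
            rows = sorted(
                (r for r in results if r.dist == dist and r.n_clusters == n),
                key=lambda r: r.rho_true,
            )
            x = [r.rho_true for r in rows]
            ax.plot(x, [r.pct_bias_hat for r in rows], "-o", ms=3, label=f"rho_hat, n={n}")
            ax.plot(x, [r.pct_bias_bc for r in rows], "--s", ms=3, label=f"rho_bc, n={n}")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("true ICC")
        ax.set_ylabel("percent bias")
        ax.set_title(f"{dist} cluster effects")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
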