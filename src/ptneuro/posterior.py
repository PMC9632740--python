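"""Posterior analysis: solution maps, KDE intersections, Wasserstein
distances and solution rankings over pooled MCMC samples."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from .diagnostics import ChainDiagnostics
from .ptmcmc import PriorBox, SampleStore

__all__ = [
    "PooledPosterior",
    "SolutionMap",
    "GriddedKDE",
    "EmptyPosteriorError",
    "EmptyIntersectionError",
    "pool_posterior",
    "build_solution_map",
    "kde2d",
    "kde_intersection",
    "wasserstein_1d_normalized",
    "wasserstein_nd_approx",
    "count_within_pct",
    "top_k_solutions",
]


class EmptyPosteriorError(ValueError):
    """All chains were discarded; there is nothing to pool."""


class EmptyIntersectionError(ValueError):
    """KDE intersection has zero mass (disjoint supports)."""


@dataclass(frozen=True)
class PooledPosterior:
    samples: np.ndarray        # (n_pooled, n_params)
    losses: np.ndarray         # (n_pooled,)
    prior: PriorBox
    label: str = ""

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, float))
        l = np.asarray(self.losses, float)
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "losses", l)
        if s.shape[0] != l.shape[0]:
            raise ValueError("samples and losses must align")
        if s.shape[0] == 0:
            raise EmptyPosteriorError("empty posterior")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def param_names(self):
        return self.prior.names


def pool_posterior(store: SampleStore,
                   diagnostics: Sequence[ChainDiagnostics],
                   chains: str = "all",
                   label: str = "") -> PooledPosterior:
    """Concatenate post-burn-in samples of retained chains.

    ``chains`` is ``"all"`` (every retained chain, as used for solution
    maps) or ``"cold"`` (only the gamma=1 chain, the estimand posterior).
    """
    if chains not in ("all", "cold"):
        raise ValueError("chains must be 'all' or 'cold'")
    idx = range(store.n_chains) if chains == "all" else [0]
    parts, loss_parts = [], []
    for k in idx:
        d = diagnostics[k]
        if not d.retained:
            continue
        parts.append(store.samples[k, d.burn_in_index:])
        loss_parts.append(store.loss[k, d.burn_in_index:])
    if not parts:
        raise EmptyPosteriorError("all chains discarded")
    return PooledPosterior(samples=np.concatenate(parts),
                           losses=np.concatenate(loss_parts),
                           prior=store.prior, label=label)


# ---------------------------------------------------------------------------
# Solution maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolutionMap:
    """1D marginal histograms plus loss-colored 2D marginal point clouds."""

    bin_edges: np.ndarray      # (n_params, bins + 1)
    histograms: np.ndarray     # (n_params, bins), each normalized to sum 1
    samples: np.ndarray        # point cloud shared by all pair panels
    losses: np.ndarray
    truth: Optional[np.ndarray]
    param_names: tuple
    point_alpha: float = 1e-3

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def pairs(self):
        n = self.n_params
        return [(i, j) for i in range(n) for j in range(i + 1, n)]


def build_solution_map(post: PooledPosterior,
                       truth: Optional[np.ndarray] = None,
                       bins: int = 50,
                       point_alpha: float = 1e-3) -> SolutionMap:
    """Histogram the pooled posterior over the prior box.

    Histograms span the prior bounds and are normalized to unit sum; the
    2D marginals are the sample cloud itself with loss color values.
    """
    n_params = post.samples.shape[1]
    edges = np.empty((n_params, bins + 1))
    hists = np.empty((n_params, bins))
    for j in range(n_params):
        edges[j] = np.linspace(post.prior.lower[j], post.prior.upper[j],
                               bins + 1)
        counts, _ = np.histogram(post.samples[:, j], bins=edges[j])
        total = counts.sum()
        hists[j] = counts / total if total > 0 else counts
    t = None if truth is None else np.asarray(truth, float)
    return SolutionMap(bin_edges=edges, histograms=hists,
                       samples=post.samples, losses=post.losses,
                       truth=t, param_names=tuple(post.param_names),
                       point_alpha=point_alpha)


def render_solution_map(smap: SolutionMap, path) -> None:
    """Write a corner-style figure: 1D marginals on the diagonal, 2D
    loss-colored point clouds below (low loss purple/blue, high yellow)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = smap.n_params
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n))
    axes = np.atleast_2d(axes)
    order = np.argsort(smap.losses)[::-1]  # draw low-loss points on top
    alpha = max(smap.point_alpha, 1.0 / max(len(smap.losses), 1))
    for i in range(n):
        for j in range(n):
            ax = axes[i, j]
            if i == j:
                centers = 0.5 * (smap.bin_edges[i][:-1] + smap.bin_edges[i][1:])
                ax.bar(centers, smap.histograms[i],
                       width=np.diff(smap.bin_edges[i]), color="tab:blue")
                if smap.truth is not None:
                    ax.axvline(smap.truth[i], color="purple", ls="--", lw=0.8)
                ax.set_xlim(smap.bin_edges[i][0], smap.bin_edges[i][-1])
            elif i > j:
                ax.scatter(smap.samples[order, j], smap.samples[order, i],
                           c=smap.losses[order], s=2, alpha=alpha,
                           cmap="viridis")
                if smap.truth is not None:
                    ax.plot(smap.truth[j], smap.truth[i], "*",
                            color="purple", ms=8)
                ax.set_xlim(smap.bin_edges[j][0], smap.bin_edges[j][-1])
                ax.set_ylim(smap.bin_edges[i][0], smap.bin_edges[i][-1])
            else:
                ax.axis("off")
            if i == n - 1:
                ax.set_xlabel(smap.param_names[j], fontsize=7)
            if j == 0 and i > 0:
                ax.set_ylabel(smap.param_names[i], fontsize=7)
            ax.tick_params(labelsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Kernel density estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GriddedKDE:
    x: np.ndarray          # grid over parameter i (length gx)
    y: np.ndarray          # grid over parameter j (length gy)
    density: np.ndarray    # (gx, gy), nonnegative
    bandwidth: tuple       # (hx, hy)

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def mass(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.y, axis=1),
                                  self.x))


def kde2d(post: PooledPosterior, param_i: int, param_j: int,
          bandwidth_rule: str = "scott", grid_size: int = 128,
          bandwidth_floor_frac: float = 0.01) -> GriddedKDE:
    """Gaussian-kernel density of a parameter pair on the prior-bounds grid.

    Scott's rule per dimension with a floor of ``bandwidth_floor_frac``
    times the parameter range (guards degenerate, zero-variance data).
    """
    data = post.samples[:, [param_i, param_j]]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    lo = post.prior.lower[[param_i, param_j]]
    hi = post.prior.upper[[param_i, param_j]]
    n = data.shape[0]
    if bandwidth_rule != "scott":
        raise ValueError("only Scott's rule is implemented")
    scott = n ** (-1.0 / 6.0)
    h = np.maximum(scott * data.std(axis=0, ddof=1),
                   bandwidth_floor_frac * (hi - lo))
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    # separable kernel: density = (Kx @ Ky^T) / (2 pi hx hy n)
    ex = np.exp(-0.5 * ((gx[:, None] - data[None, :, 0]) / h[0]) ** 2)
    ey = np.exp(-0.5 * ((gy[:, None] - data[None, :, 1]) / h[1]) ** 2)
    dens = ex @ ey.T / (2.0 * np.pi * h[0] * h[1] * n)
    return GriddedKDE(x=gx, y=gy, density=dens, bandwidth=(h[0], h[1]))


def kde_intersection(kdes: Sequence[GriddedKDE]) -> GriddedKDE:
    """Elementwise product of KDEs on identical grids, renormalized to
    unit mass on the grid."""
    if not kdes:
        raise ValueError("need at least one KDE")
    first = kdes[0]
    prod = first.density.copy()
    for k in kdes[1:]:
        if (k.density.shape != first.density.shape
                or not np.allclose(k.x, first.x)
                or not np.allclose(k.y, first.y)):
            raise ValueError("KDE grids do not match")
        prod = prod * k.density
    mass = float(np.trapezoid(np.trapezoid(prod, first.y, axis=1), first.x))
    if mass <= 0:
        raise EmptyIntersectionError("intersection has zero mass")
    return GriddedKDE(x=first.x, y=first.y, density=prod / mass,
                      bandwidth=first.bandwidth)


# ---------------------------------------------------------------------------
# Wasserstein distances
# ---------------------------------------------------------------------------

def wasserstein_1d_normalized(samples_a, samples_b, bounds) -> float:
    """W1 between two 1-d sample sets, normalized by the bounds range."""
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("invalid bounds")
    return float(wasserstein_distance(np.asarray(samples_a, float),
                                      np.asarray(samples_b, float))
                 / (hi - lo))


def wasserstein_nd_approx(samples_a, samples_b, prior: PriorBox,
                          n_projections: int = 200, seed: int = 0) -> float:
    """Sliced-W1 approximation between multivariate sample sets.

    Coordinates are normalized to [0, 1] per the prior bounds, then the 1-d
    W1 is averaged over random unit projection directions (fixed seed, so
    the value is deterministic)."""
    a = (np.atleast_2d(samples_a) - prior.lower) / prior.width
    b = (np.atleast_2d(samples_b) - prior.lower) / prior.width
    d = a.shape[1]
    rng = np.random.Generator(np.random.PCG64(seed))
    total = 0.0
    for _ in range(n_projections):
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        total += wasserstein_distance(a @ u, b @ u)
    return float(total / n_projections)


# ---------------------------------------------------------------------------
# Solution counts and rankings
# ---------------------------------------------------------------------------

def count_within_pct(post: PooledPosterior, pct: float) -> int:
    """Number of samples whose loss is within ``pct`` percent of the best."""
    if pct < 0:
        raise ValueError("pct must be nonnegative")
    best = post.losses.min()
    return int(np.sum(post.losses <= (1.0 + pct / 100.0) * best))


def top_k_solutions(post: PooledPosterior, k: int):
    """The k lowest-loss rows, ascending by loss (ties by first occurrence).

    Returns ``(params (k, d), losses (k,))``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(post.losses, kind="stable")[:k]
    return post.samples[order], post.losses[order]
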