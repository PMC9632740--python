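"""Chain diagnostics: Geweke burn-in determination and static-chain filtering.

Burn-in is the smallest candidate index on a fixed grid for which the
Geweke z-score (mean of the first 10% of the retained segment vs the last
50%, with spectral-density variance estimates) stays below 2 in magnitude
for every parameter. Chains whose parameters all have a coefficient of
variation below a threshold after burn-in are considered static and are
dropped before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .ptmcmc import SampleStore

__all__ = [
    "ChainDiagnostics",
    "DiagnosticUnavailable",
    "DEFAULT_CV_THRESHOLD",
    "spectral_variance",
    "geweke_z",
    "geweke_burn_in",
    "chain_cv",
    "diagnose_chain",
    "diagnose_store",
    "filter_static_chains",
]

DEFAULT_CV_THRESHOLD = 1e-3
_CV_EPS = 1e-12
MIN_CHAIN_LENGTH = 20


class DiagnosticUnavailable(ValueError):
    """Raised when a chain is too short or degenerate to diagnose."""


@dataclass(frozen=True)
class ChainDiagnostics:
    burn_in_index: Optional[int]   # None: no candidate converged -> discard
    geweke_z: Optional[np.ndarray]  # per-parameter z at the chosen burn-in
    cv: Optional[np.ndarray]       # per-parameter |std/mean| post burn-in
    is_static: bool

    @property
    def retained(self) -> bool:
        return self.burn_in_index is not None and not self.is_static


def spectral_variance(x: np.ndarray) -> float:
    """Estimate of S(0)/n, the variance of the sample mean accounting for
    autocorrelation (Bartlett-windowed autocovariance sum)."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        raise DiagnosticUnavailable("segment too short")
    xc = x - x.mean()
    # cube-root lag window: small bias on near-iid segments while still
    # absorbing moderate autocorrelation
    max_lag = min(n - 1, max(1, int(round(n ** (1.0 / 3.0)))))
    acov0 = np.dot(xc, xc) / n
    s = acov0
    for lag in range(1, max_lag + 1):
        w = 1.0 - lag / (max_lag + 1)
        s += 2.0 * w * np.dot(xc[:-lag], xc[lag:]) / n
    return max(s, 0.0) / n


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for a scalar chain segment."""
    x = np.asarray(x, float)
    n = len(x)
    if n < MIN_CHAIN_LENGTH:
        raise DiagnosticUnavailable(f"chain too short (n={n})")
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    var = spectral_variance(a) + spectral_variance(b)
    if var <= 0:
        raise DiagnosticUnavailable("zero variance segment")
    return float((a.mean() - b.mean()) / np.sqrt(var))


def geweke_burn_in(samples: np.ndarray, z_cut: float = 2.0,
                   grid: Sequence[float] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25,
                                            0.3, 0.35, 0.4, 0.45, 0.5)):
    """Smallest burn-in on the candidate grid passing the Geweke test.

    ``samples`` is (n, n_params). Returns ``(burn_in_index, z_scores)``;
    ``burn_in_index`` is None when no candidate passes. Degenerate
    (constant) chains raise :class:`DiagnosticUnavailable`.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.ndim != 2:
        raise ValueError("samples must be 2-d (n, n_params)")
    n = samples.shape[0]
    if n < MIN_CHAIN_LENGTH:
        raise DiagnosticUnavailable(f"chain too short (n={n})")
    if np.allclose(samples.std(axis=0), 0.0):
        raise DiagnosticUnavailable("constant chain")
    for frac in grid:
        idx = int(frac * n)
        seg = samples[idx:]
        if len(seg) < MIN_CHAIN_LENGTH:
            break
        try:
            z = np.array([geweke_z(seg[:, j])
                          for j in range(samples.shape[1])])
        except DiagnosticUnavailable:
            continue
        if np.max(np.abs(z)) < z_cut:
            return idx, z
    return None, None


def chain_cv(samples: np.ndarray, eps: float = _CV_EPS) -> np.ndarray:
    """Per-parameter ratio of standard deviation to mean magnitude."""
    samples = np.atleast_2d(np.asarray(samples, float))
    return samples.std(axis=0) / (np.abs(samples.mean(axis=0)) + eps)


def diagnose_chain(samples: np.ndarray,
                   cv_threshold: float = DEFAULT_CV_THRESHOLD,
                   z_cut: float = 2.0) -> ChainDiagnostics:
    """Full per-chain diagnostic: burn-in, Geweke z, cv, static flag."""
    try:
        burn_in, z = geweke_burn_in(samples, z_cut=z_cut)
    except DiagnosticUnavailable:
        return ChainDiagnostics(burn_in_index=None, geweke_z=None, cv=None,
                                is_static=True)
    if burn_in is None:
        return ChainDiagnostics(burn_in_index=None, geweke_z=None, cv=None,
                                is_static=False)
    cv = chain_cv(samples[burn_in:])
    is_static = bool(np.max(cv) < cv_threshold)
    return ChainDiagnostics(burn_in_index=burn_in, geweke_z=z, cv=cv,
                            is_static=is_static)


def diagnose_store(store: SampleStore,
                   cv_threshold: float = DEFAULT_CV_THRESHOLD,
                   z_cut: float = 2.0) -> List[ChainDiagnostics]:
    return [diagnose_chain(store.samples[k], cv_threshold, z_cut)
            for k in range(store.n_chains)]


def filter_static_chains(store: SampleStore,
                         cv_threshold: float = DEFAULT_CV_THRESHOLD,
                         diagnostics: Optional[List[ChainDiagnostics]] = None
                         ) -> List[int]:
    """Indices of chains retained after burn-in and the cv filter.

    A chain is retained iff its burn-in is determined and at least one
    parameter's |std/mean| is >= the threshold (ties retain).
    """
    if diagnostics is None:
        diagnostics = diagnose_store(store, cv_threshold)
    return [k for k, d in enumerate(diagnostics) if d.retained]
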