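"""Burst-feature extraction and loss functions.

The burst loss is a weighted sum of feature mismatches between a candidate
trace and a data trace,

    E = alpha*E_f + beta*E_dc + gamma*E_mid + delta*E_sw + eta*E_lag,

with defaults alpha = beta = 1000 and gamma = delta = eta = 0 (the
mid/slow-wave/lag terms are zero-weighted hooks and not implemented).
E_f is the squared relative mismatch of inter-burst frequency; E_dc is the
squared absolute mismatch of duty cycle.

A mean-squared-error loss between aligned voltage traces is also provided
for the three-channel HH inverse problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np

from .neuron_models import VoltageTrace

__all__ = [
    "BurstSegmentation",
    "BurstFeatures",
    "LossWeights",
    "LossResult",
    "FeatureUndefined",
    "DEFAULT_BURST_THRESHOLD",
    "DEFAULT_MERGE_GAP",
    "WORST_CASE_LOSS",
    "segment_bursts",
    "burst_features",
    "trace_features",
    "loss_individual",
    "loss_between_traces",
    "loss_aggregate",
    "mse_loss",
]

DEFAULT_BURST_THRESHOLD = -35.0  # mV, on the raw trace
DEFAULT_MERGE_GAP = 100.0        # ms; sub-threshold dips shorter than this
                                 # are treated as intra-burst
WORST_CASE_LOSS = 1e6            # finite sentinel so MH ratios stay defined


class FeatureUndefined(ValueError):
    """Raised when a trace has too few complete bursts to define features."""


@dataclass(frozen=True)
class BurstSegmentation:
    """Paired burst onset/offset times from threshold crossings.

    ``up_crossings[i]`` and ``down_crossings[i]`` delimit the i-th complete
    burst; both arrays are strictly increasing and interleaved
    (up[i] < down[i] < up[i+1]).
    """

    up_crossings: np.ndarray   # ms
    down_crossings: np.ndarray  # ms
    threshold: float           # mV

    def __post_init__(self):
        up = np.asarray(self.up_crossings, float)
        dn = np.asarray(self.down_crossings, float)
        object.__setattr__(self, "up_crossings", up)
        object.__setattr__(self, "down_crossings", dn)
        if len(up) != len(dn):
            raise ValueError("up/down crossings must pair one-to-one")
        if len(up) > 0:
            merged = np.empty(2 * len(up))
            merged[0::2] = up
            merged[1::2] = dn
            if not np.all(np.diff(merged) > 0):
                raise ValueError("crossings must alternate up/down, increasing")

    @property
    def n_bursts(self) -> int:
        return len(self.up_crossings)


@dataclass(frozen=True)
class BurstFeatures:
    f_burst: float     # Hz
    duty_cycle: float  # dimensionless, in [0, 1]
    n_bursts: int

    def __post_init__(self):
        if self.f_burst < 0 or not (0.0 <= self.duty_cycle <= 1.0):
            raise ValueError("invalid burst features")


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1000.0
    beta: float = 1000.0
    gamma: float = 0.0
    delta: float = 0.0
    eta: float = 0.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.delta, self.eta) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.gamma or self.delta or self.eta:
            raise NotImplementedError(
                "mid/slow-wave/lag loss terms are zero-weighted hooks")


@dataclass(frozen=True)
class LossResult:
    e_f: float
    e_dc: float
    total: float
    valid: bool = True

    @classmethod
    def invalid(cls, sentinel: float = WORST_CASE_LOSS) -> "LossResult":
        return cls(e_f=np.nan, e_dc=np.nan, total=sentinel, valid=False)


def _interp_crossing(t0, t1, v0, v1, threshold):
    # linear interpolation of the crossing time between two samples
    return t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)


def segment_bursts(trace: VoltageTrace,
                   threshold: float = DEFAULT_BURST_THRESHOLD,
                   merge_gap: float = DEFAULT_MERGE_GAP) -> BurstSegmentation:
    """Segment a trace into complete bursts by threshold crossing.

    Crossing times are linearly interpolated. Above-threshold intervals
    separated by less than ``merge_gap`` ms are merged into a single burst
    (spikes riding on a burst plateau dip briefly below threshold).
    Incomplete leading/trailing half-bursts are trimmed.
    """
    t, v = trace.t, trace.v
    above = v >= threshold
    up_idx = np.where(~above[:-1] & above[1:])[0]
    dn_idx = np.where(above[:-1] & ~above[1:])[0]

    ups = np.array([_interp_crossing(t[i], t[i + 1], v[i], v[i + 1], threshold)
                    for i in up_idx])
    dns = np.array([_interp_crossing(t[i], t[i + 1], v[i], v[i + 1], threshold)
                    for i in dn_idx])

    # trim to complete (up, down) pairs
    if len(dns) and (not len(ups) or dns[0] < ups[0]):
        dns = dns[1:]
    n = min(len(ups), len(dns))
    ups, dns = ups[:n], dns[:n]
    if n == 0:
        return BurstSegmentation(ups, dns, threshold)

    # merge above-threshold intervals separated by short gaps
    keep_up = [ups[0]]
    keep_dn = []
    for i in range(1, n):
        if ups[i] - dns[i - 1] >= merge_gap:
            keep_dn.append(dns[i - 1])
            keep_up.append(ups[i])
    keep_dn.append(dns[-1])
    return BurstSegmentation(np.array(keep_up), np.array(keep_dn), threshold)


def burst_features(seg: BurstSegmentation) -> BurstFeatures:
    """Inter-burst frequency and duty cycle from a segmentation.

    Requires at least two burst onsets; frequency is the reciprocal of the
    mean onset-to-onset period, the duty cycle the mean fraction of each
    complete cycle spent above threshold.
    """
    if seg.n_bursts < 2:
        raise FeatureUndefined(
            f"need >= 2 complete bursts, found {seg.n_bursts}")
    periods = np.diff(seg.up_crossings)  # ms
    f_burst = 1000.0 / periods.mean()
    durations = seg.down_crossings[:-1] - seg.up_crossings[:-1]
    duty = float(np.mean(durations / periods))
    return BurstFeatures(f_burst=f_burst, duty_cycle=min(duty, 1.0),
                         n_bursts=seg.n_bursts)


def trace_features(trace: VoltageTrace,
                   threshold: float = DEFAULT_BURST_THRESHOLD,
                   merge_gap: float = DEFAULT_MERGE_GAP) -> BurstFeatures:
    """Convenience composition of segmentation and feature extraction."""
    return burst_features(segment_bursts(trace, threshold, merge_gap))


def loss_individual(candidate: BurstFeatures, data: BurstFeatures,
                    weights: LossWeights = LossWeights()) -> LossResult:
    """Burst-feature loss of a candidate against reference features."""
    if data.f_burst == 0:
        raise ValueError("reference burst frequency is zero")
    e_f = ((candidate.f_burst - data.f_burst) / data.f_burst) ** 2
    e_dc = (candidate.duty_cycle - data.duty_cycle) ** 2
    total = weights.alpha * e_f + weights.beta * e_dc
    return LossResult(e_f=e_f, e_dc=e_dc, total=total)


def loss_between_traces(candidate_trace: VoltageTrace,
                        data_trace: VoltageTrace,
                        weights: LossWeights = LossWeights(),
                        threshold: float = DEFAULT_BURST_THRESHOLD,
                        merge_gap: float = DEFAULT_MERGE_GAP,
                        sentinel: float = WORST_CASE_LOSS) -> LossResult:
    """Feature loss between two traces; invalid if the candidate has too
    few bursts. Feature extraction failing on the *data* trace is a
    configuration error and raises."""
    data_feat = trace_features(data_trace, threshold, merge_gap)
    try:
        cand_feat = trace_features(candidate_trace, threshold, merge_gap)
    except FeatureUndefined:
        return LossResult.invalid(sentinel)
    return loss_individual(cand_feat, data_feat, weights)


def loss_aggregate(individual_losses: Mapping[float, LossResult],
                   required_currents=(0.0, 0.1, 0.2, 0.3, 0.4),
                   sentinel: float = WORST_CASE_LOSS) -> LossResult:
    """Maximum of individual losses over the set of injected currents.

    ``individual_losses`` maps injected current (nA) to its LossResult.
    Any invalid individual result makes the aggregate invalid.
    """
    missing = [c for c in required_currents if c not in individual_losses]
    if missing:
        raise ValueError(f"missing currents in individual losses: {missing}")
    results = [individual_losses[c] for c in required_currents]
    if not all(r.valid for r in results):
        return LossResult.invalid(sentinel)
    worst = max(results, key=lambda r: r.total)
    return LossResult(e_f=worst.e_f, e_dc=worst.e_dc, total=worst.total)


def mse_loss(candidate_trace: VoltageTrace,
             data_trace: VoltageTrace) -> float:
    """Mean squared error between voltage traces on a shared time grid."""
    if len(candidate_trace) != len(data_trace) or not np.allclose(
            candidate_trace.t, data_trace.t, rtol=0, atol=1e-9):
        raise ValueError("traces must share the same time grid")
    diff = candidate_trace.v - data_trace.v
    return float(np.mean(diff * diff))
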