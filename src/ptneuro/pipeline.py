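"""Glue between the neuron models, loss functions and the sampler.

Builds loss closures over ground-truth bundles (mapping integration
failures and feature-undefined traces to the worst-case sentinel) and runs
the full inference pipeline end to end.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .burst_loss import (
    DEFAULT_BURST_THRESHOLD,
    DEFAULT_MERGE_GAP,
    WORST_CASE_LOSS,
    FeatureUndefined,
    LossResult,
    LossWeights,
    loss_aggregate,
    loss_individual,
    mse_loss,
    trace_features,
)
from .ground_truth import GroundTruthBundle
from .neuron_models import (
    AMFixedConstants,
    AMParameters,
    HH3Parameters,
    IntegrationFailure,
    SolverSettings,
    StimulusStep,
    simulate_am8,
    simulate_hh3,
)

__all__ = [
    "am_individual_loss",
    "am_aggregate_loss",
    "make_am_loss_fn",
    "make_hh3_loss_fn",
]


def am_individual_loss(params: AMParameters, bundle: GroundTruthBundle,
                       current: float,
                       weights: LossWeights = LossWeights(),
                       consts: AMFixedConstants = AMFixedConstants(),
                       threshold: float = DEFAULT_BURST_THRESHOLD,
                       merge_gap: float = DEFAULT_MERGE_GAP,
                       sentinel: float = WORST_CASE_LOSS) -> LossResult:
    """Burst-feature loss of a candidate at one injected current."""
    if current not in bundle.traces:
        raise ValueError(f"no ground-truth trace for current {current}")
    data_trace = bundle.trace(current)
    data_feat = trace_features(data_trace, threshold, merge_gap)
    stim = StimulusStep(i_inj=current,
                       t_total=bundle.stim_template.t_total,
                       t_discard=bundle.stim_template.t_discard)
    try:
        cand_trace = simulate_am8(params, consts, stim, bundle.settings)
        cand_feat = trace_features(cand_trace, threshold, merge_gap)
    except (IntegrationFailure, FeatureUndefined):
        return LossResult.invalid(sentinel)
    return loss_individual(cand_feat, data_feat, weights)


def am_aggregate_loss(params: AMParameters, bundle: GroundTruthBundle,
                      weights: LossWeights = LossWeights(),
                      consts: AMFixedConstants = AMFixedConstants(),
                      threshold: float = DEFAULT_BURST_THRESHOLD,
                      merge_gap: float = DEFAULT_MERGE_GAP,
                      sentinel: float = WORST_CASE_LOSS) -> LossResult:
    """Maximal individual loss over every current in the bundle."""
    individual: Dict[float, LossResult] = {}
    for current in bundle.currents:
        individual[current] = am_individual_loss(
            params, bundle, current, weights, consts, threshold, merge_gap,
            sentinel)
        if not individual[current].valid:
            return LossResult.invalid(sentinel)
    return loss_aggregate(individual, required_currents=bundle.currents,
                          sentinel=sentinel)


def make_am_loss_fn(bundle: GroundTruthBundle,
                    constraint: str = "individual",
                    current: float = 0.0,
                    weights: LossWeights = LossWeights(),
                    consts: AMFixedConstants = AMFixedConstants(),
                    threshold: float = DEFAULT_BURST_THRESHOLD,
                    merge_gap: float = DEFAULT_MERGE_GAP,
                    sentinel: float = WORST_CASE_LOSS):
    """Loss closure over a 9-vector for the sampler."""
    if constraint not in ("individual", "aggregate"):
        raise ValueError("constraint must be 'individual' or 'aggregate'")
    if constraint == "individual" and current not in bundle.traces:
        raise ValueError(f"current {current} not in ground-truth bundle")

    def loss_fn(theta: np.ndarray) -> LossResult:
        try:
            params = AMParameters.from_array(theta)
        except ValueError:
            return LossResult.invalid(sentinel)
        if constraint == "individual":
            return am_individual_loss(params, bundle, current, weights,
                                      consts, threshold, merge_gap, sentinel)
        return am_aggregate_loss(params, bundle, weights, consts, threshold,
                                 merge_gap, sentinel)

    return loss_fn


def make_hh3_loss_fn(bundle: GroundTruthBundle,
                     sentinel: float = WORST_CASE_LOSS,
                     template: Optional[HH3Parameters] = None):
    """MSE loss closure over (g_na, g_k) against the HH3 data trace."""
    current = bundle.currents[0]
    data_trace = bundle.trace(current)
    tmpl = template or bundle.true_params

    def loss_fn(theta: np.ndarray) -> LossResult:
        g_na, g_k = float(theta[0]), float(theta[1])
        if g_na < 0 or g_k < 0:
            return LossResult.invalid(sentinel)
        params = HH3Parameters(
            g_na=g_na, g_k=g_k, g_leak=tmpl.g_leak, e_na=tmpl.e_na,
            e_k=tmpl.e_k, e_leak=tmpl.e_leak, c_m=tmpl.c_m)
        try:
            trace = simulate_hh3(params, bundle.stim_template,
                                 bundle.settings)
        except IntegrationFailure:
            return LossResult.invalid(sentinel)
        return LossResult(e_f=np.nan, e_dc=np.nan,
                          total=mse_loss(trace, data_trace))

    return loss_fn
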