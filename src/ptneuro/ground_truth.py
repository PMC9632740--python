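"""Noiseless ground-truth voltage traces that serve as observational data.

All inference runs in this package fit against model-generated,
deterministic traces: a single spiking trace from the three-channel HH
model at its true conductances, and five bursting-model traces, one per
injected current in {0.0, 0.1, 0.2, 0.3, 0.4} nA, at the true parameter
vector. No noise is added.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Union

from .neuron_models import (
    AMFixedConstants,
    AMParameters,
    HH3Parameters,
    SolverSettings,
    StimulusStep,
    VoltageTrace,
    simulate_am8,
    simulate_hh3,
)
from . import traceio

__all__ = [
    "TRUE_AM_PARAMS",
    "TRUE_HH3_PARAMS",
    "DEFAULT_CURRENTS",
    "DEFAULT_AM_STIM",
    "DEFAULT_HH3_STIM",
    "GroundTruthBundle",
    "make_am_ground_truth",
    "make_hh3_ground_truth",
]

# True parameter vector of the nine inferred quantities (conductances in
# uS, calcium time constant in ms).
TRUE_AM_PARAMS = AMParameters(
    g_na=1076.392, g_cat=6.4056, g_cas=10.048, g_a=8.0384, g_kca=17.584,
    g_kd=124.0928, g_h=0.11304, g_leak=0.17584, tau_ca=653.5)

# True conductance densities of the three-channel HH problem (pS/um^2).
TRUE_HH3_PARAMS = HH3Parameters(g_na=200.0, g_k=50.0)

DEFAULT_CURRENTS = (0.0, 0.1, 0.2, 0.3, 0.4)  # nA
DEFAULT_AM_STIM = StimulusStep(i_inj=0.0, t_total=12000.0, t_discard=4000.0)
# constant suprathreshold current step; repetitive firing at the true
# parameters (i_inj in uA/cm^2 for the density-based HH3 model)
DEFAULT_HH3_STIM = StimulusStep(i_inj=2.0, t_total=250.0, t_discard=0.0)
DEFAULT_HH3_SETTINGS = SolverSettings(method="LSODA", dt_out=0.05)


@dataclass(frozen=True)
class GroundTruthBundle:
    model_id: str                       # "hh3" | "am8"
    true_params: Union[HH3Parameters, AMParameters]
    currents: tuple
    traces: Dict[float, VoltageTrace]
    settings: SolverSettings
    stim_template: StimulusStep

    def __post_init__(self):
        if set(self.currents) != set(self.traces):
            raise ValueError("one trace per current required")

    def trace(self, current: float) -> VoltageTrace:
        return self.traces[current]

    def content_hash(self) -> str:
        """Hash of everything the traces deterministically depend on."""
        payload = json.dumps({
            "model_id": self.model_id,
            "params": asdict(self.true_params),
            "currents": list(self.currents),
            "settings": asdict(self.settings),
            "stim": asdict(self.stim_template),
        }, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_am_ground_truth(
        consts: AMFixedConstants = AMFixedConstants(),
        stim_template: StimulusStep = DEFAULT_AM_STIM,
        settings: SolverSettings = SolverSettings(),
        currents: Sequence[float] = DEFAULT_CURRENTS,
        true_params: AMParameters = TRUE_AM_PARAMS,
        cache_dir=None) -> GroundTruthBundle:
    """Generate (or load from cache) the bursting-model ground truth.

    Integration failure at the true parameters is a fatal configuration
    error and propagates.
    """
    currents = tuple(currents)
    traces = {}
    bundle = None
    if cache_dir is not None:
        bundle = _try_load_cache(cache_dir, "am8", true_params, currents,
                                 settings, stim_template)
        if bundle is not None:
            return bundle
    for current in currents:
        stim = StimulusStep(i_inj=current, t_total=stim_template.t_total,
                            t_discard=stim_template.t_discard)
        traces[current] = simulate_am8(true_params, consts, stim, settings)
    bundle = GroundTruthBundle(
        model_id="am8", true_params=true_params, currents=currents,
        traces=traces, settings=settings, stim_template=stim_template)
    if cache_dir is not None:
        save_bundle(
            Path(cache_dir) / f"am8-{bundle.content_hash()}", bundle)
    return bundle


def make_hh3_ground_truth(
        settings: SolverSettings = DEFAULT_HH3_SETTINGS,
        stim: StimulusStep = DEFAULT_HH3_STIM,
        true_params: HH3Parameters = TRUE_HH3_PARAMS,
        cache_dir=None) -> GroundTruthBundle:
    """Generate the single spiking HH3 trace used as data."""
    if cache_dir is not None:
        bundle = _try_load_cache(cache_dir, "hh3", true_params,
                                 (stim.i_inj,), settings, stim)
        if bundle is not None:
            return bundle
    trace = simulate_hh3(true_params, stim, settings)
    bundle = GroundTruthBundle(
        model_id="hh3", true_params=true_params, currents=(stim.i_inj,),
        traces={stim.i_inj: trace}, settings=settings, stim_template=stim)
    if cache_dir is not None:
        save_bundle(
            Path(cache_dir) / f"hh3-{bundle.content_hash()}", bundle)
    return bundle


# ---------------------------------------------------------------------------
# On-disk bundle layout: one trace file per current + manifest JSON
# ---------------------------------------------------------------------------

def save_bundle(directory, bundle: GroundTruthBundle) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model_id": bundle.model_id,
        "params": asdict(bundle.true_params),
        "currents": list(bundle.currents),
        "settings": asdict(bundle.settings),
        "stim": asdict(bundle.stim_template),
        "hash": bundle.content_hash(),
        "files": {},
    }
    for current, trace in bundle.traces.items():
        fname = f"trace_{current:g}nA.tsv"
        traceio.write_trace(directory / fname, trace, bundle.settings,
                            asdict(bundle.true_params))
        manifest["files"][f"{current:g}"] = fname
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_bundle(directory) -> GroundTruthBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    params_cls = AMParameters if manifest["model_id"] == "am8" else HH3Parameters
    params = params_cls(**manifest["params"])
    settings = SolverSettings(**manifest["settings"])
    stim = StimulusStep(**manifest["stim"])
    traces = {}
    for key, fname in manifest["files"].items():
        trace, _ = traceio.read_trace(directory / fname)
        traces[float(key)] = trace
    bundle = GroundTruthBundle(
        model_id=manifest["model_id"], true_params=params,
        currents=tuple(manifest["currents"]), traces=traces,
        settings=settings, stim_template=stim)
    if bundle.content_hash() != manifest["hash"]:
        raise ValueError("bundle manifest hash mismatch (stale cache?)")
    return bundle


def _try_load_cache(cache_dir, model_id, params, currents, settings, stim):
    # compute the hash without simulating
    payload = json.dumps({
        "model_id": model_id, "params": asdict(params),
        "currents": list(currents), "settings": asdict(settings),
        "stim": asdict(stim),
    }, sort_keys=True, default=float)
    h = hashlib.sha256(payload.encode()).hexdigest()[:16]
    directory = Path(cache_dir) / f"{model_id}-{h}"
    if (directory / "manifest.json").exists():
        try:
            return load_bundle(directory)
        except Exception:
            return None
    return None
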