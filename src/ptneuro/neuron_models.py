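"""Conductance-based neuron models and their numerical integration.

Two models are provided:

* a three-channel (Na, K, leak) Hodgkin-Huxley point neuron with classic
  squid-axon rate functions, parameterized by conductance densities in
  pS/um^2 (1 pS/um^2 = 0.1 mS/cm^2);
* an eight-conductance bursting neuron (Na, CaT, CaS, A, KCa, Kd, H, leak)
  with first-order calcium dynamics, in absolute units (uS, nF, nA, mV, ms).

Right-hand sides are jitted with numba and integrated with the stiff
solvers (BDF / LSODA) from :func:`scipy.integrate.solve_ivp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "HH3Parameters",
    "AMParameters",
    "AMFixedConstants",
    "StimulusStep",
    "SolverSettings",
    "VoltageTrace",
    "IntegrationFailure",
    "AM_PARAM_NAMES",
    "simulate_hh3",
    "simulate_am8",
    "steady_state_init",
    "steady_state_init_hh3",
    "am8_rhs",
    "hh3_rhs",
]


class IntegrationFailure(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite state.

    Carries the offending parameter vector so callers can map the failure
    to a worst-case loss.
    """

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HH3Parameters:
    """Three-channel HH parameters; conductance densities in pS/um^2."""

    g_na: float = 200.0
    g_k: float = 50.0
    g_leak: float = 0.5
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.4
    c_m: float = 1.0  # uF/cm^2

    def __post_init__(self):
        if self.g_na < 0 or self.g_k < 0 or self.g_leak <= 0 or self.c_m <= 0:
            raise ValueError("conductances must be >= 0 and g_leak, c_m > 0")


AM_PARAM_NAMES = (
    "g_na", "g_cat", "g_cas", "g_a", "g_kca", "g_kd", "g_h", "g_leak",
    "tau_ca",
)


@dataclass(frozen=True)
class AMParameters:
    """The nine inferred quantities of the bursting model.

    Eight maximal conductances in uS and the calcium removal time constant
    in ms, orderable as a fixed 9-vector (see :data:`AM_PARAM_NAMES`).
    """

    g_na: float
    g_cat: float
    g_cas: float
    g_a: float
    g_kca: float
    g_kd: float
    g_h: float
    g_leak: float
    tau_ca: float

    def __post_init__(self):
        vec = self.as_array()
        if not np.all(vec > 0):
            raise ValueError("all nine parameters must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in AM_PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "AMParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (9,):
            raise ValueError("expected a 9-vector")
        return cls(**dict(zip(AM_PARAM_NAMES, vec)))


@dataclass(frozen=True)
class AMFixedConstants:
    """Fixed constants of the bursting model (not inferred)."""

    c: float = 0.628          # membrane capacitance, nF
    e_na: float = 50.0        # mV
    e_k: float = -80.0        # mV
    e_h: float = -20.0        # mV
    e_leak: float = -50.0     # mV
    ca_out: float = 3000.0    # extracellular calcium, uM
    ca_0: float = 0.05        # steady-state intracellular calcium, uM
    f_ca: float = 5.0         # current-to-concentration factor, uM/nA
                              # (calibrated once so the true parameter set
                              # bursts at ~1 Hz; see package docs)
    nernst_prefactor: float = 12.2  # RT/zF for divalent Ca, mV

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("capacitance must be positive")
        if not (self.ca_out > self.ca_0 > 0):
            raise ValueError("require ca_out > ca_0 > 0")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.c, self.e_na, self.e_k, self.e_h, self.e_leak,
            self.ca_out, self.ca_0, self.f_ca, self.nernst_prefactor,
        ])


@dataclass(frozen=True)
class StimulusStep:
    """Constant injected current over the simulated window."""

    i_inj: float = 0.0        # nA (AM model) or uA/cm^2 (HH3)
    t_total: float = 12000.0  # ms
    t_discard: float = 4000.0  # ms, initial transient dropped from the output

    def __post_init__(self):
        if not (self.t_total > self.t_discard >= 0):
            raise ValueError("require t_total > t_discard >= 0")


@dataclass(frozen=True)
class SolverSettings:
    method: str = "LSODA"     # one of {"BDF", "LSODA"}
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = math.inf
    dt_out: float = 0.1       # output sampling step, ms

    def __post_init__(self):
        if self.method not in ("BDF", "LSODA"):
            raise ValueError("method must be 'BDF' or 'LSODA'")
        if self.rtol <= 0 or self.atol <= 0 or self.dt_out <= 0:
            raise ValueError("tolerances and dt_out must be positive")


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane potential time series."""

    t: np.ndarray             # ms
    v: np.ndarray             # mV
    i_inj: float
    dt: float

    def __post_init__(self):
        t = np.asarray(self.t, float)
        v = np.asarray(self.v, float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or t.shape != v.shape or len(t) < 2:
            raise ValueError("t and v must be 1-d arrays of equal length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage trace contains non-finite values")
        steps = np.diff(t)
        if not np.all(steps > 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-9):
            raise ValueError("t must be uniformly spaced with step dt")

    def __len__(self):
        return len(self.t)


# ---------------------------------------------------------------------------
# Three-channel HH model
# ---------------------------------------------------------------------------
# Densities arrive in pS/um^2; 1 pS/um^2 = 0.1 mS/cm^2.

_PS_PER_UM2_TO_MS_PER_CM2 = 0.1


@njit(cache=True)
def _hh3_rates(v):
    # classic squid-axon rate functions (modern voltage convention)
    if abs(v + 40.0) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * (v + 40.0) / (1.0 - math.exp(-(v + 40.0) / 10.0))
    b_m = 4.0 * math.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * math.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    if abs(v + 55.0) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * (v + 55.0) / (1.0 - math.exp(-(v + 55.0) / 10.0))
    b_n = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True)
def _hh3_rhs_jit(y, g_na, g_k, g_leak, e_na, e_k, e_leak, c_m, i_inj):
    v, m, h, n = y[0], y[1], y[2], y[3]
    a_m, b_m, a_h, b_h, a_n, b_n = _hh3_rates(v)
    i_na = g_na * m ** 3 * h * (v - e_na)
    i_k = g_k * n ** 4 * (v - e_k)
    i_leak = g_leak * (v - e_leak)
    out = np.empty(4)
    out[0] = (i_inj - i_na - i_k - i_leak) / c_m
    out[1] = a_m * (1.0 - m) - b_m * m
    out[2] = a_h * (1.0 - h) - b_h * h
    out[3] = a_n * (1.0 - n) - b_n * n
    return out


def hh3_rhs(t, y, params: HH3Parameters, i_inj: float) -> np.ndarray:
    """Time derivative of the HH3 state ``(V, m, h, n)``."""
    k = _PS_PER_UM2_TO_MS_PER_CM2
    return _hh3_rhs_jit(
        np.asarray(y, float),
        params.g_na * k, params.g_k * k, params.g_leak * k,
        params.e_na, params.e_k, params.e_leak, params.c_m, i_inj,
    )


def steady_state_init_hh3(params: HH3Parameters, v0: float = -65.0) -> np.ndarray:
    """HH3 state with gates at their steady-state values at ``v0``."""
    a_m, b_m, a_h, b_h, a_n, b_n = _hh3_rates(v0)
    return np.array([
        v0,
        a_m / (a_m + b_m),
        a_h / (a_h + b_h),
        a_n / (a_n + b_n),
    ])


# ---------------------------------------------------------------------------
# Eight-conductance bursting model
# ---------------------------------------------------------------------------
# State layout: [V, mNa, hNa, mCaT, hCaT, mCaS, hCaS, mA, hA, mKCa, mKd, mH, Ca]

N_STATE_AM8 = 13


@njit(cache=True)
def _sig(v, vh, k):
    return 1.0 / (1.0 + math.exp((v + vh) / k))


@njit(cache=True)
def _am8_rhs_jit(y, g, consts, i_inj):
    v = y[0]
    m_na, h_na = y[1], y[2]
    m_cat, h_cat = y[3], y[4]
    m_cas, h_cas = y[5], y[6]
    m_a, h_a = y[7], y[8]
    m_kca = y[9]
    m_kd = y[10]
    m_h = y[11]
    ca = y[12]

    c = consts[0]
    e_na, e_k, e_h, e_leak = consts[1], consts[2], consts[3], consts[4]
    ca_out, ca_0, f_ca, nernst = consts[5], consts[6], consts[7], consts[8]

    if ca <= 0.0:
        out = np.empty(N_STATE_AM8)
        out[:] = np.nan
        return out

    e_ca = nernst * math.log(ca_out / ca)

    g_na, g_cat, g_cas, g_a, g_kca, g_kd, g_hh, g_leak, tau_ca = (
        g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7], g[8])

    i_na = g_na * m_na ** 3 * h_na * (v - e_na)
    i_cat = g_cat * m_cat ** 3 * h_cat * (v - e_ca)
    i_cas = g_cas * m_cas ** 3 * h_cas * (v - e_ca)
    i_a = g_a * m_a ** 3 * h_a * (v - e_k)
    i_kca = g_kca * m_kca ** 4 * (v - e_k)
    i_kd = g_kd * m_kd ** 4 * (v - e_k)
    i_h = g_hh * m_h * (v - e_h)
    i_leak = g_leak * (v - e_leak)

    # steady states and time constants (stomatogastric-neuron kinetics)
    m_na_inf = _sig(v, 25.5, -5.29)
    tau_m_na = 1.32 - 1.26 * _sig(v, 120.0, -25.0)
    h_na_inf = _sig(v, 48.9, 5.18)
    tau_h_na = (0.67 * _sig(v, 62.9, -10.0)) * (1.5 + _sig(v, 34.9, 3.6))

    m_cat_inf = _sig(v, 27.1, -7.2)
    tau_m_cat = 21.7 - 21.3 * _sig(v, 68.1, -20.5)
    h_cat_inf = _sig(v, 32.1, 5.5)
    tau_h_cat = 105.0 - 89.8 * _sig(v, 55.0, -16.9)

    m_cas_inf = _sig(v, 33.0, -8.1)
    tau_m_cas = 1.4 + 7.0 / (math.exp(-(v + 27.0) / 10.0)
                             + math.exp((v + 70.0) / 13.0))
    h_cas_inf = _sig(v, 60.0, 6.2)
    tau_h_cas = 60.0 + 150.0 / (math.exp(-(v + 55.0) / 9.0)
                                + math.exp((v + 65.0) / 16.0))

    m_a_inf = _sig(v, 27.2, -8.7)
    tau_m_a = 11.6 - 10.4 * _sig(v, 32.9, -15.2)
    h_a_inf = _sig(v, 56.9, 4.9)
    tau_h_a = 38.6 - 29.2 * _sig(v, 38.9, -26.5)

    m_kca_inf = (ca / (ca + 3.0)) * _sig(v, 28.3, -12.6)
    tau_m_kca = 90.3 - 75.1 * _sig(v, 46.0, -22.7)

    m_kd_inf = _sig(v, 12.3, -11.8)
    tau_m_kd = 7.2 - 6.4 * _sig(v, 28.3, -19.2)

    m_h_inf = _sig(v, 75.0, 5.5)
    tau_m_h = 2.0 / (math.exp(-(v + 169.7) / 11.6)
                     + math.exp((v - 26.7) / 14.3))

    out = np.empty(N_STATE_AM8)
    out[0] = (i_inj - i_na - i_cat - i_cas - i_a - i_kca - i_kd - i_h
              - i_leak) / c
    out[1] = (m_na_inf - m_na) / tau_m_na
    out[2] = (h_na_inf - h_na) / tau_h_na
    out[3] = (m_cat_inf - m_cat) / tau_m_cat
    out[4] = (h_cat_inf - h_cat) / tau_h_cat
    out[5] = (m_cas_inf - m_cas) / tau_m_cas
    out[6] = (h_cas_inf - h_cas) / tau_h_cas
    out[7] = (m_a_inf - m_a) / tau_m_a
    out[8] = (h_a_inf - h_a) / tau_h_a
    out[9] = (m_kca_inf - m_kca) / tau_m_kca
    out[10] = (m_kd_inf - m_kd) / tau_m_kd
    out[11] = (m_h_inf - m_h) / tau_m_h
    out[12] = (-f_ca * (i_cat + i_cas) - ca + ca_0) / tau_ca
    return out


@njit(cache=True)
def _am8_gate_inf_jit(v, ca):
    out = np.empty(11)
    out[0] = _sig(v, 25.5, -5.29)
    out[1] = _sig(v, 48.9, 5.18)
    out[2] = _sig(v, 27.1, -7.2)
    out[3] = _sig(v, 32.1, 5.5)
    out[4] = _sig(v, 33.0, -8.1)
    out[5] = _sig(v, 60.0, 6.2)
    out[6] = _sig(v, 27.2, -8.7)
    out[7] = _sig(v, 56.9, 4.9)
    out[8] = (ca / (ca + 3.0)) * _sig(v, 28.3, -12.6)
    out[9] = _sig(v, 12.3, -11.8)
    out[10] = _sig(v, 75.0, 5.5)
    return out


def am8_rhs(state, params: AMParameters, consts: AMFixedConstants,
            i_inj: float) -> np.ndarray:
    """Time derivative of the 13-entry bursting-model state.

    Raises :class:`ValueError` when the calcium concentration is
    non-positive (the calcium reversal potential is then undefined).
    """
    state = np.asarray(state, float)
    if state.shape != (N_STATE_AM8,):
        raise ValueError(f"state must have {N_STATE_AM8} entries")
    if state[12] <= 0:
        raise ValueError("calcium concentration must be positive")
    return _am8_rhs_jit(state, params.as_array(), consts.as_array(), i_inj)


def steady_state_init(params: AMParameters, consts: AMFixedConstants,
                      v0: float = -65.0) -> np.ndarray:
    """Bursting-model state with gates at steady state at ``v0``, Ca at rest.

    ``v0`` must lie in the physiological range [-200, 40] mV (the lower end
    is permissive to allow asymptotic limit checks).
    """
    if not (-200.0 <= v0 <= 40.0):
        raise ValueError("v0 outside supported range")
    gates = _am8_gate_inf_jit(v0, consts.ca_0)
    return np.concatenate(([v0], gates, [consts.ca_0]))


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _integrate(rhs, y0, stim: StimulusStep, settings: SolverSettings,
               params_for_error):
    t_eval = np.arange(0.0, stim.t_total + 0.5 * settings.dt_out,
                       settings.dt_out)
    if settings.method == "LSODA":
        # scipy's odeint wraps the same LSODA core as solve_ivp but with
        # far less per-step Python overhead (the loss evaluates thousands
        # of simulations per inference run)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y, info = odeint(
                lambda y, t: rhs(t, y), y0, t_eval, rtol=settings.rtol,
                atol=settings.atol, mxstep=10_000_000, full_output=True)
        if info["message"] != "Integration successful.":
            raise IntegrationFailure(
                f"ODE solver failed: {info['message']}",
                params=params_for_error)
        sol_t, sol_y = t_eval, y.T
    else:
        sol = solve_ivp(
            rhs, (0.0, stim.t_total), y0, method=settings.method,
            t_eval=t_eval, rtol=settings.rtol, atol=settings.atol,
            max_step=settings.max_step, dense_output=False,
        )
        if not sol.success:
            raise IntegrationFailure(
                f"ODE solver failed: {sol.message}", params=params_for_error)
        sol_t, sol_y = sol.t, sol.y
    if not np.all(np.isfinite(sol_y)):
        raise IntegrationFailure(
            "non-finite state encountered", params=params_for_error)
    keep = sol_t >= stim.t_discard - 1e-9
    t = sol_t[keep] - stim.t_discard
    return t, sol_y[:, keep]


def simulate_hh3(params: HH3Parameters, stim: StimulusStep,
                 settings: SolverSettings) -> VoltageTrace:
    """Integrate the three-channel HH model and return the voltage trace."""
    k = _PS_PER_UM2_TO_MS_PER_CM2
    args = (params.g_na * k, params.g_k * k, params.g_leak * k,
            params.e_na, params.e_k, params.e_leak, params.c_m, stim.i_inj)

    def rhs(t, y):
        return _hh3_rhs_jit(y, *args)

    y0 = steady_state_init_hh3(params)
    t, y = _integrate(rhs, y0, stim, settings, params)
    return VoltageTrace(t=t, v=y[0], i_inj=stim.i_inj, dt=settings.dt_out)


def simulate_am8(params: AMParameters, consts: AMFixedConstants,
                 stim: StimulusStep, settings: SolverSettings,
                 return_state: bool = False):
    """Integrate the eight-conductance bursting model.

    Returns the post-transient :class:`VoltageTrace`; with
    ``return_state=True`` also returns the full saved state matrix
    (n_state x n_saved) for gating/calcium checks.
    """
    g = params.as_array()
    cvec = consts.as_array()
    i_inj = stim.i_inj

    def rhs(t, y):
        return _am8_rhs_jit(y, g, cvec, i_inj)

    y0 = steady_state_init(params, consts)
    t, y = _integrate(rhs, y0, stim, settings, params)
    trace = VoltageTrace(t=t, v=y[0], i_inj=i_inj, dt=settings.dt_out)
    if return_state:
        return trace, y
    return trace
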