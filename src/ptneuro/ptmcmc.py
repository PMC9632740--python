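"""Adaptive parallel tempering MCMC over a box prior.

Independent Markov chains target the tempered posteriors P^gamma(theta|y)
for a ladder of exponents gamma_1 = 1 > gamma_2 > ... > gamma_K > 0; each
chain runs adaptive Metropolis-Hastings, and replica-exchange swap moves
between adjacent temperatures let hot chains feed remote modes to the cold
chain. The gamma_1 chain is the estimand posterior.

The likelihood is the Gibbs form log P(y|theta) = -E(theta)/T0 with T0 = 1
by default, where E is the loss; the prior is uniform on the box.
Reproducibility contract: given the master seed, results are bitwise
identical regardless of how chain updates are scheduled (per-chain RNG
streams are spawned from the master seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .burst_loss import LossResult

__all__ = [
    "PriorBox",
    "TemperatureLadder",
    "PosteriorEvaluation",
    "ChainState",
    "PTConfig",
    "SampleStore",
    "SwapRecord",
    "DEFAULT_AM_PRIOR",
    "DEFAULT_HH3_PRIOR",
    "log_posterior",
    "mh_step",
    "adapt_proposal",
    "swap_step",
    "run_pt_mcmc",
    "save_store",
    "load_store",
]


@dataclass(frozen=True)
class PriorBox:
    """Uniform (unbiased) prior supported on an axis-aligned box."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple = None

    def __post_init__(self):
        lower = np.asarray(self.lower, float)
        upper = np.asarray(self.upper, float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower/upper must be 1-d arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("require lower < upper elementwise")
        if self.names is None:
            object.__setattr__(
                self, "names", tuple(f"p{i}" for i in range(len(lower))))

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)

    def log_prior(self, theta) -> float:
        return 0.0 if self.contains(theta) else -np.inf


# Search bounds of the nine-parameter inference (conductances in uS,
# calcium time constant in ms).
DEFAULT_AM_PRIOR = PriorBox(
    lower=np.array([800.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 100.0]),
    upper=np.array([2000.0, 10.0, 15.0, 200.0, 20.0, 200.0, 0.5, 0.5, 900.0]),
    names=("g_na", "g_cat", "g_cas", "g_a", "g_kca", "g_kd", "g_h", "g_leak",
           "tau_ca"))

# Box for the two-conductance HH3 problem (pS/um^2).
DEFAULT_HH3_PRIOR = PriorBox(
    lower=np.array([50.0, 10.0]), upper=np.array([400.0, 150.0]),
    names=("g_na", "g_k"))


@dataclass(frozen=True)
class TemperatureLadder:
    """Decreasing tempering exponents gamma_k with gamma_1 = 1 exactly."""

    gammas: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gammas, float)
        object.__setattr__(self, "gammas", g)
        if g[0] != 1.0:
            raise ValueError("gamma_1 must be exactly 1")
        if not np.all((g > 0) & (g <= 1)):
            raise ValueError("gammas must lie in (0, 1]")
        if len(g) > 1 and not np.all(np.diff(g) < 0):
            raise ValueError("gammas must be strictly decreasing")

    @classmethod
    def geometric(cls, n_chains: int, gamma_min: float = 1e-3
                  ) -> "TemperatureLadder":
        if n_chains == 1:
            return cls(np.array([1.0]))
        k = np.arange(n_chains)
        return cls(gamma_min ** (k / (n_chains - 1)))

    def __len__(self):
        return len(self.gammas)


@dataclass(frozen=True)
class PosteriorEvaluation:
    log_likelihood: float
    log_prior: float
    gamma: float
    loss: LossResult

    @property
    def log_posterior_tempered(self) -> float:
        if self.log_prior == -np.inf:
            return -np.inf
        return self.gamma * self.log_likelihood + self.log_prior

    def at_gamma(self, gamma: float) -> "PosteriorEvaluation":
        return PosteriorEvaluation(self.log_likelihood, self.log_prior,
                                   gamma, self.loss)


@dataclass
class ChainState:
    theta: np.ndarray
    eval: PosteriorEvaluation
    proposal_cov: np.ndarray
    accept_count: int = 0
    step_count: int = 0
    # running moments of the chain history for proposal adaptation
    run_mean: np.ndarray = None
    run_cov: np.ndarray = None
    run_n: int = 0


@dataclass(frozen=True)
class PTConfig:
    n_chains: int = 24
    n_samples: int = 10000
    gamma_min: float = 1e-3
    swap_interval: int = 1          # sweeps between swap attempts
    adapt_start: int = 100          # steps before covariance adaptation
    adapt_ladder: bool = True
    target_swap_accept: float = 0.234
    ladder_adapt_decay: float = 0.6
    initial_step_frac: float = 0.05  # initial proposal sd, fraction of width
    cov_floor_frac: float = 1e-5     # regularization floor, fraction of width
    likelihood_temperature: float = 1.0  # T0 in logL = -E/T0
    seed: int = 0
    sentinel: float = 1e6

    def __post_init__(self):
        if self.n_chains < 1 or self.n_samples < 1:
            raise ValueError("n_chains and n_samples must be >= 1")


@dataclass(frozen=True)
class SwapRecord:
    iteration: int
    chain_low: int   # colder slot (smaller index = larger gamma)
    chain_high: int
    accepted: bool


@dataclass
class SampleStore:
    """Per-chain MCMC output, indexed by temperature slot."""

    samples: np.ndarray        # (n_chains, n_samples, ndim)
    loss: np.ndarray           # (n_chains, n_samples)
    log_post_tempered: np.ndarray  # (n_chains, n_samples)
    accepted: np.ndarray       # (n_chains, n_samples) bool
    swap_records: List[SwapRecord]
    ladder_history: np.ndarray  # (n_records, n_chains)
    config: PTConfig
    prior: PriorBox

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def cold_chain(self) -> np.ndarray:
        return self.samples[0]

    def acceptance_rates(self) -> np.ndarray:
        return self.accepted.mean(axis=1)

    def swap_acceptance_rate(self) -> float:
        if not self.swap_records:
            return float("nan")
        return float(np.mean([r.accepted for r in self.swap_records]))


# ---------------------------------------------------------------------------
# Posterior evaluation
# ---------------------------------------------------------------------------

def _as_loss_result(value, sentinel) -> LossResult:
    if isinstance(value, LossResult):
        return value
    value = float(value)
    if not np.isfinite(value):
        return LossResult.invalid(sentinel)
    return LossResult(e_f=np.nan, e_dc=np.nan, total=value)


def log_posterior(theta, gamma: float, loss_fn: Callable, prior: PriorBox,
                  sentinel: float = 1e6,
                  likelihood_temperature: float = 1.0) -> PosteriorEvaluation:
    """Evaluate the tempered log-posterior at ``theta``.

    ``loss_fn`` maps a parameter vector to a :class:`LossResult` (or bare
    float). Outside the prior box the loss is not evaluated and the
    evaluation carries log_prior = -inf (the proposal is auto-rejected).
    """
    lp = prior.log_prior(theta)
    if lp == -np.inf:
        return PosteriorEvaluation(
            log_likelihood=-np.inf, log_prior=-np.inf, gamma=gamma,
            loss=LossResult.invalid(sentinel))
    loss = _as_loss_result(loss_fn(np.asarray(theta, float)), sentinel)
    ll = -loss.total / likelihood_temperature
    return PosteriorEvaluation(log_likelihood=ll, log_prior=lp, gamma=gamma,
                               loss=loss)


# ---------------------------------------------------------------------------
# Metropolis-Hastings step with adaptive proposal
# ---------------------------------------------------------------------------

def mh_step(state: ChainState, gamma: float, log_post_fn: Callable,
            rng: np.random.Generator) -> Tuple[ChainState, bool]:
    """One Metropolis-Hastings step with a Gaussian random-walk proposal.

    ``log_post_fn(theta, gamma)`` must return a PosteriorEvaluation.
    Accept with probability min(1, ratio); on reject the previous state is
    re-stored.
    """
    d = len(state.theta)
    try:
        chol = np.linalg.cholesky(state.proposal_cov)
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.diag(state.proposal_cov)))
    proposal = state.theta + chol @ rng.standard_normal(d)
    prop_eval = log_post_fn(proposal, gamma)
    log_ratio = (prop_eval.log_posterior_tempered
                 - state.eval.log_posterior_tempered)
    accept = np.log(rng.uniform()) < log_ratio if log_ratio < 0 else True
    if prop_eval.log_prior == -np.inf:
        accept = False
    state.step_count += 1
    if accept:
        state.theta = proposal
        state.eval = prop_eval
        state.accept_count += 1
    return state, bool(accept)


def adapt_proposal(state: ChainState, history: np.ndarray,
                   cov_floor: Union[float, np.ndarray] = 1e-10) -> np.ndarray:
    """Adapted proposal covariance from the chain history.

    Scales the empirical covariance by 2.38^2/d with a diagonal
    regularization floor; a singular or non-finite empirical covariance
    falls back to the regularized diagonal.
    """
    history = np.asarray(history, float)
    d = history.shape[1]
    floor = np.diag(np.broadcast_to(np.asarray(cov_floor, float), (d,)))
    if history.shape[0] < 2:
        emp = np.zeros((d, d))
    else:
        emp = np.cov(history.T)
        emp = np.atleast_2d(emp)
        if not np.all(np.isfinite(emp)):
            emp = np.zeros((d, d))
    cov = (2.38 ** 2 / d) * (emp + floor)
    state.proposal_cov = cov
    return cov


def _update_running_moments(state: ChainState, theta: np.ndarray):
    # recursive mean/covariance with 1/n weights; adaptation magnitude
    # decays automatically as the chain grows
    state.run_n += 1
    if state.run_mean is None:
        state.run_mean = theta.copy()
        state.run_cov = np.zeros((len(theta), len(theta)))
        return
    w = 1.0 / (state.run_n + 1)
    delta = theta - state.run_mean
    state.run_mean = state.run_mean + w * delta
    state.run_cov = (1 - w) * (state.run_cov + w * np.outer(delta, delta))


# ---------------------------------------------------------------------------
# Replica-exchange swap
# ---------------------------------------------------------------------------

def swap_step(chains: List[ChainState], ladder: TemperatureLadder,
              rng: np.random.Generator, iteration: int = 0,
              parity: int = 0) -> List[SwapRecord]:
    """Propose state exchanges between adjacent-temperature pairs.

    Pairs (k, k+1) with k of the given parity are proposed; a swap is
    accepted with probability min(1, exp((g_k - g_{k+1}) (l_{k+1} - l_k)))
    where l is the log-likelihood. Parameter states exchange; temperatures
    stay fixed to slots.
    """
    records = []
    g = ladder.gammas
    for k in range(parity, len(chains) - 1, 2):
        lo, hi = chains[k], chains[k + 1]
        log_alpha = (g[k] - g[k + 1]) * (hi.eval.log_likelihood
                                         - lo.eval.log_likelihood)
        accepted = True if log_alpha >= 0 else np.log(rng.uniform()) < log_alpha
        if accepted:
            lo.theta, hi.theta = hi.theta, lo.theta
            lo_eval, hi_eval = lo.eval, hi.eval
            lo.eval = hi_eval.at_gamma(g[k])
            hi.eval = lo_eval.at_gamma(g[k + 1])
        records.append(SwapRecord(iteration, k, k + 1, bool(accepted)))
    return records


def _adapt_ladder(gammas: np.ndarray, pair_accept: np.ndarray,
                  round_index: int, target: float, decay: float) -> np.ndarray:
    """Stochastic-approximation update of the ladder spacings toward a
    target swap acceptance; gamma_1 stays exactly 1."""
    if len(gammas) < 2:
        return gammas
    # work on log inverse-temperature differences
    t = 1.0 / gammas
    s = np.log(np.diff(t))
    kappa = 1.0 / (round_index + 1) ** decay
    s = s - kappa * (pair_accept - target)
    # keep inverse-temperature spacings in a sane range so adjacent gammas
    # can never collide (or blow up) numerically
    s = np.clip(s, np.log(1e-5), np.log(1e5))
    t_new = np.concatenate(([1.0], 1.0 + np.cumsum(np.exp(s))))
    g = 1.0 / t_new
    g[0] = 1.0
    return g


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pt_mcmc(config: PTConfig, loss_fn: Callable, prior: PriorBox,
                initial_thetas: Optional[np.ndarray] = None,
                n_workers: int = 1) -> SampleStore:
    """Run adaptive parallel tempering MCMC and return the SampleStore.

    ``loss_fn(theta) -> LossResult | float`` is evaluated only inside the
    prior box. With one chain this reduces exactly to adaptive MH (no swap
    records). ``n_workers > 1`` updates chains of a sweep in a thread
    pool; because every chain consumes only its own RNG stream, the result
    is bitwise identical regardless of the worker count or scheduling.
    """
    d = prior.ndim
    master = np.random.SeedSequence(config.seed)
    seeds = master.spawn(config.n_chains + 1)
    chain_rngs = [np.random.Generator(np.random.PCG64(s))
                  for s in seeds[:config.n_chains]]
    swap_rng = np.random.Generator(np.random.PCG64(seeds[-1]))

    ladder = TemperatureLadder.geometric(config.n_chains, config.gamma_min)
    gammas = ladder.gammas.copy()

    floor = (config.cov_floor_frac * prior.width) ** 2
    init_cov = np.diag((config.initial_step_frac * prior.width) ** 2)

    chains: List[ChainState] = []
    for k in range(config.n_chains):
        theta0 = (prior.sample(chain_rngs[k]) if initial_thetas is None
                  else np.asarray(initial_thetas[k], float))
        ev = log_posterior(theta0, gammas[k], loss_fn, prior,
                           config.sentinel, config.likelihood_temperature)
        chains.append(ChainState(theta=theta0, eval=ev,
                                 proposal_cov=init_cov.copy()))

    samples = np.empty((config.n_chains, config.n_samples, d))
    loss_out = np.empty((config.n_chains, config.n_samples))
    lpt_out = np.empty((config.n_chains, config.n_samples))
    accepted_out = np.zeros((config.n_chains, config.n_samples), bool)
    swap_records: List[SwapRecord] = []
    ladder_history = [gammas.copy()]
    pair_accept_acc = np.zeros(max(config.n_chains - 1, 1))
    pair_attempt_acc = np.zeros(max(config.n_chains - 1, 1))
    swap_round = 0

    def advance(k: int, it: int):
        chain = chains[k]

        def log_post_fn(theta, g=gammas[k]):
            return log_posterior(theta, g, loss_fn, prior, config.sentinel,
                                 config.likelihood_temperature)

        chain, acc = mh_step(chain, gammas[k], log_post_fn, chain_rngs[k])
        # moments exclude the earliest transient so the proposal settles
        # to the local posterior scale
        if chain.step_count >= config.adapt_start // 2:
            _update_running_moments(chain, chain.theta)
        if chain.step_count >= config.adapt_start:
            chain.proposal_cov = ((2.38 ** 2 / d)
                                  * (chain.run_cov + np.diag(floor)))
        samples[k, it] = chain.theta
        loss_out[k, it] = chain.eval.loss.total
        lpt_out[k, it] = chain.eval.log_posterior_tempered
        accepted_out[k, it] = acc

    executor = None
    if n_workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        executor = ThreadPoolExecutor(max_workers=n_workers)

    for it in range(config.n_samples):
        if executor is None:
            for k in range(config.n_chains):
                advance(k, it)
        else:
            list(executor.map(advance, range(config.n_chains),
                              [it] * config.n_chains))

        if config.n_chains > 1 and (it + 1) % config.swap_interval == 0:
            parity = ((it + 1) // config.swap_interval) % 2
            recs = swap_step(chains, TemperatureLadder(gammas), swap_rng,
                             iteration=it, parity=parity)
            swap_records.extend(recs)
            for r in recs:
                pair_attempt_acc[r.chain_low] += 1
                pair_accept_acc[r.chain_low] += r.accepted
            # adapt the ladder once both parities were attempted
            if config.adapt_ladder and parity == 0 and it > 0:
                attempted = pair_attempt_acc > 0
                rates = np.where(attempted,
                                 pair_accept_acc / np.maximum(pair_attempt_acc, 1),
                                 config.target_swap_accept)
                gammas = _adapt_ladder(gammas, rates, swap_round,
                                       config.target_swap_accept,
                                       config.ladder_adapt_decay)
                ladder_history.append(gammas.copy())
                for k, chain in enumerate(chains):
                    chain.eval = chain.eval.at_gamma(gammas[k])
                pair_accept_acc[:] = 0
                pair_attempt_acc[:] = 0
                swap_round += 1

    if executor is not None:
        executor.shutdown()

    return SampleStore(
        samples=samples, loss=loss_out, log_post_tempered=lpt_out,
        accepted=accepted_out, swap_records=swap_records,
        ladder_history=np.array(ladder_history), config=config, prior=prior)


# ---------------------------------------------------------------------------
# On-disk representation: one delimited table per chain + JSON manifest
# ---------------------------------------------------------------------------

def save_store(directory, store: SampleStore) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = store.prior.names
    header = "iteration\t" + "\t".join(names) + "\tloss\tlog_post_tempered\taccepted"
    for k in range(store.n_chains):
        table = np.column_stack([
            np.arange(store.n_samples), store.samples[k], store.loss[k],
            store.log_post_tempered[k], store.accepted[k].astype(int)])
        np.savetxt(directory / f"chain_{k:03d}.tsv", table, fmt="%.17g",
                   delimiter="\t", header=header, comments="# ")
    manifest = {
        "config": asdict(store.config),
        "prior": {"lower": store.prior.lower.tolist(),
                  "upper": store.prior.upper.tolist(),
                  "names": list(names)},
        "n_chains": store.n_chains,
        "n_samples": store.n_samples,
        "ladder_history": store.ladder_history.tolist(),
        "swap_records": [asdict(r) for r in store.swap_records],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest))
    return directory


def load_store(directory) -> SampleStore:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    prior = PriorBox(lower=np.array(manifest["prior"]["lower"]),
                     upper=np.array(manifest["prior"]["upper"]),
                     names=tuple(manifest["prior"]["names"]))
    config = PTConfig(**manifest["config"])
    n_chains, n_samples = manifest["n_chains"], manifest["n_samples"]
    d = prior.ndim
    samples = np.empty((n_chains, n_samples, d))
    loss = np.empty((n_chains, n_samples))
    lpt = np.empty((n_chains, n_samples))
    acc = np.zeros((n_chains, n_samples), bool)
    for k in range(n_chains):
        table = np.loadtxt(directory / f"chain_{k:03d}.tsv")
        table = np.atleast_2d(table)
        samples[k] = table[:, 1:1 + d]
        loss[k] = table[:, 1 + d]
        lpt[k] = table[:, 2 + d]
        acc[k] = table[:, 3 + d] > 0.5
    return SampleStore(
        samples=samples, loss=loss, log_post_tempered=lpt, accepted=acc,
        swap_records=[SwapRecord(**r) for r in manifest["swap_records"]],
        ladder_history=np.array(manifest["ladder_history"]),
        config=config, prior=prior)
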