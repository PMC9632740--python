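import numpy as np
import pytest

from ptneuro.burst_loss import LossResult
from ptneuro.ptmcmc import (
    ChainState,
    DEFAULT_AM_PRIOR,
    DEFAULT_HH3_PRIOR,
    PTConfig,
    PosteriorEvaluation,
    PriorBox,
    SampleStore,
    TemperatureLadder,
    adapt_proposal,
    load_store,
    log_posterior,
    mh_step,
    run_pt_mcmc,
    save_store,
    swap_step,
)

BOX = PriorBox(lower=np.array([-10.0, -10.0]), upper=np.array([10.0, 10.0]))


def gaussian_loss(mu, sd):
    mu, sd = np.asarray(mu, float), np.asarray(sd, float)

    def loss(theta):
        return 0.5 * float(np.sum(((theta - mu) / sd) ** 2))

    return loss


# ---------------------------------------------------------------------------
# prior box and ladder
# ---------------------------------------------------------------------------

def test_prior_box_validation():
    with pytest.raises(ValueError):
        PriorBox(lower=np.array([1.0]), upper=np.array([0.0]))


def test_prior_box_contains_and_sample():
    rng = np.random.default_rng(0)
    draws = np.array([BOX.sample(rng) for _ in range(100)])
    assert all(BOX.contains(d) for d in draws)
    assert BOX.log_prior(np.array([0.0, 0.0])) == 0.0
    assert BOX.log_prior(np.array([11.0, 0.0])) == -np.inf


def test_default_am_prior_matches_study_bounds():
    assert DEFAULT_AM_PRIOR.lower[0] == 800.0
    assert DEFAULT_AM_PRIOR.upper[0] == 2000.0
    assert DEFAULT_AM_PRIOR.lower[-1] == 100.0
    assert DEFAULT_AM_PRIOR.upper[-1] == 900.0
    assert DEFAULT_AM_PRIOR.names[0] == "g_na"


def test_ladder_validation():
    with pytest.raises(ValueError):
        TemperatureLadder(np.array([0.9, 0.5]))       # gamma_1 != 1
    with pytest.raises(ValueError):
        TemperatureLadder(np.array([1.0, 1.0]))        # not decreasing
    with pytest.raises(ValueError):
        TemperatureLadder(np.array([1.0, -0.1]))       # out of range


def test_geometric_ladder():
    lad = TemperatureLadder.geometric(4, gamma_min=1e-3)
    assert lad.gammas[0] == 1.0
    assert lad.gammas[-1] == pytest.approx(1e-3)
    assert np.all(np.diff(lad.gammas) < 0)
    assert len(TemperatureLadder.geometric(1)) == 1


# ---------------------------------------------------------------------------
# log-posterior
# ---------------------------------------------------------------------------

def test_log_posterior_outside_box():
    ev = log_posterior(np.array([20.0, 0.0]), 1.0, gaussian_loss(0, 1), BOX)
    assert ev.log_prior == -np.inf
    assert ev.log_posterior_tempered == -np.inf


def test_log_posterior_at_optimum():
    ev = log_posterior(np.zeros(2), 1.0, gaussian_loss(0, 1), BOX)
    assert ev.log_likelihood == 0.0
    assert ev.log_posterior_tempered == 0.0


def test_log_posterior_tempering_ratio():
    theta = np.array([1.0, 2.0])
    loss = gaussian_loss(0, 1)
    full = log_posterior(theta, 1.0, loss, BOX)
    half = log_posterior(theta, 0.5, loss, BOX)
    assert half.log_posterior_tempered == pytest.approx(
        0.5 * full.log_posterior_tempered)


def test_log_posterior_nonfinite_loss_becomes_sentinel():
    ev = log_posterior(np.zeros(2), 1.0, lambda t: np.inf, BOX,
                       sentinel=123.0)
    assert not ev.loss.valid
    assert ev.loss.total == 123.0


# ---------------------------------------------------------------------------
# MH step
# ---------------------------------------------------------------------------

def _chain_at(theta, loss_fn, gamma=1.0, cov_scale=1.0):
    ev = log_posterior(np.asarray(theta, float), gamma, loss_fn, BOX)
    return ChainState(theta=np.asarray(theta, float), eval=ev,
                      proposal_cov=np.eye(2) * cov_scale)


def test_mh_step_always_accepts_uphill():
    # from a very low-probability point, nearly every proposal is uphill
    loss = gaussian_loss(0, 1)
    rng = np.random.default_rng(0)
    state = _chain_at([8.0, 8.0], loss, cov_scale=0.25)

    def lp(theta, gamma):
        return log_posterior(theta, gamma, loss, BOX)

    accepted = 0
    for _ in range(50):
        before = state.eval.log_posterior_tempered
        state, acc = mh_step(state, 1.0, lp, rng)
        if state.eval.log_posterior_tempered > before:
            assert acc  # uphill moves are always accepted
        accepted += acc
    assert accepted > 0


def test_mh_step_flat_target_accepts_everything():
    # uniform target on the box: in-box proposals always accepted
    loss = lambda theta: 0.0
    rng = np.random.default_rng(1)
    # small steps keep the walk far from the box boundary, where the only
    # rejections (out-of-box proposals) could occur
    state = _chain_at([0.0, 0.0], loss, cov_scale=0.01)

    def lp(theta, gamma):
        return log_posterior(theta, gamma, loss, BOX)

    results = [mh_step(state, 1.0, lp, rng)[1] for _ in range(2000)]
    assert np.mean(results) > 0.999


def test_mh_step_gaussian_stationary_moments():
    """Long-run MH samples match the closed-form target moments."""
    loss = gaussian_loss([1.0, -1.0], [0.8, 0.8])
    rng = np.random.default_rng(7)
    state = _chain_at([1.0, -1.0], loss, cov_scale=0.8)

    def lp(theta, gamma):
        return log_posterior(theta, gamma, loss, BOX)

    draws = []
    for _ in range(20000):
        state, _ = mh_step(state, 1.0, lp, rng)
        draws.append(state.theta.copy())
    draws = np.array(draws)[2000:]
    # effective sample size is reduced by autocorrelation; allow 3 sigma
    # with a conservative ESS estimate
    ess = len(draws) / 20
    se = 0.8 / np.sqrt(ess)
    assert abs(draws[:, 0].mean() - 1.0) < 3 * se
    assert abs(draws[:, 1].mean() + 1.0) < 3 * se
    assert np.allclose(draws.std(axis=0), 0.8, rtol=0.15)


def test_mh_step_out_of_box_rejected():
    loss = gaussian_loss(0, 1)
    rng = np.random.default_rng(3)
    tiny_box = PriorBox(lower=np.array([-0.01, -0.01]),
                        upper=np.array([0.01, 0.01]))

    def lp(theta, gamma):
        return log_posterior(theta, gamma, loss, tiny_box)

    ev = lp(np.zeros(2), 1.0)
    state = ChainState(theta=np.zeros(2), eval=ev,
                       proposal_cov=np.eye(2) * 100.0)
    for _ in range(100):
        state, acc = mh_step(state, 1.0, lp, rng)
        assert tiny_box.contains(state.theta)


# ---------------------------------------------------------------------------
# proposal adaptation
# ---------------------------------------------------------------------------

def test_adapt_proposal_identical_points_floor():
    state = ChainState(theta=np.zeros(2), eval=None,
                       proposal_cov=np.eye(2))
    history = np.ones((50, 2))
    cov = adapt_proposal(state, history, cov_floor=1e-8)
    assert np.allclose(cov, (2.38 ** 2 / 2) * 1e-8 * np.eye(2))


def test_adapt_proposal_tracks_known_gaussian():
    rng = np.random.default_rng(0)
    target_diag = np.array([4.0, 0.25])
    history = rng.standard_normal((20000, 2)) * np.sqrt(target_diag)
    state = ChainState(theta=np.zeros(2), eval=None, proposal_cov=np.eye(2))
    cov = adapt_proposal(state, history, cov_floor=1e-12)
    expected = (2.38 ** 2 / 2) * target_diag
    assert np.allclose(np.diag(cov), expected, rtol=0.2)


def test_adaptation_decays_with_iteration():
    from ptneuro.ptmcmc import _update_running_moments

    rng = np.random.default_rng(5)
    state = ChainState(theta=np.zeros(2), eval=None, proposal_cov=np.eye(2))
    changes = {}
    for step in range(1, 10002):
        state.step_count = step
        before = None if state.run_cov is None else state.run_cov.copy()
        _update_running_moments(state, rng.standard_normal(2))
        if step in (101, 10001):
            changes[step] = np.linalg.norm(state.run_cov - before)
    assert changes[10001] < changes[101]


# ---------------------------------------------------------------------------
# swap step
# ---------------------------------------------------------------------------

def _eval_with_ll(ll, gamma):
    return PosteriorEvaluation(log_likelihood=ll, log_prior=0.0, gamma=gamma,
                               loss=LossResult(0.0, 0.0, -ll if ll <= 0 else 0.0))


def test_swap_equal_likelihoods_always_swaps():
    ladder = TemperatureLadder(np.array([1.0, 0.5]))
    rng = np.random.default_rng(0)
    a = ChainState(theta=np.array([1.0, 1.0]), eval=_eval_with_ll(-2.0, 1.0),
                   proposal_cov=np.eye(2))
    b = ChainState(theta=np.array([2.0, 2.0]), eval=_eval_with_ll(-2.0, 0.5),
                   proposal_cov=np.eye(2))
    recs = swap_step([a, b], ladder, rng, parity=0)
    assert len(recs) == 1 and recs[0].accepted
    assert np.array_equal(a.theta, [2.0, 2.0])
    assert np.array_equal(b.theta, [1.0, 1.0])
    # temperatures stay fixed to slots
    assert a.eval.gamma == 1.0 and b.eval.gamma == 0.5


def test_swap_uphill_for_cold_chain_always_accepted():
    # hotter chain holds the better likelihood -> exponent positive
    ladder = TemperatureLadder(np.array([1.0, 0.25]))
    rng = np.random.default_rng(0)
    a = ChainState(theta=np.zeros(2), eval=_eval_with_ll(-5.0, 1.0),
                   proposal_cov=np.eye(2))
    b = ChainState(theta=np.ones(2), eval=_eval_with_ll(-1.0, 0.25),
                   proposal_cov=np.eye(2))
    recs = swap_step([a, b], ladder, rng, parity=0)
    assert recs[0].accepted


def test_swap_acceptance_probability_formula():
    # Delta = (g1-g2)(l2-l1) = 0.5 * (-4) = -2 -> accept prob e^-2
    ladder = TemperatureLadder(np.array([1.0, 0.5]))
    n_acc = 0
    n_rep = 4000
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        a = ChainState(theta=np.zeros(2), eval=_eval_with_ll(-1.0, 1.0),
                       proposal_cov=np.eye(2))
        b = ChainState(theta=np.ones(2), eval=_eval_with_ll(-5.0, 0.5),
                       proposal_cov=np.eye(2))
        recs = swap_step([a, b], ladder, rng, parity=0)
        n_acc += recs[0].accepted
    p = n_acc / n_rep
    expected = np.exp(-2.0)
    se = np.sqrt(expected * (1 - expected) / n_rep)
    assert abs(p - expected) < 4 * se


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_run_recovers_2d_gaussian():
    mu, sd = np.array([1.0, -2.0]), np.array([0.5, 1.5])
    cfg = PTConfig(n_chains=4, n_samples=5000, seed=3)
    store = run_pt_mcmc(cfg, gaussian_loss(mu, sd), BOX)
    cold = store.cold_chain()[1000:]
    ess = len(cold) / 20
    for j in range(2):
        assert abs(cold[:, j].mean() - mu[j]) < 3 * sd[j] / np.sqrt(ess)
    assert np.allclose(cold.std(axis=0), sd, rtol=0.15)


def test_run_finds_both_modes_of_mixture():
    w = 0.7
    m1, m2 = np.array([-4.0, 0.0]), np.array([4.0, 0.0])

    def loss_bi(th):
        p = (w * np.exp(-0.5 * np.sum((th - m1) ** 2))
             + (1 - w) * np.exp(-0.5 * np.sum((th - m2) ** 2)))
        return -np.log(p + 1e-300)

    store = run_pt_mcmc(PTConfig(n_chains=6, n_samples=3000, seed=11),
                        loss_bi, BOX, initial_thetas=np.tile(m2, (6, 1)))
    x = store.cold_chain()[500:, 0]
    assert np.any(x < 0) and np.any(x > 0)
    frac = (x < 0).mean()
    assert 0.5 < frac < 0.9  # close to the 0.7 analytic weight


def test_single_chain_reduces_to_adaptive_mh():
    cfg = PTConfig(n_chains=1, n_samples=500, seed=0)
    store = run_pt_mcmc(cfg, gaussian_loss(0, 1), BOX)
    assert store.swap_records == []
    assert store.n_chains == 1


def test_all_samples_inside_box():
    cfg = PTConfig(n_chains=3, n_samples=1000, seed=9)
    store = run_pt_mcmc(cfg, gaussian_loss(0, 2), BOX)
    assert np.all(store.samples >= BOX.lower)
    assert np.all(store.samples <= BOX.upper)


def test_seed_determinism():
    cfg = PTConfig(n_chains=3, n_samples=400, seed=42)
    a = run_pt_mcmc(cfg, gaussian_loss(0, 1), BOX)
    b = run_pt_mcmc(cfg, gaussian_loss(0, 1), BOX)
    assert np.array_equal(a.samples, b.samples)
    assert np.array_equal(a.loss, b.loss)
    assert a.swap_records == b.swap_records


def test_store_shapes_and_roundtrip(tmp_path):
    cfg = PTConfig(n_chains=2, n_samples=100, seed=1)
    store = run_pt_mcmc(cfg, gaussian_loss(0, 1), BOX)
    assert store.samples.shape == (2, 100, 2)
    save_store(tmp_path / "store", store)
    loaded = load_store(tmp_path / "store")
    assert np.allclose(loaded.samples, store.samples)
    assert np.allclose(loaded.loss, store.loss)
    assert loaded.config == store.config
    assert len(loaded.swap_records) == len(store.swap_records)


def test_config_validation():
    with pytest.raises(ValueError):
        PTConfig(n_chains=0)
    with pytest.raises(ValueError):
        PTConfig(n_samples=0)
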