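import math

import numpy as np
import pytest
from scipy import stats

from tabletrade import (
    AdaptiveSchedule,
    EpsilonSchedule,
    ParticleSystem,
    PriorSpec,
    bayes_factor,
    bayes_factor_matrix,
    hdr_contains,
    perturb_particle,
    posterior_summary,
    run_abcpmc,
    sample_prior,
    tableware_prior,
    theta_to_params,
)
from tabletrade.abc_pmc import PerturbationKernel


@pytest.fixture
def rng():
    return np.random.default_rng(77)


def normal_mean_problem(seed, n_obs=20, theta_true=1.0):
    """Conjugate normal-mean toy: prior N(0,1), unit noise, distance is the
    absolute difference of sample means.  Returns (distance_fn, prior,
    analytic posterior mean, analytic posterior sd)."""
    obs_rng = np.random.default_rng(seed)
    y = obs_rng.normal(theta_true, 1.0, n_obs)
    ybar = y.mean()
    prior = PriorSpec(names=("theta",), dists=(stats.norm(0.0, 1.0),))

    def distance(theta, sim_seed):
        sim = np.random.default_rng(sim_seed).normal(theta[0], 1.0, n_obs)
        return abs(sim.mean() - ybar)

    post_mean = n_obs * ybar / (n_obs + 1)
    post_sd = math.sqrt(1.0 / (n_obs + 1))
    return distance, prior, post_mean, post_sd


class TestPriors:
    def test_hard_constraints_always_hold(self, rng):
        prior = tableware_prior("independent")
        for _ in range(300):
            theta = sample_prior(prior, rng)
            mu, mu_max, lam, lam_str, t, omega = theta
            assert 0 <= mu <= 1 and 0 <= lam <= 1
            assert omega >= 2
            assert 50 <= t / omega <= 1000

    def test_pdf_zero_outside_support(self):
        prior = tableware_prior("independent")
        theta = np.array([0.5, 5.0, 0.5, 5.0, 500.0, 1.5])  # omega < 2
        assert prior.pdf(theta) == 0.0
        theta[5] = 5.0
        assert prior.pdf(theta) > 0.0

    def test_theta_to_params_rounds_and_validates(self):
        p = theta_to_params(np.array([0.5, 2.0, 0.3, 1.0, 199.7, 3.9]), "unbiased")
        assert (p.t, p.omega) == (200, 4)
        # rounding that lands below 50 cultural steps is infeasible
        assert theta_to_params(np.array([0.5, 2.0, 0.3, 1.0, 120.0, 2.0]), "unbiased") is not None
        assert theta_to_params(np.array([0.5, 2.0, 0.3, 1.0, 60.0, 2.4]), "unbiased") is None


class TestPerturbation:
    def test_single_particle_fallback_jitter(self, rng):
        prior = tableware_prior("independent")
        theta = sample_prior(prior, rng)
        out = perturb_particle(theta[None, :], np.array([1.0]), prior, rng)
        assert np.all(np.abs(out - theta) < 0.2 * prior.ranges())

    def test_constraints_hold_after_perturbation(self, rng):
        prior = tableware_prior("independent")
        pool = np.array([sample_prior(prior, rng) for _ in range(30)])
        w = np.full(30, 1 / 30)
        kernel = PerturbationKernel(pool, w, prior)
        for _ in range(200):
            theta = kernel.sample(rng)
            assert prior.constraint(theta)
            assert 0 <= theta[0] <= 1

    def test_kernel_is_centred_on_the_pool(self, rng):
        # symmetric kernel: the mean of many draws approaches the weighted pool mean
        prior = PriorSpec(names=("x",), dists=(stats.uniform(-100, 200),))
        pool = np.array([[0.0], [2.0], [4.0]])
        w = np.array([0.5, 0.25, 0.25])
        kernel = PerturbationKernel(pool, w, prior)
        draws = np.array([kernel.sample(rng)[0] for _ in range(4000)])
        pool_mean = float(np.dot(w, pool[:, 0]))
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - pool_mean) < 3 * se


class TestSchedules:
    def test_published_ladder_is_decreasing(self):
        sched = EpsilonSchedule.published()
        assert sched.values[0] == 0.13
        assert sched.values[-1] == 0.0099
        assert all(b < a for a, b in zip(sched.values, sched.values[1:]))

    def test_non_decreasing_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            EpsilonSchedule((0.1, 0.1))

    def test_quantile_ladder_from_pilot(self):
        d = np.linspace(0.0, 1.0, 101)
        sched = EpsilonSchedule.from_distances(d, n_levels=3)
        assert len(sched.values) == 3
        assert sched.values[0] == pytest.approx(0.75)
        assert all(b < a for a, b in zip(sched.values, sched.values[1:]))


class TestRunAbcPmc:
    def test_loose_epsilon_accepts_everything(self):
        distance, prior, _, _ = normal_mean_problem(seed=1)
        run = run_abcpmc(distance, prior, EpsilonSchedule((1e9,)), quota=50, seed=2)
        assert run[0].acceptance_ratio == 1.0

    def test_accepted_distances_below_epsilon(self):
        distance, prior, _, _ = normal_mean_problem(seed=3)
        run = run_abcpmc(
            distance, prior, AdaptiveSchedule(n_levels=3, quantile=0.5), quota=60, seed=4
        )
        for system in run:
            assert np.all(system.distances <= system.epsilon)
        assert run[-1].epsilon < run[1].epsilon < run[0].epsilon

    def test_rerun_identical(self):
        distance, prior, _, _ = normal_mean_problem(seed=5)
        r1 = run_abcpmc(distance, prior, AdaptiveSchedule(3), quota=40, seed=6)
        r2 = run_abcpmc(distance, prior, AdaptiveSchedule(3), quota=40, seed=6)
        np.testing.assert_array_equal(r1[-1].thetas, r2[-1].thetas)

    def test_budget_exhaustion_returns_partial(self):
        distance, prior, _, _ = normal_mean_problem(seed=7)
        run = run_abcpmc(
            distance, prior, EpsilonSchedule((1e9, 1e-9)), quota=30, seed=8,
            proposal_budget=60,
        )
        assert not run[-1].complete
        assert len(run) == 2  # the ladder stops at the stalled level

    def test_toy_posterior_mean_recovered(self):
        distance, prior, post_mean, _ = normal_mean_problem(seed=9)
        run = run_abcpmc(distance, prior, AdaptiveSchedule(5), quota=200, seed=10)
        final = run[-1]
        mean = float(np.dot(final.weights, final.thetas[:, 0]))
        sd = float(np.sqrt(np.dot(final.weights, (final.thetas[:, 0] - mean) ** 2)))
        ess = 1.0 / np.sum(final.weights**2)
        assert abs(mean - post_mean) < 3 * sd / math.sqrt(ess)


def make_system(rate, epsilon=0.01, n=50, seed=0):
    rng = np.random.default_rng(seed)
    thetas = rng.random((n, 2))
    return ParticleSystem(
        step=2,
        epsilon=epsilon,
        names=("a", "b"),
        thetas=thetas,
        distances=rng.uniform(0, epsilon, n),
        weights=np.full(n, 1 / n),
        raw_weights=np.ones(n),
        n_proposed=int(n / rate),
    )


class TestBayesFactor:
    def test_identical_runs_give_one(self):
        run = [make_system(0.02)]
        assert bayes_factor(run, run) == pytest.approx(1.0)

    def test_rate_ratio(self):
        assert bayes_factor([make_system(0.02)], [make_system(0.01)]) == pytest.approx(2.0)

    def test_reciprocal_identity(self):
        r1, r2 = [make_system(0.02, seed=1)], [make_system(0.013, seed=2)]
        assert bayes_factor(r1, r2) * bayes_factor(r2, r1) == pytest.approx(1.0)

    def test_zero_denominator_is_infinite(self):
        empty = make_system(0.02)
        empty = ParticleSystem(
            step=2, epsilon=0.01, names=("a", "b"),
            thetas=np.empty((0, 2)), distances=np.empty(0),
            weights=np.empty(0), raw_weights=np.empty(0), n_proposed=100,
        )
        assert bayes_factor([make_system(0.02)], [empty]) == math.inf

    def test_matrix_diagonal_and_reciprocal(self):
        runs = {"m1": [make_system(0.02, seed=1)], "m2": [make_system(0.04, seed=2)]}
        mat = bayes_factor_matrix(runs)
        assert mat.loc["m1", "m1"] == 1.0
        assert mat.loc["m1", "m2"] * mat.loc["m2", "m1"] == pytest.approx(1.0)


class TestPosteriorSummary:
    def test_point_mass_zero_width(self):
        thetas = np.full((20, 1), 3.3)
        s = posterior_summary((thetas, np.full(20, 0.05)), names=("x",))
        assert s["x"].mode == pytest.approx(3.3)
        assert s["x"].hdr[0.95] == ((3.3, 3.3),)

    def test_hdr_nesting(self, rng):
        thetas = rng.normal(0, 1, (400, 1))
        s = posterior_summary((thetas, np.full(400, 1 / 400)), names=("x",))["x"]
        lo75, hi75 = s.hull(0.75)
        lo95, hi95 = s.hull(0.95)
        assert lo95 <= lo75 <= hi75 <= hi95

    def test_uniform_hdr_length(self, rng):
        thetas = rng.random((3000, 1))
        s = posterior_summary((thetas, np.full(3000, 1 / 3000)), names=("x",))["x"]
        length = sum(hi - lo for lo, hi in s.hdr[0.75])
        assert length == pytest.approx(0.75, abs=0.08)

    def test_too_few_particles(self):
        with pytest.raises(ValueError, match="10 particles"):
            posterior_summary((np.zeros((5, 1)), np.full(5, 0.2)))

    def test_matches_arviz_hdi_on_unimodal_sample(self, rng):
        import arviz

        x = rng.normal(2.0, 0.5, 2000)
        s = posterior_summary((x[:, None], np.full(x.size, 1 / x.size)), names=("x",))["x"]
        lo, hi = s.hull(0.95)
        ref_lo, ref_hi = arviz.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref_lo, abs=0.15)
        assert hi == pytest.approx(ref_hi, abs=0.15)

    def test_mode_near_density_peak(self, rng):
        x = np.concatenate([rng.normal(0, 0.2, 1500), rng.normal(3, 1.0, 500)])
        s = posterior_summary((x[:, None], np.full(x.size, 1 / x.size)), names=("x",))["x"]
        assert abs(s.mode) < 0.2
        assert hdr_contains(s, 0.95, 0.0)
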