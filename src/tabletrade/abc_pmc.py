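"""Approximate Bayesian computation with population Monte Carlo (ABC-PMC).

A particle population is filtered through a decreasing ladder of acceptance
thresholds (epsilons).  The first generation proposes from the prior; later
generations resample accepted particles by weight and perturb them with a
multivariate Gaussian kernel whose covariance is twice the weighted
empirical covariance of the previous pool.  Importance weights follow the
standard adaptive scheme (prior density over kernel mixture density); a
``weights="uniform"`` switch reproduces plain unweighted PMC.

Model evidence is approximated by the final-generation acceptance rate
(importance-weight corrected), and Bayes factors are ratios of those rates.
Posterior summaries are weighted Gaussian-KDE highest-density regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abm import SimParams, run_simulation
from .chronology import Chronology
from .patterns import PatternMatrix
from .summaries import combined_distance, simulated_patterns

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "EpsilonSchedule",
    "AdaptiveSchedule",
    "ParticleSystem",
    "sample_prior",
    "perturb_particle",
    "PerturbationKernel",
    "run_abcpmc",
    "bayes_factor",
    "bayes_factor_matrix",
    "posterior_summary",
    "hdr_contains",
    "tableware_prior",
    "theta_to_params",
    "make_distance_fn",
    "infer_variant",
    "calibrate_schedule",
    "PARAM_NAMES",
]

PARAM_NAMES: tuple[str, ...] = ("mu", "mu_max", "lam", "lam_str", "t", "omega")


# ---------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class PriorSpec:
    """Independent marginal priors plus hard joint constraints.

    ``dists`` are frozen scipy distributions, one per parameter.  ``clip_unit``
    marks rate parameters clamped to [0, 1] during kernel perturbation and
    ``clip_positive`` parameters clamped strictly positive (but *not* to their
    prior upper bound, so later generations may explore beyond it).
    ``active`` names the parameters a model variant actually uses; inactive
    ones are carried through sampling and perturbation but ignored by the
    simulator.
    """

    names: tuple[str, ...]
    dists: tuple
    constraint: Callable[[np.ndarray], bool] | None = None
    clip_unit: tuple[int, ...] = ()
    clip_positive: tuple[int, ...] = ()
    active: tuple[str, ...] | None = None
    max_tries: int = 100_000

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample one parameter vector satisfying all constraints."""
        for _ in range(self.max_tries):
            theta = np.array([d.rvs(random_state=rng) for d in self.dists])
            if self.constraint is None or self.constraint(theta):
                return theta
        raise RuntimeError("prior rejection sampling exhausted its attempt cap")

    def pdf(self, theta: np.ndarray) -> float:
        """Unnormalised joint density (constraint truncation constant dropped)."""
        theta = np.asarray(theta, float)
        if self.constraint is not None and not self.constraint(theta):
            return 0.0
        p = 1.0
        for x, d in zip(theta, self.dists):
            p *= d.pdf(x)
        return float(p)

    def ranges(self) -> np.ndarray:
        """Per-parameter reference ranges (central 99% of each marginal)."""
        lo = np.array([d.ppf(0.005) for d in self.dists])
        hi = np.array([d.ppf(0.995) for d in self.dists])
        return hi - lo

    def clamp(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        for i in self.clip_unit:
            out[i] = min(1.0, max(0.0, out[i]))
        for i in self.clip_positive:
            out[i] = max(1e-9, out[i])
        return out


def _tableware_constraint(theta: np.ndarray) -> bool:
    t, omega = theta[4], theta[5]
    if omega < 2.0:
        return False
    ci = t / omega
    return 50.0 <= ci <= 1000.0


def tableware_prior(variant: str = "independent") -> PriorSpec:
    """Priors for the market model: rates U(0,1), spreads U(0,10),
    t ~ U(50, 1000) economic steps, omega ~ U(1, 50), with the hard
    constraints omega >= 2 and 50 <= t/omega <= 1000."""
    active = {
        "independent": ("mu", "mu_max", "t", "omega"),
        "unbiased": ("mu", "mu_max", "lam", "t", "omega"),
        "success_biased": ("mu", "mu_max", "lam_str", "t", "omega"),
    }[variant]
    return PriorSpec(
        names=PARAM_NAMES,
        dists=(
            stats.uniform(0, 1),
            stats.uniform(0, 10),
            stats.uniform(0, 1),
            stats.uniform(0, 10),
            stats.uniform(50, 950),
            stats.uniform(1, 49),
        ),
        constraint=_tableware_constraint,
        clip_unit=(0, 2),
        clip_positive=(1, 3, 4, 5),
        active=active,
    )


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one constraint-satisfying parameter vector from the prior."""
    return prior.sample(rng)


# ---------------------------------------------------------------------------
# perturbation kernel

class PerturbationKernel:
    """Gaussian resample-and-jitter kernel fitted to a weighted pool."""

    def __init__(self, thetas: np.ndarray, weights: np.ndarray, prior: PriorSpec):
        self.thetas = np.asarray(thetas, float)
        self.weights = np.asarray(weights, float)
        self.prior = prior
        d = self.thetas.shape[1]
        cov = None
        if self.thetas.shape[0] > 1:
            cov = 2.0 * np.cov(self.thetas.T, aweights=self.weights, ddof=0)
            cov = np.atleast_2d(cov)
        self.fallback = False
        if cov is None or not np.all(np.isfinite(cov)):
            cov = None
        if cov is not None:
            try:
                np.linalg.cholesky(cov + 1e-12 * np.eye(d))
            except np.linalg.LinAlgError:
                cov = None
        if cov is None:
            # degenerate pool: diagonal jitter of 1% of each parameter's range
            self.fallback = True
            cov = np.diag((0.01 * prior.ranges()) ** 2)
        self.cov = cov
        self._mvn = stats.multivariate_normal(
            mean=np.zeros(d), cov=cov, allow_singular=True
        )
        self._chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))

    def sample(self, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
        """Resample a particle by weight, jitter, clamp; retry on constraint
        violation.  Falls back to the (valid) resampled particle itself if the
        retry budget is exhausted."""
        for _ in range(max_tries):
            idx = rng.choice(self.thetas.shape[0], p=self.weights)
            theta = self.thetas[idx] + self._chol @ rng.standard_normal(self.thetas.shape[1])
            theta = self.prior.clamp(theta)
            if self.prior.constraint is None or self.prior.constraint(theta):
                return theta
        logger.warning("kernel retry budget exhausted; returning resampled particle")
        return self.thetas[idx].copy()

    def mixture_density(self, new_thetas: np.ndarray) -> np.ndarray:
        """Weighted mixture density of the kernel at each new particle."""
        new_thetas = np.atleast_2d(new_thetas)
        out = np.empty(new_thetas.shape[0])
        for k, th in enumerate(new_thetas):
            out[k] = float(np.dot(self.weights, self._mvn.pdf(th - self.thetas)))
        return out


def perturb_particle(
    thetas: np.ndarray,
    weights: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One kernel draw from a weighted pool (convenience wrapper)."""
    return PerturbationKernel(np.atleast_2d(thetas), np.asarray(weights, float), prior).sample(rng)


# ---------------------------------------------------------------------------
# epsilon schedules

@dataclass(frozen=True)
class EpsilonSchedule:
    """A fixed, strictly decreasing ladder of acceptance thresholds."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("schedule must have at least one level")
        if any(b >= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("epsilons must be strictly decreasing")

    @classmethod
    def published(cls) -> "EpsilonSchedule":
        """The 13-step ladder used for the full-scale study."""
        return cls(
            (0.13, 0.011, 0.0109, 0.0108, 0.0107, 0.0106, 0.0105,
             0.0104, 0.0103, 0.0102, 0.0101, 0.0100, 0.0099)
        )

    @classmethod
    def from_distances(
        cls,
        distances: Sequence[float],
        n_levels: int = 4,
        quantiles: Sequence[float] | None = None,
    ) -> "EpsilonSchedule":
        """Quantile ladder from pilot distances (default 0.75 halving)."""
        d = np.asarray(distances, float)
        d = d[np.isfinite(d)]
        if d.size == 0:
            raise ValueError("no finite pilot distances")
        if quantiles is None:
            quantiles = [0.75 * 0.5**i for i in range(n_levels)]
        eps = [float(np.quantile(d, q)) for q in quantiles]
        out = [eps[0]]
        for e in eps[1:]:  # enforce strict decrease on ties
            out.append(min(e, out[-1] * (1 - 1e-9)))
        return cls(tuple(out))


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Epsilon chosen on the fly: level s+1 uses a quantile of level s's
    accepted distances; level 1 accepts everything."""

    n_levels: int = 4
    quantile: float = 0.5


# ---------------------------------------------------------------------------
# the PMC loop

@dataclass
class ParticleSystem:
    """One ABC-PMC generation: accepted particles with their bookkeeping."""

    step: int
    epsilon: float
    names: tuple[str, ...]
    thetas: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    raw_weights: np.ndarray
    n_proposed: int
    complete: bool = True

    @property
    def n_accepted(self) -> int:
        return self.thetas.shape[0]

    @property
    def acceptance_ratio(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0

    @property
    def likelihood(self) -> float:
        """Importance-weight-corrected acceptance rate: the ABC estimate of
        the prior-predictive probability of landing within epsilon."""
        return float(self.raw_weights.sum() / self.n_proposed) if self.n_proposed else 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thetas, columns=list(self.names))
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


def _proposal_seed(master_seed: int, step: int, counter: int) -> int:
    """Counter-based fan-out: identical regardless of evaluation order."""
    return int(
        np.random.SeedSequence((master_seed, step, counter)).generate_state(1)[0]
        % (2**31)
    )


def run_abcpmc(
    distance_fn: Callable[[np.ndarray, int], float],
    prior: PriorSpec,
    schedule: EpsilonSchedule | AdaptiveSchedule,
    quota: int = 500,
    seed: int = 0,
    proposal_budget: int | None = None,
    weights: str = "pmc",
) -> list[ParticleSystem]:
    """Run the full PMC ladder; returns one ParticleSystem per level.

    ``distance_fn(theta, sim_seed)`` must be a pure function.  If a level
    exhausts ``proposal_budget`` proposals before filling the quota, the
    partial pool is returned flagged incomplete and the ladder stops.
    """
    if weights not in ("pmc", "uniform"):
        raise ValueError("weights must be 'pmc' or 'uniform'")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xABC)))
    if proposal_budget is None:
        proposal_budget = 200 * quota
    adaptive = isinstance(schedule, AdaptiveSchedule)
    n_levels = schedule.n_levels if adaptive else len(schedule.values)

    systems: list[ParticleSystem] = []
    kernel: PerturbationKernel | None = None
    for level in range(n_levels):
        if adaptive:
            if level == 0:
                eps = math.inf
            else:
                prev_d = systems[-1].distances
                eps = float(np.quantile(prev_d, schedule.quantile))
        else:
            eps = schedule.values[level]
        acc_t: list[np.ndarray] = []
        acc_d: list[float] = []
        n_prop = 0
        while len(acc_t) < quota and n_prop < proposal_budget:
            if kernel is None:
                theta = prior.sample(rng)
            else:
                theta = kernel.sample(rng)
            sim_seed = _proposal_seed(seed, level, n_prop)
            n_prop += 1
            d = distance_fn(theta, sim_seed)
            if d < eps:
                acc_t.append(theta)
                acc_d.append(float(d))
        complete = len(acc_t) >= quota
        thetas = np.array(acc_t) if acc_t else np.empty((0, prior.dim))
        dists = np.array(acc_d)
        if kernel is None or weights == "uniform" or thetas.shape[0] == 0:
            raw = np.ones(thetas.shape[0])
        else:
            prior_pdf = np.array([prior.pdf(th) for th in thetas])
            mix = kernel.mixture_density(thetas)
            raw = np.where(mix > 0, prior_pdf / np.maximum(mix, 1e-300), 0.0)
        if thetas.shape[0] and raw.sum() > 0:
            norm_w = raw / raw.sum()
        else:
            if thetas.shape[0] and weights == "pmc" and kernel is not None:
                logger.warning("all importance weights vanished; using uniform")
            norm_w = (
                np.full(thetas.shape[0], 1.0 / thetas.shape[0])
                if thetas.shape[0]
                else np.empty(0)
            )
        systems.append(
            ParticleSystem(
                step=level + 1,
                epsilon=eps,
                names=prior.names,
                thetas=thetas,
                distances=dists,
                weights=norm_w,
                raw_weights=raw,
                n_proposed=n_prop,
                complete=complete,
            )
        )
        if not complete:
            logger.warning(
                "level %d incomplete: %d/%d accepted after %d proposals",
                level + 1,
                len(acc_t),
                quota,
                n_prop,
            )
            break
        kernel = PerturbationKernel(thetas, norm_w, prior)
    return systems


# ---------------------------------------------------------------------------
# model-level plumbing

def theta_to_params(
    theta: np.ndarray,
    variant: str,
    N: int = 500,
    T: float | None = None,
    copy_scope: str = "full",
) -> SimParams | None:
    """Map a continuous parameter vector onto integer-valued SimParams.

    Returns None when integer rounding lands outside the feasible region
    (the caller should treat that proposal as infinitely distant).
    """
    mu, mu_max, lam, lam_str, t, omega = theta
    t_i = int(round(t))
    om_i = max(2, int(round(omega)))
    if t_i < 50 * om_i or t_i // om_i > 1000:
        return None
    return SimParams(
        t=t_i,
        omega=om_i,
        mu=min(1.0, max(0.0, float(mu))),
        mu_max=max(0.0, float(mu_max)),
        variant=variant,
        lam=min(1.0, max(0.0, float(lam))),
        lam_str=max(0.0, float(lam_str)),
        N=N,
        T=T,
        copy_scope=copy_scope,
    )


def make_distance_fn(
    variant: str,
    obsA: PatternMatrix,
    obsB: PatternMatrix,
    N: int = 500,
    chronology: Chronology | None = None,
    method: str = "mean_sq",
    T: float | None = None,
) -> Callable[[np.ndarray, int], float]:
    """Build the pure (theta, seed) -> Delta simulator for one variant."""

    def distance(theta: np.ndarray, sim_seed: int) -> float:
        params = theta_to_params(theta, variant, N=N, T=T)
        if params is None:
            return math.inf
        log = run_simulation(params, chronology, rng=sim_seed)
        sA, sB = simulated_patterns(log)
        return combined_distance(sA, obsA, sB, obsB, method=method).combined

    return distance


def infer_variant(
    variant: str,
    observed: tuple[PatternMatrix, PatternMatrix],
    schedule: EpsilonSchedule | AdaptiveSchedule,
    quota: int = 500,
    seed: int = 0,
    N: int = 500,
    chronology: Chronology | None = None,
    prior: PriorSpec | None = None,
    **kwargs,
) -> list[ParticleSystem]:
    """ABC-PMC posterior for one learning variant against observed patterns."""
    prior = prior if prior is not None else tableware_prior(variant)
    fn = make_distance_fn(variant, observed[0], observed[1], N=N, chronology=chronology)
    return run_abcpmc(fn, prior, schedule, quota=quota, seed=seed, **kwargs)


def calibrate_schedule(
    distance_fns: Sequence[Callable[[np.ndarray, int], float]],
    prior: PriorSpec,
    n_pilot: int = 50,
    n_levels: int = 4,
    seed: int = 0,
    quantiles: Sequence[float] | None = None,
) -> EpsilonSchedule:
    """Fixed quantile ladder from a prior-predictive pilot pooled over models.

    Using one shared ladder for every model keeps cross-model acceptance
    rates (and hence Bayes factors) comparable.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB07)))
    dists: list[float] = []
    for k in range(n_pilot):
        theta = prior.sample(rng)
        for m, fn in enumerate(distance_fns):
            dists.append(fn(theta, _proposal_seed(seed, 1000 + m, k)))
    return EpsilonSchedule.from_distances(dists, n_levels=n_levels, quantiles=quantiles)


# ---------------------------------------------------------------------------
# model selection and posterior summaries

def bayes_factor(
    run_m1: Sequence[ParticleSystem], run_m2: Sequence[ParticleSystem]
) -> float:
    """K = L(m1) / L(m2) from final-level acceptance rates.

    Both runs should have reached the same final epsilon; a mismatch is
    tolerated with a warning (the comparison is then approximate).
    """
    f1, f2 = run_m1[-1], run_m2[-1]
    if not math.isclose(f1.epsilon, f2.epsilon, rel_tol=1e-9):
        logger.warning(
            "final epsilons differ (%g vs %g); Bayes factor is approximate",
            f1.epsilon,
            f2.epsilon,
        )
    L1, L2 = f1.likelihood, f2.likelihood
    if L2 == 0.0:
        logger.warning("zero acceptance in denominator model; K = +inf")
        return math.inf
    return L1 / L2


def bayes_factor_matrix(runs: dict[str, Sequence[ParticleSystem]]) -> pd.DataFrame:
    """Pairwise Bayes-factor matrix (rows over columns; ones on the diagonal)."""
    names = list(runs)
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a in names:
        for b in names:
            if a != b:
                mat.loc[a, b] = bayes_factor(runs[a], runs[b])
    return mat


@dataclass
class ParamSummary:
    """Weighted-KDE posterior summary of one parameter."""

    name: str
    mode: float
    mean: float
    sd: float
    hdr: dict[float, tuple[tuple[float, float], ...]] = field(default_factory=dict)

    def hull(self, mass: float) -> tuple[float, float]:
        iv = self.hdr[mass]
        return iv[0][0], iv[-1][1]


def _hdr_from_kde(grid: np.ndarray, dens: np.ndarray, mass: float) -> tuple[tuple[float, float], ...]:
    """Smallest density-ranked set of grid points covering the mass, merged
    into contiguous intervals (Hyndman highest-density-region construction)."""
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order])
    cum /= cum[-1]
    k = int(np.searchsorted(cum, mass))
    threshold = dens[order[min(k, len(order) - 1)]]
    sel = dens >= threshold
    intervals = []
    start = None
    for i, s in enumerate(sel):
        if s and start is None:
            start = i
        elif not s and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return tuple(intervals)


def posterior_summary(
    system: ParticleSystem | tuple[np.ndarray, np.ndarray],
    masses: Sequence[float] = (0.75, 0.95),
    names: Sequence[str] | None = None,
    grid_size: int = 512,
) -> dict[str, ParamSummary]:
    """Per-parameter mode and highest-density regions of a weighted pool.

    Weighted Gaussian KDE with Silverman bandwidth; the HDR for each mass is
    the smallest density-ranked region covering it.  A (numerically) point-
    mass parameter gets a zero-width HDR at the point.  Requires >= 10
    particles.
    """
    if isinstance(system, ParticleSystem):
        thetas, weights = system.thetas, system.weights
        names = names if names is not None else system.names
    else:
        thetas, weights = system
        thetas = np.atleast_2d(np.asarray(thetas, float))
        names = (
            tuple(names)
            if names is not None
            else tuple(f"param_{i}" for i in range(thetas.shape[1]))
        )
        weights = np.asarray(weights, float)
    if thetas.shape[0] < 10:
        raise ValueError("need at least 10 particles for a posterior summary")
    w = weights / weights.sum()
    out: dict[str, ParamSummary] = {}
    for i, name in enumerate(names):
        x = thetas[:, i]
        mean = float(np.dot(w, x))
        var = float(np.dot(w, (x - mean) ** 2))
        if var < 1e-20:
            point = float(x[0])
            out[name] = ParamSummary(
                name=name,
                mode=point,
                mean=mean,
                sd=0.0,
                hdr={m: ((point, point),) for m in masses},
            )
            continue
        kde = stats.gaussian_kde(x, weights=w, bw_method="silverman")
        bw = math.sqrt(float(kde.covariance[0, 0]))
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
        dens = kde(grid)
        summary = ParamSummary(
            name=name,
            mode=float(grid[int(np.argmax(dens))]),
            mean=mean,
            sd=math.sqrt(var),
        )
        for m in masses:
            summary.hdr[m] = _hdr_from_kde(grid, dens, m)
        out[name] = summary
    return out


def hdr_contains(summary: ParamSummary, mass: float, value: float) -> bool:
    """Whether a value lies inside any interval of the given-mass HDR."""
    return any(lo <= value <= hi for lo, hi in summary.hdr[mass])


def summary_table(summaries: dict[str, ParamSummary]) -> pd.DataFrame:
    """Flat table of modes and HDR hulls (one row per parameter)."""
    rows = []
    for name, s in summaries.items():
        row = {"parameter": name, "mode": s.mode, "mean": s.mean, "sd": s.sd}
        for m in s.hdr:
            lo, hi = s.hull(m)
            row[f"hdr{int(m * 100)}_lo"] = lo
            row[f"hdr{int(m * 100)}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
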