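"""Production--trade--consumption market over a dated chronology.

Each agent is the aggregated set of traders of one urban settlement.  Five
agents produce one ware each; the rest produce money.  Every economic step,
producers restock, every ordered pair of agents with distinct goods gets a
chance to trade (bid/ask ratios from private value vectors, geometric-mean
price, unit lots), and all goods are then consumed.  Every ``omega`` economic
steps a cultural step evaluates scores ("exchanged enough but not too much")
and lets the learning variant update value vectors.  Ware availability
follows the dated chronology, mapped linearly onto simulation steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import period_kernel, trade_kernel
from .chronology import WARES, Chronology, default_chronology

__all__ = [
    "GoodRegistry",
    "SimParams",
    "Population",
    "AcquisitionLog",
    "init_population",
    "produce",
    "trade_round",
    "consume_and_score",
    "apply_chronology",
    "run_simulation",
    "year_of_step",
]

VARIANTS = ("independent", "unbiased", "success_biased")


@dataclass
class GoodRegistry:
    """Ordered goods: the five wares plus money; per-good active flag.

    Money is always active; wares toggle with the chronology.
    """

    wares: tuple[str, ...] = WARES
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = np.zeros(self.n_goods, dtype=bool)
            self.active[self.money] = True
        else:
            self.active = np.asarray(self.active, dtype=bool).copy()
            if not self.active[self.money]:
                raise ValueError("money must always be active")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.wares + ("MONEY",)

    @property
    def n_goods(self) -> int:
        return len(self.wares) + 1

    @property
    def money(self) -> int:
        return len(self.wares)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def set_active_wares(self, ware_labels: Sequence[str]) -> None:
        new = np.zeros(self.n_goods, dtype=bool)
        new[self.money] = True
        for w in ware_labels:
            new[self.index(w)] = True
        self.active = new


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    ``t`` economic steps total; one cultural step every ``omega`` economic
    steps (``omega >= 2``), so ``CI = t // omega`` cultural steps, constrained
    to [50, 1000].  ``T`` is the score target per cultural window (defaults to
    ``omega``: one unit per economic step).  ``q_ware`` defaults to
    consumers / active wares so aggregate ware supply matches aggregate money
    demand; ``q_money`` is the per-consumer money income per step.
    """

    t: int
    omega: int
    mu: float
    mu_max: float
    variant: str = "independent"
    lam: float = 0.0
    lam_str: float = 1.0
    N: int = 500
    T: float | None = None
    q_ware: float | None = None
    q_money: float = 1.0
    copy_scope: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.omega < 2:
            raise ValueError("omega must be >= 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.lam_str < 0:
            raise ValueError("lam_str must be >= 0")
        if self.T is not None and self.T <= 0:
            raise ValueError("score target T must be positive")

    @property
    def CI(self) -> int:
        return self.t // self.omega

    def with_variant(self, variant: str) -> "SimParams":
        return replace(self, variant=variant)


@dataclass
class Population:
    """State of all agents: produced goods, value vectors, inventories, scores."""

    goods: GoodRegistry
    produced: np.ndarray  # (N,) good index each agent produces
    values: np.ndarray  # (N, n_goods) strictly positive private values
    inventory: np.ndarray  # (N, n_goods) nonnegative stock
    score: np.ndarray  # (N,) in [0, 1]
    tally: np.ndarray  # (N,) score-relevant units since last cultural step
    _pairs: tuple | None = field(default=None, repr=False)

    @property
    def n_agents(self) -> int:
        return self.produced.shape[0]

    @property
    def consumer_mask(self) -> np.ndarray:
        return self.produced == self.goods.money

    @property
    def consumers(self) -> np.ndarray:
        return np.flatnonzero(self.consumer_mask)

    def producer_of(self, ware: str) -> int:
        idx = self.goods.index(ware)
        return int(np.flatnonzero(self.produced == idx)[0])

    def invalidate_pairs(self) -> None:
        self._pairs = None

    def trade_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Ordered (buyer, seller) pairs among agents whose good is active."""
        key = self.goods.active.tobytes()
        if self._pairs is not None and self._pairs[0] == key:
            return self._pairs[1]
        eligible = np.flatnonzero(self.goods.active[self.produced])
        gi = self.produced[eligible]
        buyers, sellers = np.meshgrid(eligible, eligible, indexing="ij")
        distinct = gi[:, None] != gi[None, :]
        b = buyers[distinct].astype(np.int64)
        s = sellers[distinct].astype(np.int64)
        order = np.arange(b.shape[0], dtype=np.int64)
        self._pairs = (key, (b, s, order))
        return b, s, order


def init_population(
    params: SimParams,
    goods: GoodRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """One producer per ware (dormant until its phase), the rest consumers.

    Inventories start empty; every value v_ij is drawn uniformly from (0, 1].
    """
    rng = np.random.default_rng(rng)
    goods = goods if goods is not None else GoodRegistry()
    n_wares = len(goods.wares)
    if params.N < n_wares + 1:
        raise ValueError(f"N={params.N} too small for {n_wares} ware producers")
    produced = np.full(params.N, goods.money, dtype=np.int64)
    produced[:n_wares] = np.arange(n_wares)
    values = 1.0 - rng.random((params.N, goods.n_goods))  # uniform (0, 1]
    return Population(
        goods=goods,
        produced=produced,
        values=values,
        inventory=np.zeros((params.N, goods.n_goods)),
        score=np.zeros(params.N),
        tally=np.zeros(params.N),
    )


def produce(pop: Population, q_ware: float | None = None, q_money: float = 1.0) -> None:
    """Restock: active ware producers gain ``q_ware`` units (default
    consumers / active wares), consumers gain ``q_money`` money.  Dormant
    producers gain nothing."""
    goods = pop.goods
    active_wares = np.flatnonzero(goods.active[: goods.money])
    consumers = pop.consumer_mask
    n_consumers = int(consumers.sum())
    if active_wares.size:
        q = q_ware if q_ware is not None else n_consumers / active_wares.size
        for w in active_wares:
            producer = np.flatnonzero(pop.produced == w)
            pop.inventory[producer, w] += q
    pop.inventory[consumers, goods.money] += q_money


def trade_round(
    pop: Population,
    rng: np.random.Generator,
    acq: np.ndarray | None = None,
) -> np.ndarray:
    """Run one all-pairs trade round; returns the acquisition ledger.

    ``acq[agent, good]`` accumulates non-money units acquired this round
    (pass a buffer to accumulate across rounds).
    """
    if acq is None:
        acq = np.zeros_like(pop.inventory)
    buyers, sellers, order = pop.trade_pairs()
    if buyers.size:
        trade_kernel(
            pop.values,
            pop.inventory,
            pop.produced,
            pop.goods.money,
            buyers,
            sellers,
            order,
            acq,
            pop.tally,
            pop.consumer_mask,
            rng,
        )
    return acq


def consume_and_score(pop: Population, T: float | None = None, cultural: bool = False) -> None:
    """All goods are consumed (inventories zeroed).  At a cultural step the
    running tally c is scored as 1 - min(1, |c - T| / T) and reset."""
    from ._kernels import score_kernel

    pop.inventory[:] = 0.0
    if cultural:
        if T is None or T <= 0:
            raise ValueError("score target T must be positive")
        score_kernel(pop.tally, pop.score, float(T))


def apply_chronology(
    pop: Population, active_wares: Sequence[str], rng: np.random.Generator
) -> None:
    """Switch the market to a new phase's ware set.

    Newly available wares get a fresh uniform (0, 1] value at every agent and
    their producer re-enters the market; departing wares keep their (frozen)
    values but are excluded from production and trade.
    """
    goods = pop.goods
    old = goods.active.copy()
    goods.set_active_wares(active_wares)
    newly = np.flatnonzero(goods.active & ~old)
    for g in newly:
        pop.values[:, g] = 1.0 - rng.random(pop.n_agents)
    pop.invalidate_pairs()


def year_of_step(step: int, t: int) -> float:
    """Linear calendar mapping of economic steps onto -200..300."""
    return -200.0 + 500.0 * step / t


@dataclass
class AcquisitionLog:
    """Per-period acquisition record of a run: (50, n_consumers, n_wares)."""

    units: np.ndarray
    wares: tuple[str, ...]
    params: SimParams
    t_effective: int

    @property
    def n_periods(self) -> int:
        return self.units.shape[0]

    @property
    def n_consumers(self) -> int:
        return self.units.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format (period, agent, ware, units), nonzero entries only."""
        p, a, w = np.nonzero(self.units)
        return pd.DataFrame(
            {
                "period": p,
                "agent": a,
                "ware": [self.wares[i] for i in w],
                "units": self.units[p, a, w],
            }
        )


def run_simulation(
    params: SimParams,
    chronology: Chronology | None = None,
    rng: np.random.Generator | int | None = None,
    n_periods: int = 50,
) -> AcquisitionLog:
    """Run the full market simulation and return the acquisition log.

    ``t`` is rounded down to the nearest multiple of ``n_periods * omega`` so
    the 50 reporting periods each hold a whole number of cultural steps; a
    ``t`` below one cultural step per period is an error.
    """
    chronology = chronology if chronology is not None else default_chronology()
    rng = np.random.default_rng(rng)
    block = n_periods * params.omega
    if params.t < block:
        raise ValueError(
            f"t={params.t} gives fewer than {n_periods} cultural steps (omega={params.omega})"
        )
    t_eff = block * (params.t // block)
    steps_per_period = t_eff // n_periods
    T = params.T if params.T is not None else float(params.omega)

    goods = GoodRegistry()
    pop = init_population(params, goods, rng)
    consumers = pop.consumers
    n_wares = len(goods.wares)

    phase_starts = np.array([p.year_from for p in chronology.phases], dtype=float)
    years = -200.0 + 500.0 * np.arange(t_eff) / t_eff
    phase_idx = np.searchsorted(phase_starts, years, side="right") - 1
    change_steps = [0] + list(np.flatnonzero(np.diff(phase_idx)) + 1)

    # segment the run at phase changes and period boundaries; inside a
    # segment one kernel call handles economic and cultural steps alike
    seg_starts = sorted(
        set(change_steps) | set(range(0, t_eff, steps_per_period))
    )
    seg_ends = seg_starts[1:] + [t_eff]
    variant_code = {"independent": 0, "unbiased": 1, "success_biased": 2}[params.variant]
    group = consumers.astype(np.int64)
    scratch_a = np.empty(params.N, dtype=np.int64)
    scratch_b = np.empty(params.N, dtype=np.int64)

    log = np.zeros((n_periods, consumers.size, n_wares))
    acq = np.zeros_like(pop.inventory)
    for s0, s1 in zip(seg_starts, seg_ends):
        if s0 in change_steps:
            apply_chronology(pop, chronology.phases[int(phase_idx[s0])].wares, rng)
        active_wares = np.flatnonzero(goods.active[: goods.money])
        prod_agents = np.array(
            [np.flatnonzero(pop.produced == w)[0] for w in active_wares], dtype=np.int64
        )
        q_ware = (
            params.q_ware
            if params.q_ware is not None
            else consumers.size / max(1, active_wares.size)
        )
        quota = min(int(0.2 * params.N / goods.n_active), group.size - 1)
        buyers, sellers, order = pop.trade_pairs()
        period_kernel(
            pop.values,
            pop.inventory,
            pop.produced,
            goods.money,
            buyers,
            sellers,
            order,
            acq,
            pop.tally,
            pop.score,
            pop.consumer_mask,
            prod_agents,
            active_wares.astype(np.int64),
            float(q_ware),
            consumers.astype(np.int64),
            float(params.q_money),
            s1 - s0,
            s0,
            params.omega,
            T,
            variant_code,
            group,
            float(params.lam),
            float(params.lam_str),
            quota,
            10 * group.size,
            goods.money if params.copy_scope == "single_good" else -1,
            float(params.mu),
            float(params.mu_max),
            np.flatnonzero(goods.active).astype(np.int64),
            rng,
            scratch_a,
            scratch_b,
        )
        log[s0 // steps_per_period] += acq[consumers, :n_wares]
        acq[:] = 0.0
    return AcquisitionLog(units=log, wares=goods.wares, params=params, t_effective=t_eff)
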