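"""Cultural transmission of buying strategies, plus innovation.

A strategy is an agent's whole value vector.  At each cultural step one of
three variants runs:

* independent -- no copying at all; strategies drift only by innovation;
* unbiased -- each agent copies a random peer's vector with probability
  ``lam`` (the social-learning rate);
* success-biased -- low-scoring agents are preferentially selected for
  replacement and preferentially copy high-scoring peers, with the bias
  strength ``lam_str`` entering as an exponent on scores in both selection
  tests (``lam_str = 1`` is the plain algorithm).

Copying happens among agents producing the same good: with one producer per
ware, the consumers (money producers) -- the settlement traders whose buying
strategies the hypotheses concern -- form the only group where copying can
occur.  Innovation perturbs one active-good value per innovating agent.
Learning touches only value vectors, never inventories or scores.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .abm import Population, SimParams

logger = logging.getLogger(__name__)

__all__ = ["innovate", "unbiased_copy", "success_biased_copy", "cultural_transmission"]

_EPS = 1e-9


def innovate(
    pop: "Population",
    mu: float,
    mu_max: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> int:
    """Each agent, with probability ``mu``, redraws one active-good value.

    The replacement is uniform on (max(eps, v(1-mu_max)), v(1+mu_max)), so
    values stay strictly positive however large the innovation spread.
    Returns the number of agents that innovated.
    """
    from ._kernels import innovate_kernel

    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if mu_max < 0:
        raise ValueError("mu_max must be >= 0")
    active = np.flatnonzero(pop.goods.active).astype(np.int64)
    if active.size == 0:
        return 0
    hit = np.empty(pop.n_agents, dtype=np.int64)
    col = np.empty(pop.n_agents, dtype=np.int64)
    n_hit = innovate_kernel(pop.values, active, mu, mu_max, rng, hit, col)
    if events is not None:
        events.extend(
            ("innovate", int(hit[k]), int(col[k])) for k in range(n_hit)
        )
    return int(n_hit)


def _groups(pop: "Population") -> list[np.ndarray]:
    """Same-produced-good groups among agents whose good is active."""
    out = []
    for g in np.flatnonzero(pop.goods.active):
        members = np.flatnonzero(pop.produced == g)
        if members.size:
            out.append(members)
    return out


def unbiased_copy(
    pop: "Population",
    lam: float,
    rng: np.random.Generator,
    events: list | None = None,
) -> int:
    """Each agent, with probability ``lam``, copies a uniformly chosen other
    agent's entire value vector (within its produced-good group).

    Copies are simultaneous: everyone copies from the pre-step snapshot, so
    with ``lam = 1`` a two-agent group swaps vectors.  Groups of one are
    skipped.  Returns the number of copy events.
    """
    from ._kernels import unbiased_kernel

    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    n_copied = 0
    for group in _groups(pop):
        gsize = group.size
        if gsize <= 1:
            continue
        src = np.empty(gsize, dtype=np.int64)
        tgt = np.empty(gsize, dtype=np.int64)
        n = unbiased_kernel(pop.values, group.astype(np.int64), lam, rng, src, tgt)
        if events is not None:
            events.extend(
                ("unbiased", int(src[k]), int(tgt[k])) for k in range(n)
            )
        n_copied += int(n)
    return n_copied


def success_biased_copy(
    pop: "Population",
    lam_str: float,
    rng: np.random.Generator,
    to_get: int | None = None,
    copy_scope: str = "full",
    attempt_factor: int = 10,
    events: list | None = None,
) -> dict:
    """Success-biased transmission: the low-scoring copy the high-scoring.

    Per good g (group = agents producing g, skipped if of size one):

    1. a replacement quota ``ToGet = floor(0.2 N / n_good)`` (capped at
       group size - 1) is filled by repeatedly sampling j uniformly and
       admitting it when a uniform draw X satisfies X > score(j)**lam_str --
       low scores are admitted preferentially;
    2. while candidates remain, a random j from the set and a random model i
       from the group are drawn; j copies i's vector when a uniform draw X
       satisfies X < score(i)**lam_str *and* score(i) > score(j) strictly.

    Both loops are bounded by ``attempt_factor * group size`` attempts;
    leftover candidates are dropped with a log entry.  ``copy_scope`` is
    "full" (whole vector) or "single_good" (only good g's value).
    Returns counters {"copied", "dropped"}.
    """
    if lam_str < 0:
        raise ValueError("lam_str must be >= 0")
    if copy_scope not in ("full", "single_good"):
        raise ValueError("copy_scope must be 'full' or 'single_good'")
    from ._kernels import success_biased_kernel

    n_good = pop.goods.n_active
    quota_default = int(0.2 * pop.n_agents / n_good)
    copied = dropped = 0
    for group in _groups(pop):
        gsize = group.size
        if gsize <= 1:
            continue
        g = int(pop.produced[group[0]])
        quota = min(quota_default if to_get is None else to_get, gsize - 1)
        if quota <= 0:
            continue
        budget = attempt_factor * gsize
        src = np.empty(quota, dtype=np.int64)
        tgt = np.empty(quota, dtype=np.int64)
        n_copied, n_left = success_biased_kernel(
            pop.values,
            pop.score,
            group.astype(np.int64),
            quota,
            budget,
            lam_str,
            g if copy_scope == "single_good" else -1,
            rng,
            src,
            tgt,
        )
        copied += n_copied
        if events is not None:
            events.extend(
                ("success_biased", int(src[k]), int(tgt[k])) for k in range(n_copied)
            )
        if n_left:
            dropped += n_left
            logger.debug(
                "success-biased pass: %d replacement candidates dropped "
                "after attempt budget (good %d)",
                n_left,
                g,
            )
    return {"copied": copied, "dropped": dropped}


def cultural_transmission(
    pop: "Population",
    params: "SimParams",
    rng: np.random.Generator,
    events: list | None = None,
) -> None:
    """Dispatch the variant's copying step (innovation is applied separately)."""
    if params.variant == "independent":
        return
    if params.variant == "unbiased":
        unbiased_copy(pop, params.lam, rng, events=events)
    else:
        success_biased_copy(
            pop, params.lam_str, rng, copy_scope=params.copy_scope, events=events
        )
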