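"""Numba kernels for the inner market loop.

The all-pairs trade round dominates simulation cost (O(N) producers x
consumers per economic step, every step).  Each operation has its own
kernel, exposed through the module-level API; ``period_kernel`` composes
them so a full reporting period (many economic steps plus its cultural
steps) costs a single dispatch.  All randomness flows through the numpy
Generator passed in, so equal-seed runs are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def trade_kernel(values, inv, produced, money, buyers, sellers, order, acq, tally, is_consumer, rng):
    """One trade round over every ordered (buyer, seller) pair.

    A buyer i facing seller j (distinct produced goods) bids
    b = v_i(g_j)/v_i(g_i); the seller asks a = v_j(g_j)/v_j(g_i).  One unit
    of g_j moves iff b >= a, the seller has stock and the buyer can pay the
    geometric-mean price sqrt(a*b) in units of its own good.  Pairs are
    visited in a fresh random order each round.

    Side effects: inventories updated in place; ``acq[agent, good]``
    accumulates non-money units flowing to each agent (bought, or received
    as payment); ``tally`` accumulates the score-relevant quantity --
    non-money units for consumers, money earned for producers.
    """
    n_pairs = buyers.shape[0]
    # Fisher-Yates shuffle of the visiting order (scaled-float index draws
    # are much cheaper than bounded integer draws in this inner loop)
    for k in range(n_pairs - 1, 0, -1):
        r = int(rng.random() * (k + 1))
        tmp = order[k]
        order[k] = order[r]
        order[r] = tmp
    for idx in range(n_pairs):
        m = order[idx]
        i = buyers[m]
        j = sellers[m]
        g = produced[j]
        pay = produced[i]
        if inv[j, g] < 1.0:
            continue
        b = values[i, g] / values[i, pay]
        a = values[j, g] / values[j, pay]
        if b < a:
            continue
        price = np.sqrt(a * b)
        if inv[i, pay] < price:
            continue
        inv[j, g] -= 1.0
        inv[i, g] += 1.0
        inv[i, pay] -= price
        inv[j, pay] += price
        if g == money:
            # buyer is a producer converting stock into money
            tally[i] += 1.0
        else:
            acq[i, g] += 1.0
            if is_consumer[i]:
                tally[i] += 1.0
        if pay == money:
            # seller is a producer earning money
            tally[j] += price
        else:
            acq[j, pay] += price
            if is_consumer[j]:
                tally[j] += price


@njit(cache=False)
def score_kernel(tally, score, T):
    """Score = 1 - min(1, |c - T| / T) from the running tally, then reset."""
    for i in range(tally.shape[0]):
        dev = abs(tally[i] - T) / T
        if dev > 1.0:
            dev = 1.0
        score[i] = 1.0 - dev
        tally[i] = 0.0


@njit(cache=False)
def innovate_kernel(values, active_goods, mu, mu_max, rng, hit_out, col_out):
    """Each agent, with probability mu, redraws one active-good value
    uniformly on (max(eps, v(1-mu_max)), v(1+mu_max)).  Innovating agents
    and columns are written to hit_out/col_out; returns the count."""
    eps = 1e-9
    n_hit = 0
    n_active = active_goods.shape[0]
    for i in range(values.shape[0]):
        if rng.random() < mu:
            c = active_goods[rng.integers(0, n_active)]
            v = values[i, c]
            hi = v * (1.0 + mu_max)
            lo = v * (1.0 - mu_max)
            if lo < eps:
                lo = eps
            if lo > hi:
                lo = hi
            values[i, c] = lo + rng.random() * (hi - lo)
            hit_out[n_hit] = i
            col_out[n_hit] = c
            n_hit += 1
    return n_hit


@njit(cache=False)
def unbiased_kernel(values, group, lam, rng, src_out, tgt_out):
    """Each group member, with probability lam, copies a uniformly chosen
    *other* member's whole value vector.  Copies are simultaneous (from a
    pre-step snapshot), so lam = 1 on a pair swaps the two vectors.
    Copy pairs are written to src_out/tgt_out; returns the count."""
    gsize = group.shape[0]
    snapshot = values[group].copy()
    n_copied = 0
    for k in range(gsize):
        if rng.random() < lam:
            d = rng.integers(0, gsize - 1)
            if d >= k:
                d += 1
            values[group[k]] = snapshot[d]
            src_out[n_copied] = group[d]
            tgt_out[n_copied] = group[k]
            n_copied += 1
    return n_copied


@njit(cache=False)
def success_biased_kernel(values, score, group, quota, budget, lam_str, single_good, rng, src_out, tgt_out):
    """Success-biased copying within one produced-good group.

    Phase 1 admits agents to the replacement set preferentially at *low*
    score (admit j when X > score_j**lam_str); phase 2 lets replaced agents
    copy preferentially *high*-scoring models (accept i when
    X < score_i**lam_str and score_i > score_j strictly).  Both phases are
    bounded by ``budget`` attempts.  Executed copies are written to
    src_out/tgt_out; returns (n_copied, n_dropped).
    """
    gsize = group.shape[0]
    to_replace = np.empty(quota, dtype=np.int64)
    in_set = np.zeros(gsize, dtype=np.bool_)
    n_rep = 0
    attempts = 0
    while n_rep < quota and attempts < budget:
        attempts += 1
        pos = rng.integers(0, gsize)
        j = group[pos]
        if in_set[pos]:
            continue
        if rng.random() > score[j] ** lam_str:
            to_replace[n_rep] = pos
            in_set[pos] = True
            n_rep += 1
    n_copied = 0
    attempts = 0
    while n_rep > 0 and attempts < budget:
        attempts += 1
        k = rng.integers(0, n_rep)
        jpos = to_replace[k]
        j = group[jpos]
        i = group[rng.integers(0, gsize)]
        if rng.random() < score[i] ** lam_str and score[i] > score[j]:
            if single_good >= 0:
                values[j, single_good] = values[i, single_good]
            else:
                for c in range(values.shape[1]):
                    values[j, c] = values[i, c]
            src_out[n_copied] = i
            tgt_out[n_copied] = j
            n_copied += 1
            n_rep -= 1
            to_replace[k] = to_replace[n_rep]
    return n_copied, n_rep


@njit(cache=False)
def period_kernel(
    values,
    inv,
    produced,
    money,
    buyers,
    sellers,
    order,
    acq,
    tally,
    score,
    is_consumer,
    prod_agents,
    prod_goods,
    q_ware,
    cons_rows,
    q_money,
    n_steps,
    step_offset,
    omega,
    T,
    variant_code,
    group,
    lam,
    lam_str,
    quota,
    budget,
    copy_single,
    mu,
    mu_max,
    active_goods,
    rng,
    scratch_a,
    scratch_b,
):
    """Run ``n_steps`` economic steps (produce -> trade -> consume), firing
    a cultural step (score, variant copying, innovation) whenever the global
    step count reaches a multiple of omega.  variant_code: 0 independent,
    1 unbiased, 2 success-biased.  ``scratch_a``/``scratch_b`` are reusable
    event buffers."""
    for s in range(n_steps):
        for k in range(prod_agents.shape[0]):
            inv[prod_agents[k], prod_goods[k]] += q_ware
        for k in range(cons_rows.shape[0]):
            inv[cons_rows[k], money] += q_money
        trade_kernel(values, inv, produced, money, buyers, sellers, order, acq, tally, is_consumer, rng)
        for i in range(inv.shape[0]):
            for c in range(inv.shape[1]):
                inv[i, c] = 0.0
        if (step_offset + s + 1) % omega == 0:
            score_kernel(tally, score, T)
            if variant_code == 1 and group.shape[0] > 1:
                unbiased_kernel(values, group, lam, rng, scratch_a, scratch_b)
            elif variant_code == 2 and group.shape[0] > 1 and quota > 0:
                success_biased_kernel(
                    values, score, group, quota, budget, lam_str, copy_single, rng, scratch_a, scratch_b
                )
            innovate_kernel(values, active_goods, mu, mu_max, rng, scratch_a, scratch_b)
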