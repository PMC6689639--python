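"""Compiled inner loop of the simulation engine.

This kernel replays, draw for draw, the exact random stream consumed by
the pure-numpy stage functions (science, evolution, funding), so a run
through the kernel is bit-identical to stepping the stages from Python.
numba's ``np.random.Generator`` support produces the same streams as
numpy for ``random``, ``integers``, ``normal`` and ``permutation``, and
every subset sample goes through the shared partial Fisher–Yates
protocol of ``_sampling``.

Strategy codes: 0=PH, 1=MI, 2=RA, 3=MS, 4=ML.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate", "STRATEGY_CODES"]

STRATEGY_CODES = {"PH": 0, "MI": 1, "RA": 2, "MS": 3, "ML": 4}


@njit(cache=True)
def _sample_wor(rng, pool, n, d):
    """Partial Fisher–Yates into pool[:d]; consumes one rng.random(d)."""
    u = rng.random(d)
    for i in range(n):
        pool[i] = i
    for i in range(d):
        j = i + int(u[i] * (n - i))
        tmp = pool[i]
        pool[i] = pool[j]
        pool[j] = tmp
    return d


@njit(cache=True)
def simulate(
    rng,
    alpha,
    funds,
    age,
    ids,
    pubs,
    errs,
    next_id,
    b,
    W,
    G0,
    G,
    d,
    eps,
    r,
    p,
    strategy,
    X,
    A,
    strong_selection,
    disable_evolution,
    disable_funding,
    auto_refund,
    iterations,
    record_interval,
    win_records,
    times,
    alpha_out,
    fdrcum_out,
    fdrwin_out,
    cumpub_out,
    cumerr_out,
):
    n = alpha.size
    pool = np.empty(n, dtype=np.int64)
    tie = np.empty(n, dtype=np.int64)
    funded = np.empty(n, dtype=np.int64)
    cum_pub = 0
    cum_err = 0

    # record the initial state
    times[0] = 0
    s = 0.0
    for i in range(n):
        s += alpha[i]
    alpha_out[0] = s / n
    fdrcum_out[0] = np.nan
    fdrwin_out[0] = np.nan
    cumpub_out[0] = 0
    cumerr_out[0] = 0
    rec = 1

    for t in range(1, iterations + 1):
        # ---- Science ----
        k = 0
        for i in range(n):
            if funds[i] > 0:
                funded[k] = i
                k += 1
        if k > 0:
            order = rng.permutation(funded[:k])
            u_truth = rng.random(k)
            u_pos = rng.random(k)
            u_pub = rng.random(k)
            for ii in range(k):
                lab = order[ii]
                truth = u_truth[ii] < b
                p_pos = W if truth else alpha[lab]
                pos = u_pos[ii] < p_pos
                err = truth != pos
                if pos:
                    pub_p = 1.0 if truth else 1.0 - r
                else:
                    pub_p = p * (1.0 - r) if truth else p
                funds[lab] -= 1
                if u_pub[ii] < pub_p:
                    pubs[lab] += 1
                    cum_pub += 1
                    if err:
                        errs[lab] += 1
                        cum_err += 1

        # ---- Evolution ----
        child_idx = -1
        if not disable_evolution:
            # death: oldest of a uniform d-sample, ties uniform
            _sample_wor(rng, pool, n, d)
            max_age = np.int64(-1)
            for i in range(d):
                a_ = age[pool[i]]
                if a_ > max_age:
                    max_age = a_
            nt = 0
            for i in range(d):
                if age[pool[i]] == max_age:
                    tie[nt] = pool[i]
                    nt += 1
            dead = tie[rng.integers(0, nt)]

            # parent from the n-1 survivors
            m = n - 1
            if strong_selection:
                dp = d if d < m else m
                _sample_wor(rng, pool, m, dp)
                best = np.int64(-1)
                for i in range(dp):
                    v = pool[i]
                    if v >= dead:
                        v += 1
                    pool[i] = v
                    if pubs[v] > best:
                        best = pubs[v]
                nt = 0
                for i in range(dp):
                    if pubs[pool[i]] == best:
                        tie[nt] = pool[i]
                        nt += 1
                parent = tie[rng.integers(0, nt)]
            else:
                total = np.int64(0)
                for i in range(n):
                    if i != dead:
                        total += pubs[i]
                if total > 0:
                    u = rng.random() * total
                    acc = 0.0
                    parent = -1
                    for i in range(n):
                        if i == dead:
                            continue
                        acc += pubs[i]
                        if u < acc:
                            parent = i
                            break
                    if parent < 0:
                        parent = n - 1 if dead != n - 1 else n - 2
                else:
                    pos = rng.integers(0, m)
                    parent = pos + 1 if pos >= dead else pos

            v = alpha[parent] + rng.normal(0.0, eps)
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            alpha[dead] = v
            funds[dead] = G0
            age[dead] = 0
            pubs[dead] = 0
            errs[dead] = 0
            ids[dead] = next_id
            next_id += 1
            child_idx = dead

        # ---- Grant-Seeking ----
        if not disable_funding:
            _sample_wor(rng, pool, n, d)
            st = strategy
            if st == 3:  # MS resolves to MI or RA per award
                st = 1 if rng.random() < X else 2
            winner = -1
            if st == 0:  # PH: most publications, ties uniform
                best = np.int64(-1)
                for i in range(d):
                    if pubs[pool[i]] > best:
                        best = pubs[pool[i]]
                nt = 0
                for i in range(d):
                    if pubs[pool[i]] == best:
                        tie[nt] = pool[i]
                        nt += 1
                winner = tie[rng.integers(0, nt)]
            elif st == 1:  # MI: lowest alpha, ties uniform
                best_a = 2.0
                for i in range(d):
                    if alpha[pool[i]] < best_a:
                        best_a = alpha[pool[i]]
                nt = 0
                for i in range(d):
                    if alpha[pool[i]] == best_a:
                        tie[nt] = pool[i]
                        nt += 1
                winner = tie[rng.integers(0, nt)]
            elif st == 2:  # RA
                winner = pool[rng.integers(0, d)]
            else:  # ML: uniform over qualified, none -> no award
                nt = 0
                for i in range(d):
                    if alpha[pool[i]] <= A:
                        tie[nt] = pool[i]
                        nt += 1
                if nt > 0:
                    winner = tie[rng.integers(0, nt)]
            if winner >= 0:
                funds[winner] += G

        # ---- iteration end ----
        for i in range(n):
            age[i] += 1
        if child_idx >= 0:
            age[child_idx] = 0
        if auto_refund:
            for i in range(n):
                funds[i] = G0

        if t % record_interval == 0:
            times[rec] = t
            s = 0.0
            for i in range(n):
                s += alpha[i]
            alpha_out[rec] = s / n
            cumpub_out[rec] = cum_pub
            cumerr_out[rec] = cum_err
            fdrcum_out[rec] = cum_err / cum_pub if cum_pub > 0 else np.nan
            j = rec - win_records
            if j < 0:
                j = 0
            dpb = cum_pub - cumpub_out[j]
            de = cum_err - cumerr_out[j]
            fdrwin_out[rec] = de / dpb if dpb > 0 else np.nan
            rec += 1

    return next_id, cum_pub, cum_err
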