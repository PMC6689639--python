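"""Iteration scheduler, metric accounting, and seeded reproducibility.

Each iteration applies the three stages in fixed order — Science,
Evolution, Grant-Seeking — then increments survivors' ages (the newborn
ends its birth iteration at age 0). All randomness flows through one
seeded ``numpy`` Generator in a fixed draw order (science permutation and
Bernoulli vectors; death sample and tie-break; parent sample and
tie-break; mutation; applicant sample; award draw), so a run is fully
determined by ``(seed, params)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .evolution import run_evolution_step
from .funding import award_grant, select_applicants
from .science import run_science_step
from .types import (
    LabPopulation,
    Params,
    RunRecord,
    StepStats,
    validate_params,
)

__all__ = [
    "SimState",
    "initial_state",
    "step",
    "mean_alpha",
    "fdr",
    "run",
    "detect_convergence",
]


@dataclass
class SimState:
    """Mutable simulation state: the population plus cumulative tallies."""

    labs: LabPopulation
    rng: np.random.Generator
    iteration: int = 0
    cum_publications: int = 0
    cum_erroneous: int = 0


def initial_state(params: Params) -> SimState:
    """Founding state: all labs at alpha0 with funds G0 and age 0."""
    return SimState(
        labs=LabPopulation.initial(params),
        rng=np.random.default_rng(params.seed),
    )


def mean_alpha(state: SimState) -> float:
    """Community mean false positive rate over all labs."""
    if len(state.labs) == 0:
        raise ValueError("empty population has no mean alpha")
    return float(state.labs.alpha.mean())


def fdr(cum_erroneous: int, cum_publications: int) -> float:
    """False discovery rate erroneous/published; NaN when nothing published."""
    if cum_publications == 0:
        return math.nan
    return cum_erroneous / cum_publications


def step(
    state: SimState,
    params: Params,
    hooks: Optional[list[Callable[[str, SimState], None]]] = None,
) -> StepStats:
    """Advance one iteration in place: Science, Evolution, Grant-Seeking.

    ``hooks``, when given, are called as ``hook(stage_name, state)`` after
    each stage — instrumentation for tests asserting stage order and
    per-stage invariants.
    """

    def _notify(stage: str) -> None:
        if hooks:
            for h in hooks:
                h(stage, state)

    stats, _ = run_science_step(state.labs, params, state.rng)
    _notify("science")

    event = None
    if not params.disable_evolution:
        event = run_evolution_step(state.labs, params, state.rng)
        stats.dead_id = event.dead_id
        stats.dead_funds = event.dead_funds
    _notify("evolution")

    if not params.disable_funding:
        applicants = select_applicants(state.labs, params.d, state.rng)
        award = award_grant(state.labs, applicants, params, state.rng)
        stats.grant_awarded = award.winner_id is not None
        stats.winner_id = award.winner_id
    _notify("funding")

    state.labs.age += 1
    if event is not None:
        state.labs.age[event.index] = 0
    if params.auto_refund:
        state.labs.funds[:] = params.G0

    state.cum_publications += stats.publications
    state.cum_erroneous += stats.erroneous_publications
    state.iteration += 1
    return stats


def _alloc_series(params: Params):
    n_rec = params.iterations // params.record_interval + 1
    return (
        np.empty(n_rec, dtype=np.int64),
        np.empty(n_rec, dtype=np.float64),
        np.empty(n_rec, dtype=np.float64),
        np.empty(n_rec, dtype=np.float64),
        np.empty(n_rec, dtype=np.int64),
        np.empty(n_rec, dtype=np.int64),
    )


def run(params: Params, compiled: bool = True) -> RunRecord:
    """Execute ``params.iterations`` steps and record the metric series.

    The mean false positive rate, cumulative false discovery rate, and
    the false discovery rate over the trailing ``fdr_window`` iterations
    are recorded every ``record_interval`` iterations (iteration 0, the
    initial state, included).

    ``compiled=True`` runs the numba kernel, which replays the same
    random stream as the Python stages and therefore yields an identical
    RunRecord (asserted in the test suite); ``compiled=False`` steps the
    stage functions directly.
    """
    validate_params(params)
    if not params.disable_evolution and params.n < 2:
        raise ValueError("n must be >= 2 when the evolution stage is enabled")
    if compiled:
        return _run_compiled(params)
    return _run_python(params)


def _run_compiled(params: Params) -> RunRecord:
    from ._kernel import STRATEGY_CODES, simulate

    labs = LabPopulation.initial(params)
    rng = np.random.default_rng(params.seed)
    times, alpha_s, fdr_cum, fdr_win, cum_pub, cum_err = _alloc_series(params)
    win_records = max(1, params.fdr_window // params.record_interval)
    _, total_pub, total_err = simulate(
        rng,
        labs.alpha,
        labs.funds,
        labs.age,
        labs.ids,
        labs.publications,
        labs.erroneous_publications,
        labs.next_id,
        params.b,
        params.W,
        params.G0,
        params.G,
        params.d,
        params.epsilon,
        params.r,
        params.p,
        STRATEGY_CODES[params.strategy.value],
        -1.0 if params.X is None else params.X,
        -1.0 if params.A is None else params.A,
        params.selection_mode == "strong",
        params.disable_evolution,
        params.disable_funding,
        params.auto_refund,
        params.iterations,
        params.record_interval,
        win_records,
        times,
        alpha_s,
        fdr_cum,
        fdr_win,
        cum_pub,
        cum_err,
    )
    return RunRecord(
        params=params,
        times=times,
        mean_alpha=alpha_s,
        fdr_cumulative=fdr_cum,
        fdr_windowed=fdr_win,
        cum_publications=cum_pub,
        cum_erroneous=cum_err,
        total_publications=int(total_pub),
        total_erroneous=int(total_err),
    )


def _run_python(params: Params) -> RunRecord:
    state = initial_state(params)
    interval = params.record_interval
    times, alpha_s, fdr_cum, fdr_win, cum_pub, cum_err = _alloc_series(params)
    win_records = max(1, params.fdr_window // interval)

    def record(i: int) -> None:
        times[i] = state.iteration
        alpha_s[i] = mean_alpha(state)
        fdr_cum[i] = fdr(state.cum_erroneous, state.cum_publications)
        cum_pub[i] = state.cum_publications
        cum_err[i] = state.cum_erroneous
        j = max(0, i - win_records)
        dp = cum_pub[i] - cum_pub[j]
        de = cum_err[i] - cum_err[j]
        fdr_win[i] = de / dp if dp > 0 else math.nan

    record(0)
    rec = 1
    for t in range(1, params.iterations + 1):
        step(state, params)
        if t % interval == 0:
            record(rec)
            rec += 1

    return RunRecord(
        params=params,
        times=times,
        mean_alpha=alpha_s,
        fdr_cumulative=fdr_cum,
        fdr_windowed=fdr_win,
        cum_publications=cum_pub,
        cum_erroneous=cum_err,
        total_publications=state.cum_publications,
        total_erroneous=state.cum_erroneous,
    )


def detect_convergence(
    series: np.ndarray | list[float], window: int, tolerance: float
) -> Optional[int]:
    """First index whose trailing-window mean stays near the final one.

    ``window`` counts series entries. Returns the first position ``i``
    (>= window - 1) at which the mean over entries ``i-window+1 .. i``
    lies within ``tolerance`` of the final-window mean, does so for every
    later position, and is followed by at least one further full window
    of stability — so a series still drifting into its last window (a
    ramp with no plateau) reports ``None`` rather than its own endpoint.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    s = np.asarray(series, dtype=np.float64)
    if s.size < window:
        return None
    cs = np.concatenate(([0.0], np.cumsum(s)))
    means = (cs[window:] - cs[:-window]) / window  # means[i] ends at i+window-1
    ok = np.abs(means - means[-1]) <= tolerance
    # positions from which ok holds for every later window
    stable = np.flip(np.logical_and.accumulate(np.flip(ok)))
    hits = np.flatnonzero(stable[: max(0, means.size - window + 1)])
    if hits.size == 0:
        return None
    return int(hits[0]) + window - 1
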