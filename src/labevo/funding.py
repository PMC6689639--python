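"""Grant-seeking stage: application and allocation under five strategies.

Each iteration a uniformly random pool of ``d`` labs applies and at most
one grant of size ``G`` is awarded: to the most published applicant (PH),
the lowest-alpha applicant (MI), a uniform random applicant (RA), MI with
probability ``X`` else RA (MS), or a uniform random applicant among those
with ``alpha <= A`` (ML — no award if none qualifies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._sampling import sample_without_replacement
from .evolution import _uniform_tie_argbest
from .types import FundingStrategy, LabPopulation, Params

__all__ = ["GrantAward", "select_applicants", "award_grant"]


@dataclass
class GrantAward:
    """Outcome of one grant-seeking stage.

    ``strategy_used`` records the rule actually applied — for MS it
    resolves the per-award coin flip to MI or RA; otherwise it equals the
    configured strategy. ``winner_id`` is None only for ML with an empty
    qualified pool.
    """

    applicant_ids: list[int]
    winner_id: Optional[int]
    strategy_used: FundingStrategy
    winner_index: Optional[int] = None  # population slot of the winner


def select_applicants(
    labs: LabPopulation, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random ``d``-subset of positions, without replacement.

    Funding status and funds level play no role in eligibility.
    """
    return sample_without_replacement(len(labs), d, rng)


def _award_mi(labs, applicants, rng) -> int:
    return _uniform_tie_argbest(
        applicants, labs.alpha[applicants], rng, maximize=False
    )


def _award_ra(applicants, rng) -> int:
    return int(applicants[rng.integers(0, applicants.size)])


def award_grant(
    labs: LabPopulation,
    applicants: np.ndarray,
    params: Params,
    rng: np.random.Generator,
) -> GrantAward:
    """Apply the configured allocation rule and pay the winner, in place.

    The winner's funds increase by exactly ``G``. ML awards nothing when
    no applicant has ``alpha <= A``; every other strategy always awards.
    ML with every applicant qualified consumes the same single uniform
    draw as RA, so ML(A=1) reproduces RA trace-for-trace at a fixed seed.
    """
    if applicants.size == 0:
        raise ValueError("empty applicant pool")
    kind = params.strategy
    used = kind
    winner: Optional[int]
    if kind is FundingStrategy.MS:
        used = (
            FundingStrategy.MI
            if rng.random() < params.X
            else FundingStrategy.RA
        )
        kind = used
    if kind is FundingStrategy.PH:
        winner = _uniform_tie_argbest(
            applicants, labs.publications[applicants], rng, maximize=True
        )
    elif kind is FundingStrategy.MI:
        winner = _award_mi(labs, applicants, rng)
    elif kind is FundingStrategy.RA:
        winner = _award_ra(applicants, rng)
    elif kind is FundingStrategy.ML:
        qualified = applicants[labs.alpha[applicants] <= params.A]
        winner = _award_ra(qualified, rng) if qualified.size else None
    else:  # pragma: no cover - exhaustive over FundingStrategy
        raise ValueError(f"unknown strategy {kind!r}")

    if winner is not None:
        labs.funds[winner] += params.G
    return GrantAward(
        applicant_ids=[int(i) for i in labs.ids[applicants]],
        winner_id=None if winner is None else int(labs.ids[winner]),
        strategy_used=used,
        winner_index=winner,
    )
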