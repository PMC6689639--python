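"""Science stage: hypothesis selection, investigation, communication.

Each funded lab spends one unit of funds to investigate a fresh hypothesis,
true with probability ``b``. A true hypothesis yields a positive result
with probability ``W`` (power); a false one with probability ``alpha``
(the lab's false positive rate). Communication applies two independent
filters: negative results are publishable with probability ``p``
(publication bias), and erroneous results — positive on a false hypothesis
or negative on a true one — are blocked by peer review with probability
``r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import LabPopulation, Params, StepStats

__all__ = [
    "Investigation",
    "draw_hypothesis",
    "investigate",
    "publication_probability",
    "run_science_step",
]


@dataclass
class Investigation:
    """Outcome of a single study: truth, result, and publication fate."""

    lab_id: int
    hypothesis_true: bool
    result_positive: bool
    published: bool
    erroneous: bool


def draw_hypothesis(b: float, rng: np.random.Generator) -> bool:
    """Draw a hypothesis; true with probability ``b`` (the base rate)."""
    return bool(rng.random() < b)


def investigate(
    hypothesis_true: bool, alpha: float, W: float, rng: np.random.Generator
) -> bool:
    """Return the result sign: positive w.p. ``W`` if true, ``alpha`` if false."""
    return bool(rng.random() < (W if hypothesis_true else alpha))


def publication_probability(
    hypothesis_true: bool, result_positive: bool, p: float, r: float
) -> float:
    """Closed-form probability that a result is published.

    Positive results are always publishable; negative results with
    probability ``p``. Independently, erroneous results are blocked with
    probability ``r``. The two filters multiply:

    ==================  ===========
    (truth, result)     probability
    ==================  ===========
    (true,  positive)   1
    (false, positive)   1 - r
    (false, negative)   p
    (true,  negative)   p * (1 - r)
    ==================  ===========
    """
    base = 1.0 if result_positive else p
    erroneous = hypothesis_true != result_positive
    return base * (1.0 - r) if erroneous else base


def run_science_step(
    labs: LabPopulation,
    params: Params,
    rng: np.random.Generator,
    record_investigations: bool = False,
) -> tuple[StepStats, Optional[list[Investigation]]]:
    """Run one Science stage in place over every funded lab.

    Labs are visited in a fresh uniformly random order; each lab with
    funds >= 1 pays 1 unit and produces exactly one investigation whose
    publication fate follows :func:`publication_probability` (realized as a
    single Bernoulli draw — the two filters are independent, so the
    composite draw is distributionally identical to drawing them in
    sequence). Labs with zero funds are untouched.

    Returns the per-step tallies and, when ``record_investigations`` is
    true, the list of individual :class:`Investigation` records in visit
    order (``None`` otherwise, to avoid materializing millions of objects
    over a long run).
    """
    funded = np.flatnonzero(labs.funds > 0)
    if funded.size == 0:
        return StepStats(), ([] if record_investigations else None)
    order = rng.permutation(funded)
    k = order.size

    truth = rng.random(k) < params.b
    p_positive = np.where(truth, params.W, labs.alpha[order])
    positive = rng.random(k) < p_positive
    erroneous = truth != positive
    # publication probability per the closed-form table above
    keep_r = 1.0 - params.r
    pub_p = np.where(
        positive,
        np.where(truth, 1.0, keep_r),
        np.where(truth, params.p * keep_r, params.p),
    )
    published = rng.random(k) < pub_p

    labs.funds[order] -= 1
    labs.publications[order] += published
    labs.erroneous_publications[order] += published & erroneous

    stats = StepStats(
        investigations=int(k),
        publications=int(published.sum()),
        erroneous_publications=int((published & erroneous).sum()),
        true_hypotheses=int(truth.sum()),
        positive_results=int(positive.sum()),
    )
    events = None
    if record_investigations:
        events = [
            Investigation(
                lab_id=int(labs.ids[order[i]]),
                hypothesis_true=bool(truth[i]),
                result_positive=bool(positive[i]),
                published=bool(published[i]),
                erroneous=bool(erroneous[i]),
            )
            for i in range(k)
        ]
    return stats, events
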