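"""Evolution stage: death–birth replacement with mutation of rigour.

Each iteration one lab dies and one is born. Death: the oldest lab in a
uniformly random sample of ``d`` (ties broken uniformly). Birth: from a
fresh sample of ``d`` drawn from the survivors, the lab with the most
publications becomes parent (strong selection; ties uniform), or — in the
proportional mode — every survivor may parent with probability
proportional to its publication count. The child starts at age 0 with
startup funds G0, empty publication record, and the parent's alpha
perturbed by a zero-mean Gaussian of standard deviation ``epsilon``,
clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sampling import sample_without_replacement
from .types import Lab, LabPopulation, Params

__all__ = [
    "ReplacementEvent",
    "select_death",
    "select_parent",
    "mutate_alpha",
    "run_evolution_step",
]


@dataclass
class ReplacementEvent:
    """One death–birth event: who died, who parented, who was born."""

    dead_id: int
    parent_id: int
    child: Lab
    index: int  # population slot reused by the child
    dead_funds: int  # funds destroyed with the dying lab (ledger bookkeeping)


def _uniform_tie_argbest(
    candidates: np.ndarray, values: np.ndarray, rng: np.random.Generator,
    maximize: bool,
) -> int:
    """Index (into the population) of the max/min value, ties uniform.

    Always consumes exactly one integer draw so that RNG usage does not
    depend on whether a tie occurred.
    """
    best = values.max() if maximize else values.min()
    ties = candidates[values == best]
    return int(ties[rng.integers(0, ties.size)])


def select_death(
    labs: LabPopulation, d: int, rng: np.random.Generator
) -> int:
    """Position of the lab chosen to die.

    Samples ``d`` labs uniformly without replacement and returns the
    oldest; equally old labs are chosen among uniformly at random.
    """
    n = len(labs)
    if n == 0:
        raise ValueError("cannot select a death from an empty population")
    sample = sample_without_replacement(n, d, rng)
    return _uniform_tie_argbest(sample, labs.age[sample], rng, maximize=True)


def select_parent(
    labs: LabPopulation,
    d: int,
    mode: str,
    rng: np.random.Generator,
    exclude: int | None = None,
) -> int:
    """Position of the lab chosen to reproduce.

    ``mode='strong'``: most-published lab of a fresh uniform ``d``-subset
    (ties uniform). ``mode='proportional'``: each lab weighted by its
    publication count over the whole population (uniform fallback when all
    counts are zero). ``exclude`` removes one position (the dead lab) from
    consideration.
    """
    n = len(labs)
    if exclude is not None:
        # sample over n-1 virtual positions, then shift past the hole
        m = n - 1
        if m == 0:
            raise ValueError("no candidate parents remain")
    else:
        m = n
    if mode == "strong":
        sample = sample_without_replacement(m, min(d, m), rng)
        if exclude is not None:
            sample = np.where(sample >= exclude, sample + 1, sample)
        return _uniform_tie_argbest(
            sample, labs.publications[sample], rng, maximize=True
        )
    if mode == "proportional":
        weights = labs.publications.astype(np.float64)
        if exclude is not None:
            weights = np.delete(weights, exclude)
        total = weights.sum()
        if total == 0.0:
            pos = int(rng.integers(0, m))
        else:
            cdf = np.cumsum(weights)
            pos = int(np.searchsorted(cdf, rng.random() * total, side="right"))
            pos = min(pos, m - 1)  # guard the u == total rounding edge
        if exclude is not None and pos >= exclude:
            pos += 1
        return pos
    raise ValueError(f"unknown selection mode {mode!r}")


def mutate_alpha(
    parent_alpha: float, epsilon: float, rng: np.random.Generator
) -> float:
    """Parent alpha plus N(0, epsilon), truncated to [0, 1]."""
    v = parent_alpha + rng.normal(0.0, epsilon)
    return 0.0 if v < 0.0 else (1.0 if v > 1.0 else float(v))


def run_evolution_step(
    labs: LabPopulation, params: Params, rng: np.random.Generator
) -> ReplacementEvent:
    """One death–birth replacement, in place.

    The dying lab is removed before the parent sample is drawn, so it can
    never reproduce. The child occupies the freed slot with a fresh id,
    age 0, funds G0, zero publications, and mutated alpha; population size
    is unchanged.
    """
    dead = select_death(labs, params.d, rng)
    dead_id = int(labs.ids[dead])
    dead_funds = int(labs.funds[dead])
    parent = select_parent(
        labs, params.d, params.selection_mode, rng, exclude=dead
    )
    parent_id = int(labs.ids[parent])
    child_alpha = mutate_alpha(float(labs.alpha[parent]), params.epsilon, rng)

    child_id = labs.next_id
    labs.next_id += 1
    labs.ids[dead] = child_id
    labs.alpha[dead] = child_alpha
    labs.funds[dead] = params.G0
    labs.age[dead] = 0
    labs.publications[dead] = 0
    labs.erroneous_publications[dead] = 0

    child = Lab(id=child_id, alpha=child_alpha, funds=params.G0, age=0)
    return ReplacementEvent(
        dead_id=dead_id,
        parent_id=parent_id,
        child=child,
        index=dead,
        dead_funds=dead_funds,
    )
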