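"""Closed-form expectations for a static, fully funded population.

With evolution and funding switched off and every lab funded, the four
(truth, result) outcome cells of a single investigation have fixed
occurrence and publication probabilities, so the long-run false discovery
rate of the literature and the publication yield per investigation have
exact closed forms. These serve as ground truth for Monte Carlo
validation of the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OutcomeCell",
    "OutcomeTable",
    "outcome_table",
    "static_fdr",
    "expected_publications_per_investigation",
]


@dataclass(frozen=True)
class OutcomeCell:
    occurrence: float  # probability the investigation lands in this cell
    publication: float  # probability the result is then published
    erroneous: bool  # result sign disagrees with the hypothesis truth


@dataclass(frozen=True)
class OutcomeTable:
    """Per-cell probabilities keyed by (hypothesis_true, result_positive)."""

    cells: dict[tuple[bool, bool], OutcomeCell]

    def published_mass(self, erroneous_only: bool = False) -> float:
        return sum(
            c.occurrence * c.publication
            for c in self.cells.values()
            if c.erroneous or not erroneous_only
        )

    def to_dict(self) -> dict[str, dict[str, float | bool]]:
        label = {
            (True, True): "true_positive",
            (True, False): "false_negative",
            (False, True): "false_positive",
            (False, False): "true_negative",
        }
        return {
            label[k]: {
                "occurrence": c.occurrence,
                "publication": c.publication,
                "erroneous": c.erroneous,
            }
            for k, c in self.cells.items()
        }


def outcome_table(
    alpha: float, b: float, W: float, p: float, r: float
) -> OutcomeTable:
    """Occurrence and publication probability of each outcome cell.

    Occurrence: (T,+) bW; (T,-) b(1-W); (F,+) (1-b)alpha;
    (F,-) (1-b)(1-alpha). Publication follows the communication filters:
    positives always pass publication bias, negatives pass with
    probability p; erroneous results are additionally blocked with
    probability r.
    """
    return OutcomeTable(
        cells={
            (True, True): OutcomeCell(b * W, 1.0, False),
            (True, False): OutcomeCell(b * (1 - W), p * (1 - r), True),
            (False, True): OutcomeCell((1 - b) * alpha, 1 - r, True),
            (False, False): OutcomeCell((1 - b) * (1 - alpha), p, False),
        }
    )


def static_fdr(
    alpha: float, b: float, W: float, p: float, r: float
) -> float:
    """Long-run false discovery rate of a static population's literature.

    The published-erroneous mass divided by the total published mass:

        [(1-b) a (1-r) + b(1-W) p (1-r)]
        --------------------------------------------------------
        [bW + (1-b)(1-a) p + (1-b) a (1-r) + b(1-W) p (1-r)]

    NaN when nothing is ever published (zero denominator).
    """
    table = outcome_table(alpha, b, W, p, r)
    denom = table.published_mass()
    if denom == 0.0:
        return math.nan
    return table.published_mass(erroneous_only=True) / denom


def expected_publications_per_investigation(
    alpha: float, b: float, W: float, p: float, r: float
) -> float:
    """Probability that a single investigation yields a publication."""
    return outcome_table(alpha, b, W, p, r).published_mass()
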