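"""Domain types, configuration and validation shared by all simulation stages.

The model is a population of ``n`` research labs. Each lab carries a single
evolving trait — its intrinsic false positive rate ``alpha`` — together with
a funds balance (one unit buys one study), an age, and lifetime publication
tallies. ``Params`` holds the full parameter set of the simulation plus
run-control fields; ``validate_params`` enforces the ranges.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "FundingStrategy",
    "Lab",
    "LabPopulation",
    "Params",
    "StepStats",
    "RunRecord",
    "validate_params",
    "load_config",
]


class FundingStrategy(str, enum.Enum):
    """Grant-allocation rule applied to each iteration's applicant pool.

    PH — publication history: most published papers wins.
    MI — methodological integrity: lowest false positive rate wins.
    RA — random allocation: uniform lottery over applicants.
    MS — mixed strategy: MI with probability ``X``, RA otherwise.
    ML — modified lottery: uniform over applicants with ``alpha <= A``.
    """

    PH = "PH"
    MI = "MI"
    RA = "RA"
    MS = "MS"
    ML = "ML"


@dataclass
class Lab:
    """One research group.

    ``alpha`` is the lab's intrinsic false positive rate (the probability
    that investigating a false hypothesis yields a positive result); it is
    the trait under selection. ``funds`` counts studies the lab can still
    afford; ``age`` counts completed iterations survived.
    """

    id: int
    alpha: float
    funds: int
    age: int = 0
    publications: int = 0
    erroneous_publications: int = 0


# Probability-valued Params fields, checked for [0, 1] membership.
_PROB_FIELDS = ("b", "W", "alpha0", "r", "p")


@dataclass
class Params:
    """Full parameter set plus run-control fields.

    Defaults follow the model's standard configuration: n=100 labs, base
    rate b=0.1, power W=0.8, initial false positive rate alpha0=0.05,
    startup funds G0=10, grant size G=10, event sample size d=10, mutation
    standard deviation epsilon=0.01, and no open-science improvements
    (p=r=0).
    """

    n: int = 100
    b: float = 0.1
    W: float = 0.8
    alpha0: float = 0.05
    G0: int = 10
    G: int = 10
    d: int = 10
    epsilon: float = 0.01
    r: float = 0.0
    p: float = 0.0
    strategy: FundingStrategy = FundingStrategy.PH
    X: Optional[float] = None
    A: Optional[float] = None
    selection_mode: str = "strong"
    iterations: int = 100_000
    seed: int = 0
    record_interval: int = 100
    fdr_window: int = 10_000
    # Frozen-dynamics switches, used only by oracle-equivalence tests:
    # disable the evolution and/or funding stages and top funds back up to
    # G0 every iteration so every lab investigates every step.
    disable_evolution: bool = False
    disable_funding: bool = False
    auto_refund: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.strategy, str) and not isinstance(
            self.strategy, FundingStrategy
        ):
            self.strategy = FundingStrategy(self.strategy)

    def replace(self, **changes: Any) -> "Params":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["strategy"] = self.strategy.value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def validate_params(params: Params) -> Params:
    """Check every invariant; return ``params`` unchanged if all hold.

    Raises ``ValueError`` naming the offending field otherwise.
    """
    for name in _PROB_FIELDS:
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
    for name in ("n", "d"):
        v = getattr(params, name)
        if not (isinstance(v, (int, np.integer)) and v >= 1):
            raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
    if params.d > params.n:
        raise ValueError(f"d must not exceed n (d={params.d}, n={params.n})")
    for name in ("G", "G0"):
        v = getattr(params, name)
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if not (isinstance(params.epsilon, (int, float)) and params.epsilon >= 0):
        raise ValueError(f"epsilon must be >= 0, got {params.epsilon!r}")
    for name in ("iterations", "seed"):
        v = getattr(params, name)
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    for name in ("record_interval", "fdr_window"):
        v = getattr(params, name)
        if not (isinstance(v, (int, np.integer)) and v >= 1):
            raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
    if params.selection_mode not in ("strong", "proportional"):
        raise ValueError(
            f"selection_mode must be 'strong' or 'proportional', "
            f"got {params.selection_mode!r}"
        )
    kind = params.strategy
    if kind is FundingStrategy.MS:
        if params.X is None:
            raise ValueError("X must be set for the MS strategy")
        if not 0.0 <= params.X <= 1.0:
            raise ValueError(f"X must be a probability in [0, 1], got {params.X!r}")
    if kind is FundingStrategy.ML:
        if params.A is None:
            raise ValueError("A must be set for the ML strategy")
        if not 0.0 <= params.A <= 1.0:
            raise ValueError(f"A must be a probability in [0, 1], got {params.A!r}")
    return params


def load_config(path: str | Path, **overrides: Any) -> Params:
    """Read a YAML or JSON config mirroring ``Params`` field names.

    Keyword overrides (e.g. from CLI flags) take precedence over file
    values. The result is validated before being returned.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return validate_params(Params.from_dict(data))


class LabPopulation:
    """Array-backed collection of labs (struct-of-arrays layout).

    Positions 0..n-1 are stable slots; when a lab dies its slot is reused
    by the newborn, which receives a fresh ``id`` from a monotone counter.
    """

    __slots__ = ("ids", "alpha", "funds", "age", "publications",
                 "erroneous_publications", "next_id")

    def __init__(
        self,
        ids: np.ndarray,
        alpha: np.ndarray,
        funds: np.ndarray,
        age: np.ndarray,
        publications: np.ndarray,
        erroneous_publications: np.ndarray,
        next_id: int,
    ) -> None:
        self.ids = ids
        self.alpha = alpha
        self.funds = funds
        self.age = age
        self.publications = publications
        self.erroneous_publications = erroneous_publications
        self.next_id = next_id

    def __len__(self) -> int:
        return self.ids.size

    @classmethod
    def initial(cls, params: Params) -> "LabPopulation":
        """Founding population: all labs at alpha0, funds G0, age 0."""
        n = params.n
        return cls(
            ids=np.arange(n, dtype=np.int64),
            alpha=np.full(n, params.alpha0, dtype=np.float64),
            funds=np.full(n, params.G0, dtype=np.int64),
            age=np.zeros(n, dtype=np.int64),
            publications=np.zeros(n, dtype=np.int64),
            erroneous_publications=np.zeros(n, dtype=np.int64),
            next_id=n,
        )

    @classmethod
    def from_labs(cls, labs: Iterable[Lab]) -> "LabPopulation":
        labs = list(labs)
        ids = np.array([lab.id for lab in labs], dtype=np.int64)
        return cls(
            ids=ids,
            alpha=np.array([lab.alpha for lab in labs], dtype=np.float64),
            funds=np.array([lab.funds for lab in labs], dtype=np.int64),
            age=np.array([lab.age for lab in labs], dtype=np.int64),
            publications=np.array(
                [lab.publications for lab in labs], dtype=np.int64
            ),
            erroneous_publications=np.array(
                [lab.erroneous_publications for lab in labs], dtype=np.int64
            ),
            next_id=int(ids.max(initial=-1)) + 1,
        )

    def to_labs(self) -> list[Lab]:
        return [
            Lab(
                id=int(self.ids[i]),
                alpha=float(self.alpha[i]),
                funds=int(self.funds[i]),
                age=int(self.age[i]),
                publications=int(self.publications[i]),
                erroneous_publications=int(self.erroneous_publications[i]),
            )
            for i in range(len(self))
        ]

    def copy(self) -> "LabPopulation":
        return LabPopulation(
            self.ids.copy(),
            self.alpha.copy(),
            self.funds.copy(),
            self.age.copy(),
            self.publications.copy(),
            self.erroneous_publications.copy(),
            self.next_id,
        )

    def index_of(self, lab_id: int) -> int:
        pos = np.flatnonzero(self.ids == lab_id)
        if pos.size == 0:
            raise KeyError(f"no lab with id {lab_id}")
        return int(pos[0])


@dataclass
class StepStats:
    """Per-iteration tallies produced by the three stages."""

    investigations: int = 0
    publications: int = 0
    erroneous_publications: int = 0
    true_hypotheses: int = 0
    positive_results: int = 0
    grant_awarded: bool = False
    winner_id: Optional[int] = None
    # extra bookkeeping used by the funds-ledger invariant
    dead_id: Optional[int] = None
    dead_funds: int = 0


@dataclass
class RunRecord:
    """Recorded time series of a single simulation run.

    ``mean_alpha`` is the community mean false positive rate;
    ``fdr_cumulative`` the cumulative false discovery rate of the
    published literature since iteration 0; ``fdr_windowed`` the rate over
    the trailing ``fdr_window`` iterations. Entries are NaN wherever no
    paper has (yet) been published in the relevant span.
    """

    params: Params
    times: np.ndarray
    mean_alpha: np.ndarray
    fdr_cumulative: np.ndarray
    fdr_windowed: np.ndarray
    cum_publications: np.ndarray
    cum_erroneous: np.ndarray
    total_publications: int
    total_erroneous: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.times,
                "mean_alpha": self.mean_alpha,
                "fdr_cumulative": self.fdr_cumulative,
                "fdr_windowed": self.fdr_windowed,
                "cum_publications": self.cum_publications,
                "cum_erroneous": self.cum_erroneous,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the series as CSV plus a JSON sidecar with params/seed."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "params": self.params.to_dict(),
                    "total_publications": self.total_publications,
                    "total_erroneous": self.total_erroneous,
                },
                indent=2,
            )
        )
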