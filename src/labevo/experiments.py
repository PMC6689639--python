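"""Replicated parameter sweeps over funding strategies and open-science levels.

A sweep crosses named parameter axes (e.g. strategy x grant size x p=r),
runs each condition for a number of replicate seeds, and aggregates
equilibrium statistics: the community mean false positive rate and the
windowed false discovery rate over the final ``equilibrium_window``
iterations, plus the detected convergence iteration. Per-run seeds are
derived deterministically from the sweep seed and the condition *content*
(not its position), so adding conditions to a sweep never changes
existing results and execution order is irrelevant.

The default protocol is a desk-scale reduction of the model's standard
experiment (1e5 iterations, 5 replicates per condition): runs converge on
the order of 1e5 iterations, so equilibria measured over the final 1e4
iterations are already stable at this scale.
"""

from __future__ import annotations

import itertools
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import detect_convergence, run
from .types import Params, RunRecord, validate_params

__all__ = [
    "SweepSpec",
    "SweepResult",
    "derive_seed",
    "equilibrium_stats",
    "run_sweep",
    "load_sweep_spec",
    "relative_reduction",
]

DEFAULT_ITERATIONS = 100_000
DEFAULT_EQUILIBRIUM_WINDOW = 10_000
CONVERGENCE_TOLERANCE = 0.05


@dataclass
class SweepSpec:
    """A crossed parameter sweep.

    ``axes`` maps Params field names to lists of values; a comma-joined
    key such as ``"p,r"`` sets several fields to the same value (the
    coupled open-science axis p = r used by the hybrid-strategy
    experiments).
    """

    base: Params = field(default_factory=Params)
    axes: dict[str, list[Any]] = field(default_factory=dict)
    replicates: int = 5
    seed_base: int = 0
    iterations: int = DEFAULT_ITERATIONS
    equilibrium_window: int = DEFAULT_EQUILIBRIUM_WINDOW

    def conditions(self) -> list[dict[str, Any]]:
        """All axis crossings as field->value dicts, in axis order."""
        if not self.axes:
            return [{}]
        names = list(self.axes)
        out = []
        for combo in itertools.product(*(self.axes[k] for k in names)):
            cond: dict[str, Any] = {}
            for name, value in zip(names, combo):
                for f in name.split(","):
                    cond[f.strip()] = value
            out.append(cond)
        return out


@dataclass
class SweepResult:
    """Per-run rows and per-condition aggregates of a sweep."""

    spec: SweepSpec
    runs: pd.DataFrame  # one row per condition x replicate
    summary: pd.DataFrame  # one row per condition

    def condition_rows(self, **fields: Any) -> pd.DataFrame:
        mask = np.ones(len(self.runs), dtype=bool)
        for k, v in fields.items():
            mask &= self.runs[k] == v
        return self.runs[mask]


def derive_seed(seed_base: int, condition: dict[str, Any], replicate: int) -> int:
    """Deterministic per-run seed below 2**31.

    The condition dict is serialized canonically (sorted JSON), hashed
    with CRC-32, and combined with the sweep seed and replicate index
    through a SeedSequence. Depends only on content, never on position.
    """
    key = json.dumps(condition, sort_keys=True, default=str)
    h = zlib.crc32(key.encode())
    ss = np.random.SeedSequence([seed_base, h, replicate])
    return int(ss.generate_state(1)[0] >> 1)


def equilibrium_stats(
    record: RunRecord, equilibrium_window: int
) -> dict[str, float]:
    """Equilibrium summaries of one run.

    Mean alpha and mean windowed false discovery rate over the records in
    the final ``equilibrium_window`` iterations, plus the convergence
    iteration of the alpha series (trailing window of the same length,
    tolerance 0.05); NaN when never converged or nothing was published in
    the window.
    """
    t_end = record.times[-1]
    mask = record.times > t_end - equilibrium_window
    eq_alpha = float(record.mean_alpha[mask].mean())
    win = record.fdr_windowed[mask]
    eq_fdr = float(np.nanmean(win)) if not np.all(np.isnan(win)) else float("nan")
    w = max(1, equilibrium_window // record.params.record_interval)
    idx = detect_convergence(record.mean_alpha, w, CONVERGENCE_TOLERANCE)
    conv = float(record.times[idx]) if idx is not None else float("nan")
    return {
        "eq_alpha": eq_alpha,
        "eq_fdr": eq_fdr,
        "convergence_iteration": conv,
        "total_publications": float(record.total_publications),
        "final_alpha": float(record.mean_alpha[-1]),
        "final_fdr_cumulative": float(record.fdr_cumulative[-1]),
    }


def _run_one(
    spec: SweepSpec, condition: dict[str, Any], replicate: int
) -> dict[str, Any]:
    seed = derive_seed(spec.seed_base, condition, replicate)
    params = spec.base.replace(
        **condition, iterations=spec.iterations, seed=seed
    )
    validate_params(params)
    record = run(params)
    row: dict[str, Any] = {
        **{k: (v.value if hasattr(v, "value") else v) for k, v in condition.items()},
        "replicate": replicate,
        "seed": seed,
    }
    row.update(equilibrium_stats(record, spec.equilibrium_window))
    return row


def run_sweep(spec: SweepSpec, n_jobs: int = 1) -> SweepResult:
    """Run every condition x replicate and aggregate across replicates.

    Results are independent of execution order and of ``n_jobs`` because
    each run's seed is derived from its condition and replicate alone.
    """
    conditions = spec.conditions()
    tasks = [
        (cond, rep)
        for cond in conditions
        for rep in range(spec.replicates)
    ]
    if n_jobs == 1:
        rows = [_run_one(spec, cond, rep) for cond, rep in tasks]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_one)(spec, cond, rep) for cond, rep in tasks
        )
    runs = pd.DataFrame(rows)

    cond_cols = sorted({f for cond in conditions for f in cond})
    stat_cols = ["eq_alpha", "eq_fdr", "convergence_iteration",
                 "total_publications"]
    with warnings.catch_warnings():
        # runs that never converge leave all-NaN columns; NaN aggregates
        # are the documented sentinel, not an error
        warnings.simplefilter("ignore", RuntimeWarning)
        if cond_cols:
            grouped = runs.groupby(cond_cols, dropna=False, sort=False)
            summary = grouped[stat_cols].agg(["mean", "median", "std"])
            summary.columns = ["_".join(c) for c in summary.columns]
            summary["replicates"] = grouped.size()
            summary = summary.reset_index()
        else:
            agg = {
                f"{c}_{s}": getattr(runs[c], s)()
                for c in stat_cols
                for s in ("mean", "median", "std")
            }
            agg["replicates"] = len(runs)
            summary = pd.DataFrame([agg])
    return SweepResult(spec=spec, runs=runs, summary=summary)


def load_sweep_spec(path: str | Path) -> SweepSpec:
    """Read a sweep spec from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"sweep spec {path} must contain a mapping")
    base = Params.from_dict(data.get("base", {}))
    return SweepSpec(
        base=base,
        axes={k: list(v) for k, v in data.get("axes", {}).items()},
        replicates=int(data.get("replicates", 5)),
        seed_base=int(data.get("seed_base", 0)),
        iterations=int(data.get("iterations", DEFAULT_ITERATIONS)),
        equilibrium_window=int(
            data.get("equilibrium_window", DEFAULT_EQUILIBRIUM_WINDOW)
        ),
    )


def relative_reduction(f_treatment: float, f_reference: float) -> float:
    """Relative reduction of the treatment versus the reference, in percent.

    ``(f_reference - f_treatment) / f_reference * 100``; e.g. a false
    discovery rate falling from 0.8 to 0.2 is a 75% reduction.
    """
    if f_reference == 0:
        raise ValueError("reference value must be non-zero")
    return (f_reference - f_treatment) / f_reference * 100.0
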