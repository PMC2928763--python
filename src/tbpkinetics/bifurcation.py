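"""Parameter sweeps, the (k3, k5) stability region map, and sensitivities.

Brute one-dimensional sweeps with bisection refinement locate the
saddle-node folds in k3, k5 and the basal rate k0; a two-parameter grid
classifies the (k3, k5) plane into the monostable-zero and bistable
regions; and relative sensitivity quantifies how far the high-TBP state
moves when one rate constant is rescaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import KineticParameters
from .steady_state import (
    SteadyStateRecord,
    find_steady_states,
    high_state,
)

__all__ = [
    "BifurcationBranch",
    "RegionMap",
    "SensitivityResult",
    "sweep_1d",
    "region_map_2d",
    "relative_sensitivity",
]

SWEEPABLE = ("k0", "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")


@dataclass
class BifurcationBranch:
    parameter: str
    values: np.ndarray
    records: list[list[SteadyStateRecord]]  # fixed points per sweep value
    critical_values: list[float] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return np.array([len(r) for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (sweep value, fixed point)."""
        rows = []
        for v, recs in zip(self.values, self.records):
            for rec in recs:
                rows.append({self.parameter: v, "label": rec.label,
                             "T": rec.T, "T2": rec.T2, "TD": rec.TD,
                             "D": rec.D, "total": rec.total,
                             "stability": rec.stability})
        return pd.DataFrame(rows)


@dataclass
class RegionMap:
    k3_values: np.ndarray
    k5_values: np.ndarray
    classification: np.ndarray  # (len(k5), len(k3)) array of region labels

    def to_frame(self) -> pd.DataFrame:
        rows = [{"k3": k3, "k5": k5, "region": self.classification[i, j]}
                for i, k5 in enumerate(self.k5_values)
                for j, k3 in enumerate(self.k3_values)]
        return pd.DataFrame(rows)


def _refine_critical(name: str, lo: float, hi: float, p: KineticParameters,
                     n_lo: int, sig_figs: int = 4, **ss_kw) -> float:
    """Bisect a root-count change between two sweep values to ~sig_figs."""
    rel = 10.0 ** (-sig_figs - 1)
    while hi - lo > rel * hi:
        mid = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        n = len(find_steady_states(p.replace(**{name: mid}),
                                   classify_stability=False, **ss_kw))
        if n == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sweep_1d(name: str, values, p: KineticParameters,
             classify_stability: bool = True, refine: bool = True,
             **ss_kw) -> BifurcationBranch:
    """Fixed points (with stability) at each value of one swept parameter.

    Wherever the number of fixed points changes between adjacent sweep
    values, the transition is refined by bisection and recorded as a
    critical value.
    """
    if name not in SWEEPABLE:
        raise ValueError(f"unknown parameter {name!r}; one of {SWEEPABLE}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sweep")
    if np.any(values < 0) or np.any(np.diff(values) <= 0):
        raise ValueError("sweep values must be positive and strictly increasing")
    records = [find_steady_states(p.replace(**{name: v}),
                                  classify_stability=classify_stability, **ss_kw)
               for v in values]
    branch = BifurcationBranch(name, values, records)
    if refine:
        counts = branch.counts()
        for i in range(len(values) - 1):
            if counts[i] != counts[i + 1]:
                branch.critical_values.append(
                    _refine_critical(name, values[i], values[i + 1], p,
                                     counts[i], **ss_kw))
    return branch


def region_map_2d(k3_values, k5_values, p: KineticParameters) -> RegionMap:
    """Classify each (k3, k5) cell as monostable_zero or bistable.

    Run with k0 = 0 (the three-state setting); a cell is bistable when the
    low/high pair exists alongside the zero state.
    """
    k3_values = np.asarray(k3_values, dtype=float)
    k5_values = np.asarray(k5_values, dtype=float)
    cls = np.empty((k5_values.size, k3_values.size), dtype=object)
    for i, k5 in enumerate(k5_values):
        for j, k3 in enumerate(k3_values):
            recs = find_steady_states(p.replace(k3=k3, k5=k5),
                                      classify_stability=False)
            n_pos = sum(1 for r in recs if r.T > 0)
            cls[i, j] = "bistable" if n_pos >= 2 else "monostable_zero"
    return RegionMap(k3_values, k5_values, cls)


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    factor: float
    baseline_total: float        # M
    perturbed_total: float | None  # None when the high state is lost
    percent_reduction: float | None  # 100*(base-pert)/base; None if lost

    @property
    def state_lost(self) -> bool:
        return self.perturbed_total is None


def relative_sensitivity(name: str, factor: float,
                         p: KineticParameters) -> SensitivityResult:
    """Percent change of the high-TBP total when one parameter is rescaled.

    Positive percentages are reductions.  If rescaling pushes the system
    through the fold so the high state disappears, the result is flagged
    ``state_lost`` rather than reported as a number.
    """
    base = high_state(find_steady_states(p, classify_stability=False))
    if base is None:
        raise ValueError("baseline has no high-TBP state (monostable zero)")
    pert = high_state(find_steady_states(p.replace(**{name: factor * getattr(p, name)}),
                                         classify_stability=False))
    if pert is None:
        return SensitivityResult(name, factor, base.total, None, None)
    return SensitivityResult(name, factor, base.total, pert.total,
                             100.0 * (base.total - pert.total) / base.total)
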