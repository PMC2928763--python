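"""Fixed points of the TBP model and closed-form critical parameter values.

Setting the four mass balances to zero collapses the model to a single
scalar condition on the free-monomer concentration T:

    f(T) = (k8*T - k0) * (k7^k6 + TD(T)^k6) - k5 * TD(T)^k6 = 0,
    TD(T) = T*D0 / (k4/k3 + T)

because at steady state dimerization and DNA binding are individually
equilibrated (T2 = (k1/k2)*T^2, TD given by the binding isotherm).  Every
root of f is a fixed point of the full system.  Note f contains neither k1
nor k2: the dimer shifts total TBP but not the existence, location (in T,
TD) or number of steady states.

For k6 = 2 and no basal synthesis (k0 = 0) the positive roots solve a
quadratic in t = T/D0:

    (1 + K7^2) t^2 + (2*K*K7^2 - K5) t + K7^2 K^2 = 0,   K = K4/K3,

whose tangency (zero discriminant) gives closed-form saddle-node values of
k3 and k5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import (
    DimensionlessParameters,
    KineticParameters,
    SystemState,
    nondimensionalize,
    total_tbp,
)

__all__ = [
    "SteadyStateRecord",
    "CriticalValue",
    "steady_state_function",
    "find_steady_states",
    "critical_k3",
    "critical_k5",
    "critical_k0",
    "predicted_multiplicity",
]

DEFAULT_SEARCH_RANGE = (1e-16, 1e-3)  # M; spans all physiological regimes
DEFAULT_GRID_POINTS = 2000
ROOT_RTOL = 1e-10
MERGE_RTOL = 1e-4  # near-tangency double roots reported once, multiplicity 2


@dataclass
class SteadyStateRecord:
    """One fixed point, completed to all four species.

    ``label`` is 'zero'/'low'/'high' in the three-state case, otherwise an
    ordinal 'state0', 'state1', ...  ``stability`` is filled in by
    :func:`tbpkinetics.stability.classify` (or left 'undetermined').
    """

    T: float
    T2: float
    TD: float
    D: float
    total: float
    label: str = ""
    stability: str = "undetermined"
    eigenvalues: tuple[complex, ...] = ()
    multiplicity: int = 1
    converged: bool = True

    def state(self) -> SystemState:
        return SystemState(T=self.T, T2=self.T2, TD=self.TD, D=self.D)


@dataclass
class CriticalValue:
    """A saddle-node location in one parameter."""

    parameter: str
    value: float | None
    method: str  # 'closed_form' or 'numeric_scan'
    regime: str = ""
    extras: dict = field(default_factory=dict)


def bound_tbp(T: float | np.ndarray, p: KineticParameters) -> float | np.ndarray:
    """Binding isotherm TD(T) = T*D0/(k4/k3 + T)."""
    return T * p.D0 / (p.kd_dna + T)


def steady_state_function(T: float | np.ndarray, p: KineticParameters) -> float | np.ndarray:
    """Scalar steady-state condition f(T); its roots are the fixed points."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("free-TBP concentration must be >= 0")
    TDk = np.power(bound_tbp(T, p), p.k6)
    out = (p.k8 * T - p.k0) * (p.k7 ** p.k6 + TDk) - p.k5 * TDk
    return float(out) if out.ndim == 0 else out


def _complete(T: float, p: KineticParameters, *, converged: bool = True,
              multiplicity: int = 1) -> SteadyStateRecord:
    TD = float(bound_tbp(T, p))
    T2 = (p.k1 / p.k2) * T * T if p.k1 > 0 else 0.0
    D = p.D0 - TD
    s = SystemState(T=T, T2=T2, TD=TD, D=D)
    return SteadyStateRecord(T=T, T2=T2, TD=TD, D=D, total=total_tbp(s),
                             multiplicity=multiplicity, converged=converged)


def _positive_roots(p: KineticParameters, search_range: tuple[float, float],
                    n_grid: int) -> list[tuple[float, bool]]:
    """All strictly positive roots of f as (value, converged) pairs.

    Sign-change bracketing on a log grid, with one extra level of local
    refinement around minima of |f| so that near-tangency root pairs closer
    than the coarse grid spacing are still separated.
    """
    lo, hi = search_range
    grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
    fv = steady_state_function(grid, p)

    brackets: list[tuple[float, float]] = []
    for i in range(len(grid) - 1):
        if fv[i] == 0.0:
            brackets.append((grid[i], grid[i]))
        elif fv[i] * fv[i + 1] < 0:
            brackets.append((grid[i], grid[i + 1]))
    # probe local minima of |f| (df changes sign) for root pairs the coarse
    # grid straddles without a sign change
    df = np.diff(fv)
    for i in range(1, len(df)):
        if df[i - 1] < 0 <= df[i] or df[i - 1] > 0 >= df[i]:
            a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
            sub = np.logspace(math.log10(a), math.log10(b), 64)
            fs = steady_state_function(sub, p)
            for j in range(len(sub) - 1):
                if fs[j] * fs[j + 1] < 0:
                    brackets.append((sub[j], sub[j + 1]))

    roots: list[tuple[float, bool]] = []
    for a, b in brackets:
        if a == b:
            roots.append((a, True))
            continue
        try:
            # xtol must be far below the smallest admissible root (1e-16 M);
            # the default absolute xtol (2e-12) would dominate rtol here
            r = brentq(lambda x: steady_state_function(x, p), a, b,
                       rtol=ROOT_RTOL, xtol=1e-300, maxiter=300)
            roots.append((float(r), True))
        except (ValueError, RuntimeError):
            roots.append((0.5 * (a + b), False))
    roots.sort(key=lambda rc: rc[0])

    # a merged pair is one tangency root of multiplicity 2, not two states
    merged: list[tuple[float, bool, int]] = []
    for r, conv in roots:
        if merged and abs(r - merged[-1][0]) <= MERGE_RTOL * max(abs(r), 1e-300):
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1] and conv, prev[2] + 1)
        else:
            merged.append((r, conv, 1))
    return [(r, conv, m) for r, conv, m in merged]


def find_steady_states(
    p: KineticParameters,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    n_grid: int = DEFAULT_GRID_POINTS,
    classify_stability: bool = True,
) -> list[SteadyStateRecord]:
    """All fixed points in ``search_range``, sorted by total TBP.

    The T = 0 root is added analytically when k0 = 0 (a log grid cannot
    bracket it); for k0 > 0, f(0) = -k0*k7^k6 < 0, so zero is never a
    fixed point.  Records are completed via T2 = (k1/k2)T^2 and the binding
    isotherm; in the canonical three-state case they are labeled
    zero/low/high.  Stability labels come from the linearized system.
    """
    roots = _positive_roots(p, search_range, n_grid)
    records = [_complete(r, p, converged=c, multiplicity=m) for r, c, m in roots]
    if p.k0 == 0.0:
        records.insert(0, _complete(0.0, p))
    records.sort(key=lambda r: r.total)

    if len(records) == 3 and records[0].T == 0.0:
        records[0].label, records[1].label, records[2].label = "zero", "low", "high"
    elif len(records) == 1 and records[0].T == 0.0:
        records[0].label = "zero"
    else:
        for i, rec in enumerate(records):
            rec.label = "zero" if rec.T == 0.0 else f"state{i}"
        if records and records[-1].T > 0:
            records[-1].label = "high"

    if classify_stability:
        from .stability import classify

        for rec in records:
            rep = classify(rec, p)
            rec.stability = rep.classification
            rec.eigenvalues = rep.eigenvalues
    return records


def high_state(records: list[SteadyStateRecord],
               stable_only: bool = False) -> SteadyStateRecord | None:
    """The largest-total positive fixed point, or None if only zero exists."""
    pos = [r for r in records if r.T > 0]
    if stable_only:
        pos = [r for r in pos if r.stability == "stable"]
    return max(pos, key=lambda r: r.total) if pos else None


# ---------------------------------------------------------------------------
# saddle-node critical values
# ---------------------------------------------------------------------------

def _closed_form_K5c(K: float, K7: float) -> float:
    # zero discriminant of (1+K7^2)t^2 + (2K*K7^2 - K5)t + K7^2*K^2
    return 2.0 * (K * K7 ** 2 + math.sqrt(K ** 2 * K7 ** 2 + K ** 2 * K7 ** 4))


def _count_positive(p: KineticParameters, search_range, n_grid) -> int:
    return len(_positive_roots(p, search_range, n_grid))


def _numeric_fold(p: KineticParameters, name: str, lo: float, hi: float,
                  search_range, n_grid, iters: int = 60) -> float | None:
    """Bisect on the positive-root count between parameter values lo < hi.

    Assumes more roots at ``hi`` (the multistable side)."""
    n_lo = _count_positive(p.replace(**{name: lo}), search_range, n_grid)
    n_hi = _count_positive(p.replace(**{name: hi}), search_range, n_grid)
    if n_lo == n_hi:
        return None
    for _ in range(iters):
        mid = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        if _count_positive(p.replace(**{name: mid}), search_range, n_grid) == n_lo:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-7 * hi:
            break
    return 0.5 * (lo + hi)


def critical_k3(p: KineticParameters, method: str = "auto",
                search_range=DEFAULT_SEARCH_RANGE,
                n_grid: int = DEFAULT_GRID_POINTS) -> CriticalValue:
    """Saddle-node value of the DNA-association constant k3.

    Below k3_c only the zero state survives; above it the low/high pair
    exists.  Closed form (valid for k6 = 2, k0 = 0):

        K3_c = 2*(K4*K5*K7^2 + sqrt(K4^2*K5^2*K7^2 + K4^2*K5^2*K7^4)) / K5^2

    in D0 / (1/k8) units, i.e. k3_c = K3_c * k8 / D0.  For other k6 or
    k0 > 0 a numeric bisection on the root count is used.
    """
    if p.k5 == 0:
        raise ZeroDivisionError("k5 = 0: no regulated synthesis, k3_c undefined")
    closed_ok = (p.k6 == 2.0 and p.k0 == 0.0)
    if method == "auto":
        method = "closed_form" if closed_ok else "numeric_scan"
    if method == "closed_form":
        if not closed_ok:
            raise ValueError("closed form requires k6 = 2 and k0 = 0")
        dp = nondimensionalize(p)
        K4, K5, K7 = dp.K4, dp.K5, dp.K7
        K3c = 2.0 * (K4 * K5 * K7 ** 2
                     + math.sqrt(K4 ** 2 * K5 ** 2 * K7 ** 2
                                 + K4 ** 2 * K5 ** 2 * K7 ** 4)) / K5 ** 2
        value = K3c * p.k8 / p.D0
    else:
        value = _numeric_fold(p, "k3", p.k3 * 1e-3, p.k3 * 1e3,
                              search_range, n_grid)
    return CriticalValue("k3", value, method,
                         regime="zero only below; zero+low+high above")


def critical_k5(p: KineticParameters, method: str = "auto",
                search_range=DEFAULT_SEARCH_RANGE,
                n_grid: int = DEFAULT_GRID_POINTS) -> CriticalValue:
    """Saddle-node value of the maximal synthesis rate k5.

    Closed form (k6 = 2, k0 = 0): K5_c = 2*(K*K7^2 + sqrt(K^2*K7^2 +
    K^2*K7^4)) with K = K4/K3; k5_c = K5_c * k8 * D0.
    """
    closed_ok = (p.k6 == 2.0 and p.k0 == 0.0)
    if method == "auto":
        method = "closed_form" if closed_ok else "numeric_scan"
    if method == "closed_form":
        if not closed_ok:
            raise ValueError("closed form requires k6 = 2 and k0 = 0")
        dp = nondimensionalize(p)
        value = _closed_form_K5c(dp.K, dp.K7) * p.k8 * p.D0
    else:
        value = _numeric_fold(p, "k5", p.k5 * 1e-3, p.k5 * 1e3,
                              search_range, n_grid)
    return CriticalValue("k5", value, method,
                         regime="zero only below; zero+low+high above")


def critical_k0(p: KineticParameters, search_range=DEFAULT_SEARCH_RANGE,
                n_grid: int = 4000, iters: int = 80) -> CriticalValue:
    """Basal-rate threshold k0_c: three positive states below, one above.

    Located by bisection on the positive-root count of f over k0 in
    (0, k5]: three positive roots just below k0_c collapse to one above it.
    Reports the ratio k0_c/k5 alongside the absolute value.
    """
    multistable = lambda k0: _count_positive(p.replace(k0=k0),
                                             search_range, n_grid) >= 3
    # find a multistable anchor; if none exists in (0, k5], report no fold
    lo = None
    for k0_probe in p.k5 * np.logspace(-1, -6, 6):
        if multistable(k0_probe):
            lo = k0_probe
            break
    if lo is None or multistable(p.k5):
        return CriticalValue("k0", None, "numeric_scan",
                             regime="no multiplicity change in (0, k5]")
    hi = p.k5
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if multistable(mid):
            lo = mid
        else:
            hi = mid
    value = 0.5 * (lo + hi)
    return CriticalValue("k0", value, "numeric_scan",
                         regime="three positive states below; one above",
                         extras={"ratio_to_k5": value / p.k5})


# ---------------------------------------------------------------------------
# multiplicity predicates (k6 in {1, 2})
# ---------------------------------------------------------------------------

def predicted_multiplicity(dp: DimensionlessParameters, k6: float,
                           k0_zero: bool, k0c_dimensionless: float | None = None,
                           much_less_factor: float = 100.0) -> int:
    """Predicted number of strictly positive steady states.

    Analytical conditions for the two canonical Hill exponents (the zero
    state, a root only when k0 = 0, is not counted — the convention here is
    strictly positive roots):

    * k6 = 2, k0 = 0: two positive states (low/high pair) iff the system
      sits above the saddle-node, K5 > K5_c(K, K7) = 2*(K*K7^2 +
      K*K7*sqrt(1+K7^2)); else none.  The weaker pair of inequalities
      K5 > 2*K7^2*K and K7 < 1 is necessary but not sufficient (it ignores
      the discriminant band just below the fold), so the exact tangency
      condition is used.
    * k6 = 2, k0 > 0: three positive states iff K0 < K0_c, else one
      (K0_c must be supplied, computed numerically via :func:`critical_k0`).
    * k6 = 1, k0 = 0: one positive state iff K5 > K7*K (exact: the positive
      root is t = (K5 - K7*K)/(1+K7)); else none.
    * k6 = 1, k0 > 0: exactly one positive state for any parameters (the
      quadratic's root product is negative); the regime where that state is
      a genuinely high, hysteretic-free state is delimited heuristically by
      K0 << K (implemented as K0 < K/much_less_factor) and K5 > K7*K.

    Agreement with :func:`find_steady_states` is a property to test, not an
    assumption.
    """
    if k6 not in (1.0, 2.0):
        raise NotImplementedError(f"no tabulated condition for k6={k6}")
    K, K5, K7, K0 = dp.K, dp.K5, dp.K7, dp.K0
    if k6 == 2.0:
        if k0_zero:
            return 2 if K5 > _closed_form_K5c(K, K7) else 0
        if k0c_dimensionless is None:
            raise ValueError("k0 > 0 case needs k0c_dimensionless (from critical_k0)")
        return 3 if K0 < k0c_dimensionless else 1
    # k6 == 1
    if k0_zero:
        return 1 if K5 > K7 * K else 0
    return 1
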