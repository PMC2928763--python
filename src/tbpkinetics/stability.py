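"""Linear stability of fixed points via the reduced 3-variable Jacobian.

The site balance D = D0 - TD eliminates one variable, so stability is read
off the 3x3 Jacobian of (dT/dt, dT2/dt, dTD/dt) with respect to
(T, T2, TD).  For the canonical parameter set the zero and high-TBP states
are attractors and the intermediate low-TBP state is a saddle, which is the
bistability that makes a minimum initial TBP dose necessary for reaching
the physiological state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KineticParameters, SystemState, hill_derivative, rhs_reduced
from .steady_state import SteadyStateRecord

__all__ = ["StabilityReport", "jacobian", "classify", "linearized_response_time"]

# eigenvalue sign tolerance, scaled by the degradation rate (the slowest
# intrinsic rate in the canonical parameter set)
EIG_TOL_FACTOR = 1e-12


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: tuple[complex, ...]
    classification: str  # stable | unstable | marginal | undetermined
    relaxation_time: float | None  # 1/|max Re of stable eigenvalues| (s)
    method: str = "eigenvalues"  # or "perturbation"


def jacobian(s: SystemState, p: KineticParameters) -> np.ndarray:
    """Analytic Jacobian of the reduced system at state ``s`` (s^-1 units).

    Raises ValueError when the Hill derivative diverges (k6 < 1 at TD = 0);
    :func:`classify` falls back to numeric perturbation there.
    """
    T, T2, TD = s.T, s.T2, s.TD
    D = p.D0 - TD
    dh = hill_derivative(TD, p)
    if not np.isfinite(dh):
        raise ValueError("Hill derivative diverges at TD=0 for k6 < 1; "
                         "Jacobian undefined")
    return np.array([
        [-4.0 * p.k1 * T - p.k3 * D - p.k8, 2.0 * p.k2, p.k4 + p.k3 * T + dh],
        [2.0 * p.k1 * T, -p.k2, 0.0],
        [p.k3 * D, 0.0, -p.k3 * T - p.k4],
    ])


def _perturbation_classify(s: SystemState, p: KineticParameters,
                           rel: float = 0.01) -> str:
    """Integrate +/-1% perturbations of each coordinate; return/escape test.

    Used when the Jacobian is undefined (sub-linear Hill exponent at the
    zero state).  A state is called stable only if every perturbed
    trajectory returns to within 0.1% (absolute floor D0*1e-9 for the zero
    state); unstable if any departs by more than 10x the perturbation.
    """
    from .dynamics import integrate  # local import: avoid module cycle

    y0 = s.reduced()
    scale = max(float(np.max(np.abs(y0))), p.D0)
    t_end = 50.0 / p.k8
    escaped = False
    returned = True
    for i in range(3):
        for sgn in (+1.0, -1.0):
            y = y0.copy()
            delta = rel * (y[i] if y[i] > 0 else scale * 1e-3)
            y[i] = max(y[i] + sgn * delta, 0.0)
            if np.allclose(y, y0):
                continue
            traj = integrate(p, SystemState.from_reduced(*y, p=p), t_end)
            yf = traj.states[-1].reduced()
            dist = float(np.max(np.abs(yf - y0)))
            if dist > 10.0 * abs(delta) + 1e-3 * scale:
                escaped = True
            if dist > 1e-3 * max(float(np.max(np.abs(y0))), 1e-9 * p.D0):
                returned = False
    if escaped:
        return "unstable"
    return "stable" if returned else "undetermined"


def classify(ss: SteadyStateRecord | SystemState, p: KineticParameters,
             tol: float | None = None) -> StabilityReport:
    """Eigenvalue classification of a fixed point.

    stable iff all Re(lambda) < -tol, unstable iff any Re(lambda) > +tol,
    marginal when the leading real part sits inside [-tol, +tol].  The
    default tol is 1e-12 * k8, far below the slowest kinetic rate.
    """
    s = ss.state() if isinstance(ss, SteadyStateRecord) else ss
    if tol is None:
        tol = EIG_TOL_FACTOR * p.k8
    try:
        J = jacobian(s, p)
    except ValueError:
        label = _perturbation_classify(s, p)
        return StabilityReport((), label, None, method="perturbation")
    eig = np.linalg.eigvals(J)
    re = eig.real
    if np.any(re > tol):
        label = "unstable"
    elif np.all(re < -tol):
        label = "stable"
    else:
        label = "marginal"
    stable_parts = re[re < -tol]
    relax = float(1.0 / np.abs(stable_parts.max())) if stable_parts.size else None
    return StabilityReport(tuple(map(complex, eig)), label, relax)


def linearized_response_time(ss: SteadyStateRecord, p: KineticParameters,
                             recovery_fraction: float = 0.9) -> float:
    """Single-mode estimate of the recovery time after a small perturbation.

    Assumes the slowest stable eigenmode dominates, so a perturbation decays
    as exp(Re(lambda_slow)*t) and recovering a fraction f of it takes
    -ln(1-f)/|Re(lambda_slow)|.  ``recovery_fraction`` is the fraction of
    the *perturbation* recovered (the nonlinear experiment's 10% dip
    regained to 99% of steady state corresponds to f = 0.9).  An estimate to
    compare against the simulated :func:`tbpkinetics.dynamics.response_time`,
    not a replacement for it.
    """
    if not 0.0 <= recovery_fraction < 1.0:
        raise ValueError("recovery_fraction must be in [0, 1)")
    rep = classify(ss, p)
    if rep.classification != "stable":
        raise ValueError(f"fixed point is {rep.classification}, not stable")
    if recovery_fraction == 0.0:
        return 0.0
    return -np.log(1.0 - recovery_fraction) * rep.relaxation_time
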