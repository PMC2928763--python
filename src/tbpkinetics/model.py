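"""Kinetic model of autocatalytic TBP expression.

TATA-binding protein (TBP) drives transcription from its own (and every
other) promoter, so promoter-bound TBP feeds back positively on TBP
synthesis.  Free TBP also dimerizes, and the dimer cannot bind DNA, which
sequesters monomer away from the positive loop.  The model tracks four
species by mass-action kinetics, with synthesis lumped into a single
Hill-type step driven by the bound-TBP concentration:

    T  + T  <-> T2        dimerization            (k1 forward, k2 back)
    T  + D  <-> TD        promoter binding        (k3 forward, k4 back)
    0   ->  T             synthesis               k0 + k5*TD^k6/(k7^k6+TD^k6)
    T   ->  0             degradation             k8*T

Only the free monomer is degraded; dimeric and DNA-bound TBP are assumed
protected.  Promoter sites are conserved: D + TD = D0.

All concentrations are molar and all times seconds (SI throughout).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "KineticParameters",
    "SystemState",
    "DimensionlessParameters",
    "synthesis_rate",
    "hill_derivative",
    "rhs",
    "rhs_reduced",
    "nondimensionalize",
    "dimensionalize",
    "total_tbp",
]

_PARAM_KEYS = ("k0", "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "D0")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and site concentration defining one model instance.

    Parameters
    ----------
    k0 : basal (TBP-independent) synthesis rate, M s^-1.
    k1 : dimer association rate constant, M^-1 s^-1.
    k2 : dimer dissociation rate constant, s^-1.
    k3 : TBP-DNA association rate constant, M^-1 s^-1.
    k4 : TBP-DNA dissociation rate constant, s^-1.
    k5 : maximal regulated synthesis rate, M s^-1.
    k6 : Hill cooperativity coefficient, dimensionless (> 0).
    k7 : bound-TBP concentration at half-maximal synthesis, M.
    k8 : free-monomer degradation rate constant, s^-1.
    D0 : total promoter-site concentration, M.
    """

    k0: float
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    D0: float

    def __post_init__(self) -> None:
        for key in _PARAM_KEYS:
            v = getattr(self, key)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{key} must be finite and >= 0, got {v!r}")
        if self.k6 <= 0:
            raise ValueError("Hill coefficient k6 must be > 0")
        if self.D0 <= 0:
            raise ValueError("total site concentration D0 must be > 0")
        if self.k8 <= 0:
            raise ValueError("degradation rate k8 must be > 0")

    @property
    def kd_dna(self) -> float:
        """Equilibrium dissociation constant of TBP-DNA binding, k4/k3 (M)."""
        if self.k3 == 0:
            raise ZeroDivisionError("k3 = 0: DNA binding Kd undefined")
        return self.k4 / self.k3

    def replace(self, **changes: float) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        unknown = set(d) - set(_PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(_PARAM_KEYS) - set(d)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "KineticParameters":
        """Load from a flat TOML or JSON file keyed k0..k8, D0 (SI units)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        import tomllib

        return cls.from_dict(tomllib.loads(text))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass(frozen=True)
class SystemState:
    """Concentrations (M) of the four species at one time point."""

    T: float   # free TBP monomer
    T2: float  # TBP dimer
    TD: float  # promoter-bound TBP
    D: float   # free promoter sites

    def __post_init__(self) -> None:
        for name in ("T", "T2", "TD", "D"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"concentration {name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_reduced(cls, T: float, T2: float, TD: float, p: KineticParameters) -> "SystemState":
        """Build a full state from the reduced variables, with D = D0 - TD."""
        return cls(T=T, T2=T2, TD=TD, D=p.D0 - TD)

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.T2, self.TD, self.D])

    def reduced(self) -> np.ndarray:
        return np.array([self.T, self.T2, self.TD])


@dataclass(frozen=True)
class DimensionlessParameters:
    """Rate constants rescaled by D0 (concentration) and 1/k8 (time).

    K = K4/K3 is the dimensionless TBP-DNA dissociation constant, i.e. the
    binding Kd measured in units of D0.  k6 is already dimensionless and is
    carried through unchanged.
    """

    K0: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K7: float
    k6: float

    @property
    def K(self) -> float:
        if self.K3 == 0:
            raise ZeroDivisionError("K3 = 0: dimensionless Kd undefined")
        return self.K4 / self.K3


def synthesis_rate(TD: float | np.ndarray, p: KineticParameters) -> float | np.ndarray:
    """Total TBP synthesis rate k0 + k5*TD^k6/(k7^k6 + TD^k6), in M s^-1.

    The Hill term lumps transcription and translation driven by the average
    promoter occupancy; it is phenomenological, not mechanistic.
    """
    TD = np.asarray(TD, dtype=float)
    if np.any(TD < 0):
        raise ValueError("bound-TBP concentration must be >= 0")
    num = np.power(TD, p.k6)
    hill = np.divide(num, p.k7 ** p.k6 + num,
                     out=np.zeros_like(num), where=(p.k7 ** p.k6 + num) > 0)
    out = p.k0 + p.k5 * hill
    return float(out) if out.ndim == 0 else out


def hill_derivative(TD: float, p: KineticParameters) -> float:
    """d/dTD of the regulated synthesis term k5*TD^k6/(k7^k6+TD^k6).

    Diverges at TD = 0 when k6 < 1 (returns +inf there); zero at TD = 0
    when k6 > 1.
    """
    if TD < 0:
        raise ValueError("bound-TBP concentration must be >= 0")
    if TD == 0.0:
        if p.k6 > 1:
            return 0.0
        if p.k6 == 1:
            return p.k5 / p.k7
        return float("inf")
    num = TD ** p.k6
    den = p.k7 ** p.k6 + num
    return p.k5 * p.k6 * p.k7 ** p.k6 * TD ** (p.k6 - 1.0) / den ** 2


def rhs(s: SystemState, p: KineticParameters) -> np.ndarray:
    """Time derivatives (dT, dT2, dTD, dD) of the full 4-species system.

    Dimerization enters dT/dt with stoichiometric factor 2; dimer and bound
    TBP carry no degradation term; dD/dt = -dTD/dt exactly (site
    conservation).
    """
    T, T2, TD, D = s.T, s.T2, s.TD, s.D
    dim = 2.0 * p.k2 * T2 - 2.0 * p.k1 * T * T
    bind = p.k4 * TD - p.k3 * T * D
    dT = dim + bind + synthesis_rate(TD, p) - p.k8 * T
    dT2 = p.k1 * T * T - p.k2 * T2
    dTD = p.k3 * T * D - p.k4 * TD
    return np.array([dT, dT2, dTD, -dTD])


def rhs_reduced(y: np.ndarray, p: KineticParameters) -> np.ndarray:
    """Derivatives of the reduced (T, T2, TD) system with D = D0 - TD.

    Used by the integrator and the stability analysis; unlike :func:`rhs`
    it tolerates slightly negative components (solvers step outside the
    positive orthant transiently), clipping only inside the Hill term where
    a fractional power would be undefined.
    """
    T, T2, TD = y
    D = p.D0 - TD
    dim = 2.0 * p.k2 * T2 - 2.0 * p.k1 * T * T
    bind = p.k4 * TD - p.k3 * T * D
    TDc = max(TD, 0.0)
    num = TDc ** p.k6
    syn = p.k0 + (p.k5 * num / (p.k7 ** p.k6 + num) if num > 0 or p.k7 > 0 else p.k0 * 0)
    dT = dim + bind + syn - p.k8 * T
    dT2 = p.k1 * T * T - p.k2 * T2
    dTD = p.k3 * T * D - p.k4 * TD
    return np.array([dT, dT2, dTD])


def nondimensionalize(p: KineticParameters) -> DimensionlessParameters:
    """Rescale with D0 as reference concentration and 1/k8 as reference time.

    Ki = ki * D0^(a) / k8 with the power fixed by each constant's units:
    K1 = k1*D0/k8, K2 = k2/k8, K3 = k3*D0/k8, K4 = k4/k8,
    K5 = k5/(k8*D0), K7 = k7/D0, K0 = k0/(k8*D0).
    """
    return DimensionlessParameters(
        K0=p.k0 / (p.k8 * p.D0),
        K1=p.k1 * p.D0 / p.k8,
        K2=p.k2 / p.k8,
        K3=p.k3 * p.D0 / p.k8,
        K4=p.k4 / p.k8,
        K5=p.k5 / (p.k8 * p.D0),
        K7=p.k7 / p.D0,
        k6=p.k6,
    )


def dimensionalize(dp: DimensionlessParameters, D0: float, k8: float) -> KineticParameters:
    """Inverse of :func:`nondimensionalize` for given reference scales."""
    if D0 <= 0 or k8 <= 0:
        raise ValueError("reference scales D0 and k8 must be > 0")
    return KineticParameters(
        k0=dp.K0 * k8 * D0,
        k1=dp.K1 * k8 / D0,
        k2=dp.K2 * k8,
        k3=dp.K3 * k8 / D0,
        k4=dp.K4 * k8,
        k5=dp.K5 * k8 * D0,
        k6=dp.k6,
        k7=dp.K7 * D0,
        k8=k8,
        D0=D0,
    )


def total_tbp(s: SystemState) -> float:
    """Equivalent total TBP concentration T + 2*T2 + TD (M).

    Each dimer counts as two monomer equivalents, so this is the
    concentration of TBP polypeptide chains in whatever form.
    """
    return s.T + 2.0 * s.T2 + s.TD
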