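"""Physiological condition generator: parameter sets spanning cell types.

Reported TBP abundance spans ~2e3 molecules (yeast) to ~2e6 (sea-urchin
egg), and cell volumes span 4.17e-15 L (1 um radius) to 5.22e-10 L, so
physiological TBP concentration covers 1e-8 to 1e-5 M and promoter-site
concentration 1e-9 to 1e-5 M.  The generator produces kinetic parameter
sets across those ranges by varying the site concentration D0, the
half-saturation k7 and the maximal synthesis rate k5 — the same knobs a
cell type actually differs by — while keeping the binding, dimerization and
degradation constants at their literature values.  Each scenario is placed
above its own saddle-node in k5 so a high-TBP state exists; scenarios whose
realized high state falls outside the physiological TBP window are labeled
"extreme".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .model import KineticParameters, nondimensionalize
from .steady_state import critical_k5, find_steady_states, high_state

__all__ = [
    "Scenario",
    "default_parameters",
    "generate_grid",
    "preset",
    "molecules_to_molar",
    "molar_to_molecules",
]

PHYSIOLOGICAL_TBP_RANGE = (1e-8, 1e-5)   # M
PHYSIOLOGICAL_D0_RANGE = (1e-9, 1e-5)    # M
YEAST_CELL_VOLUME_L = 4.17e-15           # 1 um radius sphere
YEAST_EXPRESSED_GENES = 3000


def molecules_to_molar(n: float, volume_l: float) -> float:
    """Concentration (M) of n molecules in a cell of given volume (L)."""
    if volume_l <= 0:
        raise ValueError("volume must be > 0")
    return n / (Avogadro * volume_l)


def molar_to_molecules(c: float, volume_l: float) -> float:
    return c * Avogadro * volume_l


@dataclass
class Scenario:
    id: str
    label: str  # e.g. mammalian-like, yeast-like, physiological, extreme
    params: KineticParameters
    tbp_scale: float  # realized high-state total TBP (M), 0 if no high state
    D0: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"id": self.id, "label": self.label, "tbp_scale": self.tbp_scale,
                "D0": self.D0, "metadata": self.metadata, **self.params.to_dict()}


def default_parameters() -> KineticParameters:
    """Literature parameter set for a typical mammalian cell.

    ~25000 TBP molecules and ~25000 promoter sites; dimerization and DNA
    binding rates from in vitro TBP studies, degradation from the measured
    monomer half-life, k7 set to half the site concentration, basal rate
    1% of the maximal regulated rate.
    """
    return KineticParameters(
        k0=5e-15,   # M/s, 0.01*k5
        k1=1e5,     # M^-1 s^-1
        k2=1e-3,    # s^-1
        k3=2e5,     # M^-1 s^-1
        k4=4e-4,    # s^-1
        k5=5e-13,   # M/s
        k6=2.0,
        k7=1.25e-8,  # M, half of D0
        k8=7.4e-5,  # s^-1
        D0=2.5e-8,  # M
    )


def _classify_label(total: float | None) -> str:
    lo, hi = PHYSIOLOGICAL_TBP_RANGE
    if total is None or not (lo <= total <= hi):
        return "extreme"
    return "physiological"


def _axis(n: int, lo: float, hi: float, default: float) -> np.ndarray:
    """Log-spaced axis; a single-point axis collapses onto the default."""
    if n < 1:
        raise ValueError("grid counts must be >= 1")
    if n == 1:
        return np.array([default])
    return np.logspace(np.log10(lo), np.log10(hi), n)


def generate_grid(n_k5: int = 4, n_k7: int = 3, n_D0: int = 4,
                  seed: int = 0, jitter: float = 0.0) -> list[Scenario]:
    """Factorial grid of conditions over (D0, k7/D0, k5).

    D0 spans the physiological site range [1e-9, 1e-5] M and k7 spans
    [1e-2, 1e2]*D0.  For each (D0, k7) cell the synthesis axis runs from
    just above the saddle-node, 1.1*k5_c, to 1e3*k5_c, so every scenario
    has a high-TBP state; its stability and realized concentration decide
    the physiological/extreme label.  Deterministic for a given seed;
    ``jitter`` optionally perturbs interior grid points log-uniformly by up
    to that fraction of a grid step.
    """
    base = default_parameters()
    rng = np.random.default_rng(seed)
    d0_axis = _axis(n_D0, *PHYSIOLOGICAL_D0_RANGE, default=base.D0)
    k7_ratio_axis = _axis(n_k7, 1e-2, 1e2, default=base.k7 / base.D0)

    scenarios: list[Scenario] = []
    idx = 0
    for D0 in d0_axis:
        for k7r in k7_ratio_axis:
            probe = base.replace(k0=0.0, D0=float(D0), k7=float(k7r * D0))
            k5c = critical_k5(probe).value
            # a single-point k5 axis keeps the literature value where it is
            # admissible (above the fold), so grid (1,1,1) is the default set
            k5_default = base.k5 if base.k5 > 1.1 * k5c else np.sqrt(1.1 * 1e3) * k5c
            k5_axis = _axis(n_k5, 1.1 * k5c, 1e3 * k5c, default=k5_default)
            for k5 in k5_axis:
                if jitter > 0:
                    k5 = float(k5 * 10 ** (rng.uniform(-1, 1) * jitter))
                # basal rate follows the literature convention k0 = 0.01*k5
                p = base.replace(k0=0.01 * float(k5), D0=float(D0),
                                 k7=float(k7r * D0), k5=float(k5))
                recs = find_steady_states(p)
                hs = high_state(recs, stable_only=True)
                total = hs.total if hs is not None else None
                scenarios.append(Scenario(
                    id=f"grid-{idx:03d}",
                    label=_classify_label(total),
                    params=p,
                    tbp_scale=total if total is not None else 0.0,
                    D0=float(D0),
                    metadata={"k7_over_D0": float(k7r),
                              "k5_over_k5c": float(k5 / k5c),
                              "dimer_to_bound": (hs.T2 / hs.TD
                                                 if hs is not None and hs.TD > 0
                                                 else None)},
                ))
                idx += 1
    return scenarios


def preset(name: str) -> Scenario:
    """Named physiological presets.

    ``mammalian``: the literature default (~25000 TBP molecules and sites).
    ``yeast``: D0 from ~3000 expressed genes in a 4.17e-15 L cell; k5 and
    k7 rescaled proportionally to D0 so the dimensionless synthesis
    strength K5 and saturation K7 match the mammalian set, keeping the
    system in the bistable regime (recorded in the metadata).
    """
    base = default_parameters()
    if name == "mammalian":
        recs = find_steady_states(base)
        hs = high_state(recs, stable_only=True)
        return Scenario("mammalian", "mammalian-like", base,
                        hs.total if hs else 0.0, base.D0,
                        metadata={"molecules_TBP": 25000,
                                  "molecules_sites": 25000})
    if name == "yeast":
        D0 = molecules_to_molar(YEAST_EXPRESSED_GENES, YEAST_CELL_VOLUME_L)
        scale = D0 / base.D0
        p = base.replace(D0=D0, k7=base.k7 * scale, k5=base.k5 * scale,
                         k0=base.k0 * scale)
        recs = find_steady_states(p)
        hs = high_state(recs, stable_only=True)
        return Scenario("yeast", "yeast-like", p, hs.total if hs else 0.0, D0,
                        metadata={"molecules_sites": YEAST_EXPRESSED_GENES,
                                  "cell_volume_l": YEAST_CELL_VOLUME_L,
                                  "tuning": "k5, k7, k0 scaled by D0 ratio to "
                                            "preserve dimensionless K5, K7, K0"})
    raise KeyError(f"unknown preset {name!r}; choose 'mammalian' or 'yeast'")


def scenarios_to_frame(scenarios: list[Scenario]) -> pd.DataFrame:
    rows = []
    for s in scenarios:
        row = s.to_dict()
        meta = row.pop("metadata")
        row.update({f"meta_{k}": v for k, v in meta.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def save_scenarios(scenarios: list[Scenario], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps([s.to_dict() for s in scenarios], indent=1))
    else:
        scenarios_to_frame(scenarios).to_csv(path, index=False)
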