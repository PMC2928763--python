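#!/usr/bin/env python
"""Basins of attraction and the slow binding manifold.

Integrates a fan of initial conditions spanning 1e-11 to 1e-7 M total TBP
(k0 = 0).  Trajectories below ~0.1 nM collapse to the zero state — a cell
seeded with too little TBP cannot bootstrap its own transcription — while
larger doses reach the high state.  Along the way all trajectories land on
the manifold where T*D/TD equals the binding dissociation constant k4/k3.
Writes results/phase_plane.csv and results/basins.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tbpkinetics import (
    SystemState,
    default_parameters,
    integrate,
    phase_plane,
    slow_manifold_ratio,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    p = default_parameters().replace(k0=0.0)

    totals = np.logspace(-11, -7, 9)
    inits = [SystemState.from_reduced(t0, 0.0, 0.0, p=p) for t0 in totals]
    trajs, summary = phase_plane(p, inits)

    frames = []
    for t0, traj in zip(totals, trajs):
        frames.append(pd.DataFrame({"initial_total": t0,
                                    "attractor": traj.attractor,
                                    "t": traj.t, "T": traj.T, "T2": traj.T2,
                                    "TD": traj.TD, "D": traj.D}))
    pd.concat(frames).to_csv(OUT / "phase_plane.csv", index=False)
    (OUT / "basins.json").write_text(json.dumps(summary, indent=1) + "\n")

    for t0, traj in zip(totals, trajs):
        print(f"  initial total {t0:.2e} M -> {traj.attractor} state")
    print(f"\nseparatrix bracket: zero-basin up to "
          f"{summary['largest_total_to_zero']:.2e} M, high-basin from "
          f"{summary['smallest_total_to_high']:.2e} M")

    traj = integrate(p, SystemState.from_reduced(1e-8, 0.0, 0.0, p=p),
                     50.0 / p.k8)
    _, med = slow_manifold_ratio(traj, p)
    print(f"late-time T*D/TD = {med:.3e} M vs binding Kd k4/k3 = "
          f"{p.k4 / p.k3:.3e} M")


if __name__ == "__main__":
    main()
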