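# tbpkinetics

Kinetic analysis of TATA-binding-protein (TBP) autoregulation: bistability,
saddle-node bifurcations, and the role of dimerization in buffering TBP
levels.

TBP is required for transcription initiation by all three eukaryotic RNA
polymerases — including transcription of its own gene — so bound TBP feeds
back positively on TBP synthesis, while solution dimerization sequesters
the DNA-binding monomer.  This package implements the resulting
four-species kinetic model

```
T + T ⇌ T₂              (k₁, k₂)     dimerization
T + D ⇌ TD              (k₃, k₄)     promoter binding
∅ → T                   k₀ + k₅·TD^k₆/(k₇^k₆ + TD^k₆)
T → ∅                   k₈·T
```

with D + TD = D₀, and provides:

- **steady states** — all roots of the scalar fixed-point condition
  f(T) = (k₈T − k₀)(k₇^k₆ + TD^k₆) − k₅·TD^k₆, completed to full states and
  classified by the eigenvalues of the reduced 3×3 Jacobian;
- **bifurcation analysis** — closed-form saddle-node values of k₃ and k₅
  (from the tangency condition of the dimensionless quadratic), numeric
  fold location for everything else, 1-D branch sweeps, and the
  monostable/bistable map of the (k₃, k₅) plane;
- **dynamics** — stiff integration (LSODA), basins of attraction, the slow
  manifold where T·D/TD → k₄/k₃, and the response-time experiment that
  compares recovery from a 10% dip in free TBP with and without the
  dimerization reaction;
- **scenarios** — parameter sets spanning physiological cell types (yeast
  to mammalian, promoter sites 1e-9–1e-5 M), each placed above its own
  fold so a high-TBP state exists.

See `docs/methods.md` for the model's assumptions and every numerical
choice.

## Worked example

```python
import tbpkinetics as tk

p = tk.default_parameters().replace(k0=0.0)   # mammalian set, no basal rate

for r in tk.find_steady_states(p):
    print(f"{r.label:>5}  total = {r.total:.3e} M  {r.stability}")

print(f"k3_c = {tk.critical_k3(p).value:.4g} M^-1 s^-1")
print(f"k5_c = {tk.critical_k5(p).value:.4g} M s^-1")
print(f"halving k3 costs {tk.relative_sensitivity('k3', 0.5, p).percent_reduction:.1f}%")
```

prints

```
 zero  total = 0.000e+00 M  stable
  low  total = 2.260e-09 M  unstable
 high  total = 2.556e-08 M  stable
k3_c = 9.579e+04 M^-1 s^-1
k5_c = 2.395e-13 M s^-1
halving k3 costs 46.8%
```

Read: without basal synthesis the system is bistable.  A cell at the
26 nM high-TBP state is viable; one that starts below the ~2.3 nM saddle
decays to the absorbing zero state — a minimum TBP dose (e.g. maternally
inherited protein) is needed to bootstrap TBP's own transcription.  The
high state sits about 2× above the fold in k₃: halving the DNA binding
rate costs nearly half the TBP pool, and a slightly larger drop abolishes
the viable state entirely.

The dimer-buffering experiment:

```python
res = tk.compare_dimer_effect(tk.preset("yeast").params)
print(res.dimer_to_bound_ratio, res.ratio)   # 5.73, 0.0053
res = tk.compare_dimer_effect(tk.preset("mammalian").params)
print(res.dimer_to_bound_ratio, res.ratio)   # 0.117, 1.08
```

Under yeast-like conditions the dimer pool dwarfs the DNA-bound pool and
recovery from a 10% dip in free TBP is two orders of magnitude faster with
dimerization;
under mammalian-like conditions most TBP sits on DNA and the dimer makes
essentially no difference.

## Analysis scripts

The numbered drivers under `analysis/` run the full study and write tables
to `results/`:

| script | what it computes |
|---|---|
| `01_steady_states.py` | fixed points and stability, with and without basal synthesis |
| `02_bifurcation.py` | folds in k₃/k₅/k₆/k₀, closed form vs numeric, (k₃, k₅) region map |
| `03_sensitivity.py` | high-state shift under rescaling of k₃, k₅, k₆ |
| `04_phase_plane.py` | basins of attraction, separatrix bracket, slow-manifold ratio |
| `05_dimer_buffering.py` | response-time ratios across the scenario grid and presets |

A `tbpkin` console command exposes the same stages
(`tbpkin steady-states --k0-zero`, `tbpkin bifurcate --param k3`, ...);
every run writes a `manifest.json` from which its outputs can be
regenerated exactly.

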