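# Methods

## The model

TATA-binding protein (TBP) is required for transcription initiation by all
three eukaryotic RNA polymerases, including transcription of its own gene,
so promoter-bound TBP feeds back positively on TBP synthesis.  Free TBP
also dimerizes in solution, and the dimer cannot bind DNA: dimerization
sequesters monomer away from the positive loop and shields it from
degradation.  The model tracks free monomer T, dimer T2, promoter-bound
TBP TD and free promoter sites D (all molar), with mass-action kinetics
for binding steps and a lumped Hill term for transcription plus
translation:

    dT/dt  = 2 k2 T2 − 2 k1 T² + k4 TD − k3 T D
             + k0 + k5 TD^k6/(k7^k6 + TD^k6) − k8 T
    dT2/dt = k1 T² − k2 T2
    dTD/dt = k3 T D − k4 TD
    dD/dt  = −dTD/dt,        D + TD = D0

Assumptions: only free monomer is degraded (dimeric and DNA-bound TBP are
protected); TBP has equal affinity for all promoter sites, so synthesis is
driven by the average occupancy TD rather than the occupancy of the TBP
promoter alone; the Hill term is phenomenological — it encodes a saturating,
possibly cooperative dependence of protein output on bound TBP, not a
specific promoter-state mechanism.

Site conservation eliminates D, leaving a 3-variable system used for
integration and linear stability; the 4-variable form is kept for
conservation checks.

## Parameters

Defaults describe a typical mammalian cell (~25,000 TBP molecules and
~25,000 promoter sites):

| symbol | meaning | default | units |
|---|---|---|---|
| k0 | basal synthesis rate | 5e-15 (= 0.01·k5) | M s⁻¹ |
| k1 | dimer association | 1e5 | M⁻¹ s⁻¹ |
| k2 | dimer dissociation | 1e-3 | s⁻¹ |
| k3 | TBP–DNA association | 2e5 | M⁻¹ s⁻¹ |
| k4 | TBP–DNA dissociation | 4e-4 | s⁻¹ |
| k5 | maximal regulated synthesis | 5e-13 | M s⁻¹ |
| k6 | Hill cooperativity | 2 | — |
| k7 | half-saturation occupancy | 1.25e-8 (= D0/2) | M |
| k8 | monomer degradation | 7.4e-5 | s⁻¹ |
| D0 | total promoter sites | 2.5e-8 | M |

Note the binding/dimerization rates are in vitro values; the literature
also reports a dimer dissociation constant of ~5e-10 M, whereas k2/k1 here
is 1e-8 M.  The package uses the tabulated rate constants throughout and
does not attempt to reconcile the two.

Nondimensionalization uses D0 as the concentration scale and 1/k8 as the
time scale: K1 = k1·D0/k8, K2 = k2/k8, K3 = k3·D0/k8, K4 = k4/k8,
K5 = k5/(k8·D0), K7 = k7/D0, K0 = k0/(k8·D0), and K = K4/K3 is the binding
Kd in units of D0.  These are the unique dimensionally consistent scalings
for those references, and `dimensionalize(nondimensionalize(p), D0, k8)`
round-trips to machine precision.

## Steady states and root finding

At steady state the dimerization and binding reactions equilibrate
individually (T2 = (k1/k2)T², TD = T·D0/(k4/k3 + T)), collapsing the model
to one scalar condition

    f(T) = (k8 T − k0)(k7^k6 + TD(T)^k6) − k5 TD(T)^k6 = 0.

`find_steady_states` scans a 2000-point log grid on [1e-16, 1e-3] M (three
decades beyond the physiological range on either side), brackets sign
changes, and refines each bracket with Brent's method at relative tolerance
1e-10 with the absolute tolerance effectively disabled — roots live at
1e-10 M scales where any absolute floor would dominate.  Two safeguards
matter near folds: intervals containing a local extremum of f are re-probed
on a 64-point sub-grid so a barely-separated root pair closer than the
coarse grid spacing is still caught, and refined roots agreeing within 1e-4
relative are merged into a single record with multiplicity 2 (a tangency,
not two states).  The T = 0 root is inserted analytically when k0 = 0 — a
log grid cannot bracket it, and for k0 > 0, f(0) = −k0·k7^k6 < 0 rules it
out.  Since f contains neither k1 nor k2, the existence and location (in T,
TD) of every fixed point is independent of dimerization; only the totals
shift, by exactly 2(k1/k2)T².

Total TBP is counted in monomer equivalents, T + 2·T2 + TD; this is the
convention under which the computed high state reproduces the published
~2.55e-8 M figure.

For k6 = 2, k0 = 0 the positive roots solve the quadratic (in t = T/D0)

    (1 + K7²) t² + (2K·K7² − K5) t + K7²K² = 0,

whose zero-discriminant (tangency) condition yields closed-form saddle-node
values, re-derived here independently:

    K5_c = 2(K·K7² + √(K²K7² + K²K7⁴)),
    K3_c = 2(K4·K5·K7² + √(K4²K5²K7² + K4²K5²K7⁴))/K5².

At the defaults these give k3_c = 9.579e4 M⁻¹s⁻¹ and k5_c = 2.3947e-13
M s⁻¹, and the package's independent numeric fold location (bisection on
the root count) agrees to five significant figures.  The basal-rate
threshold k0_c — three positive states below, one above — has no closed
form and is found by bisection on the root count over k0 ∈ (0, k5]; at the
defaults k0_c = 2.988e-15 M s⁻¹ = 0.00598·k5, confirmed against the
positive-real-root count of the exact dimensionless cubic.

Multiplicity conditions (`predicted_multiplicity`, k6 ∈ {1, 2}, counting
strictly positive roots; the zero state is reported separately): for
k6 = 2, k0 = 0 the low/high pair exists iff K5 > K5_c(K, K7) — the exact
tangency condition is used, because the weaker pair of inequalities
K5 > 2K·K7² and K7 < 1 is necessary but not sufficient (it ignores the
complex-root band just below the fold).  For k6 = 1, k0 = 0 the condition
K5 > K7·K is exact (the unique positive root is t = (K5 − K7K)/(1 + K7)).
For k6 = 1, k0 > 0 the quadratic's root product is negative, so there is
exactly one positive state for any parameters; the "K0 much smaller than
K" clause found in analyses of this case delimits a regime, not a count,
and is exposed only as a documented heuristic (default factor 100).

## Stability

The analytic 3×3 Jacobian of the reduced system is evaluated at each fixed
point; a state is stable iff all eigenvalue real parts are below −tol and
unstable iff any exceeds +tol, with tol = 1e-12·k8 — twelve orders below
the slowest kinetic rate, so the tolerance only guards against floating-
point noise, and anything inside the band is reported "marginal" rather
than silently stable.  The Hill derivative diverges at TD = 0 when k6 < 1;
there the classification falls back to integrating ±1% perturbations of
each coordinate and testing return versus escape.  At the mammalian
defaults with k0 = 0 the pattern is stable (zero) / unstable (low) /
stable (high): bistability, with the low state the separatrix-defining
saddle.

`linearized_response_time` estimates recovery as single-mode exponential
decay, −ln(1 − f)/|Re λ_slow| for recovering a fraction f of the
perturbation.  It is an order-of-magnitude cross-check on the simulated
response time, not a replacement: at the defaults the slow eigenmode
(1/|Re λ| ≈ 6.9e4 s) predicts ~1.6e5 s for 90% recovery versus ~6.2e4 s
simulated — within a factor of 3, the gap reflecting multi-mode and
nonlinear contributions.

## Dynamics

DNA binding relaxes in ~1/(k3·T + k4) ≈ minutes while synthesis and
degradation act on 1/k8 ≈ 4 hours, so the system is stiff; integration
uses `scipy.integrate.solve_ivp` with LSODA (adaptive implicit for stiff
segments), rtol 1e-8 and atol 1e-20 M — far below any physiological
concentration so near-zero species are still resolved.  Past the binding
transient (t > 10/k4) trajectories collapse onto the slow manifold where
T·D/TD equals the binding Kd k4/k3; `slow_manifold_ratio` reports the
late-time median, excluding points with TD below 1e-18 M where the ratio
is 0/0-like.

The response-time experiment places the system at its high-TBP state,
reduces free monomer by 10% (dimer and bound pools untouched), and reports
the first time after which T stays within 1% of its steady-state value for
the remainder of the integration (t_end = 50/k8).  "Sustained within
threshold" rather than first crossing guards against overshoot in the
3-variable relaxation.  `compare_dimer_effect` runs this for the model and
its k1 = 0 variant — both share the same T and TD fixed point, so each is
perturbed at its own high state — and reports the time ratio against the
relative dimer abundance T2ss/TDss.

## Scenario generator

The generator emulates the spread of real cell types, which differ by
orders of magnitude in promoter-site concentration and TBP level: site
concentration D0 spans 1e-9 to 1e-5 M (from ~3,000 expressed genes in a
1 μm yeast cell to dense mammalian genomes), k7 spans 1e-2 to 1e2 times D0,
and for each (D0, k7) cell the synthesis axis runs from 1.1× to 1e3× that
cell's own saddle-node value k5_c, so every scenario possesses a high-TBP
state by construction.  Anchoring the k5 axis to the local fold (rather
than to a single global range) is the package's choice; a fixed global
range would leave small-D0/large-k7 corners entirely below their fold.
Grid scenarios keep the basal-rate convention k0 = 0.01·k5, so they are
monostable-high and both dimer variants recover from perturbations without
basin-escape complications.  Scenarios whose realized high state falls
outside 1e-8–1e-5 M total TBP are labeled "extreme" but retained — they
exercise the far ends of the dimer-to-bound spectrum (the default grids
cover more than three decades of T2ss/TDss on each side of 1).  A
single-cell grid reduces to the mammalian default set.  The ``yeast``
preset converts 3,000 sites in 4.17e-15 L to D0 ≈ 1.19e-6 M and rescales
k5, k7 and k0 proportionally to D0 so the dimensionless K5, K7, K0 match
the mammalian set, keeping the dynamics in the same regime at 48-fold
higher concentrations.

What the generator does not emulate: cell-to-cell variability within a
type, stochasticity at low copy number (the model is deterministic and
continuous; several scenarios have species below ~100 molecules where that
matters), transcription/translation delay, and chromatin-driven changes in
accessible site number.  Tests passing on this grid show the model's
structural claims hold across the parameter ranges, not that any particular
cell type is quantitatively captured.

## Numerical choices and edge cases

- Root search: log grid [1e-16, 1e-3] M × 2000 points; Brent refinement
  rtol 1e-10; near-duplicate merge at 1e-4 relative; fold bisection refined
  to better than 4 significant figures.
- k6 is any positive real; power functions are evaluated on clipped
  nonnegative TD inside the integrator, since adaptive solvers step
  transiently outside the positive orthant.
- Response-time resolution is set by the output sampling (4000 points over
  50/k8, ~170 s per sample); ratios between two such times inherit that
  granularity.
- Degenerate inputs raise: k5 = 0 for critical values (no fold), zero D0 or
  k8 for scaling, unstable states for response times, monostable-zero
  baselines for sensitivity — with the failing variant named in the dimer
  comparison.
- The buffering claim is quantified as: time ratio < 0.5 whenever
  T2ss/TDss > 10, and ratio ∈ [0.8, 1.25] whenever T2ss/TDss < 0.01.  The
  bands are this package's operationalization of "much less" and "almost
  identical"; in the intermediate band the ratio is reported but nothing is
  asserted — the dimer-to-bound ratio is genuinely not predictive there.

## Known limitations

- Deterministic ODEs only; no stochastic simulation, delays or spatial
  structure.
- Closed-form critical values exist only for k6 = 2, k0 = 0; elsewhere the
  numeric fold search is used, and for non-integer k6 between 1 and 2 the
  sweep output is reported without analytical cross-check.
- The stability of the zero state for k6 ≤ 1, k0 = 0 comes from the
  perturbation fallback and is reported as computed, without an analytic
  guarantee.
- Problem sizes in the analysis drivers (200-point sweeps, 60×60 region
  map, 3×3×3 scenario grid) were chosen so each driver completes in seconds
  while resolving every feature it reports; all are arguments, not
  constants, and scale up directly.
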