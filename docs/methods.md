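# Methods

## Model structure and assumptions

Three compartments are distinguished: extracellular space, cytosol and
ER.  The nucleus only excludes volume; it stores no calcium.  The cell
is a sphere (radius `R_cell = 8 μm` for the Jurkat line, matching a
2 pl cell volume); the ER occupies a volume fraction `f_V = 0.01` and
its strongly folded membrane has `f_A = 30` times the area of a sphere
of equal volume.  Only the product `f_A · f_V^(2/3)` enters the
equations, so these two parameters are redundant by construction and
are kept separate purely for physiological interpretability (a property
test asserts the invariance).

Key simplifications, inherited from the modeling framework:

* **Fixed membrane potential.**  `V = V_ER = −60 mV` throughout;
  calcium currents are assumed charge-compensated by other ions.
* **Rapid buffering.**  Calcium–buffer binding is instantaneous; each
  compartment's raw flux is divided by `1 + B(C)` with
  `B = b_tot K / (C + K)²` (cytosol: 100 μM calmodulin sites,
  K = 0.1 μM; ER: 30 mM calreticulin sites, K = 0.1 mM, giving ~2%
  free ER calcium).
* **Ohmic currents with shifted Nernst reversals.**  The non-linear
  I–V relations of CRAC and IP3R are linearized around the physiological
  range by empirical shifts (ΔV_C = 78 mV fixed; ΔV_C,ER = 63 mV, a fit
  parameter).
* **Space-averaged concentrations** (no microdomains), **no RyR /
  cADPR / NAADP pathways**, **no mitochondrial uptake or leak
  currents**, **no CRAC inactivation** (its ~1000 s time scale exceeds
  the protocols simulated), **no ATP or calmodulin dependence of the
  pumps/IP3R** in the regimes simulated.

Single-protein models: CRAC is a 2 fS Ohmic channel whose *active
density* (not conductance) is the dynamic quantity, relaxing with
τ = 5 s toward a store-depletion-controlled target
`ρ̄(C_ER) = ρ⁻ + (ρ⁺ − ρ⁻)(1 − H(C_ER, 169 μM, 4.2))`.  IP3R follows
the Mak–McBride–Foskett two-gate description; the inhibition half-point
follows IP3 in quasi-steady state while the two gates relax with
τ = 0.1 s and θ = 0.3 s.  PMCA (isoform 4b) is a Hill-activated pump
(n = 2, K = 0.2 μM) with a slow activation delay τ = 50 s; SERCA (2b)
responds instantaneously (n = 2, K = 0.25 μM).  Pump unitary currents
come from turnover rates (PMCA ~30 Hz, SERCA2b ~5 Hz, two charges per
cycle) and are used as the rounded constants 1e-5 pA and 3e-6 pA; the
underlying turnover arithmetic is documentation, not runtime code.

### Sign conventions and rectification

Positive ions entering the cytosol are negative currents.  The IP3R
current is clamped at zero from above: the receptor can release ER
calcium but never transport it back.  The CRAC current is deliberately
*not* clamped — at surrogate-zero external calcium a small outward CRAC
current exists and is the only clearance route once both pumps are
blocked, which the pulse-clearance protocol relies on.

### Steady-state closure

Four parameters are fixed by requiring the resting state
(C = 0.1 μM, C_ER = 400 μM, P = 8.7 nM, ρ_CRAC = 0.6/μm²) to be an
exact fixed point:

| derived | closure | value |
|---|---|---|
| ρ_PMCA | balances resting CRAC influx | 68.57 /μm² |
| ρ_IP3R | balances resting SERCA uptake | 11.35 /μm² |
| γ_P | balances resting IP3 production | 0.01149 /s |
| ρ_CRAC⁻ | recruitment target equals resting density | 0.5115 /μm² |

The ρ_CRAC⁻ expression is implemented in the closed form derived from
`ρ̄(C_ER,0) = ρ_CRAC,0`, i.e. `ρ⁻ = ρ0 (1 − f_CRAC (1 − H0)) / H0`;
this reproduces 0.5115/μm² exactly and is the only bracketing of the
published formula consistent with the recruitment fixed point.  The
closure is idempotent and re-run for every fit candidate, so every
objective evaluation starts from a true resting state.

### Zero-calcium surrogate

The Nernst potential diverges at zero external calcium, so
zero-calcium protocols instead use the unique concentration `C_ext*` at
which the resting CRAC current vanishes:
`C_ext* = C0 exp((V0 + ΔV_C) z F / RT) ≈ 0.385 μM`.  Note the sign
convention: with the Nernst form `V̄ = (RT/zF) ln(C_out/C_in) − ΔV`,
only the `(V0 + ΔV_C)` exponent satisfies the defining condition
`I_CRAC(V0, C0, C_ext*) = 0`; the package implements the defining
condition, and a test asserts it to machine precision.

## Units

Internally: concentrations μM, potentials mV, times s, currents A,
conductances S, lengths μm.  The flux assembly converts
`ξ[1/μm] · ρ[1/μm²] · I[A] / (z_Ca F)` → mol s⁻¹ μm⁻³, then ×10²¹ to
μM/s; the factor is pinned by a worked-example unit test
(ρ = 3.9/μm², ξ = 0.385/μm, I = −2·10⁻¹⁶ A → ≈1.56 μM/s raw).  Config
files keep the conventional units of the literature (mM, nM, fS, pA)
with unit-suffixed keys, converted at load.

## Numerics

* **Stepper.**  A Dormand–Prince 5(4) pair with embedded error control
  (scaled RMS norm, PI-free step factor in [0.2, 5]), JIT-compiled with
  numba.  Output times are reached by clamping the step, so sampled
  values carry no interpolation error.  The same right-hand side also
  runs under `scipy.integrate.solve_ivp` RK45 (`method="scipy"`); a
  test holds the two steppers to agreement on all presets, and another
  holds the compiled RHS to the readable Python RHS point-wise at
  random states.
* **Tolerances.**  Defaults rtol = 1e-8, atol = 1e-10 (μM scale),
  max_step = 0.5 s so the 0.1–0.3 s gate dynamics are always resolved.
  Halving the tolerances moves the stimulation peak by far less than
  0.1% (convergence test).
* **Discontinuities.**  Protocols are piecewise constant; the
  integrator restarts exactly at each segment boundary.  Protocol
  queries are right-continuous.
* **Concentration floor.**  10⁻⁴ μM on C and C_ER keeps the Nernst
  logarithms finite; reaching the floor aborts the run with the
  protocol context, since the electro-diffusion description is not
  meaningful there.
* **Degenerate inputs.**  Closure denominators of zero (e.g. a
  vanishing resting IP3R current) raise a dedicated error rather than
  producing infinite densities; density orderings
  (ρ⁻ ≤ ρ0 ≤ ρ⁺) are re-validated after every closure.

## Fitting

The quality index `QI = (1/N) Σ (X_i − E_i)²/E_i²` is minimised over
six variable parameters (ΔV_C,ER, P0, β_P, ρ_SERCA, ρ_CRAC,0, ρ_CRAC⁺)
with `scipy.optimize.differential_evolution` (Storn–Price; defaults
CR = 0.7, dithered mutation, latin-hypercube init, population
15×dim), followed by a derivative-free Powell refinement.  Two
numerical choices matter:

* the optimizer works in unit-box coordinates, because the physical
  parameters span six orders of magnitude;
* the refinement is Powell rather than a gradient method: near the
  optimum the QI surface has a long, shallow valley of correlated
  parameters in which finite-difference gradients drown in integrator
  noise, while Powell's line searches descend it reliably.

Upper bounds on ρ_CRAC⁺ are validated against the experimental ~10-fold
recruitment ceiling relative to ρ_CRAC,0.  Failed candidate
integrations map to a large penalty QI so the population can continue.
The historical two-step procedure (coarse fit over all non-derived
parameters, fine fit over the six variable ones) is expressible as two
`fit_parameters` calls with `x0` chaining; a test asserts the second
step never increases QI.

The ±10% sensitivity scan perturbs each non-derived parameter, re-runs
closure and simulation, and reports `100·|ΔQI|/QI`.  Derived parameters
are skipped — they move with their parents.  The scan requires a
non-zero baseline QI (on a noiseless self-target the relative change is
undefined) and is deterministic for fixed solver settings.

## Synthetic targets

The model was originally calibrated against ~22 points digitized from a
published figure; that dataset is not redistributable, so
`datasets.generate_target` builds synthetic equivalents: simulate a
protocol, sample 22 points on a peak-weighted grid (about two thirds of
the points in the 0–150 s transient, mirroring how digitized data
resolve the peak), and apply multiplicative lognormal noise
(default sd = 0.05).  Multiplicative noise matches the relative-error
metric, so E[QI] ≈ sd² — a Monte-Carlo test checks this.  What the
synthetic targets do *not* emulate: digitization bias, correlated
drifts from dye bleaching or focus, and cell-to-cell variability; tests
passing on them demonstrate internal consistency and recoverability,
not agreement with any particular measurement.

## Problem sizes used by the test suite

The acceptance checks use the study's own scales: 400 s (stimulation),
600 s (store depletion / conservation / hold) and 1000 s
(pulse-clearance) protocols at 0.5 s output resolution, 22-point
targets, and a recovery fit of all six variable parameters against a
noiseless synthetic target (bounds −20%/+25% around the generating
values, start perturbed by +12%, fixed seed; recovered within 5% at
QI ≈ 1e-7).  Because the QI valley is genuinely shallow, recovery
accuracy at fixed effort varies somewhat with the optimizer seed; the
documented seed and settings are part of the recorded conditions.

## Known limitations

* Zero-calcium media are represented by the surrogate concentration,
  not by true zero; the Nernst/Ohm description is at its validity edge
  there.
* Whole-cell behavior below the concentration floor, oscillatory
  single-cell dynamics, and spatially resolved entry microdomains are
  out of scope.
* The slow clearance observed experimentally under combined PMCA+CRAC
  block is *not* reproduced (the model has no leak or mitochondrial
  pathway); the model predicts no clearance at all, and the
  corresponding test asserts exactly that.
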