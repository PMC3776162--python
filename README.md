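# tcell-calcium

Whole-cell calcium dynamics of T lymphocytes, assembled bottom-up from
single transmembrane protein characteristics.

## The problem

Upon T-cell receptor (TCR) stimulation, free cytosolic calcium in a
T lymphocyte rises to a peak above 1 μM within 50–100 s and settles to a
sustained plateau around 0.7 μM.  How much of that signal is released
from the endoplasmic reticulum (ER) through IP3 receptors, and how much
enters from outside through calcium-release activated channels (CRAC),
is a long-standing question.  This package implements a quantitative
compartmental model that addresses it: each transmembrane transport
protein (CRAC, IP3R, PMCA, SERCA) is described at the single-molecule
level with independently measured parameters, and whole-cell behavior
emerges from surface densities and cell geometry.  It is aimed at
systems biologists and electrophysiologists who want a tested,
scriptable simulator of Jurkat T-cell calcium handling.

## The model

Seven state variables: free cytosolic calcium `C`, free ER calcium
`C_ER`, IP3 `P`, active CRAC density `ρ_CRAC`, IP3R gates `g, h`, and
the PMCA gate `g_PMCA`.  The calcium balances are

    dC/dt    = −[ ξ ρ_PMCA I_PMCA + ξ ρ_CRAC I_CRAC
                  + ξ_ERC ρ_SERCA I_SERCA + ξ_ERC ρ_IP3R I_IP3R ]
               / (z_Ca F (1 + B_C))
    dC_ER/dt = +ξ_ER (ρ_SERCA I_SERCA + ρ_IP3R I_IP3R)
               / (z_Ca F (1 + B_C,ER))

with surface-to-volume ratios ξ from the spherical cell geometry, rapid
buffering factors `B`, and single-protein currents: Ohmic CRAC and IP3R
currents with Nernst reversal potentials (empirically shifted), and
Hill-activated PMCA/SERCA pump currents.  IP3R gating follows the
Mak–McBride–Foskett model (calcium activation × IP3-dependent calcium
inhibition, giving the bell-shaped open probability); active CRAC
density is recruited by ER store depletion.  IP3 is produced in a TCR-
and calcium-dependent way, `dP/dt = β_P H(C, C_P, n_P) T(t) − γ_P P`.

Four parameters are not measurable and are fixed by requiring the
resting state to be an exact fixed point (steady-state closure):
the PMCA density (68.57/μm²), the ER IP3R density (11.35/μm²), the IP3
degradation rate (0.01149/s) and the minimal active CRAC density
(0.5115/μm²).  Six "variable" parameters (ER reversal shift ΔV_C,ER,
resting IP3 P₀, production rate β_P, and the densities ρ_SERCA,
ρ_CRAC,0, ρ_CRAC⁺) are estimated from a calcium time series by
differential evolution, minimising the quality index
`QI = (1/N) Σ (X_i − E_i)² / E_i²`.

## Worked example

```python
from tcell_calcium.model import CalciumModel

m = CalciumModel(protocol="fig3")      # sustained TCR stimulation
tr = m.simulate()
t, C = tr.times, tr["C"]
print(f"peak C = {C.max():.3f} uM at t = {t[C.argmax()]:.1f} s")
print(f"plateau (300-400 s) = {tr.window(300, 400)['C'].mean():.3f} uM")
```

prints

```
peak C = 1.239 uM at t = 76.5 s
plateau (300-400 s) = 0.718 uM
```

i.e. stimulation at t = 10 s drives a calcium peak of 1.24 μM about
66 s after onset, relaxing to a 0.72 μM plateau — the canonical Jurkat
response.  The trace also carries the per-protein current decomposition
(`I_*`, `J_*` columns) and the CRAC recruitment time course (about
sixfold here).  Fitting against a measured (here: synthetic) series:

```python
import tcell_calcium as tc

target = tc.generate_target(tc.TargetSpec(m.params, noise_sd=0.05, seed=7))
m2 = CalciumModel.from_dataframe(target, protocol="fig3")
res = m2.fit(variable=("P0", "dV_CER"), seed=1, popsize=8, maxiter=25)
print(res.summary())
```

```
T-lymphocyte calcium model — differential evolution fit
==========================================================
protocol:        fig3
target points:   22
quality index:   0.00165839
...
parameter             estimate         lower         upper
P0                  0.00876631         0.005          0.01
dV_CER                 62.8918            40            90
==========================================================
```

The recovered resting IP3 (8.77 nM vs the generating 8.7 nM) and ER
reversal shift (62.9 mV vs 63 mV) sit within the noise of the target,
and the QI ≈ 0.0017 matches the expectation sd² ≈ 0.0025 for 5%
multiplicative noise.  `res.sensitivity()` produces the +10%
one-at-a-time sensitivity table.

The same operations are available from the shell:

```sh
tcell-calcium simulate --preset fig3 --out trace.csv
tcell-calcium make-target --preset fig3 --sd 0.05 --seed 1 --out target.csv
tcell-calcium fit --target target.csv --seed 42 --out fit.json
tcell-calcium sensitivity --target target.csv --out sens.csv
```

Protocol presets `fig3`–`fig7` cover sustained stimulation, stimulation
at (surrogate) zero external calcium, SERCA block / store depletion,
calcium-pulse clearance with and without PMCA block, and PMCA block
during stimulation; arbitrary piecewise schedules can be built with
`tcell_calcium.protocols.build_protocol`.

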