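# Methods

## Model

The package couples two layers.

**Biophysical layer.**  Each of the `z` expression domains hosts an
independent heterodimer equilibrium A + B ⇌ AB with association
constant `K_eq`.  Given total concentrations `[A]t`, `[B]t`, the bound
concentration `x = [AB]` solves

    K_eq · x² − (K_eq·[A]t + K_eq·[B]t + 1) · x + K_eq·[A]t·[B]t = 0,

derived directly from the mass balance
`K_eq·([A]t − x)·([B]t − x) = x`.  Only the smaller root is physical
(`0 ≤ x ≤ min([A]t, [B]t)`); the larger root would imply negative free
concentrations.  The exposed-hydrophobic-patch load of the domain is
`[hp] = [A]free + [B]free`.  Concentrations are carried in mol/mL and
`K_eq` is treated as a plain number in that unit system; no unit
conversion is performed anywhere.

**Population layer.**  The chain over `{0 … z−1, S, Y}` starts fully
redundant (state 0).  Rates combine mutational opportunity with a
population-scaled fixation factor `G = g·N_e`:

    q(0→1)   = 2z · G · u_r          q(0→Y)   = 2 · G · u_c
    q(i→i+1) = (z−i) · G · u_r       q(i→S)   = (z−i) · G · u_r   (1 ≤ i ≤ z−2)
    q(i→Y)   = G · u_c               (1 ≤ i ≤ z−2)
    q(z−1→S) = G · u_r               q(z−1→Y) = G · (u_c + u_r)

with `u_c = u_h·l_c`, `u_r = u_b·l_r`, and `G ≡ 1` for the neutral
variant.  For the dosage-aware variant, `g` is the haploid fixation
probability evaluated at the fitness of the current state and of the
configuration the fixing mutation creates.

**State loads.**  Under WGD, state `i` has `i` domains at a 1:2
A-deficit against the partner (duplicated pair expressing once vs the
partner's doubled total) and `z−i` balanced domains; Y imbalances all
`z`.  The configuration entered into the lumped absorbing state S from
state `i` carries the load of `i+1` lost domains — the fixation step
concerns the single mutation being fixed, and from state `z−1` that is
the all-domains (Y) load.  This makes the rate into S from state `i`
numerically equal to the rate into state `i+1`, as the transition
structure requires.  Under SSD the pair is born imbalanced in every
domain (2:1 excess over the single-copy partner) and each loss repairs
one domain, so the same counting applies to the *balanced* domains;
the chain topology is unchanged and only the loads flip.  Whether SSD
should also alter the multiplicity of the Y route is not resolvable
from the repaired-balance narrative alone; we keep the WGD topology.

## Parameters

| Symbol | Meaning | Default | Units |
|---|---|---|---|
| `z` | regulatory domains | 4 | count (≥ 2) |
| `l_c`, `l_r` | coding / regulatory region length | 5e4, 775 | nt |
| `u_b`, `u_h` | regulatory / coding per-nt loss rate | 2.5e-8 | per generation |
| `w` | fitness penalty scalar | 1.0 | per (mol/mL) |
| `N_e` | effective population size | 1.4e5 | individuals |
| `K_eq` | dimer association constant | 1e10 | 1/(mol/mL) |
| per-copy expression | one copy, one domain | 1.25e-6 | mol/mL |
| partner total | `[B]t` per domain | 2.5e-6 (WGD), 1.25e-6 (SSD) | mol/mL |

Defaults give `u_c = 1.25e-3` and `u_r = 1.9375e-5` per generation.
`N_e` is accepted as a real number ≥ 2: the fixation formula is
continuous in it and sweeps stay smooth.  `z` is free although all
reference results use `z = 4`.  The sweep lists used for the
selection-efficacy analyses are exposed as `NE_SWEEP`
(1e2 … 1e7) and `KEQ_SWEEP` (1e4, 1e6, 1e9, 1e12).

## Numerical choices

- **Quadratic root.**  Computed as `2·K·[A]t·[B]t / (b + √disc)` with
  `b = K·[A]t + K·[B]t + 1` (conjugate form).  The textbook
  `(b − √disc)/2K` form loses all significant digits when
  `K·totals ≫ 1` (the defaults give `K·[A]t ≈ 2.5e4`).  Discriminants
  that round slightly negative are clamped to zero; a discriminant
  materially below zero (impossible for valid inputs) raises.
- **Fixation probability.**  Evaluated as
  `expm1(ln r) / expm1(N_e·ln r)` with `r = f_i/f_j`, so nearly
  neutral transitions (`|s| ~ 1e-6`) lose no precision.  When
  `N_e·ln r > 700` the denominator would overflow; the tail form
  `(r−1)·exp(−N_e·ln r)` underflows smoothly to zero instead.
  Transitions with `|ln r| < 1e-14` are treated as exactly neutral and
  return `1/N_e`, so `g·N_e == 1.0` holds bitwise for the neutral
  reduction; at the model's parameter scales the smallest selected
  `|ln r|` is ~1e-9, far above the cutoff.
- **Propagation.**  `scipy.linalg.expm` on the (z+2)×(z+2) generator,
  once per requested time; at these sizes repeated `expm` is as cheap
  as an eigendecomposition and avoids conditioning questions.  Output
  is clipped at zero and renormalized (drift is ≤ 1e-13).
- **Absorption.**  Fundamental-matrix solve `B = (−T)⁻¹R` on the
  transient block — exact for positive rates and immune to the
  stiffness of exponentiating to ~4e6 generations; `expm` at t = 4e6
  is kept as a cross-check and agrees to better than 1e-6.
- **Crossing times.**  The neutral and dosage-aware S-trajectories are
  compared on a uniform grid (500 points) and a detected sign change
  is refined by bisection; either crossing direction is detected, so
  the same routine serves WGD and SSD.
- **Gillespie simulator.**  One user seed keys a counter-based Philox
  stream per replicate (`key = (seed, replicate)`), so replicate `i`
  is reproducible regardless of execution order or replicate count.
  Replicates draw exponential waiting times from the current exit rate
  and jump proportionally to off-diagonal rates; absorbing starts are
  valid and simply stay put.

## State labelling

Model states are 0-based: state `i` = `i` regulatory domains lost on
one copy, with S at index `z` and Y at index `z+1`.  Display-oriented
presentations sometimes label these "State 1 … State 4" for the
transients; the package uses the model numbering everywhere (CLI
columns `state_0 … state_{z−1}, S, Y`).

## Design choices on genuinely open points

- The dosage-aware Table-style comparison at N_e = 1.4e5 yields 47.0%
  fully redundant at 400 generations and a terminal subfunctionalized
  fraction of 0.39%.  Published comparisons of this kind depend
  sensitively on the generating `N_e`, which is not uniquely pinned
  down for the tabulated dosage column; the package therefore treats
  that comparison as an ordering claim (more redundancy retained, less
  early pseudogenization, higher terminal S, lower terminal Y than
  neutral) and exposes every knob so users can search calibrations.
- Sweep diagnostics evaluate the "delay" at t = 200 generations: early
  enough that the ordering of S-occupancy is uniformly reversed across
  both the `N_e` and `K_eq` sweeps (at later times, e.g. t ≥ 400, the
  weakest-selection `K_eq` curves have already crossed each other and
  the early ordering is no longer monotone).
- Presets (`fig2`, `fig3a`, `fig3b`, `fig4`, `fig6a`, `table4`) bundle
  the per-analysis parameter rows; for the two sweep analyses the
  preset fixes the shared values and the swept parameter is taken from
  `NE_SWEEP`/`KEQ_SWEEP` by the caller.

## What the tests do and do not show

The stochastic simulator is the only data-like generator in the
package: it emulates the chain itself, not biological data, so
agreement (3-standard-error bands and a χ² goodness-of-fit at
α = 0.001 on 1e5 replicates) validates the analytic propagation, not
the model's realism.  Properties verified analytically: generator rows
sum to zero with absorbing S/Y rows; distributions stay on the
simplex; `w = 0` reduces the dosage-aware generator bitwise to the
neutral one; neutral results are invariant to `N_e`; the equilibrium
closed form matches a bisection oracle to 1e-9 relative; the fixation
evaluation matches a 50-digit arithmetic oracle to 1e-10 relative.

## Limitations

Haploid genetics only (no recombination, no dominance); expression
levels fixed over time; heterodimers only (no trimers or higher-order
complexes, no kinetics); no neofunctionalization route; selection
enters solely through the summed hydrophobic-patch proxy, with `w`
confounded with `N_e` in setting selection strength.  Plotting is
deliberately out of scope; tables are the output surface.
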