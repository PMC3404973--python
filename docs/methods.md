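# Methods

## The gating model

hERG (Kv11.1) gating is represented as a continuous-time Markov chain over
five conformational states arranged in a line,

    C1 <-> C2 <-> C3 <-> O <-> I

(three closed states, one open, one inactivated; transitions only between
neighbours).  Each transition rate follows a single-exponential voltage
dependence

    k_ij(V) = a * exp(b * (V + v0)),    [1/ms], V in mV,

and a *condition* is one set of eight such laws (k12, k21, k23, k32, k34,
k43, k45, k54).  Two sets ship with the package as JSON at full printed
precision: `PSS` (control physiological saline) and `C16CAR` (3 µM
palmitoyl-carnitine).  Only k45/k54 carry voltage offsets (PSS: V+18 mV,
C16CAR: V+4.5 mV); k23 and k32 are voltage-independent.

The chain's occupancies `p` obey the master equation `dp/dt = Q(V) p`,
where `Q` is tridiagonal with columns summing to zero.  Because the chain
is a birth–death process it satisfies detailed balance, so the stationary
distribution has the closed form `p_{i+1}/p_i = k_{i,i+1}/k_{i+1,i}`,
evaluated in log space so it stays finite at extreme voltages.

**The control k32.**  The control set specifies k32 = 1.5686841e7 / ms —
seven orders of magnitude above every other rate (the treated set's k32 is
0.01686841, suggestive of a lost decimal point).  The value is implemented
exactly as specified, never silently corrected: users can override any rate
law through `RateConstantSet.replace`.  Its consequences are embraced
rather than hidden: C3 drains to C2 essentially instantaneously, the open
state barely populates under control conditions (open probability ~1e-8 at
0 mV), simulated control currents are ~1e-7 pA/pF, and the generator is
extremely stiff.  All fitted quantities on control traces remain well
defined because the analyses are amplitude-scale invariant.

## Numerics of occupancy integration

Two backends integrate the master equation under piecewise-constant
voltage commands, and they are checked against each other and against an
independent oracle:

* **`bdf`** (default): scipy's adaptive implicit BDF at rtol 1e-8,
  atol 1e-10, with the analytic (constant) Jacobian per segment.  The huge
  control k32 makes the Newton matrices nearly singular, so the solver's
  *interior interpolants* lose probability mass at the ~1e-7 level even
  though segment endpoints are accurate to ~1e-15.  Output occupancies are
  therefore projected back onto the probability simplex (renormalized);
  the pre-projection drift is retained as a solver-health guard (error if
  above 1e-5).
* **`expm`**: analytic within-segment propagation.  One step matrix
  `expm(Q dt)` is computed at the output-sampling interval and applied
  repeatedly with renormalization.  This deliberately avoids a single
  matrix exponential over a whole segment: at `||Q dt|| ~ 1e10` the Padé
  scaling-and-squaring loses ~1e-6 of accuracy, while stepping keeps the
  norm moderate and powering a column-stochastic propagator is stable.
  Against a 50-digit multiprecision ground truth the stepped form is
  accurate to ~1e-9 on the stiff control set and ~1e-12 on the treated
  set.

A symmetrized-eigendecomposition propagator (using detailed balance to
make `Q` similar to a symmetric tridiagonal matrix) was evaluated and
rejected: the graded spectrum (gap ratio ~1e11) rotates the computed slow
eigenvectors by ~3e-5, worse than either retained backend.

Tests compare both backends against chained `scipy.linalg.expm` with
norm-bounded substeps — an independent code path from the BDF route.
Steady states are checked against the *exact rational* null space of the
generator (sympy), because floating-point SVD null spaces themselves only
reach ~1e-7 on the stiff control generator.

## Voltage-clamp protocols and measurements

Protocols are data: ordered `(duration, voltage)` segments, sampled at
0.2 ms (5 kHz) by default.  Three built-in families reproduce the standard
hERG characterization from a −70 mV holding potential:

* **IV/activation**: 5 s steps, −80..+50 mV in 10 mV increments, tail at
  −55 mV;
* **single step**: repeated 5 s pulses to −10 mV every 18 s, tail at
  −55 mV (the deactivation-analysis protocol);
* **availability**: 1 s conditioning at +40 mV, 25 ms interpulse at
  −120..+10 mV, test pulse at +40 mV.

Every sweep starts from the state carried through an 18 s inter-sweep
interval at the holding potential (simulated, not assumed instantaneous);
the first sweep starts from the holding-potential steady state.  The 18 s
interval is applied to all families although the source protocol states it
only for the single-step series — a deliberate uniformity choice.

Open-channel current is ohmic, `I = g_Kr * f_Ko * p_O * (V − E_K)`, with
clamp defaults g_Kr = 0.153 nS/pF, E_K = −88.8 mV (Nernst potential for
4 mM external / 130 mM internal K+ at 23 °C) and f_Ko = sqrt(4/5.4).
These are conventions, not measured quantities: the source never states
the current equation or conductance, so all three are configurable and
none is asserted in tests.

Measurements: *end-pulse current* is the mean over the final 50 ms of a
segment (window configurable); *tail peak* is the largest-magnitude sample
of the tail segment, excluding the first sample after the step (which
carries the instantaneous-jump artifact).  Both are invariant to time
offsets.

A note on the simulated availability curve: under the treated parameter
set, deactivation is fast enough that channels begin to *close* during the
25 ms interpulse at −120/−110 mV, so the normalized curve peaks at −80 mV
instead of plateauing — a real property of fast-deactivating channels
under this protocol.  The monotone-decrease property is therefore asserted
from −120 mV for control but from −80 mV for the treated set.

## Curve fitting

**Deactivation** is fitted with the standard offset-plus-two-exponential
form `I(t) = A0 + A1 exp(−t/τ1) + A2 exp(−t/τ2)`, time measured from the
window start, with τ1 ≥ τ2 (slow component first, matching the convention
that the slow cohort constant is reported first).  Amplitudes are solved
by linear projection at fixed time constants (variable projection), so the
nonlinear search is two-dimensional in (log τ1, log τ2); it is initialized
from a 3×3 log-spaced grid and refined by damped least squares (lmfit).
Amplitudes are not constrained positive — hooked (rising-then-falling)
tails need a negative fast amplitude.  Fits never raise on bad data:
non-convergence and degeneracy (τ ratio < 1.05 or a vanishing component,
i.e. effectively mono-exponential input) are flagged on the result.  The
default tail fit window starts two samples (0.4 ms at 5 kHz) after the
step to −55 mV.

**Activation/availability** curves are fitted with a Boltzmann sigmoid,
`I/Imax = Imax_scale / (1 + exp((V½ − V)/s))` for activation and the
mirrored sign for availability, so the slope factor s is positive in both
directions.  V½ is initialized at the half-crossing of the data and s at
6 mV.  Data lying on a single plateau leave the midpoint unconstrained and
are flagged as non-converged.

**Rate estimation** minimizes the summed squared residual between
observed and simulated sweep families with Nelder–Mead simplex search.
Free parameters are named `(transition, field)` pairs; prefactors are
searched in log space to enforce positivity, voltage coefficients and
offsets linearly.  The search is deterministic given the initial set, and
hitting the iteration cap returns the best-so-far parameters with a flag.

## The ventricular cell model

The cell is the Ten Tusscher–Panfilov 2006 human ventricular model in its
*endocardial* parameterization (G_Ks = 0.392, G_to = 0.073 nS/pF), with
the Hodgkin–Huxley xr1·xr2 gating of I_Kr replaced by the Markov chain:
`I_Kr = g_Kr sqrt(K_o/5.4) p_O (V − E_K)` with the TTP06 endocardial
g_Kr = 0.153 nS/pF and K_o = 5.4 mM (so the scaling factor is 1).  All
other currents, gates and the calcium subsystem follow the published
equation set; the L-type driving term uses its analytic limit within
1e-7 of V = 15 mV to avoid the 0/0.

Pacing applies −52 pA/pF for 1 ms (a conventional choice; the source
states none) at a 1000 ms cycle length, 50 beats before measurement, from
the published TTP06 initial state with the Markov block equilibrated at
the initial potential.  Integration is BDF at rtol 1e-6, atol 1e-8, in
two sub-intervals per beat (stimulus on/off) with the Markov occupancies
renormalized at beat boundaries.  Fifty beats suffice for a settled limit
cycle here (beat-49 vs beat-50 APD90 differs by ~0.04 ms); full TTP06
concentration equilibration takes far longer but does not move APD at
this resolution.

APD is measured from the maximum-upstroke instant to the crossing of
`V_rest + (1 − fraction) · amplitude` on the repolarizing limb, linearly
interpolated.

**Stimulus sensitivity.**  Because the 1 ms pulse outlasts the sodium
upstroke, stimulus charge beyond threshold rides directly onto the AP
peak: doubling the amplitude at fixed duration raises the peak by ~35 mV,
recruits extra transient-outward current and shortens APD90 by ~15 ms.
The meaningful invariance — tested — is charge-matched: doubling the
amplitude while halving the duration changes APD90 by < 1 ms.

**Predicted effect.**  With the treated (acylcarnitine) rate set the
chain carries a sizeable I_Kr (open probability ~0.04 at plateau
voltages) while the control set carries almost none (the k32 consequence
above), so the paced APD90 falls from ~354 ms (control) to ~220 ms
(treated): the accelerated-deactivation parameter set produces a
pronounced action-potential shortening.  Only the *direction* of this
difference is asserted; absolute APDs depend on unstated conductance and
pacing choices.

## Synthetic data

The generator produces exactly the structures the fitters assume:

* biexponential tails, `A0 + A1 e^(−t/τ1) + A2 e^(−t/τ2)` plus additive
  i.i.d. Gaussian noise (default SD 2 % of the initial amplitude —
  parameterized, since no noise model is specified anywhere), 5 kHz, 8 s;
* normalized Boltzmann datasets with Gaussian noise on the normalized
  current axis;
* cohorts of n cells whose per-cell parameters are drawn from normal
  population distributions truncated to positive support (by redraw) for
  time constants and slopes, each fitted individually and summarized as
  mean ± SEM, with per-cell capacitances drawn uniformly from 10–20 pF.

All randomness flows through a seeded numpy PCG64 generator, so outputs
are bit-reproducible across platforms.  The generator does *not* emulate
rundown, leak, capacitive transients, series-resistance error or
filtering; passing round-trip tests therefore demonstrate estimator
correctness under the assumed noise model, not robustness to real
recording artifacts.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5 kHz / 8 s
synthetic tails (40 001 samples), 14-point voltage grids, 50-replicate
noise studies, 20 randomized protocols per parameter set for the solver
oracles, three-sweep 1 kHz families for simplex recovery, and 50 paced
beats per condition.

## Known limitations

* Rates are for room-temperature recordings; no temperature scaling to
  37 °C physiology is applied when the chain is embedded in the cell
  model.
* The control parameter set, taken exactly as printed, produces
  near-zero absolute current; its simulated activation midpoint does not
  match the measured control activation curve.  Comparisons against the
  control set are therefore directional.
* Single-cell only: no tissue coupling, restitution or reentry; epi- and
  mid-myocardial TTP06 variants are out of scope.
* Deterministic mean-field occupancies only; no stochastic single-channel
  simulation.
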