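# Methods

## The voltage-clamp model

`vclamp` simulates a whole-cell patch-clamp voltage-clamp experiment as a
coupled ODE system linking the cell to the amplifier. States: the membrane
voltage `Vm`, pipette voltage `Vp`, clamp voltage `Vclamp`, the amplifier's
estimated membrane voltage `Vest` (used by supercharging and whole-cell
capacitance compensation), the recorded current `Iout`, and the ionic-model
states. With `Cm`, `Cp` the true membrane and pipette capacitances, `Rs`
the series (access) resistance, machine estimates starred, and `Voff` the
residual lumped voltage offset:

    dVm/dt     = (Vp + Voff − Vm)/(Rs·Cm) − (Iion + Ileak)/Cm
    dVp/dt     = (Vclamp − Vp)/τclamp
    dVest/dt   = (Vcmd − Vest) / ((1 − αP)·Rs*·Cm*)
    Vcmd′      = Vcmd + Rs*·(αR·Iout + αP·Cm*·dVest/dt)
    dVclamp/dt = (Vcmd′ − Vclamp)/τsum
    Iin        = Iion + Ileak + Cp·dVp/dt − Cp*·dVclamp/dt
                 + Cm·dVm/dt − Cm*·dVest/dt
    dIout/dt   = (Iin − Iout)/τz
    Ipost      = Iout − gleak*·(Vcmd − Eleak*)

`αR` is the series-resistance compensation level and `αP` the
supercharging/prediction level, both machine settings in [0, 1). `Ileak =
gleak·(Vm − Eleak)` is the seal leak; leak subtraction (`Ipost`) is pure
post-processing with the machine estimates. `Vcmd′` is algebraic; the
`dVest/dt` it contains is substituted from its own ODE, never
differentiated numerically.

Setting `αP = 0` removes the supercharging overshoot but *not* the `Vest`
state: the capacitance-compensation subtraction `Cm*·dVest/dt` carries no
`αP` factor, and with `αP = 0` the system is exactly the earlier
no-supercharging formulation in which `Vest` relaxes with `Rs*·Cm*`. The
test suite asserts this reduction against an independent implementation.

### Units

mV, ms, MΩ, pF, nA, μS throughout the API. Internally capacitances are
converted to nF so the system is unit-consistent without scale factors
(MΩ·nF = ms, nF·mV/ms = nA, μS·mV = nA); this also keeps state magnitudes
O(1)–O(100), avoiding scale-induced stiffness pathologies.

### Amplifier time constants

`τclamp = 0.8 μs`, `τsum = 2 μs`, `τz = 7.5 μs` by default, all
configurable. The first two are order-1 μs electronics response times; a
slow `τsum` would slew-limit the command path and clip fast sodium peaks
by several percent even under otherwise perfect compensation, an
instrument artefact we deliberately keep small. `τz` is the transconductor
filter (set by the amplifier's sampling/filter configuration) and is the
model's single first-order stand-in for the recording filter chain —
multi-pole Bessel filtering is out of scope.

## Ionic models

**Electrical model cell.** `Iion = Ik + Vm/Rm` with
`dIk/dt = (Ck·dVm/dt − Ik)/(Rk·Ck)`. Defaults `Rk = 100 MΩ`, `Ck = 10 pF`,
`Rm = 10 MΩ` fix the dynamic time constant `Rk·Ck = 1 ms` and give O(10) nA
responses to a 130 mV step — current magnitudes comparable to fast sodium
recordings, which is what makes the model cell a stress test for the
amplifier model. Because the branch is driven by `dVm/dt`, the coupled RHS
evaluates `dVm/dt` first and passes it through; under ideal clamp an
instantaneous step ΔV deposits `ΔV/Rk` into `Ik` as a jump condition.
The whole coupled system is then linear time-invariant within each
protocol segment, and the test suite holds simulated traces to a
matrix-exponential closed form at 1e-6 relative error.

**Generic fast sodium current.** Hodgkin–Huxley `I = g_max·m³·h·j·(Vm −
E_Na)` with sigmoidal steady states and bell-shaped time constants. The
defaults are chosen for a cardiac-type NaV1.5 at physiological
temperature: activation midpoint −34 mV with 6 mV slope (steep enough —
e-fold per ~2 mV on m³ — to reproduce the loss-of-clamp positive-feedback
delay near threshold), `E_Na = +70 mV`, activation τ 0.1–0.25 ms,
fast/slow inactivation τ ≈ 0.5/2.5 ms depolarised. Under ideal clamp the
I-V family peaks at −10 mV with times-to-peak 0.26–0.55 ms. `g_max`
defaults to 0.6 μS (600 nS), a typical heterologous NaV1.5 whole-cell
conductance and the reference value of the fitting transform. This current
is a configurable stand-in, not a reimplementation of any published
cardiac model; third-party models plug in through the `IonicModel`
interface.

**Density calibration.** `density_to_conductance(D, Cm)` returns the
conductance whose maximal ideal-clamp |peak| over the standard I-V family
equals `D` A/F at membrane capacitance `Cm` (1 A/F·pF = 1 pA). It is exact
and linear in both arguments because the ideal-clamp gate relaxation has a
closed form.

## Numerical integration

The μs amplifier constants sit four orders of magnitude below the gating
time scales, so the system is stiff. Segments are integrated with scipy's
BDF at `rtol 1e-8 / atol 1e-10` by default; command steps are honoured
exactly by re-initialising the integrator per segment (no smoothing).
Integration runs in segment-local time — the system is autonomous within a
segment, and solver minimum-step limits scale with |t|, which would
otherwise reject the fast post-step transient after multi-second holds.
The RHS for the built-in models is numba-compiled; user models fall back
to a pure-Python RHS with identical semantics.

Initial conditions come from `steady_state_init`, which reduces the
equilibrium to a scalar root-find in `Vm` (all filters settled, `Iout =
Iion + Ileak`) and verifies the result by evaluating the full RHS.
Convergence is judged on the time-constant-scaled residual (equilibrium
displacement per state, in mV/nA), which remains meaningful at very small
`Rs` where raw `dVm/dt` is ill-conditioned in double precision; both norms
are reported.

Output is sampled at `dt_out` (default 0.01 ms, fine enough to resolve
τz-filtered transients) with long holding segments decimated to at most
`max_points_per_segment` samples; this affects only the stored trace, not
the integration. The population studies use `rtol 1e-6 / atol 1e-9` and
`dt_out 0.02 ms`: peak currents are converged far below the 10 mV voltage
grid and SEM granularity there, at a several-fold runtime saving.

## I-V extraction

The peak is the signed extremum of `Ipost` inside the test step after a
0.2 ms blanking interval (the residual capacitive spike survives
compensation because `Vm` and `Vest` follow different dynamics; it decays
within ~0.1 ms under study conditions). Ties resolve to the earliest
sample. The discrete peak is refined by a three-point parabolic fit, which
removes most of the `dt_out` dependence of both the peak value and
time-to-peak. Aggregation uses the pointwise mean with SEM = sd(ddof=1)/√n.

## The averaging-bias study

Virtual cells are drawn by Latin hypercube over conductance scale
(log-uniform in [0.2, 5]), `Rs` uniform in [4, 15] MΩ and `Cm` uniform in
[8, 22] pF, with perfect machine estimates (`Rs* = Rs`, `Cm* = Cm`),
αR = αP = 80%, and the I-V protocol: hold −100 mV (2000 ms), 20 ms steps
−90…50 mV in 10 mV increments. Conductance is density-scaled — each cell's
`g_max` is `scale × density_to_conductance(1500 A/F, Cm)` — reflecting the
density formulation of cardiac sodium models; 1500 A/F is the same
canonical wild-type density as in the mutant study, and corresponds to the
600 nS fitting reference at the nominal 15 pF cell. The artefact-free
reference is the ideal-clamp curve at scale 1 and nominal `Cm = 15 pF`.
Everything not sampled (Cp, gleak, Voff) is ideal (zero): the study
isolates the `Rs`/`Cm`/conductance artefact interaction.

Bias summary: `underestimation % = 100·(1 − |mean-curve peak| / |ideal
peak|)` and `left shift = V(ideal peak) − V(mean peak)`.

## The mutant/drug study

Two arms share the experimental-condition distributions — `Rs ~
LogNormal(mean 2.5, sd 1.5) MΩ`, `Cm ~ LogNormal(mean 40, sd 10) pF`
(log-normal parameters solved from these moments), `Voff ~ N(0, sd 2.5)
mV` — and machine estimates carry 5% multiplicative `N(1, 0.05)` error.
The only true difference between arms is peak current density: 1500 A/F
(control) vs 500 A/F (mutant/drug), a pure one-third conductance
reduction; per-cell conductance is density-calibrated with the sampled
`Cm`. Cells failing the `Rs < 4 MΩ` quality control are resampled so each
arm keeps exactly n = 15 accepted cells (fixed-n resampling rather than
shrinking-n rejection). The reported outcome is the difference in peak
voltage between the two arms' mean observed I-V curves at 80%
compensation; the ideal-clamp references peak at the same voltage by
construction. Because the voltage grid is 10 mV, the apparent shift is
quantised; across master seeds its modal value is the study's headline
number.

## Fitting

Free parameters: maximum conductance, `Rs`, `Cm`, `Voff`, `gleak`. The
four positive ones are searched as `p = p0·e^s` with references 600 nS
(conductance) and the machine estimates (`Rs*`, `Cm*`, `gleak*`); `Voff`
is searched untransformed in [−20, 20] mV. Loss: unweighted sum of squared
residuals of `Ipost` over all sweeps and time points (simulation
interpolated onto the data's time stamps); simulation failures (e.g.
unstable compensation feedback at an extreme candidate) return a large
finite penalty so the search continues.

The search is multi-restart CMA-ES — a compact standard (μ/μw, λ)
implementation lives in `vclamp._cmaes`, with box bounds enforced by
reflection and nested restart seed sequences (growing `restarts` only
appends starts) — followed by a finite-difference Gauss–Newton polish
(`scipy.optimize.least_squares`) of the best candidate in the same
transformed space. CMA-ES provides global robustness from random starts;
the polish supplies the final digits at a tiny fraction of the evaluations
a pure evolution strategy would need on this smooth, noiseless objective.
On synthetic 80%-compensated data with 5% mis-set machine estimates, all
five parameters are recovered to well under 1%.

## What the synthetic data does and does not show

All studies run on synthetic cells and the generic sodium current, so
passing tests demonstrate properties of the *instrument model and analysis
pipeline* — linearity against the closed form, the ideal-clamp limit,
compensation effect directions, bias magnitudes under stated population
distributions, and parameter identifiability without model discrepancy
(the fit sees data generated by its own equations). They do not
demonstrate kinetic fidelity of the generic current to any particular
channel, robustness of fits under ionic-model misspecification (known to
be the dominant failure mode for this class of method), nonlinear seal
leak, or multi-pole recording filters.

## Problem sizes and other fixed choices

- Averaging study at n = 5, 25, 75; mutant study at n = 15 per arm over
  10 master seeds — the sizes the studies are defined at.
- Fitting demonstrations use 3 sweeps (−30, −10, +10 mV; 5 ms hold +
  10 ms step at 0.05 ms sampling) and 2 restarts × 25 CMA-ES generations
  before polishing: the problem is smooth enough that more restarts only
  re-find the same optimum (best-of-restarts is monotone by construction).
- Peak-window blanking 0.2 ms; tie-break earliest; parabolic refinement
  skipped at window edges and on flat traces.
- Degenerate inputs: protocols must be non-empty with positive durations;
  `αP` is capped at 0.999 (the supercharging time constant vanishes as
  `αP → 1`); `gleak` fitting requires a positive `gleak*` reference.
- Unstable configurations are reported, not masked: e.g. uncompensated
  `Cp` with high `αR` genuinely destabilises the feedback loop (positive
  feedback of the pipette charging current through the compensation
  path) and raises `IntegrationError` naming the segment.

## Known limitations

- First-order filters only; no 4-pole Bessel stage, no current clamp, no
  nonlinear leak.
- The generic INa is phenomenological; time-to-peak delay patterns near
  threshold are model-sensitive, so the package asserts them ordinally
  (near-threshold delay exceeds suprathreshold delay), not quantitatively.
- `Vout = Iout·Rf` is not modelled: `Rf` enters only through `τz`.
- Command steps are instantaneous; amplifier slew is represented by
  `τsum`/`τclamp` only.
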