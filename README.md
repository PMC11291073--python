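# vclamp

Modelling and correcting whole-cell patch-clamp **voltage-clamp
artefacts** — for electrophysiologists and modellers who need to know what
their amplifier actually did to the current they recorded.

Whole-cell voltage clamp assumes the membrane voltage follows the command.
In reality the series (access) resistance `Rs`, the membrane and pipette
capacitances `Cm`/`Cp`, seal leak and residual voltage offsets make the
clamp imperfect, and amplifier compensation (series-resistance
compensation `αR`, supercharging/prediction `αP`, capacitance
compensation, leak subtraction) only partially corrects for them — with
machine *estimates* `Rs*`, `Cm*`, … standing in for the true values. For
large, fast currents such as cardiac sodium, the residual artefacts shift
and attenuate I-V curves enough to mimic genuine biology.

`vclamp` implements the amplifier + cell system as a stiff ODE model:

    dVm/dt     = (Vp + Voff − Vm)/(Rs·Cm) − (Iion + Ileak)/Cm
    dVp/dt     = (Vclamp − Vp)/τclamp
    dVest/dt   = (Vcmd − Vest)/((1 − αP)·Rs*·Cm*)
    Vcmd′      = Vcmd + Rs*·(αR·Iout + αP·Cm*·dVest/dt)
    dVclamp/dt = (Vcmd′ − Vclamp)/τsum
    Iin        = Iion + Ileak + Cp·dVp/dt − Cp*·dVclamp/dt + Cm·dVm/dt − Cm*·dVest/dt
    dIout/dt   = (Iin − Iout)/τz
    Ipost      = Iout − gleak*·(Vcmd − Eleak*)

with pluggable ionic models `Iion = f(t, Vm, states)`: an electrical
**model cell** (a linear RC network whose coupled dynamics admit an exact
matrix-exponential solution — the validation target) and a generic
Hodgkin–Huxley **fast sodium current** `g·m³·h·j·(Vm − E_Na)`.

On top of the simulator:

- **I-V extraction and compensation sweeps** (`vclamp.experiments`),
- the **averaging-bias study**: averaging 80%-compensated I-V curves from
  a virtual cell population underestimates the peak current and
  left-shifts the peak voltage relative to the artefact-free curve,
- the **mutant/drug study**: a pure one-third conductance reduction
  acquires a spurious ~10 mV apparent I-V shift under realistic
  experimental variability and quality control,
- **fitting** of conductance + artefact parameters (`Rs`, `Cm`, `Voff`,
  `gleak`) to recorded sweeps by multi-restart CMA-ES with log-transformed
  parameters `p = p0·e^s` and a Gauss–Newton polish.

See `docs/methods.md` for model details, parameter choices and
limitations.

## Worked example

Simulate the averaging-bias study at n = 5 from the command line:

```sh
vclamp study-averaging --n 5 --seed 1 --out out/avg5
```

```json
{
 "n": 5,
 "peak_shift_mV": 20.0,
 "seed": 1,
 "underestimation_pct": 11.914171859344801
}
```

Five virtual cells (conductance scale, `Rs`, `Cm` Latin-hypercube
sampled) were each clamped at αR = αP = 80% over 20 ms steps −90…50 mV
from a −100 mV hold. Averaging their I-V curves gives a peak current
**11.9% smaller** than the artefact-free curve's, peaking at −30 mV
instead of −10 mV — a **20 mV left shift** that no amount of averaging
removes, because it is a systematic bias, not noise.

The same machinery from Python:

```python
from vclamp import (AmplifierSettings, CellProperties, GenericINa,
                    Protocol, simulate, simulate_ideal)

settings = AmplifierSettings(alpha_R=0.8, alpha_P=0.8,
                             Rs_est=10.0, Cm_est=15.0)
cell = CellProperties(Rs=10.0, Cm=15.0)
prot = Protocol(((-100.0, 20.0), (-30.0, 20.0)))   # hold, test step (mV, ms)

observed = simulate(settings, cell, GenericINa(), prot, dt_out=0.01)
ideal = simulate_ideal(GenericINa(), prot, dt_out=0.01)
step = observed.t >= 20.2
print(f"observed peak {observed.Ipost[step].min():.2f} nA, "
      f"ideal peak {ideal.Ipost[step].min():.2f} nA")
print(f"max Vm during step: {observed.Vm[step].max():.1f} mV (command -30 mV)")
```

```
observed peak -14.11 nA, ideal peak -5.81 nA
max Vm during step: -0.7 mV (command -30 mV)
```

Even at 80/80% compensation the recorded peak at a −30 mV command is
nearly 2.5× the true −30 mV response: the inward current's voltage drop
across the uncompensated 20% of `Rs` depolarised the cell all the way to
−0.7 mV, so the recorded current belongs to a different voltage than the
protocol claims. This loss of clamp is what left-shifts and distorts
whole I-V families.

Other subcommands: `simulate`, `iv`, `sweep` (compensation grids),
`study-mutant`, `fit`, `fixtures` — see `vclamp --help`.

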