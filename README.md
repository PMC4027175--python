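# iffl — incoherent feed-forward loop dynamics for in vitro transcriptional circuits

`iffl` models a synthetic transcriptional "adapter" circuit built from two
genelet switches: a DNA activator strand A (the input, *u* = [A<sup>tot</sup>])
switches on both a template transcribing the fluorescent malachite-green RNA
aptamer rMG (the output, *y*) and a template transcribing an RNA inhibitor
iMG (the repressor, *x*) that sequesters rMG into a dark complex
(*z* = [rMG·iMG]). RNase R supplies tunable degradation. The package is for
researchers building or analyzing molecular circuits who need simulation,
phase-space analysis, and kinetic parameter estimation for this motif in one
tested toolchain.

## The model

With effective production coefficients α₁, α₂ (set by the transcription rate
constants, RNAP, and the template fractions) and degradation constants β₁
(free iMG) and γ₁ (rMG inside the complex, which recycles the iMG strand),
mass action gives

```
ẋ = α₁u − β₁x − kxy + γ₁z
ẏ = α₂u − kxy
ż = kxy − γ₁z
```

For constant *u* > 0 the unique equilibrium is x̄ = α₁u/β₁,
ȳ = α₂β₁/(α₁k), z̄ = α₂u/γ₁ — the output steady state is independent of the
input (**exact adaptation**), so every input step produces a transient pulse
that returns to the same level. Rescaling each variable by its steady state
and time by β₁ leaves three dimensionless groups, p₁ = α₂/α₁,
p₂ = kα₁u₀/β₁², p₃ = γ₁/β₁, and in the limit p₁ → 0, p₂ → ∞ the dynamics
collapse to Ẋ = F − X, y = F/X, which responds only to input **folds**
(fold-change detection). Variants with Michaelis–Menten enzyme saturation,
transcriptional burst phase k<sub>p2</sub>(1 + B·e^(−t/τ_b)), and explicit
template–activator binding (the five-species model) are included, along with
a synthetic spectrofluorometer data generator (linear calibration, bleaching
background, Gaussian noise) and the full estimation workflow from raw
fluorescence to refined rate constants.

## Worked example

```python
from iffl import *

dr = derived_rates(FCD_CONFIG, REPRESENTATIVE_RATES)
eq = equilibrium_simple(dr, REPRESENTATIVE_RATES.k, u=20.0)
print(f"steady state at u=20 nM: x={eq.x_bar:.3f}, y={eq.y_bar:.3f}, z={eq.z_bar:.3f} nM")

nd = nondimensionalize(dr, REPRESENTATIVE_RATES.k, u0=10.0)
print(f"dimensionless operating point: p1={nd.p1:.2f}, p2={nd.p2:.2f}, p3={nd.p3:.2f}")

m = pulse_metrics(pulse_trace((nd.p1, nd.p2, nd.p3), fold=2.0))
print(f"pulse on input doubling: amplitude A={m.A:.3f}, adaptation time T={m.T:.2f}")

table, _ = run_fold_change((nd.p1, nd.p2, nd.p3), tolerance=0.3)
print(table[["pulse", "amplitude", "ratio_to_first", "settled_before_next"]]
      .round(3).to_string(index=False))
```

prints

```
steady state at u=20 nM: x=10.000, y=1.022, z=3.115 nM
dimensionless operating point: p1=0.19, p2=0.93, p3=0.61
pulse on input doubling: amplitude A=0.314, adaptation time T=7.09
 pulse  amplitude  ratio_to_first  settled_before_next
     1      0.314           1.000                 True
     2      0.427           1.360                 True
     3      0.548           1.744                 True
     4      0.664           2.113                 True
```

The steady output (1.02 nM of free rMG) does not depend on the input level;
doubling the input produces a pulse of amplitude 0.31 (relative to the
steady level) that re-enters the ±1% band after 7.1 scaled time units. Over
a staircase of four successive input doublings the pulse amplitudes grow
toward the fold-change-detection limit (amplitude → 1): adaptation is exact,
fold-change detection at this operating point is approximate and converging.

Fitting is exposed statsmodels-style: build an `AdapterCircuitModel` from
observed traces (each tagged with its reaction composition and input
schedule) and an initial rate set from the elementary-reaction fits, call
`.fit()`, and read estimates, standard errors and diagnostics off the
results object (`results.summary()`).

A thin CLI wraps the library: `iffl simulate`, `iffl phase-space`,
`iffl fit`, and `iffl run --protocol fold_change|multi_input|...`.

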