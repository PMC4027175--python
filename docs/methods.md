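# Methods

## Circuit model and assumptions

The adapter circuit is an incoherent feed-forward loop realized with two
genelet switches. The three-species model tracks free repressor RNA
x = [iMG], free reporter RNA y = [rMG], and their duplex z = [rMG·iMG]:

    ẋ = α₁u − β₁x − kxy + γ₁z
    ẏ = α₂u − kxy
    ż = kxy − γ₁z

It rests on four assumptions. (1) Template–activator hybridization is fast,
so activated-template levels track the running activator total u
instantaneously and production is linear in u, with the input partitioned
between the two template families in proportion to their concentrations:
α₁ = k_p1·[TiMG]ᵗ/([TrMG]ᵗ+[TiMG]ᵗ), α₂ = k_p2·[TrMG]ᵗ/([TrMG]ᵗ+[TiMG]ᵗ).
(2) Enzymes operate far from saturation (first-order kinetics); the
Michaelis–Menten variant with factors f(u) = 1/(1+u/K_M) and
g(x,z) = 1/(1+x/K_Mx+z/K_Mz) is provided to probe this assumption — with a
saturable complex-degradation term the steady output is no longer
input-independent, and for sufficiently small K_Mz the complex influx can
exceed the capped degradation flux so that no steady state exists at high
input. (3) Free rMG and complexed iMG are protected from RNase R
(β₂ ≃ γ₂ ≃ 0); degradation of rMG inside the duplex releases the iMG strand,
which is why ẋ + ż carries no γ₁ term (iMG is recycled, not destroyed).
(4) Transcription and degradation rate constants scale linearly with
[RNAP] and [RNase R] relative to the reference concentrations at which they
were calibrated; this is known to be doubtful at low RNAP and is a
documented caveat, not part of the model.

The five-species "detailed" variant drops assumption (1): it integrates
[TiMG·A] and [TrMG·A] explicitly with a shared hybridization constant k₊
and obtains free activator and free templates from the conservation
relations. With k₊ fast (binding timescale ≪ 1/β₁) its output trajectory is
numerically indistinguishable (<0.1%) from the three-species model, which is
tested. Inhibitor additions that out-titrate the bound activator strip
template-bound A proportionally and instantaneously — a modeling choice
consistent with strand displacement being fast on circuit timescales; a
finite displacement rate is out of scope.

## Units, inputs, and event handling

Concentrations are in nM and time in minutes; the dimensionless model uses
τ = β₁t and all variables scaled to their baseline steady state. Inputs are
piecewise constant: timed additions of activator A raise the running total
u, additions of inhibitor I (a perfect complement of A) lower it
stoichiometrically with a floor at zero. The integrator (LSODA via
`scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-10 nM, output grid 0.1 min
by default — the fast bimolecular step against slow degradation makes the
system stiff) is stopped and restarted at every addition so each segment
sees a smooth right-hand side; the RNA state is continuous across events,
only u jumps. The reported input series is right-continuous (a sample at an
event time sees the post-addition level), which is what lets the
fold-change-limit model report its exact discontinuous peak (y jumps to the
fold at the step). The transcriptional burst factor (1 + B·e^(−t/τ_b)) runs
from reaction start (t = 0), not from each addition: it models the enzyme's
first turnovers, not a response to input.

## Pulse metrics and the phase space

The standard perturbation starts the dimensionless model at its unit steady
state and steps u from 1 to a fold f at t = 1. Amplitude A = max(y) − 1 and
adaptation time T (earliest time after which y stays inside [0.99, 1.01])
are read from a dense grid (Δτ = 0.01), T by scanning backward from the end
of the settled trace so transient band re-entries cannot truncate it; runs
are extended by doubling until the tail sits inside the band. Fold-change
quality compares the pulse at (p₁, p₂) with the pulse at (p₁, 2p₂) — the
same fold applied from a doubled baseline: R = A₂/A₁ and the normalized
error E = ∫₁^T¹|y₁−y₂|dt/(A₁T₁). E is written as a sum over integer times
in the figure-style definition; we evaluate it as a trapezoid time average,
which coincides with the unit-spaced sum up to discretization and is applied
identically to both traces. Default sweep grids are log-spaced
p₁ ∈ [10⁻², 10¹], p₂ ∈ [10⁻¹, 10²] at p₃ = 1 (5×5 in the system-level
tests); the published sweep grid is not printed anywhere, so these are
representative ranges covering the qualitative trends, and no figure-derived
numbers are treated as ground truth.

At the calibrated operating point (p₁, p₂, p₃) = (0.19, 0.93, 0.61), a
staircase of four input doublings yields pulse amplitudes 0.314, 0.427,
0.548, 0.664: monotonically converging toward the limit-model amplitude
(f − 1 = 1) as the effective p₂ doubles with each addition. Fold-change
detection there is approximate and converging — the pairwise amplitude ratio
is ≈1.3–1.4 per doubling — so a criterion requiring all four amplitudes
within ±30% of the first is not met by the model at that operating point,
and the staircase protocol reports the per-pulse ratios and the count within
tolerance rather than asserting sameness. The tolerance is a CLI flag and is
recorded in the output.

## Representative parameter set

`REPRESENTATIVE_RATES` is a synthetic calibration, not a measured one. The
magnitudes are chosen to be plausible for T7 genelet circuitry
(transcription ~10⁻² /min per activated template, rMG/iMG hybridization
~10⁵ /M/s, RNase-R-mediated degradation ~10⁻² /min, burst B = 3 with
τ_b = 15 min) and pinned so that at the fold-change reaction composition
(TrMG 50 nM, TiMG 150 nM, RNAP 171 nM, RNase R 75 nM, baseline input
10 nM) the circuit sits exactly at the dimensionless operating point
(0.19, 0.93, 0.61). Only the dimensionless triple is an externally anchored
quantity; everything pinned to it (e.g. the ~1 nM steady rMG level) follows
algebraically.

## Synthetic measurements

The generator emulates a spectrofluorometer run: raw(t) = c·[rMG](t) +
A_b·e^(−k_b·t) + ε, with linear gain c (a.u./nM), an additively decaying
free-dye background (pseudo-first-order bleaching), i.i.d. Gaussian read
noise on the fluorescence scale only, and 1-min sampling by default.
Default fixture settings (gain 1–2 a.u./nM, background ~10% of the maximum
signal, noise ~2% of the maximum) are nominal: the true bleaching rate of
the dye is not published numerically. Three elementary assays mirror the
bench characterization: production-only transcription at several activator
levels (closed form y = α₂u(t + Bτ_b(1−e^(−t/τ_b)))), the
equal-concentration second-order binding decay c(t) = 1/(kt + 1/c₀), and
the complex-degradation mini-system (hybridization + recycling) at
substoichiometric iMG, where total rMG degraded exceeding the iMG amount is
the signature of catalytic turnover. What these synthetic data do *not*
contain — abortive transcripts, nonspecific enzyme binding, batch-to-batch
enzyme variability, gel-quantitation error — is exactly what made the
published degradation constants shift between purified-component and
in-circuit estimates; passing recovery tests here therefore validates the
estimation machinery, not the transferability of elementary estimates to a
running circuit.

## Estimation workflow

Background correction fits A_b·e^(−k_b·t) either on a pre-reaction blank
window of the trace or, preferably, on a dedicated signal-free blank run of
full length, then subtracts the extrapolated curve. The dedicated-blank
route exists because the two background parameters are weakly identified on
a window much shorter than 1/k_b: at 2% noise the extrapolation error from
a 30–60 min window propagates into percent-level systematic distortion of
the corrected signal and, downstream, >10% bias in the degradation
constants, while a full-length blank pins both parameters to ~1%.
Calibration is a through-origin linear fit to known-concentration aptamer
standards. The elementary fits use `lmfit` least squares with the closed
forms above; the binding fit fixes the reciprocal intercept at 1/c₀ (the
initial concentration is known by preparation), and the transcription fit
shares one rate constant across activator levels, enforcing linearity.

Global refinement fits the shared vector (k_p1, k_p2, B, τ_b, k, β₁, γ₁) to
all circuit traces simultaneously by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF), with the three-species model as
forward operator (forward solves at rtol 1e-7 on a 2-min grid). Residuals
are weighted per trace by its maximum signal so order-of-magnitude
differences in amplitude across conditions do not let bright traces
dominate. Bounds default to ±30% around the initial point for the
transcription parameters (their assays are direct and trusted) and a decade
either way for k, β₁, γ₁ (the parameters known to shift in circuit
context). Because the published optimization method is unspecified, the
refinement is a documented default: deterministic given data, initial
point, bounds and seed, with an optional multi-start (5 seeded ±10%
log-normal jitters, best residual kept). Parameter uncertainties come from
the Gauss–Newton covariance at the optimum; parameters pinned at a bound
are flagged in the results.

## Problem sizes used in the tests

System-level tests run: exact adaptation at four input levels (settling
detection: all derivatives < 10⁻⁹ nM/min plus a ±0.1% band over 30 min,
extending the horizon by doubling as needed); a 5×5 phase-space sweep;
and three replicates of end-to-end recovery on nine conditions (three RNAP
levels × three RNase R levels × three template ratios at 200 nM total
template, 330 min, 2-min sampling, 2% noise, single-start refinement from
elementary-style perturbed initial values). These sizes give sub-minute
suite components while leaving the recovery problem genuinely
ill-conditioned enough to be informative (the burst parameters B and τ_b
trade off against k_p and are recovered to ~10%, the five criterion-listed
constants to ≤5–10%).

## Known limitations

- Deterministic mass-action only; no stochastic kinetics.
- No sequence-level thermodynamics; hybridization is a single rate constant.
- The linear enzyme-concentration scaling is unreliable at low RNAP.
- The "response time" of the condition sweeps is reported two ways (peak
  time and ±5% settling time); trend checks use peak time, because the
  settling time into a *relative* band is confounded by the
  overshoot-to-steady ratio and is not monotone in the predicted direction.
- The u₀ = 0 baseline cannot be non-dimensionalized (the output scaling is
  undefined); the dimensional model allows u = 0 but flags the output
  steady state as undetermined.
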