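# Methods

## The modelled system

A casein microparticle (CMP) is treated as a homogeneous sphere whose
volume changes only through solvent and material flows across its surface;
internal sources and sinks of volume (e.g. changes in water binding to the
caseins) are neglected. Because sphericity is maintained until
disintegration, the microscopically measured projection area A (µm²), the
volume V and the radius R are equivalent state descriptions linked by
A = πR², V = (4/3)πR³ and hence A = 3V/(4R) =
π^(1/3)·(3V/4)^(2/3). Canonical internal units are seconds, µm³ (≡ fL) and
µm²; picolitre-scale inputs (1 pL = 1000 fL) are converted on load.

## Kernels

All flows are built from two primitives:

* **Unnormalized Gaussian pulses** g(t) = n·exp(−(t−t⁺)²/(2σ²)). The
  amplitude n is the peak value and absorbs any normalization constant;
  with this convention the running integral is exactly
  √(2π)/2·n·σ·erf((t−t⁺)/(√2σ)) + const, which makes the pulse-driven
  first-order ODE dV/V = −g dt solvable in closed form with the erf
  prefactor √(2π)/2·n·σ. The alternative (density-normalized) convention
  would only rescale n; the unnormalized one is used consistently because
  it is the one under which the published closed-form parameter values are
  mutually consistent.
* **Right-continuous 0/1 gates**: a step/ramp activation is 0 before its
  start time and 1 from it on (switch-on at t ≥ t*); a pulse is 1 on the
  half-open window [start, end). Half-open windows avoid double activation
  at hand-offs where one gate's end coincides with another's start.

Widths σ are standard deviations in seconds throughout: the erf argument
(t−t⁺)/(√2σ) is dimensionless only if σ carries the unit of t, so table
entries sometimes labelled "s²" are read as seconds.

The acidification ramp is summarized by a linear time→pH map anchored at
the times the two insolubility maxima are crossed (pH 6.2 and the
isoelectric point 4.2). The map is for annotation only — all model
chronology uses measured times directly, because extrapolating the linear
map far outside its anchors yields non-physical pH values. The companion
solubility curve S(pH) = 100% − Σ pᵢ(pH) + const (two Gaussian dips on the
pH axis) is provided as a functional form; no solubility data ship with
the package.

## Phase models

**Phase I (acid shrinkage).** V(t) = V₀·exp(−Σᵢ √(2π)/2·nᵢσᵢ·erf((t−tᵢ⁺)/(√2σᵢ))),
i = 1, 2. V₀ is a fit constant anchored where the erf terms vanish
(mid-curve), *not* the volume at t = 0: well before both pulses each erf
is ≈ −1, so V(0) ≈ V₀·e^(+√(2π)/2·(n₁σ₁+n₂σ₂)). Both the implied V(0) and
the total shrink factor V(∞)/V(0) = e^(−√(2π)(n₁σ₁+n₂σ₂)) are exposed as
derived properties rather than re-interpreting the printed form.

**Phase III (pepsin decay).** Piecewise: the erf form (one pulse, fixed
width 37 s) for t < 147 s — surface hydrolysis of the κ-casein layer —
then V₄·e^(−t/t₄) + V∞ for t ≥ 147 s, bulk proteolysis decaying to the
plateau of the compact peptide core. The exponential uses absolute time,
and the two branches are fitted independently, so the model is
discontinuous at the breakpoint; the jump is reported as a diagnostic
instead of being constrained away. The breakpoint defaults to 147 s and is
configurable.

## The stock-and-flow simulator

One stock, three gated flows, dV/dt = −I_V1 + I_V2 − I_V3:

* I_V1 = V·(g₁+g₂) while t < t₂⁺ (the shrinkage minimum, 300 s in the
  reference chronology). At t₂⁺ the solvent flow reverses direction.
* I_V2, on [t₂⁺, Degt): the tail of g₂ re-enters as inflow; a sustained
  swelling term RC1·V·(V/V_ref)^(nx−1) drives the expansion; and the
  surface-proteolysis pulse g₃ subtracts volume on [t(pH 2.8), Degt),
  throttling the swelling towards the end of phase II.
* I_V3 = RC2·V − RC3 from Degt on. Its fixed point V∞ = RC3/RC2 sets the
  plateau and is independent of everything that happened before, so the
  final area A∞ = π^(1/3)·(3/4·RC3/RC2)^(2/3) is the most robust
  prediction of the model.

The swelling power law deserves a note. Writing the superlinear term as
RC1·V^nx with V in fL makes the exponent act on a dimensioned number and,
with the reference values (RC1 = 0.0032 s⁻¹, nx = 1.5, V ≈ 215 fL),
produces a finite-time blow-up *within* phase II (d(V^(−1/2))/dt = −RC1/2
diverges ≈ 43 s after the pulse opens). The implemented form
RC1·V·(V/V_ref)^(nx−1), with V_ref defaulting to the initial volume V₀,
keeps RC1 in s⁻¹ for any nx, reduces to a plain first-order swelling flow
at nx = 1, differs from the raw power law only by the constant
V_ref^(1−nx), and stays finite through the phase (the singularity moves
past the degradation cut-off). V_ref is configurable for users who want a
different scaling volume. The phase II kernel as a whole is a
reconstruction constrained by the qualitative description of the phase —
fast initial swelling, flattening from ~400 s, strong slowdown once
surface proteolysis starts — and is pluggable via the configuration;
the steady state does not depend on it.

Integration is explicit fixed-step Euler, dt = 0.25 s by default, from
t = 0 (medium exchange) to t_end = 2400 s, recording every step. Flows are
evaluated at the left endpoint of each step, so the stored flow
decomposition reproduces each volume increment to within one rounding of
the accumulator. Halving dt changes the final area by < 10⁻⁴ %, and the
plateau is a fixed point of the update for any dt, so first-order accuracy
is ample at these rates. A positivity floor (10⁻⁶ fL, configurable) clips
the volume with a warning for extreme user configurations; non-finite
states raise an error naming the step.

## Fitting

* **Phase I**: trust-region least squares on *relative volume* (series
  converted area→volume and normalized to the start of the fitting
  window; the window start is configurable, matching the convention of
  normalizing shrinkage curves to their onset, e.g. 120 s for SGF+pepsin
  and 360 s for water). σ₁ is fixed by convention; t₂⁺, when neither fixed
  nor free, defaults to the argmin of a 5-point moving average of the
  series — a reproducible surrogate for reading the shrinkage minimum off
  the plot. Starting values: amplitudes 0.01 s⁻¹, t₁⁺ at the steepest
  descent of the smoothed curve before t₂⁺. Cost tolerance 1e-10
  (configurable); under-determined windows raise rather than returning
  garbage.
* **Phase III**: the two branches are fitted independently (erf branch:
  V₀, n₃, t₃⁺ free, σ₃ fixed at 37 s; exponential branch: V₄, t₄, V∞
  free), on absolute volume in pL.
* **System model**: seeded differential evolution (population 15 per free
  parameter, up to 40 generations by default, followed by an L-BFGS-B
  polish) over explicitly bounded parameters, minimizing squared *area*
  residuals of the forward simulation sampled onto the data grid by
  nearest-grid-point lookup. With the same seed, runs are bit-identical
  including the loss trace. Typically only the degradation coefficients
  (RC2, RC3) are freed: they are well identified by the tail, whereas
  phase II parameters are entangled with the kernel reconstruction.

R² is reported as 1 − SS_res/SS_tot about the observed mean and is
undefined (NaN in fit results) for constant observations.

## Synthetic data

The generator emulates what the flow-cell experiment measures — the
projected area of one particle at 2 frames per second — for three
scenarios with known ground truth: the full simulator curve (SGF+pepsin),
the phase I closed form (water at pH 2), and the phase III piecewise model
(pre-acidified + pepsin). Defaults carry the reference parameter values.
Choices the underlying study does not pin down, made once here:

* **Noise**: multiplicative lognormal on the area with CV 1% by default —
  segmentation error scales with particle size. The log-noise is centred,
  so the noisy area is median-unbiased; its mean exceeds the noiseless
  curve by the lognormal correction √(1+cv²) ≈ 1.00005 at the default CV.
* **Absolute scale of the water scenario**: the published phase I fit is
  on relative volume, so the generator applies a representative mid-size
  particle volume of 200 fL.
* **Late expansion in water**: after the acid shrinkage, particles in
  water swell until dissolution; no fitted model exists for this, so the
  generator can append a simple exponential volume growth (default onset
  680 s, rate 0.003 s⁻¹) purely to exercise window selection and minimum
  detection. It carries no reference values and can be disabled.

What passing tests on these data do and do not show: parameter recovery on
synthetic series demonstrates that the fitting machinery inverts the
models correctly under the stated noise, *not* that the models describe
any particular measured particle — real kinetics vary between particles
and preparations, include drift and segmentation artefacts that are not
lognormal, and the phase II description is a reconstruction. Fits to real
data should therefore always inspect residuals, not only R².

## Numerical and design choices

* Gate boundary: switch-on at t ≥ start; pulses half-open [start, end).
* The phase III plateau "fraction of initial volume" depends strongly on
  which volume counts as "initial" (the fit constant V₀, or the model
  value at t = 0, which is ~1.9× larger); the package therefore takes the
  reference volume as an explicit argument.
* Closed-form amplitude scales of the phase I fit and the simulator
  differ by design (relative-volume model vs absolute-volume flow model);
  no attempt is made to reconcile them, and the simulator always uses its
  own amplitude set.
* JSON outputs round floats to 12 significant digits so seeded runs are
  byte-reproducible; CSV floats are written at 17 significant digits
  (lossless round trip).

## Problem sizes

The bundled configurations integrate 9 601 Euler steps (2400 s at
0.25 s); synthetic series hold 1 201–4 801 frames; the global fit in the
test suite and acceptance script frees two parameters over a 1 800 s
series (3 601 frames) and evaluates a few hundred to ~1 300 forward
simulations. Noisy-recovery statistics use 20 seeded replicates.

## Known limitations

* The phase II inflow kernel is a plausible reconstruction, not a
  transcription of the original simulation program; only steady-state
  quantities are kernel-independent.
* Explicit Euler is first-order; users raising rate coefficients by
  orders of magnitude should lower dt (the positivity floor guards, but
  does not fix, overshoot).
* No uncertainty quantification — point estimates only.
* No image analysis: areas are inputs; the segmentation step that
  produces them is out of scope.
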