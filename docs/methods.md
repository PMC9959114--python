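# Methods

## Physical model

A planar bilayer is treated as a parallel-plate capacitor whose dielectric
is the hydrophobic acyl-chain core: C = ε₀ε_r A/d, with ε₀ fixed at
8.8542 × 10⁻¹² F/m and ε_r defaulting to 2.5. Under an applied potential ψ
the Maxwell stress thins the film; on oil-stabilized platforms the film
simultaneously grows laterally by recruiting lipid from the Plateau
border, so area, thickness and volume all change.

Writing the capacitance in volume form C = ε₀ε_r V/d² and evaluating it at
the *zero-field* volume V₀ = A₀d₀ and the *measured* field thickness d_ψ
gives the constant-volume capacitance C_ψ = ε₀ε_r V₀/d_ψ², the capacitance
the membrane would have if only its thickness had changed. Regressing this
quantity on ψ² isolates the compressive response: the fitted slope m gives
α = m/(s·C₀) with slope factor s = 3 (see "Slope factor" below), and the
transverse Young's modulus is E⊥ = C_m/(α d₀) with C_m = C₀/A₀. The
quadratic capacitance law C_ψ = C₀(1 + αψ²) is the standard
voltage-dependent-capacitance model for bilayers; the constant-volume
evaluation is what makes it applicable when the membrane area is not
constant.

The legacy estimator works directly on the thinning, Δd = C_m ψ²/(2E⊥).
The package fits Δd = d₀ − d_ψ against ψ² (free intercept) and reports
E⊥ = C_m/(2·slope). A series expansion of the thinning law shows the two
estimators differ by exactly the slope factor in the small-amplitude
limit; on volume-growing membranes the legacy route attributes part of
the capacitance change to compression it did not cause and reads out a
~3× softer membrane. Both are reported so the discrepancy is visible per
dataset.

Thin-plate linear elasticity converts the modulus: K_A = E⊥d/(1 − v) and
k_c = K_A d²/(24(1 + v)), evaluated at the zero-field thickness d₀ and
Poisson ratio v = 0.5 (incompressible; configurable in [0, 0.5]). With
v = 0.5 the composed form is k_c = E⊥d₀³/18. The choice of d₀ (rather than
a field thickness) in the conversion is a package convention: the elastic
constants describe the unperturbed membrane.

## Analysis pipeline

1. **Segmentation.** Boundaries are placed where the potential jumps by
   more than 2 mV; segments with |level| < 5 mV are baseline
   (off-periods), on-segments shorter than 0.5 s are discarded. The ±1 mV
   reference steps of the standard protocol fall below the 5 mV floor by
   design and feed the baseline. All thresholds are configurable; the
   defaults are sized to the ±25 mV / 2 s square-wave protocol.
2. **State estimation.** C₀ and A₀ are means over all samples with
   |ψ| ≤ 5 mV; d₀, C_m, V₀ follow from the plate-capacitor relations. No
   drift correction by default; an optional linear detrend of the baseline
   capacitance is available (`detrend_baseline`).
3. **Step summaries.** Each on-step is averaged over its trailing 50%
   (`settle_fraction`, configurable) to skip settling transients; d_ψ and
   the constant-volume capacitance are computed from the averages.
4. **Fit.** Ordinary least squares of constant-volume capacitance on ψ²,
   pooled over both voltage signs, with a free intercept. The free
   intercept is a diagnostic choice: a fitted intercept deviating from the
   measured C₀ exposes baseline errors instead of hiding them
   (`intercept_relative_deviation`). Per-sign fits yield the
   branch-asymmetry diagnostic |α₊ − α₋|/mean, reported but never used as
   a gate; it is absent when only one sign is present.
5. **Moduli.** As above. A non-positive fitted α (capacitance not
   increasing with voltage) makes the moduli undefined and raises a
   pipeline error; a non-positive thinning slope only disables the legacy
   estimator. The maximum measured volume over V₀
   (`volume_growth_ratio`) quantifies how non-volume-conserving the
   response was.
6. **Uncertainty.** Residual-resampling bootstrap of the pooled
   regression: residuals are rescaled by √(n/(n−2)) to restore the
   variance absorbed by the two fitted parameters, resampled onto the
   fitted line, and the α → E⊥ → k_c chain is re-evaluated per replicate;
   intervals are the 2.5/97.5 percentiles. Without the df rescaling,
   percentile intervals on ~16-point fits systematically undercover.
   Replicate draws are seeded and deterministic; fewer than 50 replicates
   is rejected as a configuration error.

## Forward simulator

The generator is defined as the exact inverse of the analysis chain so
that parameter recovery is an identity, not an approximation: given a
target modulus E⊥, α = C_m/(E⊥d₀) and each potential thins the film to
d_ψ = d₀(1 + s·α·ψ²)^(−1/2), which makes the constant-volume capacitance
exactly linear in ψ². Area growth is quadratic, A_ψ = A₀(1 + γψ²),
mirroring the capacitance law; γ defaults to 2α, which produces the
disproportionate (volume-growing) response the correction exists for.
γ has no experimental functional form to copy — the quadratic is the
simplest law consistent with a response even in the field. An exact
volume-conserving mode (A_ψ = A₀d₀/d_ψ) exists because the quadratic law
conserves volume only to O(ψ⁴), while the nullity property of the
correction (constant-volume capacitance = measured capacitance) deserves a
test at 10⁻⁶ precision.

Default protocol: ±1 mV reference, then ±25 mV steps to ±200 mV,
interleaved in sign at each magnitude, 2 s on / 2 s off, sampled at
1 kHz. The interleaved order is a convention; analysis results do not
depend on step order. Measurement noise is multiplicative Gaussian,
independent per channel, seeded. Step response is instantaneous by
default; a first-order settling time constant (`settle_tau`, e.g. 50 ms)
can be enabled to exercise the steady-state windowing.

What the simulator does *not* emulate: electroporation and rupture at
high fields, solvent partitioning dynamics, annulus capacitance,
correlated drift, and image-analysis artifacts in the area channel.
Passing round-trip tests therefore demonstrates the correctness of the
inversion chain under the stated model, not robustness to every artifact
of bench data.

## Asymmetry bookkeeping

Aliquots of concentrated CaCl₂ stock added to the top chamber dilute as
c_n = (c_init·V + n·V_a·c_stock)/(V + n·V_a) under perfect mixing —
monotone in n and bounded by the stock concentration. The asymmetry
factor x is the top/bottom ratio. The chamber volume is a required
configuration parameter; fixtures use 1.0 mL, under which one 50 µL
aliquot of 200 mM stock takes a 2 mM chamber to 11.4 mM (x = 5.7).
Equilibration kinetics after an addition are not modeled. `run_series`
batch-analyzes one lipid series at a time (mixed lipid labels are
rejected rather than silently pooled), orders rows by x, and reports
percent changes relative to the smallest-x (symmetric) condition.

## Numerical choices and degenerate inputs

- SI units internally everywhere; the equation chain spans ~20 orders of
  magnitude and mixed units are the dominant error source in this domain.
- Slope factor: the quadratic capacitance model literally implies
  m = C₀·α, yet the α = m/3C₀ convention is established for this fit; the
  factor is a named, configurable constant (default 3) and the simulator
  uses the same factor, so the chain is self-consistent under either
  convention.
- OLS is numerically benign here (2-parameter fits on ≤ tens of points);
  a perfectly flat capacitance yields α at machine-epsilon scale, which is
  treated as "no voltage dependence" (moduli undefined).
- Trace files print 12 significant digits so read∘write is an identity to
  full measurement precision.
- Degenerate traces fail loudly with stage-named errors: constant-zero
  potential → "no voltage steps found"; no low-field samples → state
  estimation error; fewer than two distinct ψ² values → fit error.

## Test sizing

Round-trip and property tests run the simulator at 50–200 Hz sample rate
(the physics is sample-rate independent for noiseless traces); the
bootstrap-coverage study uses 200 noisy replicates × 1000 resamples at
200 Hz and the α-dispersion study 500 replicates at 100 Hz. The full
suite completes in a few seconds on one core.

## Known limitations

- The voltage-dependent capacitance model is quadratic; higher-order
  stiffening/softening at large fields is outside the model.
- The elasticity conversion assumes a homogeneous incompressible thin
  plate; leaflet coupling and tilt degrees of freedom are not resolved.
- Bootstrap intervals cover fit uncertainty only; systematic errors in
  the area channel (the usual dominant uncertainty in practice) must be
  assessed upstream.
- Capacitance and area are consumed as measured channels: deriving them
  from current transients or images is out of scope.
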