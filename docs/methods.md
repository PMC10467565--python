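# Methods

## Spin dynamics and forward model

Each exchangeable –OH environment and the water protons form a pool: an
isolated spin-1/2 with a chemical-shift offset from water (δ, ppm, downfield
positive; water pinned at 0) and a population fraction f. Fractions come from
proton molarities — each split site contributes 0.36 (α) or 0.64 (β) of the
glucose molarity, unsplit sites and C6 contribute the full molarity, and
water contributes 110.7 M protons by default (2 × 55.35; configurable).

Exchange is a first-order rate matrix `K` with the column convention
`K[i, j]` = rate j→i. For pool i with group rate k_i the water couplings are
`K[w, i] = k_i` and `K[i, w] = k_i f_i / f_w`, which closes detailed balance:
columns sum to zero and `K @ f = 0` exactly. The reported k_ex is therefore
the pseudo-first-order rate of a proton leaving its –OH site (inverse pool
lifetime), the convention of the two-site comparison models. The optional
direct OH–OH cross route between ring neighbours uses the same
fraction-scaled reverse rate; with all cross rates zero the matrix is
bit-identical to the plain restricted model.

The density operator of N pools lives in a 4N-dimensional extended Liouville
space (matrix-element basis ρ00, ρ01, ρ10, ρ11 per pool). With only the
chemical-shift term in the Hamiltonian the generator
`G = I₄⊗K + diag(0, −iω, +iω, 0)` is block-diagonal in the four element
sectors, and the single-quantum sector is exactly the transverse
Bloch–McConnell matrix `iΩ + K`. The FID starts from unit transverse
magnetization distributed ∝ f (ideal 90° on equilibrium) and sums the ρ10
elements; because `G` is time independent the propagation uses its
eigendecomposition, mathematically identical to applying `exp(G·dwell)`
16384 times. No intrinsic relaxation enters: line widths are exchange
broadening plus the processing line broadening. (Ignoring the ≲15 Hz
intrinsic widths of the real system overestimates rates by ≲1% at the top of
the measured temperature range.)

Processing mirrors routine 1D NMR with the defaults of the emulated
measurement: 15 ppm sweep width at 500 MHz, 16k points, exponential
apodization `exp(−π·LB·t)` with LB = 1 Hz (a pure line acquires FWHM = LB),
no zero-filling, FFT, real part (the simulation is intrinsically in phase).
The first FID point is halved before the transform — the standard
Euler–Maclaurin correction that removes the constant baseline offset of a
truncated-FID DFT. The –OH segment starts at the first local minimum
downfield of the water maximum (searched on a 5-point moving average, and a
candidate minimum must be followed by a rise above 10⁻⁶ of the spectrum
maximum, so fully coalesced spectra are rejected) and ends at a configurable
downfield edge (default +3.8 ppm from water, giving ≈3800 points). The
segment is normalized to unit trapezoidal integral, scaled by the
`integral_scale` fit parameter (bounded to 0.8–1.2), and the quadratic
baseline polynomial is added afterwards — the order that makes the baseline
parameters act additively on the normalized data scale.

During fitting, the extraction window is fixed once from the measured
spectrum, and model segments are evaluated only on those bins through the
closed geometric-series form of the DFT of a sum of complex exponentials —
exactly equal to the FFT path (tested to 10⁻⁹) at a fraction of the cost
(~0.6 ms per 19-parameter restricted-model evaluation).

## MCMC fitting

The error is `E = T_inv · Σ((y_data − y_model)/Y_SEM)²`. `Y_SEM = "auto"`
estimates the noise SD from the most-downfield 0.2 ppm of the segment after
removing a linear trend. The sampler perturbs one parameter per proposal by
`uniform(−1,1)·k_i`, reflects out-of-bounds proposals at the crossed edge,
and accepts by the standard Metropolis rule `u < exp(−ΔE)`. One "step" is a
sweep over all parameters; the default production length is 20 000 steps.
Two adaptation phases precede production, rescaling each `k_i` by
`exp(acceptance − 0.5)` every 50 (configurable) sweeps toward ~50%
acceptance; steps are frozen in production, preserving the Markov property.

`T_inv` defaults to 0.5: with Y_SEM equal to the Gaussian noise SD the
stationary density `exp(−E)` is then the exact likelihood
`exp(−RSS/2σ²)`, so the 2.5–97.5% production quantiles are calibrated
credible intervals. Intervals are reported symmetrized (half the
interquantile range) around the minimum-error sample, and chain health is
checked by the per-parameter step autocorrelation.

Two bounds stages reflect the assignment workflow: `initial` uses broad,
partly overlapping shift windows with only the unambiguous C1/C6 anchors
separated; `assignment_fixed` centres ±0.05 ppm windows on prior shift
assignments and shrinks neighbouring windows to the midpoint between priors,
making them pairwise disjoint and freezing the assignment. Rate bounds are
wide and non-restrictive in both stages (default upper bound 5×10⁴ s⁻¹,
comfortably above the fastest fitted rate).

## Temperature-series pipeline

Stage 1 fits spectra coldest-first. The coldest chain starts from the window
centres (or the supplied prior assignment); each warmer chain warm-starts
from the previous best fit, clipped into its bounds — the deterministic
analogue of propagating the assignment, which at scaled-down chain lengths
is substantially more reliable than independent random starts. Stage 2 fits
each rate group's (T, k) series — posterior medians with their symmetrized
95% half-widths — to the linearized Eyring form `ln(k/T) = a/T + b` by
pseudoinverse; ΔG‡ = −R·a, κ = (h/k_B)·e^b. Input 95% half-widths are
converted to 1σ (÷1.96), propagated linearly through the log, the
pseudoinverse and the exponential; no residual-based inflation is added, so
the confidence bands reflect only the rate uncertainties (they would
otherwise be dominated by the mild lack-of-fit of the two-parameter law).
ΔG‡ is treated as temperature independent; κ absorbs the entropic factor.
Physical constants are CODATA-2018. Stage 3 tabulates rates and propagated
bands on a 260–310 K grid at 0.25 K (201 rows), flagging rows above the
measured temperature range as extrapolations. Outputs carry a configuration
hash and the seeds; reruns are byte-identical.

## Virtual CPMG experiments

The CPMG train 90ₓ–[τ–180ᵧ–τ]×n acts on the full 4N space because RF terms
couple the element sectors. Pulses default to rectangular with B₁ = 25 kHz
(10 µs / 20 µs); ideal instantaneous rotations are available for oracle
comparisons. Detection is the magnitude of the collective lowering-operator
projection (total quadrature signal, as in imaging). With no other
relaxation the decay is effectively single-exponential after the first echo,
so `R2_ex = −ln(|M_end|/|M_0|)/(2nτ)` from the two-point log ratio. The
default train is 10 echo periods of 20 ms (τ = 10 ms, 200 ms total decay).
Relaxivity builds a dilute two-pool model with solute fraction
`protons_per_glucose · mM · 10⁻³ / 110.7` (rejected above 0.05), simulates
the train, and divides by the millimolar concentration; a 1 mM vs 5 mM
linearity check is available. CPMG-filtered spectra run a 4-echo train at a
list of half-echo times (Bruker d20) before a normal acquisition and keep
both quadrature channels, exposing the exchange-dependent phase patterns.

## Synthetic data

The generator emulates the measured system: restricted-model truth
parameters default to the published pH 6.21 set (shifts from the printed
assignment table, rates from the per-site Eyring parameters), temperatures
270–295 K in 5 K steps, the standard acquisition above, a small quadratic
baseline (0.03 − 0.02·δ + 0.004·δ² on the normalized scale, ~1–2% of the
peak heights), and i.i.d. Gaussian noise on the processed real spectrum with
SD = (tallest –OH intensity)/SNR, SNR = 200 by default — representative of a
32-scan 1 M measurement. Chemical shifts are temperature independent by
default (the real drift is modest); a linear-in-T drift is available for
robustness studies. The manifest records the exact per-temperature truth.

What the generator does *not* emulate: non-exchangeable ring-proton signals,
solvent-suppression and phasing artefacts, field drift and shimming,
t-domain noise correlations, ¹³C satellites, J-coupling, and intrinsic
relaxation. Passing recovery tests therefore demonstrate the correctness and
calibration of the estimation machinery under the stated noise model, not
robustness to every artefact of real spectra.

## Problem sizes in the test suite

The statistical tests run scaled-down chains chosen to keep the suite
practical while remaining in the regime where the method is exercised
honestly: credible-interval coverage uses 5 independent noise/chain seeds
with 600+600 adaptation and 4000 production sweeps on one 270 K spectrum;
the end-to-end series test runs one six-temperature series at 500+500
adaptation and 4000 production sweeps per spectrum. A full-scale analysis
would use the 20 000-step default.

## Known limitations

- Exchange rates carry the ≲1% systematic overestimate from neglecting
  intrinsic relaxation, largest at the hottest measured temperatures.
- The Eyring confidence bands deliberately exclude lack-of-fit error and are
  therefore slightly optimistic far from the measured range.
- Credible intervals assume the auto-estimated Y_SEM matches the true noise
  scale; a heavily sloped or signal-contaminated downfield tail would bias
  them.
- The cross-exchange variant's rate parameterization (fraction-scaled
  detailed balance) is one reasonable choice among several; on data without
  cross exchange it is indistinguishable from the restricted model by
  construction.
- pH enters only as a label on parameter sets; no pH-dependent rate law is
  modelled.
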