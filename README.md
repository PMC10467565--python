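# gluchange

Chemical-exchange analysis of glucose hydroxyl protons in aqueous solution.

Glucose carries five exchangeable –OH protons per molecule, doubled into nine
magnetically distinct sites by the α/β anomer equilibrium (populations
0.36 : 0.64). These protons exchange with water on the intermediate-to-fast
NMR timescale, so their resonances — 0.7–2.9 ppm downfield of water — broaden
and eventually coalesce into the water line as temperature or pH rises. The
exchange rates and chemical shifts of each site determine how well glucose can
serve as a natural MRI contrast agent (CEST, T2/T1ρ relaxation), but they are
hard to read off a spectrum directly. `gluchange` provides the full analysis
chain to extract them from conventional 1D ¹H spectra:

- **Forward simulation** of exchange-broadened spectra: each pool is an
  isolated spin-1/2 with a chemical-shift Hamiltonian, coupled to the others
  by a first-order exchange matrix *K* in extended Liouville space
  (equivalently the Bloch–McConnell equations for transverse magnetization),
  followed by routine processing (exponential apodization, FFT, quadratic
  baseline, extraction and normalization of the –OH window).
- **Model variants** differing in which sites resolve separate α/β shifts and
  rates, including the *restricted* model (9 shifts, 6 exchange rates — C2, C3
  and C4 share one rate between anomers) and a variant with direct OH–OH
  cross exchange.
- **Adaptive Metropolis MCMC fitting** of a measured (or synthetic) –OH
  segment: one-parameter-at-a-time proposals, boundary reflection, step sizes
  adapted to ~50% acceptance, and symmetrized 95% credible intervals from the
  production-phase posterior.
- **Eyring extrapolation**: each site's rate–temperature series is fitted to
  k_ex(T) = κ·(k_B·T/h)·exp(−ΔG‡/(R·T)) in linearized form
  (ln(k/T) = a/T + b, solved by pseudoinverse), with first-order propagation
  of the MCMC rate uncertainties into (κ, ΔG‡) and into tabulated rates on a
  260–310 K grid.
- **Virtual experiments**: CPMG echo trains on any exchange model — the
  exchange contribution to water R₂, relaxivity per mM glucose at arbitrary
  field, and CPMG-filtered high-resolution spectra.
- **Synthetic data** with known ground truth emulating the real measurements
  (1 M glucose in PBS, 11.7 T, 15 ppm sweep, 16k points, Gaussian noise,
  quadratic baseline, Eyring-law rates), so every pipeline stage is testable
  without any deposited data.

## Worked example

Extrapolate the β-anomeric C1 hydroxyl exchange rate (pH 6.21 parameters) to
body temperature, and predict the CPMG exchange relaxivity of the literature
two-site glucose model:

```python
import gluchange as g

params = g.EyringParams(kappa=0.00126, dG=3.852e4,
                        sigma_kappa=6e-5, sigma_dG=110.0)
pt = g.eyring_rate(params, 310.0)
print(f"k_ex(310 K) = {pt.k_ex:.0f} +/- {pt.ci95_half:.0f} Hz")

table = g.tabulate_rates(params)          # 260-310 K, 0.25 K steps, 201 rows
print(table.iloc[[0, 57, 200]].to_string(index=False))

res = g.relaxivity(1.44, 4600.0, spectrometer_freq_MHz=499.9)
print(f"relaxivity at 11.7 T: {res.relaxivity:.3f} s^-1 mM^-1")
```

prints

```
k_ex(310 K) = 2631 +/- 330 Hz
   T_K        k_ex  ci95_half
260.00  124.611175  17.021127
274.25  331.762904  44.077149
310.00 2630.927676 329.738448
relaxivity at 11.7 T: 0.101 s^-1 mM^-1
```

The first block is the Eyring law evaluated from fitted (κ, ΔG‡) with the 95%
band propagated from their uncertainties: this C1 site accelerates from
~125 Hz at 260 K to ~2.6 kHz at 310 K. The relaxivity line is a simulated
10 × 20 ms CPMG train on a dilute two-site water/solute model (offset
1.44 ppm, k_ex = 4600 Hz, 5 protons per glucose): the exchange contribution
to water R₂ is ≈ 0.10 s⁻¹ per mM glucose at 11.7 T.

A full synthetic analysis — generate a six-temperature series, fit every
spectrum by MCMC, fit the Eyring law per site, tabulate — runs through
`gluchange.fit_series` (see `docs/methods.md`), or from the shell:

```bash
gluchange synth --outdir series/ --seed 1
gluchange series --config run.yaml --outdir results/
gluchange relaxivity --freq-mhz 127.7     # 3 T
```

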