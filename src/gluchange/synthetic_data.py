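"""Synthetic spectra and temperature series with known ground truth.

The generator emulates the measured system: 1 M glucose in 1x PBS at
11.7 T, -OH resonances 0.7-2.9 ppm downfield of water, exchange rates
following an Eyring temperature law, i.i.d. Gaussian noise on the processed
real spectrum, and a slowly varying quadratic baseline.  The default truth
values are the published restricted-model parameter sets labelled by pH, so
fixtures resemble the real measurements; chemical shifts default to
temperature-independent (the measured drift is modest), with an optional
linear-in-T drift for robustness tests.

Noise is applied to the full-grid spectrum after normalizing it to unit
-OH-segment integral, with SD = (maximum -OH-window intensity) / SNR; the
noise-free spectrum, per-temperature true parameters and the true Eyring
parameters are returned in a manifest so every pipeline stage can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .exchange_models import ExchangeModelSpec, ModelParameters, build_model
from .eyring import EyringParams, eyring_rate
from .spectrum_sim import (
    AcquisitionConfig,
    Spectrum,
    find_oh_window,
    process_fid,
    single_quantum_generator,
)

__all__ = [
    "RESTRICTED_DELTAS_PH621",
    "RESTRICTED_DELTAS_PH700",
    "EYRING_PH621",
    "EYRING_PH700",
    "SeriesConfig",
    "GroundTruthManifest",
    "generate_spectrum",
    "generate_temperature_series",
]

# Published restricted-model chemical shifts (ppm downfield of water);
# pH 6.21 shifts were reported at 295 K, pH 7.00 at 277 K.
RESTRICTED_DELTAS_PH621: dict[str, float] = {
    "C1_alpha": 2.116, "C1_beta": 2.835,
    "C2_alpha": 1.055, "C2_beta": 1.252,
    "C3_alpha": 1.230, "C3_beta": 1.347,
    "C4_alpha": 1.208, "C4_beta": 1.415,
    "C6": 0.763,
}
RESTRICTED_DELTAS_PH700: dict[str, float] = {
    "C1_alpha": 2.0726, "C1_beta": 2.8231,
    "C2_alpha": 1.0599, "C2_beta": 1.2255,
    "C3_alpha": 1.2361, "C3_beta": 1.3004,
    "C4_alpha": 1.2200, "C4_beta": 1.4371,
    "C6": 0.77576,
}

# Published Eyring parameters (kappa, dG in J/mol) per rate group.
EYRING_PH621: dict[str, tuple[float, float]] = {
    "C1_alpha": (0.0162, 4.617e4),
    "C1_beta": (0.00126, 3.852e4),
    "C2": (8.2e-6, 2.793e4),
    "C3": (1.54e-6, 2.38e4),
    "C4": (2.5e-5, 3.054e4),
    "C6": (1.37e-6, 2.227e4),
}
EYRING_PH700: dict[str, tuple[float, float]] = {
    "C1_alpha": (0.247, 4.966e4),
    "C1_beta": (0.071, 4.549e4),
    "C2": (2.31e-4, 3.508e4),
    "C3": (6.0e-5, 3.192e4),
    "C4": (0.00228, 4.006e4),
    "C6": (1.43e-5, 2.810e4),
}


def _as_eyring(value) -> EyringParams:
    if isinstance(value, EyringParams):
        return value
    kappa, dG = value
    return EyringParams(kappa=kappa, dG=dG)


@dataclass
class SeriesConfig:
    """Ground-truth configuration of a synthetic temperature series.

    Defaults emulate the pH 6.21 series: restricted model, six spectra from
    270 K to 295 K, SNR 200 on the tallest -OH line, a small quadratic
    baseline, no chemical-shift drift.
    """

    variant: str = "restricted"
    eyring_truth: Mapping[str, object] = dc_field(
        default_factory=lambda: dict(EYRING_PH621)
    )
    deltas_truth: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(RESTRICTED_DELTAS_PH621)
    )
    delta_drift_ppm_per_K: float = 0.0
    drift_ref_K: float = 282.5
    temperatures_K: Sequence[float] = (270.0, 275.0, 280.0, 285.0, 290.0, 295.0)
    acq: AcquisitionConfig = dc_field(default_factory=AcquisitionConfig)
    snr: float = 200.0
    baseline_poly_truth: Sequence[float] = (0.03, -0.02, 0.004)
    glucose_molar: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for T in self.temperatures_K:
            if not 260.0 <= T <= 320.0:
                raise ValueError("temperatures must lie within [260, 320] K")


@dataclass
class GroundTruthManifest:
    """Per-temperature true parameters alongside the generating truth."""

    temperatures_K: list[float]
    params: list[ModelParameters]
    eyring_truth: dict[str, EyringParams]
    seed: int
    config: SeriesConfig | None = None


def generate_spectrum(
    params: ModelParameters,
    spec: ExchangeModelSpec,
    acq: AcquisitionConfig,
    snr: float,
    seed: int | np.random.Generator = 0,
    baseline_poly: Sequence[float] | None = None,
) -> Spectrum:
    """One noisy full-grid spectrum with known truth.

    The noiseless forward spectrum is normalized so its -OH segment
    integrates to 1 (matching the scale on which fits operate), the truth
    baseline polynomial is added over the full axis, and i.i.d. Gaussian
    noise with SD = (max -OH intensity) / snr is applied everywhere.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = single_quantum_generator(spec, params, acq)
    lam, V = np.linalg.eig(G)
    amp = np.linalg.solve(V, spec.fractions.astype(complex))
    weight = V.sum(axis=0) * amp
    fid = weight @ np.exp(np.outer(lam, acq.times_s))
    spectrum = process_fid(fid, acq)
    a, b = find_oh_window(spectrum, acq)
    integral = np.trapezoid(spectrum.intensity[a:b], spectrum.axis_ppm[a:b])
    y = spectrum.intensity / integral
    if baseline_poly is not None:
        y = y + npoly.polyval(spectrum.axis_ppm, np.asarray(baseline_poly, float))
    noise_sd = float(np.max(y[a:b])) / snr
    y = y + rng.normal(0.0, noise_sd, size=y.shape)
    meta = dict(spectrum.metadata)
    meta.update({"snr": snr, "noise_sd": noise_sd, "synthetic": True})
    return Spectrum(axis_ppm=spectrum.axis_ppm, intensity=y, metadata=meta)


def generate_temperature_series(
    config: SeriesConfig,
) -> tuple[list[Spectrum], GroundTruthManifest]:
    """One spectrum per temperature, rates drawn exactly from the Eyring truth."""
    spec = build_model(config.variant, glucose_molar=config.glucose_molar)
    truth = {name: _as_eyring(v) for name, v in config.eyring_truth.items()}
    missing = [g for g in spec.rate_group_names if g not in truth]
    if missing:
        raise ValueError(f"eyring_truth lacks rate groups: {missing}")
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    params_list: list[ModelParameters] = []
    for T in config.temperatures_K:
        rates = [eyring_rate(truth[g], T).k_ex for g in spec.rate_group_names]
        drift = config.delta_drift_ppm_per_K * (T - config.drift_ref_K)
        deltas = [config.deltas_truth[lbl] + drift for lbl in spec.non_water_labels]
        params = ModelParameters(
            deltas=deltas,
            rates=rates,
            baseline_poly=np.asarray(config.baseline_poly_truth, float),
        )
        acq = AcquisitionConfig(
            spectrometer_freq_MHz=config.acq.spectrometer_freq_MHz,
            sweep_width_ppm=config.acq.sweep_width_ppm,
            td=config.acq.td,
            lb_Hz=config.acq.lb_Hz,
            extraction_upper_ppm=config.acq.extraction_upper_ppm,
            temperature_K=T,
        )
        spectra.append(
            generate_spectrum(
                params, spec, acq, config.snr, rng,
                baseline_poly=config.baseline_poly_truth,
            )
        )
        params_list.append(params)
    manifest = GroundTruthManifest(
        temperatures_K=[float(T) for T in config.temperatures_K],
        params=params_list,
        eyring_truth=truth,
        seed=config.seed,
        config=config,
    )
    return spectra, manifest
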