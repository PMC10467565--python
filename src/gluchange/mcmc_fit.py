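"""Adaptive Metropolis MCMC fitting of spectra with bounded parameters.

The sampler walks an n-dimensional box one parameter at a time: parameter i
is perturbed by uniform(-1, 1) * k_i, proposals crossing a boundary are
mirrored back at the crossed edge, and moves are accepted by the standard
Metropolis rule on the error

    E = T_inv * sum(((y_data - y_model) / Y_SEM)**2).

With Y_SEM equal to the noise standard deviation, the stationary density
exp(-E) equals the Gaussian likelihood at T_inv = 1/2 (the default), so the
reported 95% intervals are calibrated credible intervals.  During two
adaptation phases the step sizes k_i are rescaled every ``adapt_window``
sweeps by exp(observed acceptance - target) toward a ~50% acceptance rate;
step sizes are frozen during the production phase, which preserves the
Markov property.  Credible intervals are symmetrized as half the 2.5-97.5%
interquantile range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .exchange_models import ParameterBounds
from .spectrum_sim import SpectrumSegment

__all__ = [
    "MCMCConfig",
    "Trace",
    "PosteriorSummary",
    "error_function",
    "estimate_y_sem",
    "run_mcmc",
    "summarize_posterior",
    "step_autocorrelation",
]


@dataclass
class MCMCConfig:
    """Sampler settings.

    A "step" is one sweep over all parameters (each parameter gets one
    proposal per sweep), so the number of forward simulations is
    n_steps * n_parameters.  ``y_sem="auto"`` estimates the noise scale from
    the signal-free downfield end of the data segment.
    """

    n_adapt1: int = 1000
    n_adapt2: int = 1000
    n_production: int = 20000
    target_acceptance: float = 0.5
    adapt_window: int = 50
    t_inv: float = 0.5
    seed: int = 0
    y_sem: float | str = "auto"
    step_init_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_production < 1:
            raise ValueError("n_production must be at least 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")


@dataclass
class Trace:
    """Production-phase samples and bookkeeping of one MCMC run."""

    samples: np.ndarray          # (n_production, n_params)
    errors: np.ndarray           # (n_production,)
    acceptance: np.ndarray       # per-parameter acceptance fraction (production)
    step_sizes: np.ndarray       # final k_i
    config: MCMCConfig
    y_sem: float
    names: list[str] = field(default_factory=list)
    n_forward_failures: int = 0


@dataclass
class PosteriorSummary:
    """Best-fit vector and symmetrized 95% credible intervals."""

    best: np.ndarray
    best_error: float
    ci95_half: np.ndarray
    quantiles: np.ndarray        # (3, n_params): 2.5%, 50%, 97.5%
    names: list[str] = field(default_factory=list)


def error_function(
    model: np.ndarray, data: np.ndarray, y_sem: float, t_inv: float = 0.5
) -> float:
    """Scaled sum of squares E = T_inv * RSS / Y_SEM**2."""
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data segments must share one grid")
    if y_sem <= 0:
        raise ValueError("y_sem must be positive")
    r = (data - model) / y_sem
    return float(t_inv * (r @ r))


def estimate_y_sem(segment: SpectrumSegment, tail_ppm: float = 0.2) -> float:
    """Noise SD from the most-downfield, signal-free ``tail_ppm`` of a segment."""
    axis = segment.axis_ppm
    mask = axis >= axis[-1] - tail_ppm
    tail = np.real(segment.intensity[mask])
    if tail.size < 4:
        raise ValueError("segment too short for noise estimation")
    # remove the residual linear trend of the baseline tail
    coef = np.polyfit(axis[mask], tail, 1)
    sd = float(np.std(tail - np.polyval(coef, axis[mask])))
    return max(sd, 1e-300)


def _reflect(v: float, lo: float, hi: float) -> float:
    while v < lo or v > hi:
        if v < lo:
            v = 2 * lo - v
        else:
            v = 2 * hi - v
    return v


def run_mcmc(
    forward: Callable[[np.ndarray], np.ndarray],
    data_segment: SpectrumSegment | np.ndarray,
    bounds: ParameterBounds,
    config: MCMCConfig,
    x0: np.ndarray | None = None,
) -> Trace:
    """Run the adaptive Metropolis sampler.

    ``forward`` maps a parameter vector (inside ``bounds``) to a model
    segment on the data grid.  The chain starts at ``x0`` or at a random
    point of the box, runs two adaptation phases, then records the
    production phase.  Fully reproducible for a given config (seed included).
    Forward-model failures reject the proposal and are counted.
    """
    if isinstance(data_segment, SpectrumSegment):
        data = np.real(np.asarray(data_segment.intensity, dtype=float))
    else:
        data = np.asarray(data_segment, dtype=float)
    if config.y_sem == "auto":
        if not isinstance(data_segment, SpectrumSegment):
            raise ValueError("y_sem='auto' needs a SpectrumSegment with an axis")
        y_sem = estimate_y_sem(data_segment)
    else:
        y_sem = float(config.y_sem)

    lo, hi = bounds.lower, bounds.upper
    n = bounds.n
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    x = np.array(x0, dtype=float) if x0 is not None else lo + rng.random(n) * span
    if not bounds.contains(x):
        raise ValueError("starting point outside bounds")
    step = config.step_init_frac * span
    E = error_function(forward(x), data, y_sem, config.t_inv)

    n_fail = 0
    samples = np.empty((config.n_production, n))
    errors = np.empty(config.n_production)
    prod_acc = np.zeros(n)

    phases = (
        (config.n_adapt1, True),
        (config.n_adapt2, True),
        (config.n_production, False),
    )
    for n_sweeps, adapting in phases:
        win_acc = np.zeros(n)
        win_cnt = 0
        for sweep in range(n_sweeps):
            for i in range(n):
                prop = x.copy()
                prop[i] = _reflect(
                    x[i] + (2.0 * rng.random() - 1.0) * step[i], lo[i], hi[i]
                )
                u = rng.random()
                try:
                    E2 = error_function(forward(prop), data, y_sem, config.t_inv)
                except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                    n_fail += 1
                    continue
                dE = E2 - E
                if dE < 0 or u < math.exp(-min(dE, 700.0)):
                    x, E = prop, E2
                    win_acc[i] += 1
                    if not adapting:
                        prod_acc[i] += 1
            win_cnt += 1
            if adapting and win_cnt == config.adapt_window:
                frac = win_acc / config.adapt_window
                step = step * np.exp(frac - config.target_acceptance)
                step = np.clip(step, 1e-12 * span, span)
                win_acc[:] = 0.0
                win_cnt = 0
            if not adapting:
                samples[sweep] = x
                errors[sweep] = E

    return Trace(
        samples=samples,
        errors=errors,
        acceptance=prod_acc / config.n_production,
        step_sizes=step,
        config=replace(config),
        y_sem=y_sem,
        names=list(bounds.names),
        n_forward_failures=n_fail,
    )


def summarize_posterior(trace: Trace, alpha: float = 0.05) -> PosteriorSummary:
    """Best-fit (minimum-E sample) and symmetrized 1-alpha intervals."""
    if trace.samples.size == 0:
        raise ValueError("empty trace")
    q = np.quantile(trace.samples, [alpha / 2, 0.5, 1 - alpha / 2], axis=0)
    best_idx = int(np.argmin(trace.errors))
    return PosteriorSummary(
        best=trace.samples[best_idx].copy(),
        best_error=float(trace.errors[best_idx]),
        ci95_half=(q[2] - q[0]) / 2.0,
        quantiles=q,
        names=list(trace.names),
    )


def step_autocorrelation(
    trace: Trace | np.ndarray, param_index: int = 0, max_lag: int = 100
) -> np.ndarray:
    """Normalized autocorrelation of one parameter's production samples.

    A well-mixed chain decorrelates within a few trajectory steps; the lag-0
    value is exactly 1.
    """
    if isinstance(trace, Trace):
        x = trace.samples[:, param_index].astype(float)
    else:
        x = np.asarray(trace, dtype=float)
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the trace length")
    x = x - x.mean()
    var = float(x @ x)
    if var == 0.0:
        raise ValueError("zero-variance trace has no autocorrelation")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for lag in range(1, max_lag + 1):
        acf[lag] = float(x[:-lag] @ x[lag:]) / var
    return acf
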