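"""Eyring temperature dependence of exchange rates, with error propagation.

Exchange rates of -OH protons follow transition-state theory,

    k_ex(T) = kappa * (k_B * T / h) * exp(-dG / (R * T)),

with the transmission coefficient kappa (dimensionless, absorbing entropy
and catalysis effects) and the Gibbs activation energy dG (J/mol) as the two
fitted parameters.  Fitting uses the linearized form

    ln(k/T) = a * (1/T) + b,    a = -dG/R,  b = ln(kappa * k_B / h),

solved by the pseudoinverse of the [1/T, 1] design matrix.  Rate
uncertainties (95% half-widths, converted to 1 sigma by /1.96) are
propagated to first order through the log, the pseudoinverse and back
through the exponential; no residual-based inflation is added, so the
confidence bands reflect only the uncertainty of the input rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_J_PER_K",
    "PLANCK_J_S",
    "GAS_CONSTANT_J_PER_MOL_K",
    "EyringParams",
    "RatePoint",
    "eyring_rate",
    "fit_eyring_linearized",
    "tabulate_rates",
]

# CODATA-2018
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
GAS_CONSTANT_J_PER_MOL_K = 8.31446


@dataclass
class EyringParams:
    """Transmission coefficient and Gibbs activation energy of one rate group.

    ``cov`` is the 2x2 covariance of (slope, intercept) of the linearized
    fit; when absent (parameters quoted from a table) the propagation falls
    back to the marginal sigmas, ignoring the kappa-dG correlation.
    ``T_measured_max`` flags the top of the measured range: tabulated rates
    above it are extrapolations.
    """

    kappa: float
    dG: float
    sigma_kappa: float = 0.0
    sigma_dG: float = 0.0
    cov: np.ndarray | None = None
    T_measured_max: float | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.dG <= 0:
            raise ValueError("kappa and dG must be positive")


@dataclass
class RatePoint:
    T_K: float
    k_ex: float
    ci95_half: float = 0.0


def _var_ln_k(params: EyringParams, T: float) -> float:
    """First-order variance of ln k(T) from the linearized-fit covariance."""
    J = np.array([1.0 / T, 1.0])
    if params.cov is not None:
        return float(J @ params.cov @ J)
    s_b = params.sigma_kappa / params.kappa
    s_a = params.sigma_dG / GAS_CONSTANT_J_PER_MOL_K
    return float((s_a / T) ** 2 + s_b**2)


def eyring_rate(params: EyringParams, T: float) -> RatePoint:
    """Evaluate k_ex(T) with its propagated 95% half-width."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    k = (
        params.kappa
        * (BOLTZMANN_J_PER_K * T / PLANCK_J_S)
        * np.exp(-params.dG / (GAS_CONSTANT_J_PER_MOL_K * T))
    )
    ci = 1.96 * k * np.sqrt(_var_ln_k(params, T))
    return RatePoint(T_K=float(T), k_ex=float(k), ci95_half=float(ci))


def fit_eyring_linearized(
    points: Sequence[RatePoint | tuple], T_measured_max: float | None = None
) -> EyringParams:
    """Fit (kappa, dG) to a temperature series of rates by the linearized form.

    ``points`` are (T, k_ex, ci95_half) triples or RatePoints.  The
    regression of ln(k/T) on 1/T is solved by the pseudoinverse; input 95%
    half-widths are converted to 1 sigma and propagated linearly into the
    (slope, intercept) covariance.  Zero input uncertainties yield
    zero-uncertainty parameters (exact-model recovery).
    """
    pts = [p if isinstance(p, RatePoint) else RatePoint(*p) for p in points]
    if len(pts) < 2:
        raise ValueError("at least two temperature points are required")
    T = np.array([p.T_K for p in pts])
    k = np.array([p.k_ex for p in pts])
    ci = np.array([p.ci95_half for p in pts])
    if len(np.unique(T)) < 2:
        raise ValueError("temperatures must be distinct")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")

    y = np.log(k / T)
    sigma_y = (ci / 1.96) / k  # d ln k / dk = 1/k
    X = np.column_stack([1.0 / T, np.ones_like(T)])
    P = np.linalg.pinv(X)
    a, b = P @ y
    cov = P @ np.diag(sigma_y**2) @ P.T

    dG = -GAS_CONSTANT_J_PER_MOL_K * a
    kappa = (PLANCK_J_S / BOLTZMANN_J_PER_K) * np.exp(b)
    sigma_dG = GAS_CONSTANT_J_PER_MOL_K * np.sqrt(cov[0, 0])
    sigma_kappa = kappa * np.sqrt(cov[1, 1])
    if T_measured_max is None:
        T_measured_max = float(T.max())
    return EyringParams(
        kappa=float(kappa),
        dG=float(dG),
        sigma_kappa=float(sigma_kappa),
        sigma_dG=float(sigma_dG),
        cov=cov,
        T_measured_max=T_measured_max,
    )


def tabulate_rates(
    params: EyringParams,
    Tmin: float = 260.0,
    Tmax: float = 310.0,
    step: float = 0.25,
) -> pd.DataFrame:
    """Tabulate k_ex with 95% half-widths on a uniform temperature grid.

    Defaults give the 201-row 260-310 K table at 0.25 K steps.  The
    ``extrapolated`` column marks rows above the measured temperature range.
    """
    if Tmin >= Tmax or step <= 0:
        raise ValueError("require Tmin < Tmax and step > 0")
    grid = np.arange(Tmin, Tmax + 0.5 * step, step)
    rows = [eyring_rate(params, float(T)) for T in grid]
    table = pd.DataFrame(
        {
            "T_K": grid,
            "k_ex": [r.k_ex for r in rows],
            "ci95_half": [r.ci95_half for r in rows],
        }
    )
    if params.T_measured_max is not None:
        table["extrapolated"] = grid > params.T_measured_max
    return table
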