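"""Exchange models for the hydroxyl protons of aqueous glucose.

Glucose in solution is a mixture of the alpha and beta anomers (fractions
0.36 : 0.64) and carries five exchangeable -OH protons per molecule (at C1,
C2, C3, C4 and C6).  Each -OH proton and the water protons form a "pool":
a magnetically distinct environment characterised by a chemical-shift offset
from water and a fractional proton concentration.  Chemical exchange moves
protons between the -OH pools and the (vastly larger) water pool, and is
described by a first-order rate matrix K.

The module defines the family of model variants differing in how many sites
resolve distinct alpha/beta chemical shifts and exchange rates:

``split_anomeric``
    only the anomeric C1 -OH is split into alpha/beta (7 pools).
``split2`` / ``split3``
    one / two additional non-anomeric sites are split, each split site with
    its own exchange rate per anomer.  Which of C2/C3/C4 splits is not
    asserted; the extra split sites are generic labelled slots.
``restricted``
    all of C1..C4 carry distinct alpha/beta chemical shifts, but C2, C3 and
    C4 each share a single exchange rate between the anomers: 9 non-water
    pools and 6 rate groups.  This is the variant used for final results.
``restricted_cross``
    the restricted model plus direct OH-OH exchange between the
    (C1,C2), (C2,C3) and (C3,C4) neighbours within each anomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ALPHA_FRACTION",
    "BETA_FRACTION",
    "WATER_PROTON_MOLAR",
    "MODEL_VARIANTS",
    "ProtonPool",
    "ExchangeModelSpec",
    "ModelParameters",
    "ExchangeMatrix",
    "ParameterBounds",
    "build_model",
    "two_site_model",
    "assemble_exchange_matrix",
    "parameter_bounds",
]

#: anomer population fractions of aqueous D-glucose at equilibrium
ALPHA_FRACTION = 0.36
BETA_FRACTION = 0.64

#: default proton molarity of pure water (2 x 55.35 mol/L of H2O)
WATER_PROTON_MOLAR = 110.7

MODEL_VARIANTS = ("split_anomeric", "split2", "split3", "restricted", "restricted_cross")

_OH_PER_GLUCOSE = 5


@dataclass(frozen=True)
class ProtonPool:
    """One exchangeable proton environment (or the water pool).

    ``delta_ppm`` is the chemical-shift offset from water in ppm, downfield
    positive; ``fraction`` is the proton-population fraction (all pools sum
    to 1); ``anomer`` is one of ``alpha``, ``beta``, ``shared`` or ``water``.
    """

    label: str
    delta_ppm: float
    fraction: float
    anomer: str


@dataclass
class ExchangeModelSpec:
    """A model variant binding pools to shared exchange-rate parameters."""

    variant: str
    pools: list[ProtonPool]
    rate_groups: list[tuple[str, ...]]
    rate_group_names: list[str]
    cross_pairs: list[tuple[str, str]] = field(default_factory=list)
    glucose_molar: float = 1.0
    water_proton_molar: float = WATER_PROTON_MOLAR

    def __post_init__(self) -> None:
        waters = [p for p in self.pools if p.anomer == "water"]
        if len(waters) != 1:
            raise ValueError("model must contain exactly one water pool")
        f = self.fractions
        if np.any(f <= 0):
            raise ValueError("all pool fractions must be positive")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("pool fractions must sum to 1")
        grouped = [lbl for g in self.rate_groups for lbl in g]
        non_water = [p.label for p in self.pools if p.anomer != "water"]
        if sorted(grouped) != sorted(non_water):
            raise ValueError("every non-water pool must belong to exactly one rate group")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_labels(self) -> list[str]:
        return [p.label for p in self.pools]

    @property
    def non_water_labels(self) -> list[str]:
        return [p.label for p in self.pools if p.anomer != "water"]

    @property
    def water_index(self) -> int:
        return next(i for i, p in enumerate(self.pools) if p.anomer == "water")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p.fraction for p in self.pools])

    @property
    def n_rate_groups(self) -> int:
        return len(self.rate_groups)

    def pool_index(self, label: str) -> int:
        for i, p in enumerate(self.pools):
            if p.label == label:
                return i
        raise KeyError(label)

    def n_free_parameters(self) -> int:
        """Spectral + baseline parameter count (deltas + rates [+ cross] + 4)."""
        return (
            len(self.non_water_labels)
            + self.n_rate_groups
            + len(self.cross_pairs)
            + 4
        )

    def to_frame(self):
        """Pool table (label, anomer, delta_ppm, fraction) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [p.label for p in self.pools],
                "anomer": [p.anomer for p in self.pools],
                "delta_ppm": [p.delta_ppm for p in self.pools],
                "fraction": [p.fraction for p in self.pools],
            }
        )


@dataclass
class ModelParameters:
    """Free parameters of a forward spectrum simulation.

    ``deltas``: ppm offsets from water, one per non-water pool (spec order).
    ``rates``: exchange rate k_ex (1/s) per rate group — the pseudo-first-order
    rate of a proton leaving its -OH site.
    ``baseline_poly``: ascending coefficients (c0, c1, c2) of the quadratic
    baseline added to the normalized segment.
    ``integral_scale``: multiple of the unit-integral normalization, bounded
    to [0.8, 1.2] during fitting.
    """

    deltas: np.ndarray
    rates: np.ndarray
    cross_rates: np.ndarray | None = None
    baseline_poly: np.ndarray = field(default_factory=lambda: np.zeros(3))
    integral_scale: float = 1.0

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.cross_rates is not None:
            self.cross_rates = np.asarray(self.cross_rates, dtype=float)
        self.baseline_poly = np.asarray(self.baseline_poly, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("exchange rates must be non-negative")

    def to_vector(self) -> np.ndarray:
        parts = [self.deltas, self.rates]
        if self.cross_rates is not None:
            parts.append(self.cross_rates)
        parts.append(self.baseline_poly)
        parts.append([self.integral_scale])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    @classmethod
    def from_vector(cls, vec: np.ndarray, spec: ExchangeModelSpec) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        nd = len(spec.non_water_labels)
        ng = spec.n_rate_groups
        nc = len(spec.cross_pairs)
        expect = nd + ng + nc + 4
        if vec.size != expect:
            raise ValueError(f"expected {expect} parameters, got {vec.size}")
        i = 0
        deltas = vec[i : i + nd]; i += nd
        rates = vec[i : i + ng]; i += ng
        cross = vec[i : i + nc] if nc else None; i += nc
        poly = vec[i : i + 3]; i += 3
        scale = float(vec[i])
        return cls(deltas, rates, cross, poly, scale)


@dataclass
class ExchangeMatrix:
    """First-order exchange matrix, column convention: K[i, j] = rate j -> i."""

    K: np.ndarray
    pool_order: list[str]


def _pool_definitions(variant: str) -> tuple[list[tuple[str, str, float]], list[tuple[str, ...]], list[str]]:
    """Non-water pool definitions (label, anomer, protons-per-glucose) plus
    rate-group topology for each variant."""
    if variant == "split_anomeric":
        pools = [
            ("C1_alpha", "alpha", ALPHA_FRACTION),
            ("C1_beta", "beta", BETA_FRACTION),
            ("C2", "shared", 1.0),
            ("C3", "shared", 1.0),
            ("C4", "shared", 1.0),
            ("C6", "shared", 1.0),
        ]
        groups = [("C1_alpha",), ("C1_beta",), ("C2",), ("C3",), ("C4",), ("C6",)]
        names = ["C1_alpha", "C1_beta", "C2", "C3", "C4", "C6"]
    elif variant == "split2":
        # one extra split slot S2; its site identity (C2/C3/C4) is a label only
        pools = [
            ("C1_alpha", "alpha", ALPHA_FRACTION),
            ("C1_beta", "beta", BETA_FRACTION),
            ("S2_alpha", "alpha", ALPHA_FRACTION),
            ("S2_beta", "beta", BETA_FRACTION),
            ("X3", "shared", 1.0),
            ("X4", "shared", 1.0),
            ("C6", "shared", 1.0),
        ]
        groups = [(p[0],) for p in pools]
        names = [p[0] for p in pools]
    elif variant == "split3":
        pools = [
            ("C1_alpha", "alpha", ALPHA_FRACTION),
            ("C1_beta", "beta", BETA_FRACTION),
            ("S2_alpha", "alpha", ALPHA_FRACTION),
            ("S2_beta", "beta", BETA_FRACTION),
            ("S3_alpha", "alpha", ALPHA_FRACTION),
            ("S3_beta", "beta", BETA_FRACTION),
            ("X4", "shared", 1.0),
            ("C6", "shared", 1.0),
        ]
        groups = [(p[0],) for p in pools]
        names = [p[0] for p in pools]
    elif variant in ("restricted", "restricted_cross"):
        pools = [
            ("C1_alpha", "alpha", ALPHA_FRACTION),
            ("C1_beta", "beta", BETA_FRACTION),
            ("C2_alpha", "alpha", ALPHA_FRACTION),
            ("C2_beta", "beta", BETA_FRACTION),
            ("C3_alpha", "alpha", ALPHA_FRACTION),
            ("C3_beta", "beta", BETA_FRACTION),
            ("C4_alpha", "alpha", ALPHA_FRACTION),
            ("C4_beta", "beta", BETA_FRACTION),
            ("C6", "shared", 1.0),
        ]
        groups = [
            ("C1_alpha",),
            ("C1_beta",),
            ("C2_alpha", "C2_beta"),
            ("C3_alpha", "C3_beta"),
            ("C4_alpha", "C4_beta"),
            ("C6",),
        ]
        names = ["C1_alpha", "C1_beta", "C2", "C3", "C4", "C6"]
    else:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}"
        )
    return pools, groups, names


def build_model(
    variant: str,
    glucose_molar: float = 1.0,
    water_proton_molar: float = WATER_PROTON_MOLAR,
) -> ExchangeModelSpec:
    """Enumerate the pools of a model variant with normalized fractions.

    Each split site contributes ``glucose_molar * 0.36`` (alpha) or ``* 0.64``
    (beta) protons, each unsplit site and C6 contribute ``glucose_molar``,
    water contributes ``water_proton_molar``; fractions are the proton
    molarities normalized to sum 1.
    """
    if glucose_molar <= 0 or water_proton_molar <= 0:
        raise ValueError("concentrations must be positive")
    defs, groups, names = _pool_definitions(variant)
    total = _OH_PER_GLUCOSE * glucose_molar + water_proton_molar
    pools = [
        ProtonPool(label, 0.0, protons * glucose_molar / total, anomer)
        for label, anomer, protons in defs
    ]
    pools.append(ProtonPool("water", 0.0, water_proton_molar / total, "water"))
    cross: list[tuple[str, str]] = []
    if variant == "restricted_cross":
        cross = [
            ("C1_alpha", "C2_alpha"),
            ("C2_alpha", "C3_alpha"),
            ("C3_alpha", "C4_alpha"),
            ("C1_beta", "C2_beta"),
            ("C2_beta", "C3_beta"),
            ("C3_beta", "C4_beta"),
        ]
    return ExchangeModelSpec(
        variant=variant,
        pools=pools,
        rate_groups=groups,
        rate_group_names=names,
        cross_pairs=cross,
        glucose_molar=glucose_molar,
        water_proton_molar=water_proton_molar,
    )


def two_site_model(
    solute_fraction: float,
    label: str = "solute",
    water_proton_molar: float = WATER_PROTON_MOLAR,
) -> ExchangeModelSpec:
    """Minimal solute/water two-pool model (e.g. for relaxivity simulations)."""
    if not 0 < solute_fraction < 1:
        raise ValueError("solute fraction must be in (0, 1)")
    pools = [
        ProtonPool(label, 0.0, solute_fraction, "shared"),
        ProtonPool("water", 0.0, 1.0 - solute_fraction, "water"),
    ]
    return ExchangeModelSpec(
        variant="two_site",
        pools=pools,
        rate_groups=[(label,)],
        rate_group_names=[label],
        glucose_molar=solute_fraction * water_proton_molar / (1 - solute_fraction),
        water_proton_molar=water_proton_molar,
    )


def assemble_exchange_matrix(
    spec: ExchangeModelSpec, params: ModelParameters
) -> ExchangeMatrix:
    """Assemble the N x N first-order exchange matrix K.

    For each non-water pool i with group rate k_i, protons leave i to water at
    k_i and return at k_i * f_i / f_water, which closes detailed balance so
    that K @ f = 0 holds by construction.  Cross pairs (i, j) add a direct
    OH-OH route with forward rate k_c out of i and the fraction-scaled reverse
    rate k_c * f_i / f_j out of j.  Columns sum to zero (population
    conservation); the diagonal is minus the column sum.
    """
    if len(params.rates) != spec.n_rate_groups:
        raise ValueError(
            f"expected {spec.n_rate_groups} rates, got {len(params.rates)}"
        )
    if np.any(params.rates < 0):
        raise ValueError("exchange rates must be non-negative")
    n = spec.n_pools
    f = spec.fractions
    w = spec.water_index
    K = np.zeros((n, n))
    for group, k in zip(spec.rate_groups, params.rates):
        for label in group:
            i = spec.pool_index(label)
            K[w, i] += k
            K[i, w] += k * f[i] / f[w]
    if spec.cross_pairs:
        cross = params.cross_rates
        if cross is None:
            cross = np.zeros(len(spec.cross_pairs))
        if len(cross) != len(spec.cross_pairs):
            raise ValueError("cross-rate count does not match cross pairs")
        if np.any(cross < 0):
            raise ValueError("cross rates must be non-negative")
        for (a, b), kc in zip(spec.cross_pairs, cross):
            i, j = spec.pool_index(a), spec.pool_index(b)
            K[j, i] += kc
            K[i, j] += kc * f[i] / f[j]
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=0))
    return ExchangeMatrix(K=K, pool_order=spec.pool_labels)


# -- fitting bounds ------------------------------------------------------------

@dataclass
class ParameterBounds:
    """Per-parameter box bounds aligned with ModelParameters.to_vector order."""

    lower: np.ndarray
    upper: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.upper <= self.lower):
            raise ValueError("upper bounds must exceed lower bounds")

    @property
    def n(self) -> int:
        return self.lower.size

    def contains(self, vec: np.ndarray) -> bool:
        vec = np.asarray(vec)
        return bool(np.all(vec >= self.lower) and np.all(vec <= self.upper))


def _initial_delta_window(label: str) -> tuple[float, float]:
    # broad windows; only the obvious C1 / C6 anchors are non-overlapping
    if label.startswith("C1_alpha"):
        return (1.7, 2.5)
    if label.startswith("C1_beta"):
        return (2.5, 3.2)
    if label == "C6":
        return (0.4, 1.0)
    return (0.9, 1.7)


def parameter_bounds(
    spec: ExchangeModelSpec,
    stage: str = "initial",
    delta_priors: Sequence[float] | dict | None = None,
    delta_halfwidth: float = 0.05,
    k_upper: float = 5.0e4,
    cross_upper: float = 1.0e3,
    baseline_halfwidth: float = 0.5,
) -> ParameterBounds:
    """Box bounds for the MCMC fit.

    ``initial`` returns broad, partly overlapping chemical-shift windows with
    the C1/C6 anchors separated; ``assignment_fixed`` centres a +/-
    ``delta_halfwidth`` window on each prior shift and shrinks neighbouring
    windows to the midpoint between priors so the windows are pairwise
    disjoint, freezing the assignment.  Exchange-rate bounds are wide and
    non-restrictive in both stages; integral_scale is always [0.8, 1.2].
    """
    labels = spec.non_water_labels
    if stage == "initial":
        lows, highs = zip(*[_initial_delta_window(lbl) for lbl in labels])
        d_lo = np.array(lows)
        d_hi = np.array(highs)
    elif stage == "assignment_fixed":
        if delta_priors is None:
            raise ValueError("assignment_fixed stage requires delta_priors")
        if isinstance(delta_priors, dict):
            priors = np.array([delta_priors[lbl] for lbl in labels], dtype=float)
        else:
            priors = np.asarray(delta_priors, dtype=float)
        if priors.size != len(labels):
            raise ValueError("one delta prior per non-water pool required")
        d_lo = priors - delta_halfwidth
        d_hi = priors + delta_halfwidth
        order = np.argsort(priors)
        for a, b in zip(order[:-1], order[1:]):
            mid = 0.5 * (priors[a] + priors[b])
            d_hi[a] = min(d_hi[a], mid)
            d_lo[b] = max(d_lo[b], mid)
    else:
        raise ValueError(f"unknown bounds stage {stage!r}")

    names = [f"delta:{lbl}" for lbl in labels]
    names += [f"k:{g}" for g in spec.rate_group_names]
    lo = [d_lo, np.zeros(spec.n_rate_groups)]
    hi = [d_hi, np.full(spec.n_rate_groups, k_upper)]
    if spec.cross_pairs:
        names += [f"k_cross:{a}-{b}" for a, b in spec.cross_pairs]
        lo.append(np.zeros(len(spec.cross_pairs)))
        hi.append(np.full(len(spec.cross_pairs), cross_upper))
    names += ["baseline:c0", "baseline:c1", "baseline:c2", "integral_scale"]
    lo.append(np.full(3, -baseline_halfwidth))
    hi.append(np.full(3, baseline_halfwidth))
    lo.append([0.8])
    hi.append([1.2])
    return ParameterBounds(
        lower=np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in lo]),
        upper=np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in hi]),
        names=names,
    )
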