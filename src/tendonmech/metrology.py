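"""Measurement-uncertainty propagation and two-sample power analysis.

Instrument calibration gives absolute uncertainties for the displacement
transducer (0.01 mm), the fascicle thickness measurement (0.0025 mm), the
load cell (0.0001 g) and TEM lengths via the diffraction-grating spatial
calibration (0.5 nm).  These propagate to derived quantities through
add-in-quadrature models: for sums/differences
delta_Q = sqrt(sum delta_i^2); for products/quotients
delta_Q = |Q| sqrt(sum (delta_i / a_i)^2), where a squared variable
contributes its relative term twice as two independent entries (so the area
A = pi d^2 / 4 carries sqrt(2) * delta_d / d).  A Monte-Carlo propagation
with Gaussian input errors is available as an independent cross-check.

The power of the between-age-group comparisons uses the two-sample t test
for unequal sample sizes and variances (Welch): power is computed from the
noncentral t distribution with Welch-Satterthwaite degrees of freedom and
noncentrality |mean1 - mean2| / sqrt(sd1^2/n1 + sd2^2/n2).  When a table
reports SEMs, SD = SEM * sqrt(n) recovers the standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError


@dataclass
class UncertainQuantity:
    """A value with an absolute uncertainty in the same units."""

    value: float
    delta: float

    def __post_init__(self):
        if self.delta < 0:
            raise DomainError("uncertainty must be non-negative")

    @property
    def relative(self) -> float:
        return self.delta / abs(self.value) if self.value else math.inf


@dataclass
class InstrumentBudget:
    """Absolute instrument uncertainties of the test rig and TEM."""

    delta_x: float = 0.01        # displacement, mm
    delta_d: float = 0.0025      # fascicle thickness, mm
    delta_P: float = 0.0001      # load, g
    delta_D_tem: float = 0.5     # TEM length, nm

    def __post_init__(self):
        for name in ("delta_x", "delta_d", "delta_P", "delta_D_tem"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


def quad_add(terms: Sequence[float]) -> float:
    """Root-sum-of-squares of absolute uncertainties (sums/differences)."""
    t = np.asarray(terms, dtype=float)
    if np.any(t < 0):
        raise DomainError("uncertainty terms must be non-negative")
    return float(np.sqrt(np.sum(t ** 2)))


def quad_mul(Q: float, rel_terms: Sequence[float]) -> float:
    """delta_Q = |Q| * sqrt(sum rel^2) for products/quotients.

    A squared factor contributes its relative term twice (pass it as two
    entries).
    """
    r = np.asarray(rel_terms, dtype=float)
    if np.any(r < 0):
        raise DomainError("relative terms must be non-negative")
    return float(abs(Q) * np.sqrt(np.sum(r ** 2)))


def uncertainty_budget(x_mm: float, L0_mm: float, d_mm: float, P_g: float,
                       D_nm: float = 400.0,
                       field_w_nm: float = 5000.0, field_h_nm: float = 4000.0,
                       budget: InstrumentBudget | None = None,
                       ) -> dict[str, UncertainQuantity]:
    """Assemble the per-quantity uncertainty budget.

    Term lists (all via :func:`quad_mul` on the relative uncertainties):

    - ``eps`` = x/L0: [dx/x]  (L0 is the nominal gauge length; its
      uncertainty is conventionally not propagated)
    - ``A`` = pi d^2/4: [dd/d, dd/d]
    - ``sigma`` = P/A: [dP/P, dd/d, dd/d]
    - ``E`` = sigma/eps: [d_sigma/sigma, d_eps/eps]
    - ``a_f`` = pi D^2/4: [dD/D, dD/D]
    - ``field_area`` = w*h: [dD/w, dD/h]
    - ``rho`` = sum(a_f)/field_area: [d_a_f/a_f, d_field/field] (single
      fibril's relative term, a conservative bound for the sum)
    """
    if budget is None:
        budget = InstrumentBudget()
    for name, v in (("x", x_mm), ("L0", L0_mm), ("d", d_mm), ("P", P_g),
                    ("D", D_nm)):
        if v <= 0:
            raise DomainError(f"{name} must be positive")
    out: dict[str, UncertainQuantity] = {}

    eps = x_mm / L0_mm
    out["eps"] = UncertainQuantity(eps, quad_mul(eps, [budget.delta_x / x_mm]))

    A = math.pi * d_mm ** 2 / 4.0
    rel_d = budget.delta_d / d_mm
    out["A"] = UncertainQuantity(A, quad_mul(A, [rel_d, rel_d]))

    sigma = P_g * 9.80665e-3 / A
    out["sigma"] = UncertainQuantity(
        sigma, quad_mul(sigma, [budget.delta_P / P_g, rel_d, rel_d]))

    E = sigma / eps
    out["E"] = UncertainQuantity(
        E, quad_mul(E, [out["sigma"].relative, out["eps"].relative]))

    a_f = math.pi * D_nm ** 2 / 4.0
    rel_D = budget.delta_D_tem / D_nm
    out["a_f"] = UncertainQuantity(a_f, quad_mul(a_f, [rel_D, rel_D]))

    field = field_w_nm * field_h_nm
    out["field_area"] = UncertainQuantity(
        field, quad_mul(field, [budget.delta_D_tem / field_w_nm,
                                budget.delta_D_tem / field_h_nm]))

    rho = a_f / field   # representative single-fibril fraction; scales out
    out["rho"] = UncertainQuantity(
        rho, quad_mul(rho, [out["a_f"].relative, out["field_area"].relative]))
    return out


def monte_carlo_budget(x_mm: float, L0_mm: float, d_mm: float, P_g: float,
                       budget: InstrumentBudget | None = None,
                       n: int = 100_000, seed: int = 0,
                       ) -> dict[str, float]:
    """Monte-Carlo cross-check of the eps/sigma quadrature deltas.

    Draws Gaussian input errors and returns the sample SD of the derived
    quantities; agrees with the quadrature model to first order.
    """
    if budget is None:
        budget = InstrumentBudget()
    rng = np.random.default_rng(seed)
    x = x_mm + rng.normal(0, budget.delta_x, n)
    d = d_mm + rng.normal(0, budget.delta_d, n)
    d2 = d_mm + rng.normal(0, budget.delta_d, n)   # two independent d factors
    P = P_g + rng.normal(0, budget.delta_P, n)
    eps = x / L0_mm
    A = math.pi * d * d2 / 4.0
    sigma = P * 9.80665e-3 / A
    return {"eps": float(eps.std(ddof=1)), "sigma": float(sigma.std(ddof=1))}


# ---------------------------------------------------------------------------
# Welch two-sample power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Two-sample comparison: group means, SDs and sizes."""

    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise DomainError("need n >= 2 per group")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0,1)")
        if self.sides not in (1, 2):
            raise DomainError("sides must be 1 or 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise DomainError("SDs must be non-negative")
        if self.sd1 == 0 and self.sd2 == 0:
            raise DomainError("both group variances are zero")


def sd_from_sem(sem: float, n: int) -> float:
    """Recover SD from a reported standard error: SD = SEM * sqrt(n)."""
    return sem * math.sqrt(n)


def welch_df(sd1: float, sd2: float, n1: int, n2: int) -> float:
    """Welch-Satterthwaite degrees of freedom."""
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    return (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))


def welch_power(spec: PowerSpec) -> float:
    """Analytic power of the Welch t test from the noncentral t."""
    v1, v2 = spec.sd1 ** 2 / spec.n1, spec.sd2 ** 2 / spec.n2
    se = math.sqrt(v1 + v2)
    nc = abs(spec.mean1 - spec.mean2) / se
    df = welch_df(spec.sd1, spec.sd2, spec.n1, spec.n2)
    if spec.sides == 2:
        tc = stats.t.ppf(1 - spec.alpha / 2, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def monte_carlo_power(spec: PowerSpec, n_rep: int = 20_000,
                      seed: int = 0) -> float:
    """Simulated Welch-test rejection rate (independent check of the
    analytic power)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(spec.mean1, spec.sd1, size=(n_rep, spec.n1))
    y = rng.normal(spec.mean2, spec.sd2, size=(n_rep, spec.n2))
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) / spec.n1
    v2 = y.var(axis=1, ddof=1) / spec.n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (spec.n1 - 1) + v2 ** 2 / (spec.n2 - 1))
    if spec.sides == 2:
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        sign = np.sign(spec.mean1 - spec.mean2) or 1.0
        p = stats.t.sf(sign * t, df)
    return float(np.mean(p < spec.alpha))
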