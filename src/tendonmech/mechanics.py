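"""Tensile property derivation for tendon fascicle load-displacement traces.

The pipeline mirrors the classical fascicle workflow: a slack-to-taut trace
is zeroed at the load-cutoff point (1% of maximum load by default), the
displacement at that point defines the nominal gauge length L0, and the
zeroed record is converted to engineering stress and strain

    sigma = P / A   (MPa, with A = pi d^2 / 4 in mm^2 and P in gram-force)
    eps   = x / L0

Four landmarks structure the curve: the origin O, the point of inflexion p
(max dsigma/deps; its stress/strain are the yield stress sigma_Y and yield
strain eps_Y, and the slope there is the reported stiffness E), the maximum
stress q (strength sigma_U at strain eps_U), and the rupture point r.
Strain-energy densities (MPa = MJ/m^3) are trapezium-rule integrals of
sigma deps over the segments O-p (resilience u_Y), p-q (plastic loading
u_P), q-r (rupture u_R); u_F = u_P + u_R and u_0 = u_Y + u_F, both exact by
shared-endpoint construction.

dsigma/deps is evaluated by central finite differences of a least-squares
polynomial (degree `orderpoly`, 2-7) fitted to the O-q segment; smoothing
the measured curve before differencing is what makes yield detection usable
on noisy low-load data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateTraceError,
    GeometryError,
    IntegrationError,
    NumericError,
    PipelineError,
)
from .io import LoadDisplacementTrace

#: standard gravity, N per gram-force (so MPa = g * this / mm^2)
GRAM_FORCE_TO_NEWTON = 9.80665e-3


@dataclass
class FascicleGeometry:
    """Specimen geometry: mean thickness d (mm, mean of 6 repeats) and area."""

    d: float
    d_sem: float | None = None
    L0: float | None = None

    def __post_init__(self):
        if self.d <= 0:
            raise GeometryError(f"thickness must be positive, got {self.d}")

    @property
    def A(self) -> float:
        """Cross-sectional area, mm^2, assuming a circular profile."""
        return math.pi * self.d ** 2 / 4.0


@dataclass
class AnalysisConfig:
    """Inputs of one tensile analysis (mirrors the classic tool's prompts)."""

    diameter: float                    # fascicle thickness d, mm
    laststrainpt: float                # estimated strain at rupture
    orderpoly: int = 5                 # polynomial degree, 2-7
    loadat1percent: bool = True        # automatic zeroing at 1% of max load
    manual_start_index: int | None = None   # used when loadat1percent=False
    load_cutoff_fraction: float = 0.01
    gram_force_to_newton: float = GRAM_FORCE_TO_NEWTON

    def __post_init__(self):
        if not 2 <= int(self.orderpoly) <= 7:
            raise ConfigurationError(
                f"orderpoly must be an integer in 2..7, got {self.orderpoly}")
        if not 0 < self.load_cutoff_fraction < 1:
            raise ConfigurationError("load_cutoff_fraction must be in (0,1)")
        if not self.loadat1percent and self.manual_start_index is None:
            raise ConfigurationError(
                "manual truncation mode needs manual_start_index")


@dataclass
class StressStrainCurve:
    """Zeroed, unit-converted sigma-eps samples with landmark indices."""

    strain: np.ndarray
    stress: np.ndarray
    L0: float
    A: float
    O: int = 0
    p: int | None = None
    q: int | None = None
    r: int | None = None

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain[self.O] != 0.0 or self.stress[self.O] != 0.0:
            raise ContractError("curve must start at (0, 0)")
        if not np.all(np.diff(self.strain) >= 0):
            raise ContractError("strain must be non-decreasing")


@dataclass
class MechanicalProperties:
    """The full per-specimen property set."""

    sigma_Y: float
    eps_Y: float
    E: float
    sigma_U: float
    eps_U: float
    u_Y: float
    u_P: float
    u_R: float
    u_F: float
    u_0: float
    ratio_Y: float      # u_Y / sigma_Y
    ratio_F: float      # u_F / sigma_U
    warnings: tuple[str, ...] = ()

    def as_sheet_values(self) -> dict[str, float]:
        """Column map matching the 'Derived parameters' worksheet."""
        return {"sY": self.sigma_Y, "eY": self.eps_Y, "E": self.E,
                "sU": self.sigma_U, "eU": self.eps_U,
                "uY": self.u_Y, "uP": self.u_P, "uR": self.u_R,
                "uF": self.u_F, "u0": self.u_0,
                "uY/sY": self.ratio_Y, "uF/sU": self.ratio_F}


@dataclass
class ZeroedTrace:
    disp_mm: np.ndarray     # zeroed: 0 at the new origin
    load_g: np.ndarray      # zeroed likewise
    L0: float               # displacement (mm) at the zero-load point


def zero_trace(trace: LoadDisplacementTrace,
               cfg: AnalysisConfig) -> ZeroedTrace:
    """Remove the slack region and define the origin and gauge length.

    With ``loadat1percent`` the origin is the first sample whose load is at
    or above ``load_cutoff_fraction`` x max load; otherwise the caller's
    ``manual_start_index`` is used (the manual fallback for noisy low-load
    data).  L0 is the grip-to-grip displacement at that origin.
    """
    load = trace.load_g
    disp = trace.disp_mm
    if cfg.loadat1percent:
        max_load = load.max()
        if max_load <= 0:
            raise DegenerateTraceError(
                f"{trace.specimen_id}: max load {max_load} g; cannot zero")
        cutoff = cfg.load_cutoff_fraction * max_load
        above = np.nonzero(load >= cutoff)[0]
        if len(above) == 0:
            raise DegenerateTraceError(
                f"{trace.specimen_id}: no sample reaches the load cutoff")
        i0 = int(above[0])
    else:
        i0 = int(cfg.manual_start_index)
        if not 0 <= i0 < len(load) - 1:
            raise ConfigurationError(
                f"manual_start_index {i0} outside trace of length {len(load)}")
    L0 = float(disp[i0])
    if L0 <= 0:
        raise GeometryError(
            f"{trace.specimen_id}: gauge length L0={L0} mm is not positive")
    return ZeroedTrace(disp_mm=disp[i0:] - disp[i0],
                       load_g=load[i0:] - load[i0], L0=L0)


def to_stress_strain(zeroed: ZeroedTrace,
                     geometry: FascicleGeometry | None,
                     cfg: AnalysisConfig) -> StressStrainCurve:
    """Convert a zeroed record to engineering stress (MPa) and strain."""
    if geometry is None:
        geometry = FascicleGeometry(d=cfg.diameter)
    A = geometry.A
    if A <= 0:
        raise GeometryError(f"cross-sectional area {A} mm^2 is not positive")
    if zeroed.L0 <= 0:
        raise GeometryError(f"gauge length {zeroed.L0} mm is not positive")
    strain = zeroed.disp_mm / zeroed.L0
    stress = zeroed.load_g * cfg.gram_force_to_newton / A
    return StressStrainCurve(strain=strain, stress=stress,
                             L0=zeroed.L0, A=A)


@dataclass
class YieldResult:
    p: int
    sigma_Y: float
    eps_Y: float
    E: float
    boundary_warning: bool = False


def locate_max_stress(curve: StressStrainCurve) -> int:
    """Index q of the maximum stress (strength); earliest on ties."""
    return int(np.argmax(curve.stress))


def locate_yield(curve: StressStrainCurve, orderpoly: int) -> YieldResult:
    """Find the point of inflexion p (max dsigma/deps on [O, q]).

    A least-squares polynomial of degree `orderpoly` is fitted to the
    sigma-eps samples from the origin to the maximum stress; dsigma/deps is
    evaluated by central finite differences (one-sided at the ends) of the
    fitted curve on the sample grid.  p is the argmax (earliest index on
    ties, so the constant-gradient case is deterministic); E is the
    derivative there; sigma_Y/eps_Y are read from the fitted curve at p.
    """
    q = curve.q if curve.q is not None else locate_max_stress(curve)
    eps = curve.strain[:q + 1]
    sig = curve.stress[:q + 1]
    if len(eps) < orderpoly + 2:
        raise NumericError(
            f"{len(eps)} samples on [O,q]; need >= orderpoly+2 = {orderpoly + 2}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            poly = np.polynomial.Polynomial.fit(eps, sig, int(orderpoly))
        except np.exceptions.RankWarning as exc:
            raise NumericError(f"polynomial fit is rank deficient: {exc}")
    fitted = poly(eps)
    dsde = np.gradient(fitted, eps)
    # earliest index among numerical ties (constant-gradient curves)
    tol = 1e-9 * max(abs(dsde.max()), 1.0)
    p = int(np.argmax(dsde >= dsde.max() - tol))
    return YieldResult(p=p, sigma_Y=float(fitted[p]), eps_Y=float(eps[p]),
                       E=float(dsde[p]),
                       boundary_warning=(p == 0 or p == q))


def locate_rupture(curve: StressStrainCurve,
                   laststrainpt: float) -> tuple[int, bool]:
    """Index r of the rupture point.

    r is the last sample with eps <= laststrainpt when that estimate lies
    beyond the maximum-stress strain; otherwise (or when the estimate
    exceeds the record) r falls back to the final sample, with a warning
    flag in the first case.
    """
    q = curve.q if curve.q is not None else locate_max_stress(curve)
    last = len(curve.strain) - 1
    if laststrainpt <= curve.strain[q]:
        return last, bool(laststrainpt < curve.strain[q])
    within = np.nonzero(curve.strain <= laststrainpt)[0]
    r = int(within[-1]) if len(within) else last
    return max(r, q), False


def strain_energy_partition(curve: StressStrainCurve, p: int, q: int,
                            r: int) -> tuple[float, float, float, float, float]:
    """Trapezium-rule strain-energy densities (u_Y, u_P, u_R, u_F, u_0).

    Segments share endpoint samples, so u_0 = u_Y + u_P + u_R holds to
    machine precision by construction.
    """
    O = curve.O
    if not O <= p <= q <= r:
        raise ContractError(f"landmarks must satisfy O<=p<=q<=r, got "
                            f"{O},{p},{q},{r}")
    eps, sig = curve.strain, curve.stress
    for a, b, name in ((O, p, "O-p"), (p, q, "p-q"), (q, r, "q-r")):
        if np.any(np.diff(eps[a:b + 1]) < 0):
            raise IntegrationError(f"strain not monotone on segment {name}")

    def seg(a: int, b: int) -> float:
        if b <= a:
            return 0.0
        return float(np.trapezoid(sig[a:b + 1], eps[a:b + 1]))

    u_Y, u_P, u_R = seg(O, p), seg(p, q), seg(q, r)
    u_F = u_P + u_R
    u_0 = u_Y + u_F
    return u_Y, u_P, u_R, u_F, u_0


def derive_properties(trace: LoadDisplacementTrace, cfg: AnalysisConfig,
                      geometry: FascicleGeometry | None = None,
                      ) -> tuple[MechanicalProperties, StressStrainCurve]:
    """Full per-specimen pipeline: zero, convert, locate landmarks, integrate.

    Errors from any stage are re-raised as :class:`PipelineError` carrying
    the stage name.
    """
    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc)

    zeroed = _stage("zero_trace", zero_trace, trace, cfg)
    curve = _stage("to_stress_strain", to_stress_strain, zeroed, geometry, cfg)
    curve.q = _stage("locate_max_stress", locate_max_stress, curve)
    yr = _stage("locate_yield", locate_yield, curve, cfg.orderpoly)
    curve.p = yr.p
    r, rupture_warn = _stage("locate_rupture", locate_rupture, curve,
                             cfg.laststrainpt)
    curve.r = r
    u_Y, u_P, u_R, u_F, u_0 = _stage(
        "strain_energy_partition", strain_energy_partition,
        curve, curve.p, curve.q, curve.r)
    warns = []
    if yr.boundary_warning:
        warns.append("yield point at grid boundary")
    if rupture_warn:
        warns.append("laststrainpt below maximum-stress strain; "
                     "rupture set to final sample")
    sigma_U = float(curve.stress[curve.q])
    props = MechanicalProperties(
        sigma_Y=yr.sigma_Y, eps_Y=yr.eps_Y, E=yr.E,
        sigma_U=sigma_U, eps_U=float(curve.strain[curve.q]),
        u_Y=u_Y, u_P=u_P, u_R=u_R, u_F=u_F, u_0=u_0,
        ratio_Y=u_Y / yr.sigma_Y if yr.sigma_Y else float("nan"),
        ratio_F=u_F / sigma_U if sigma_U else float("nan"),
        warnings=tuple(warns))
    return props, curve


def aggregate(specimens: pd.DataFrame,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-level averaging: specimen -> tail (mouse) -> age group.

    `specimens` must carry columns ``age_group``, ``sample`` (the mouse/tail
    id) plus numeric property columns.  Fascicle segments are technical
    replicates: they are first averaged within each tail, then tail means
    are averaged within each age group.  Group dispersion is the SEM over
    tails (n = number of mice, not specimens); a single-tail group reports a
    missing SEM.
    """
    required = {"age_group", "sample"}
    if not required <= set(specimens.columns):
        raise ContractError(f"specimen table needs columns {sorted(required)}")
    if len(specimens) == 0:
        raise ContractError("no specimens to aggregate")
    props = [c for c in specimens.columns if c not in required]
    tails = (specimens.groupby(["age_group", "sample"], sort=True)[props]
             .mean().reset_index())
    g = tails.groupby("age_group", sort=True)[props]
    means = g.mean()
    sems = g.sem(ddof=1)       # NaN when a group has a single tail
    groups = pd.concat(
        [means.add_prefix("mean_"), sems.add_prefix("sem_")],
        axis=1).reset_index()
    return tails, groups


def plot_diagnostic(curve: StressStrainCurve, path: str) -> None:
    """Optional diagnostic figure of the curve and its landmarks.

    Replaces the by-eye confirmation of the zeroing cutoff; requires
    matplotlib (the ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.strain, curve.stress, lw=0.8, color="0.3")
    for idx, name in ((curve.O, "O"), (curve.p, "p"),
                      (curve.q, "q"), (curve.r, "r")):
        if idx is not None:
            ax.plot(curve.strain[idx], curve.stress[idx], "o", ms=4)
            ax.annotate(name, (curve.strain[idx], curve.stress[idx]),
                        textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("strain")
    ax.set_ylabel("stress (MPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
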