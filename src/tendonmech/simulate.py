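"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, each a pure function of its parameters (seed included):

``simulate_trace``
    A slack-then-taut load-displacement record in the mtt dialect.  The
    pre-peak stress-strain segment is a single quintic with analytically
    prescribed landmarks -- sigma(0) = 0, a gentle toe-start slope, maximum
    slope E_true exactly at (eps_Y, sigma_Y), zero slope at the peak
    (eps_U, sigma_U) -- followed by a linear post-peak decay to rupture.
    Choosing one smooth closed-form family keeps every derived property
    (including the trapezium energies) analytically known, so recovery by
    the analysis pipeline can be scored exactly.  Displacement is absolute
    grip-to-grip travel (the gauge length L0 is the displacement where the
    specimen goes taut); the mV signal columns are affine maps of the
    physical columns, and Gaussian sensor noise is added to the load.

``simulate_diameters``
    Fibril diameters from a two-component Gaussian mixture at the scales
    seen in aged mouse tail tendon, with per-draw component bookkeeping.

``simulate_field``
    A 4x5 um^2 field of non-overlapping circular fibrils placed by
    rejection sampling until a target area fraction is reached; discs
    crossing the field boundary are clipped and their clipped area counted,
    mirroring how part fibrils at a micrograph edge are traced.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, box

from .errors import FeasibilityError, ParameterError
from .fibrils import FibrilImageRecord
from .io import LoadDisplacementTrace
from .mechanics import GRAM_FORCE_TO_NEWTON


@dataclass
class TraceParams:
    """Ground-truth mechanical landmarks and acquisition settings."""

    E_true: float = 600.0        # stiffness (max slope), MPa
    sigmaU_true: float = 27.0    # strength, MPa
    epsY_true: float = 0.05      # strain at the max-slope point
    epsU_true: float = 0.09      # strain at maximum stress
    rupture_eps: float = 0.13
    slack_mm: float = 0.5        # pre-taut crosshead travel
    noise_sd_g: float = 0.3      # load sensor noise, grams
    d: float = 0.3               # fascicle thickness, mm
    L0: float = 5.0              # gauge length (taut grip-to-grip), mm
    rate: float = 0.067          # crosshead rate, mm/s
    sample_hz: float = 20.0
    toe_slope_frac: float = 0.2  # toe-start slope as a fraction of E_true
    end_stress_frac: float = 0.2  # stress at rupture as a fraction of sigma_U
    disp_gain_mv: float = 400.0  # mV per mm (affine signal map)
    disp_offset_mv: float = -120.0
    load_gain_mv: float = 2.5    # mV per gram
    load_offset_mv: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.epsY_true < self.epsU_true < self.rupture_eps:
            raise ParameterError(
                "landmarks must satisfy 0 < epsY < epsU < rupture_eps")
        for name in ("E_true", "sigmaU_true", "d", "L0", "rate", "sample_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.slack_mm < 0 or self.noise_sd_g < 0:
            raise ParameterError("slack and noise must be non-negative")


@dataclass
class TraceGroundTruth:
    """Analytic values of every property the pipeline derives."""

    E: float
    sigma_Y: float
    eps_Y: float
    sigma_U: float
    eps_U: float
    u_Y: float
    u_P: float
    u_R: float
    u_F: float
    u_0: float
    L0: float
    A: float


def _prepeak_quintic(p: TraceParams) -> np.polynomial.Polynomial:
    """Quintic sigma(eps) on [0, epsU] with the prescribed landmarks.

    Conditions: sigma(0)=0, sigma'(0)=toe_slope_frac*E, sigma'(epsY)=E,
    sigma''(epsY)=0 (so the max slope sits exactly at epsY), sigma'(epsU)=0,
    sigma(epsU)=sigmaU.
    """
    eY, eU = p.epsY_true, p.epsU_true
    E, sU = p.E_true, p.sigmaU_true

    def val(e): return [e ** i for i in range(6)]
    def der(e): return [0.0] + [i * e ** (i - 1) for i in range(1, 6)]
    def der2(e): return [0.0, 0.0] + [i * (i - 1) * e ** (i - 2)
                                      for i in range(2, 6)]
    M = np.array([val(0.0), der(0.0), der(eY), der2(eY), der(eU), val(eU)])
    b = np.array([0.0, p.toe_slope_frac * E, E, 0.0, 0.0, sU])
    coeffs = np.linalg.solve(M, b)
    poly = np.polynomial.Polynomial(coeffs)
    grid = np.linspace(0.0, eU, 2001)
    dvals = poly.deriv()(grid)
    if dvals.min() < -1e-6 * E:
        raise ParameterError(
            "infeasible landmark combination: pre-peak stress not monotone "
            "(try a larger toe_slope_frac or smaller E*epsY/sigmaU)")
    if dvals.max() > E * (1 + 1e-6):
        raise ParameterError(
            "infeasible landmark combination: pre-peak slope exceeds E_true "
            "away from the yield point")
    return poly


def trace_stress(p: TraceParams, eps: np.ndarray) -> np.ndarray:
    """Noise-free stress (MPa) at the given true strains."""
    poly = _prepeak_quintic(p)
    eU, erup, sU = p.epsU_true, p.rupture_eps, p.sigmaU_true
    post = sU * (1 - (1 - p.end_stress_frac) * (eps - eU) / (erup - eU))
    return np.where(eps <= 0, 0.0,
                    np.where(eps <= eU, poly(np.clip(eps, 0.0, eU)), post))


def _ground_truth(p: TraceParams) -> TraceGroundTruth:
    poly = _prepeak_quintic(p)
    eY, eU, erup, sU = (p.epsY_true, p.epsU_true, p.rupture_eps,
                        p.sigmaU_true)
    anti = poly.integ()
    u_Y = float(anti(eY) - anti(0.0))
    u_P = float(anti(eU) - anti(eY))
    u_R = 0.5 * (sU + p.end_stress_frac * sU) * (erup - eU)
    A = math.pi * p.d ** 2 / 4.0
    return TraceGroundTruth(
        E=p.E_true, sigma_Y=float(poly(eY)), eps_Y=eY,
        sigma_U=sU, eps_U=eU,
        u_Y=u_Y, u_P=u_P, u_R=u_R, u_F=u_P + u_R, u_0=u_Y + u_P + u_R,
        L0=p.L0, A=A)


def simulate_trace(p: TraceParams,
                   specimen_id: str = "mtt01_1_t1a",
                   ) -> tuple[LoadDisplacementTrace, TraceGroundTruth]:
    """Generate one mtt-dialect trace plus its analytic ground truth."""
    truth = _ground_truth(p)
    rng = np.random.default_rng(p.seed)
    travel_total = p.slack_mm + p.rupture_eps * p.L0
    n = max(int(round(travel_total / p.rate * p.sample_hz)), 8)
    t_s = np.arange(n) / p.sample_hz
    travel = t_s * p.rate
    disp_mm = (p.L0 - p.slack_mm) + travel      # absolute grip-to-grip
    eps = (disp_mm - p.L0) / p.L0               # negative while slack
    sigma = trace_stress(p, eps)
    load_g = sigma * truth.A / GRAM_FORCE_TO_NEWTON
    if p.noise_sd_g > 0:
        load_g = load_g + rng.normal(0.0, p.noise_sd_g, n)
    trace = LoadDisplacementTrace(
        specimen_id=specimen_id,
        time_ms=t_s * 1000.0,
        disp_signal_mv=disp_mm * p.disp_gain_mv + p.disp_offset_mv,
        load_signal_mv=load_g * p.load_gain_mv + p.load_offset_mv,
        disp_mm=disp_mm,
        load_g=load_g)
    return trace, truth


# ---------------------------------------------------------------------------
# Fibril-diameter mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureParams:
    """Two-component diameter mixture at aged-tendon scales (nm)."""

    mu1: float = 100.0
    mu2: float = 250.0
    sd1: float = 30.0
    sd2: float = 50.0
    weight1: float = 0.5
    n: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not self.mu1 < self.mu2:
            raise ParameterError("mu1 must be below mu2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ParameterError("SDs must be positive")
        if not 0 < self.weight1 < 1:
            raise ParameterError("weight1 must be in (0,1)")


@dataclass
class DiameterGroundTruth:
    params: MixtureParams
    component: np.ndarray        # 0/1 label per draw


def simulate_diameters(p: MixtureParams,
                       ) -> tuple[np.ndarray, DiameterGroundTruth]:
    """Draw n diameters; negative draws are redrawn; labels are bookkept."""
    rng = np.random.default_rng(p.seed)
    comp = (rng.random(p.n) >= p.weight1).astype(int)
    mu = np.where(comp == 0, p.mu1, p.mu2)
    sd = np.where(comp == 0, p.sd1, p.sd2)
    d = rng.normal(mu, sd)
    bad = d <= 0
    while np.any(bad):
        d[bad] = rng.normal(mu[bad], sd[bad])
        bad = d <= 0
    return d, DiameterGroundTruth(params=p, component=comp)


# ---------------------------------------------------------------------------
# Packed-disc fibril fields
# ---------------------------------------------------------------------------

@dataclass
class FieldParams:
    """A synthetic micrograph field of non-overlapping circular fibrils."""

    width: float = 5000.0        # nm
    height: float = 4000.0       # nm
    target_rho: float = 0.5
    mixture: MixtureParams = field(default_factory=MixtureParams)
    seed: int = 0
    max_attempts: int = 100_000

    def __post_init__(self):
        if not 0 < self.target_rho < 0.91:
            raise ParameterError(
                "target_rho must be in (0, 0.91): random disc packings jam "
                "below the 0.91 feasibility cap")
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("field dimensions must be positive")


def simulate_field(p: FieldParams, image_id: str = "Scan001",
                   ) -> tuple[FibrilImageRecord, float]:
    """Place non-overlapping discs until the target area fraction is met.

    Disc diameters are drawn from the mixture; centres are uniform over the
    field, so discs may cross the boundary, in which case the clipped area
    is counted toward rho (and the fibril flagged as non-interior).  The
    returned rho ground truth is the exact bookkept ratio.  Exhausting the
    attempt budget raises :class:`FeasibilityError` with a hint to lower
    the target.
    """
    rng = np.random.default_rng(p.seed)
    W, H = p.width, p.height
    field_area = W * H
    frame = box(0.0, 0.0, W, H)
    cap = 4 * p.max_attempts  # generous array bound
    xs = np.empty(0)
    ys = np.empty(0)
    rs = np.empty(0)
    areas: list[float] = []
    interior: list[bool] = []
    total = 0.0
    attempts = 0
    while total / field_area < p.target_rho:
        if attempts >= p.max_attempts:
            raise FeasibilityError(
                f"reached rho={total / field_area:.3f} after "
                f"{attempts} attempts; lower target_rho (requested "
                f"{p.target_rho})")
        attempts += 1
        comp = rng.random() >= p.mixture.weight1
        D = rng.normal(p.mixture.mu2 if comp else p.mixture.mu1,
                       p.mixture.sd2 if comp else p.mixture.sd1)
        if D <= 0:
            continue
        r = D / 2.0
        x, y = rng.random() * W, rng.random() * H
        if len(rs) and np.any((xs - x) ** 2 + (ys - y) ** 2
                              < (rs + r) ** 2):
            continue
        fully_inside = (x - r >= 0 and y - r >= 0
                        and x + r <= W and y + r <= H)
        if fully_inside:
            a = math.pi * r * r
        else:
            a = Point(x, y).buffer(r, quad_segs=128).intersection(frame).area
            if a <= 0:
                continue
        xs = np.append(xs, x)
        ys = np.append(ys, y)
        rs = np.append(rs, r)
        areas.append(a)
        interior.append(fully_inside)
        total += a
    record = FibrilImageRecord(
        image_id=image_id, field_area=field_area,
        fibril_areas=np.array(areas), interior=np.array(interior))
    return record, total / field_area


# ---------------------------------------------------------------------------
# Sidecar ground-truth serialisation
# ---------------------------------------------------------------------------

def write_ground_truth(truth, path: str | Path) -> None:
    """Write a generator's ground truth as a JSON sidecar."""
    if hasattr(truth, "component"):
        payload = {"params": asdict(truth.params),
                   "component": truth.component.tolist()}
    elif hasattr(truth, "__dataclass_fields__"):
        payload = asdict(truth)
    else:
        payload = dict(truth)
    Path(path).write_text(json.dumps(payload, indent=1))
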