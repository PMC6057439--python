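"""Two-Gaussian finite-mixture fitting of fibril-diameter histograms by
simulated annealing.

Tendon fibril-diameter histograms are typically bimodal; the fitted model is
a linear combination of unit-amplitude Gaussian profiles

    f(x) = sum_i amp_i * exp(-(x - mu_i)^2 / (2 sigma_i^2))

evaluated on the histogram bin centres.  For a candidate (mu, sigma)
configuration the amplitudes are solved by non-negative least squares
against the *normalised* frequencies (amplitudes are proportions and must
not be negative); the objective is the residual sum of squares.  The
annealer proposes new parameter values through the affine maps
value = A + B*u with u ~ uniform(0,1) (the MUA/MUB and SDA/SDB coefficient
pairs of the classic parameter file), clipped to the [lower, upper]
diameter limits; one randomly chosen parameter is redrawn per move.
Moves are accepted by the Metropolis rule (always when the objective
improves, else with probability exp(-delta/T)); after NSUCCLIMIT
acceptances or NCONFIG proposals the temperature is multiplied by Tfactr
and the next of NTRIALS steps begins.  The best configuration ever seen is
returned with components sorted so D_D1 < D_D2, and an initial run is
conventionally followed by a refinement run with proposal ranges narrowed
around the first estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateFitError,
    DomainError,
)
from .io import FibrilHistogram


@dataclass
class SAConfig:
    """Annealing schedule and proposal ranges (classic parameter-file keys).

    ``mua[i] + mub[i] * u`` with u ~ uniform(0,1) generates mean proposals
    for component i (``sda``/``sdb`` likewise for the SDs), clipped to
    [lower, upper]; ``mu_init``/``sd_init`` seed the chain.
    """

    lower: float                    # fibril-diameter limits, nm
    upper: float
    mu_init: tuple[float, ...]
    sd_init: tuple[float, ...]
    mua: tuple[float, ...]
    mub: tuple[float, ...]
    sda: tuple[float, ...]
    sdb: tuple[float, ...]
    nconfig: int = 100              # max configurations per temperature
    nsucclimit: int = 10            # acceptances before the next temperature
    ntrials: int = 100              # temperature steps
    seed: int = 0
    temperature: float = 0.5        # initial T
    tfactr: float = 0.9             # temperature reduction factor
    ngauss: int = 2
    nonneg: bool = True             # amplitudes by NNLS (plain LS if False)

    def __post_init__(self):
        if not 0 < self.tfactr < 1:
            raise ConfigurationError("Tfactr must be in (0,1)")
        if self.temperature <= 0:
            raise ConfigurationError("Temperature must be positive")
        if self.lower >= self.upper:
            raise ConfigurationError("lower must be below upper")
        for name in ("mu_init", "sd_init", "mua", "mub", "sda", "sdb"):
            if len(getattr(self, name)) != self.ngauss:
                raise ConfigurationError(
                    f"{name} must have {self.ngauss} entries")
        for i in range(self.ngauss):
            lo = min(self.mua[i], self.mua[i] + self.mub[i])
            hi = max(self.mua[i], self.mua[i] + self.mub[i])
            if hi < self.lower or lo > self.upper:
                raise ConfigurationError(
                    f"mean proposal range for component {i} lies entirely "
                    f"outside [{self.lower}, {self.upper}]")
            if self.sda[i] + max(self.sdb[i], 0.0) <= 0:
                raise ConfigurationError(
                    f"SD proposal range for component {i} is non-positive")

    @classmethod
    def from_histogram(cls, hist: FibrilHistogram, seed: int = 0,
                       ngauss: int = 2, **overrides) -> "SAConfig":
        """Default configuration derived from the histogram support.

        The diameter limits span the occupied bins; the mean proposal range
        of each component covers one of ``ngauss`` equal slices of that
        span (small-diameter component first), and SD proposals span half a
        bin width up to a third of the full span.
        """
        occupied = np.nonzero(hist.freq > 0)[0]
        if len(occupied) == 0:
            raise DataError("histogram is empty")
        lower = float(hist.bin_edges[occupied[0]])
        upper = float(hist.bin_edges[occupied[-1] + 1])
        span = upper - lower
        sd_lo = hist.bin_width / 2.0
        sd_hi = max(span / 3.0, sd_lo * 2)
        slice_w = span / ngauss
        mua = tuple(lower + i * slice_w for i in range(ngauss))
        mub = (slice_w,) * ngauss
        kwargs = dict(
            lower=lower, upper=upper,
            mu_init=tuple(lower + (i + 0.5) * slice_w for i in range(ngauss)),
            sd_init=((sd_lo + sd_hi) / 2,) * ngauss,
            mua=mua, mub=mub,
            sda=(sd_lo,) * ngauss, sdb=(sd_hi - sd_lo,) * ngauss,
            seed=seed, ngauss=ngauss)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class MixtureFit:
    """Fitted subpopulations, sorted so mu[0] = D_D1 < D_D2 = mu[1]."""

    mu: tuple[float, ...]           # nm
    sigma: tuple[float, ...]        # nm
    amplitude: tuple[float, ...]    # proportion weights, >= 0
    objective: float                # SSE against the normalised histogram
    trace: tuple[float, ...]        # best objective after each temperature step

    def composite(self, x: np.ndarray) -> np.ndarray:
        G = _component_matrix(np.asarray(x, dtype=float),
                              np.array(self.mu), np.array(self.sigma))
        return G @ np.array(self.amplitude)


def gaussian_component(x, mu: float, sigma: float):
    """Unit-amplitude Gaussian profile exp(-(x-mu)^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    xv = np.asarray(x, dtype=float)
    out = np.exp(-((xv - mu) ** 2) / (2.0 * sigma ** 2))
    return float(out) if np.isscalar(x) else out


def _component_matrix(x: np.ndarray, mu: np.ndarray,
                      sd: np.ndarray) -> np.ndarray:
    return np.exp(-((x[:, None] - mu[None, :]) ** 2)
                  / (2.0 * sd[None, :] ** 2))


def solve_amplitudes(norm_freq: np.ndarray, components: np.ndarray,
                     nonneg: bool = True) -> np.ndarray:
    """Least-squares amplitudes of the composite against the histogram.

    `components` has one column per Gaussian evaluated on the bin centres.
    Non-negative least squares by default; identical (rank-deficient)
    components raise :class:`DegenerateFitError`.
    """
    y = np.asarray(norm_freq, dtype=float)
    G = np.asarray(components, dtype=float)
    if G.ndim != 2 or G.shape[0] != len(y):
        raise DataError("component matrix shape mismatch")
    if G.shape[0] < 2:
        raise DataError("need at least two bins")
    if np.linalg.matrix_rank(G, tol=1e-10) < G.shape[1]:
        raise DegenerateFitError("component matrix is rank deficient "
                                 "(identical components?)")
    if nonneg:
        amp, _ = nnls(G, y)
    else:
        amp, *_ = np.linalg.lstsq(G, y, rcond=None)
    return amp


def metropolis_accept(delta: float, T: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: accept improvements; else with prob exp(-delta/T)."""
    if T <= 0:
        raise DomainError("temperature must be positive")
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / T))


def _objective(x: np.ndarray, y: np.ndarray, mu: np.ndarray, sd: np.ndarray,
               nonneg: bool) -> tuple[float, np.ndarray]:
    G = _component_matrix(x, mu, sd)
    if nonneg:
        amp, rnorm = nnls(G, y)
        return float(rnorm ** 2), amp
    amp, *_ = np.linalg.lstsq(G, y, rcond=None)
    resid = y - G @ amp
    return float(resid @ resid), amp


def _draw(a: float, b: float, lo: float, hi: float, u: float,
          floor: float = 1e-6) -> float:
    return float(np.clip(a + b * u, max(lo, floor), hi))


def sa_fit(hist: FibrilHistogram, cfg: SAConfig) -> MixtureFit:
    """Anneal a `cfg.ngauss`-component Gaussian mixture to the histogram.

    Pure function of (histogram, config): the SEED fully determines the
    proposal stream, so identical inputs give identical fits.
    """
    if hist.freq.sum() <= 0:
        raise DataError("histogram is empty")
    x = hist.bin_centres
    y = hist.norm_freq
    rng = np.random.default_rng(cfg.seed)

    mu = np.array(cfg.mu_init, dtype=float)
    sd = np.array(cfg.sd_init, dtype=float)
    sd = np.maximum(sd, 1e-6)
    cur, cur_amp = _objective(x, y, mu, sd, cfg.nonneg)
    best, best_mu, best_sd, best_amp = cur, mu.copy(), sd.copy(), cur_amp
    trace = []
    T = cfg.temperature
    for _ in range(cfg.ntrials):
        successes = 0
        for _ in range(cfg.nconfig):
            i = int(rng.integers(cfg.ngauss))
            which_sd = bool(rng.integers(2))
            new_mu, new_sd = mu.copy(), sd.copy()
            u = rng.random()
            if which_sd:
                new_sd[i] = _draw(cfg.sda[i], cfg.sdb[i],
                                  1e-6, np.inf, u)
            else:
                new_mu[i] = _draw(cfg.mua[i], cfg.mub[i],
                                  cfg.lower, cfg.upper, u)
            new, new_amp = _objective(x, y, new_mu, new_sd, cfg.nonneg)
            if metropolis_accept(new - cur, T, rng):
                mu, sd, cur, cur_amp = new_mu, new_sd, new, new_amp
                successes += 1
                if cur < best:
                    best, best_mu, best_sd, best_amp = (
                        cur, mu.copy(), sd.copy(), cur_amp)
            if successes >= cfg.nsucclimit:
                break
        trace.append(best)
        T *= cfg.tfactr

    order = np.argsort(best_mu)
    return MixtureFit(
        mu=tuple(float(m) for m in best_mu[order]),
        sigma=tuple(float(s) for s in best_sd[order]),
        amplitude=tuple(float(a) for a in best_amp[order]),
        objective=best, trace=tuple(trace))


def refine_fit(first: MixtureFit, hist: FibrilHistogram, cfg: SAConfig,
               shrink: float = 0.25) -> MixtureFit:
    """Refinement run: proposal ranges re-centred on `first`, widths scaled.

    Each component's mean range is re-centred on its first-run estimate
    with width ``shrink`` times the original; likewise for SDs.  The seed
    advances by one so ``shrink=1`` behaves as an independent second run.
    Returns the better of the two fits by objective.
    """
    if not 0 < shrink <= 1:
        raise ConfigurationError("shrink must be in (0, 1]")
    mua, mub, sda, sdb = [], [], [], []
    for i in range(cfg.ngauss):
        w_mu = abs(cfg.mub[i]) * shrink
        w_sd = abs(cfg.sdb[i]) * shrink
        mua.append(first.mu[i] - w_mu / 2)
        mub.append(w_mu)
        sda.append(max(first.sigma[i] - w_sd / 2, 1e-6))
        sdb.append(w_sd)
    cfg2 = replace(cfg, mua=tuple(mua), mub=tuple(mub),
                   sda=tuple(sda), sdb=tuple(sdb),
                   mu_init=tuple(first.mu), sd_init=tuple(first.sigma),
                   seed=cfg.seed + 1)
    second = sa_fit(hist, cfg2)
    return second if second.objective <= first.objective else first


def fit_subpopulations(hist: FibrilHistogram, seed: int = 0,
                       shrink: float = 0.25, **overrides) -> MixtureFit:
    """Convenience wrapper: initial run + refinement with default config."""
    cfg = SAConfig.from_histogram(hist, seed=seed, **overrides)
    first = sa_fit(hist, cfg)
    return refine_fit(first, hist, cfg, shrink=shrink)


# ---------------------------------------------------------------------------
# Classic key-value parameter files
# ---------------------------------------------------------------------------

_SCALAR_KEYS = {"NCONFIG": ("nconfig", int), "NSUCCLIMIT": ("nsucclimit", int),
                "NTRIALS": ("ntrials", int), "SEED": ("seed", int),
                "Temperature": ("temperature", float),
                "Tfactr": ("tfactr", float), "LOWER": ("lower", float),
                "UPPER": ("upper", float), "ngauss": ("ngauss", int)}
_VECTOR_KEYS = {"mu": "mu_init", "sigma": "sd_init", "MUA": "mua",
                "MUB": "mub", "SDA": "sda", "SDB": "sdb"}


def write_sa_config(cfg: SAConfig, path: str | Path) -> None:
    """Write a plain key-value parameter file (classic key names)."""
    lines = [f"NCONFIG {cfg.nconfig}", f"NSUCCLIMIT {cfg.nsucclimit}",
             f"NTRIALS {cfg.ntrials}", f"SEED {cfg.seed}",
             f"Temperature {cfg.temperature}", f"Tfactr {cfg.tfactr}",
             f"LOWER {cfg.lower}", f"UPPER {cfg.upper}",
             f"ngauss {cfg.ngauss}"]
    for key, attr in _VECTOR_KEYS.items():
        for i, v in enumerate(getattr(cfg, attr), start=1):
            lines.append(f"{key}({i}) {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sa_config(path: str | Path) -> SAConfig:
    """Read a key-value parameter file written by :func:`write_sa_config`."""
    scalars: dict[str, object] = {}
    vectors: dict[str, dict[int, float]] = {v: {} for v in _VECTOR_KEYS.values()}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, _, val = ln.partition(" ")
        if "(" in key:
            base, _, idx = key.partition("(")
            if base not in _VECTOR_KEYS:
                raise ConfigurationError(f"unknown parameter '{key}'")
            vectors[_VECTOR_KEYS[base]][int(idx.rstrip(")"))] = float(val)
        else:
            if key not in _SCALAR_KEYS:
                raise ConfigurationError(f"unknown parameter '{key}'")
            attr, cast = _SCALAR_KEYS[key]
            scalars[attr] = cast(val)
    kwargs = dict(scalars)
    for attr, entries in vectors.items():
        if entries:
            kwargs[attr] = tuple(entries[i] for i in sorted(entries))
    return SAConfig(**kwargs)
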