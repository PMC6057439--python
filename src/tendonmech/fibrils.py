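"""Collagen-fibril morphometry from traced cross-sectional areas.

Fibril cross sections traced on transmission electron micrographs yield an
area a_f (nm^2) per fibril; the equivalent-circle diameter is
D = sqrt(4 a_f / pi), the exact inverse of a_f = pi D^2 / 4.  Per image, the
area fraction rho is the summed fibril area (part fibrils at the image
boundary contribute their clipped area) over the field area (nominally
4x5 um^2 = 2e7 nm^2).  Group histograms of D use contiguous right-open bins
[k w, (k+1) w); a boundary diameter therefore lands deterministically in
the upper bin.  Part fibrils are excluded from the diameter histogram: a
clipped area underestimates D.

Image selection follows the two-stage randomisation used when pooling
micrographs per age group: every image id is tagged with a uniform(0,1)
draw and the pool sorted ascending by tag (stable, so equal tags preserve
input order), then the number of images N_c is drawn uniformly from 4..11
and the first N_c sorted ids are kept.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, EmptyHistogramError
from .io import FibrilHistogram

#: inclusive range of the random per-group image count N_c
NC_RANGE = (4, 11)


def diameter_from_area(a_f):
    """Equivalent-circle diameter D (nm) from cross-sectional area (nm^2)."""
    a = np.asarray(a_f, dtype=float)
    if np.any(a <= 0):
        raise DomainError("fibril area must be positive")
    D = np.sqrt(4.0 * a / np.pi)
    return float(D) if np.isscalar(a_f) else D


def area_from_diameter(D):
    """Inverse map: a_f = pi D^2 / 4 (nm^2)."""
    d = np.asarray(D, dtype=float)
    if np.any(d <= 0):
        raise DomainError("diameter must be positive")
    a = np.pi * d ** 2 / 4.0
    return float(a) if np.isscalar(D) else a


@dataclass
class FibrilImageRecord:
    """One micrograph's traced fibrils (ScanNNN naming)."""

    image_id: str
    field_area: float                       # nm^2
    fibril_areas: np.ndarray                # nm^2, clipped for part fibrils
    interior: np.ndarray | None = None      # bool mask: fully inside the field

    def __post_init__(self):
        self.fibril_areas = np.asarray(self.fibril_areas, dtype=float)
        if self.field_area <= 0:
            raise DomainError("field area must be positive")
        if np.any(self.fibril_areas < 0):
            raise DataError("negative fibril area")
        if self.interior is not None:
            self.interior = np.asarray(self.interior, dtype=bool)

    @property
    def rho(self) -> float:
        return area_fraction(self)

    def interior_diameters(self) -> np.ndarray:
        """Diameters of fully interior fibrils (part fibrils excluded)."""
        areas = self.fibril_areas
        if self.interior is not None:
            areas = areas[self.interior]
        if len(areas) == 0:
            return np.empty(0)
        return diameter_from_area(areas)


def area_fraction(image: FibrilImageRecord) -> float:
    """rho = sum(a_f) / field_area, boundary part fibrils included."""
    return float(image.fibril_areas.sum() / image.field_area)


def sample_images(pool: Sequence[str], seed: int | np.random.Generator,
                  ) -> list[str]:
    """Two-stage random image selection; pure function of (pool, seed).

    Stage 1 random-sorts the pool by uniform tags; stage 2 draws N_c
    uniformly from 4..11 and keeps the first min(N_c, len(pool)) ids.
    Undersized pools truncate with a warning rather than failing.
    """
    if len(pool) == 0:
        raise DataError("image pool is empty")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    tags = rng.random(len(pool))
    order = np.argsort(tags, kind="stable")
    n_c = int(rng.integers(NC_RANGE[0], NC_RANGE[1] + 1))
    if n_c > len(pool):
        _warnings.warn(f"pool of {len(pool)} images truncates N_c={n_c}")
    return [pool[i] for i in order[:min(n_c, len(pool))]]


def build_histogram(diameters: Sequence[float], bin_width: float = 20.0,
                    group_id: str = "") -> FibrilHistogram:
    """Bin diameters into right-open bins [k w, (k+1) w) covering max(D)."""
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    d = np.asarray(diameters, dtype=float)
    if len(d) == 0:
        raise EmptyHistogramError("no diameters to bin")
    if np.any(d < 0):
        raise DataError("negative diameter")
    nbins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(nbins + 1, dtype=float) * bin_width
    # np.histogram closes the last bin; right-open semantics need one more
    freq = np.zeros(nbins)
    idx = np.floor(d / bin_width).astype(int)
    np.add.at(freq, idx, 1.0)
    return FibrilHistogram(bin_edges=edges, freq=freq,
                           norm_freq=freq / freq.sum(), group_id=group_id)


def group_area_fraction(rhos: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group mean and SEM of per-image area fractions.

    Mirrors the summary columns of the deposited 'Fibril area fraction'
    sheet; a single-image group reports a missing SEM.
    """
    rows = []
    for group, vals in rhos.items():
        v = np.asarray(list(vals), dtype=float)
        if len(v) == 0:
            raise DataError(f"group '{group}' has no images")
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        rows.append({"age_group": group, "mean_rho": float(v.mean()),
                     "sem_rho": sem, "n_images": len(v)})
    return pd.DataFrame(rows)
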