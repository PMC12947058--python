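"""Microdosimetric summaries and spatial analyses of specific-energy fields.

Computes the quantities conventionally tabulated for f(z; D): mean
specific energy zbar, relative standard deviation sigma_z/zbar, zero
fraction f_{z=0}, the normalized distribution itself (explicit point mass
at z = 0 plus a binned density over z > 0), and normalized 2-D maps with
grid sub-sampling mirroring a Raman raster.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import SpecificEnergyField
from .errors import DomainError

__all__ = [
    "MicrodoseSummary",
    "SpecificEnergyHistogram",
    "SpatialMap",
    "summarize_field",
    "histogram_f",
    "grid_sample",
    "normalize_map",
]


@dataclass(frozen=True)
class MicrodoseSummary:
    """Scalar summaries of one field: zbar, spread, f_{z=0}."""

    dose: float
    spread: float  # NaN when undefined (all-zero field)
    zero_fraction: float
    n_voxels: int
    standard_error_of_mean: float

    @property
    def spread_defined(self) -> bool:
        return not math.isnan(self.spread)


@dataclass
class SpecificEnergyHistogram:
    """f(z; D): point mass at z = 0 plus binned density for z > 0.

    Total mass (zero_mass + integral of the density) is 1.
    """

    zero_mass: float
    bin_edges: np.ndarray  # length n_bins + 1, Gy; empty -> no positive mass
    densities: np.ndarray  # per-bin density (1/Gy)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if (self.densities < 0).any():
            raise DomainError("densities must be non-negative")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_mass(self) -> float:
        return float(self.zero_mass + (self.densities * self.widths).sum())

    def mean(self) -> float:
        """Mean of the histogram (zero spike contributes 0)."""
        return float((self.mids * self.densities * self.widths).sum())

    @classmethod
    def point_mass_at_zero(cls) -> "SpecificEnergyHistogram":
        """The degenerate D = 0 distribution: unit spike at z = 0."""
        return cls(1.0, np.empty(0), np.empty(0))


@dataclass
class SpatialMap:
    """2-D map of a per-pixel quantity with its pixel pitch (um)."""

    values: np.ndarray
    pitch: float = 1.0
    reference: float | None = None  # normalization reference, if applied

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("map must be 2-D")


def _values(field) -> np.ndarray:
    if isinstance(field, SpecificEnergyField):
        return field.values
    return np.asarray(field, dtype=float)


def summarize_field(field) -> MicrodoseSummary:
    """zbar, population sigma_z/zbar, exact zero fraction, SE of mean."""
    z = _values(field).ravel()
    if z.size == 0:
        raise DomainError("cannot summarize an empty field")
    mean = float(z.mean())
    sd = float(z.std())  # population SD, microdosimetric convention
    spread = sd / mean if mean > 0 else float("nan")
    return MicrodoseSummary(
        dose=mean,
        spread=spread,
        zero_fraction=float((z == 0).mean()),
        n_voxels=z.size,
        standard_error_of_mean=sd / math.sqrt(z.size),
    )


def histogram_f(field, n_bins: int = 200, binning: str = "log") -> SpecificEnergyHistogram:
    """Normalized f(z; D) with the zero spike kept separate.

    Log binning (default) spans [min positive z, max z], appropriate for
    distributions spanning decades at low dose; linear binning spans
    [0, max z].
    """
    if n_bins < 1:
        raise DomainError("n_bins must be >= 1")
    z = _values(field).ravel()
    if z.size == 0:
        raise DomainError("cannot histogram an empty field")
    pos = z[z > 0]
    zero_mass = 1.0 - pos.size / z.size
    if pos.size == 0:
        return SpecificEnergyHistogram(zero_mass, np.empty(0), np.empty(0))
    lo, hi = pos.min(), pos.max()
    if binning == "log":
        if lo == hi:
            edges = np.array([lo * 0.999, hi * 1.001])
        else:
            edges = np.geomspace(lo, hi, n_bins + 1)
    elif binning == "linear":
        edges = np.linspace(0.0 if lo != hi else lo * 0.999, hi if lo != hi else hi * 1.001, n_bins + 1)
    else:
        raise ValueError(f"binning must be 'linear' or 'log', got {binning!r}")
    counts, edges = np.histogram(pos, bins=edges)
    dens = counts / z.size / np.diff(edges)
    return SpecificEnergyHistogram(zero_mass, edges, dens)


def grid_sample(map2d, nx: int = 10, ny: int = 10) -> SpatialMap:
    """Sub-sample a 2-D map on an evenly spaced nx x ny index grid.

    Mirrors reading a large scored slice on a sparse measurement raster
    (e.g. a 10 x 10 Raman grid over the central 100 x 100 voxels).
    """
    src = map2d.values if isinstance(map2d, SpatialMap) else np.asarray(map2d, dtype=float)
    if src.ndim != 2:
        raise DomainError("source map must be 2-D")
    if src.shape[0] < ny or src.shape[1] < nx:
        raise DomainError(f"source {src.shape} smaller than requested grid {(ny, nx)}")
    rows = np.round(np.linspace(0, src.shape[0] - 1, ny)).astype(int)
    cols = np.round(np.linspace(0, src.shape[1] - 1, nx)).astype(int)
    pitch = map2d.pitch if isinstance(map2d, SpatialMap) else 1.0
    step = (src.shape[0] - 1) / max(ny - 1, 1)
    return SpatialMap(src[np.ix_(rows, cols)], pitch=pitch * step)


def normalize_map(map2d, reference: float | None = None) -> SpatialMap:
    """Divide a map by a reference (default: its own ROI mean).

    The full-ROI normalized map then has mean exactly 1.
    """
    src = map2d.values if isinstance(map2d, SpatialMap) else np.asarray(map2d, dtype=float)
    ref = float(src.mean()) if reference is None else float(reference)
    if ref <= 0:
        raise DomainError(f"normalization reference must be positive, got {ref}")
    pitch = map2d.pitch if isinstance(map2d, SpatialMap) else 1.0
    return SpatialMap(src / ref, pitch=pitch, reference=ref)
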