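"""Optical-density computation and map-level dose-trend statistics.

Net OD from 16-bit transmission scans (OD = log10(I0/I), red channel by
convention), 3x3 block averaging (300 -> 100 dpi), pixel-wise 0 Gy offset
correction, and power-law fits of relative-SD-vs-dose trends.  A pure
compound-Poisson field has relative SD proportional to D^-1/2; dose-
independent film inhomogeneity flattens the fitted exponent toward 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError
from .field_stats import SpatialMap

__all__ = [
    "ODScan",
    "TrendFit",
    "od_from_transmission",
    "block_average",
    "net_od_map",
    "offset_correct",
    "power_law_fit",
    "PowerLawTrend",
    "map_stats",
]


@dataclass
class ODScan:
    """A 16-bit single-channel transmission scan of one film sample."""

    values: np.ndarray
    channel: str = "red"
    dpi: float = 300.0
    dose: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DomainError("scan must be a 2-D pixel array")
        if (self.values < 1).any() or (self.values > 65535).any():
            raise DomainError("transmission readings must lie in [1, 65535]")

    @property
    def pitch(self) -> float:
        """Pixel pitch in um (25400 um per inch)."""
        return 25400.0 / self.dpi


def od_from_transmission(i0, i):
    """Optical density log10(i0 / i); readings must be positive."""
    i0 = np.asarray(i0, dtype=float)
    i = np.asarray(i, dtype=float)
    if (i0 <= 0).any() or (i <= 0).any():
        raise DomainError("transmission readings must be positive")
    return np.log10(i0 / i)[()]


def block_average(image: np.ndarray, factor: int = 3) -> np.ndarray:
    """Non-overlapping factor x factor block means (300 -> 100 dpi at 3).

    Trailing rows/columns that do not fill a block are cropped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("image must be 2-D")
    if factor < 1:
        raise DomainError("factor must be >= 1")
    ny, nx = (img.shape[0] // factor) * factor, (img.shape[1] // factor) * factor
    if ny == 0 or nx == 0:
        raise DomainError("image smaller than one block")
    img = img[:ny, :nx]
    return img.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def net_od_map(scan: ODScan, control_scan: ODScan, factor: int = 3,
               order: str = "average-first") -> SpatialMap:
    """Pixel-wise net OD of an irradiated scan against a control scan.

    ``order='average-first'`` (default) block-averages the transmissions
    before taking logs; ``'od-first'`` converts per pixel then averages.
    """
    if scan.values.shape != control_scan.values.shape:
        raise DomainError("scan and control must have the same shape")
    if order == "average-first":
        od = od_from_transmission(block_average(control_scan.values, factor),
                                  block_average(scan.values, factor))
    elif order == "od-first":
        od = block_average(od_from_transmission(control_scan.values, scan.values), factor)
    else:
        raise ValueError("order must be 'average-first' or 'od-first'")
    return SpatialMap(od, pitch=scan.pitch * factor)


def offset_correct(map2d, control_map) -> SpatialMap:
    """Subtract the 0 Gy map pixel-by-pixel.

    Removes the intrinsic (radiation-independent) offset signal so the
    corrected control has mean exactly 0 and relative-SD trends across
    dose become comparable with microdosimetric spread.
    """
    a = map2d.values if isinstance(map2d, SpatialMap) else np.asarray(map2d, dtype=float)
    b = control_map.values if isinstance(control_map, SpatialMap) else np.asarray(control_map, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"shape mismatch: {a.shape} vs {b.shape}")
    pitch = map2d.pitch if isinstance(map2d, SpatialMap) else 1.0
    return SpatialMap(a - b, pitch=pitch)


def map_stats(map2d) -> tuple[float, float, float]:
    """(mean, SD, relative SD) of a map's values."""
    v = map2d.values if isinstance(map2d, SpatialMap) else np.asarray(map2d, dtype=float)
    mean, sd = float(v.mean()), float(v.std())
    return mean, sd, (sd / mean if mean != 0 else float("nan"))


@dataclass(frozen=True)
class TrendFit:
    """Power-law trend rel_SD = amplitude * D ** exponent."""

    amplitude: float
    exponent: float
    r_squared: float

    def predict(self, doses) -> np.ndarray:
        return self.amplitude * np.asarray(doses, dtype=float) ** self.exponent


class PowerLawTrend(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator for y = a * x^b via log-log least squares.

    Recovers (a, b) exactly on noise-free power-law data; requires
    strictly positive x and y.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 2:
            raise DomainError("need >= 2 (x, y) pairs of equal length")
        if (x <= 0).any() or (y <= 0).any():
            raise DomainError("power-law fit requires positive data")
        lx, ly = np.log(x), np.log(y)
        b, loga = np.polyfit(lx, ly, 1)
        self.amplitude_ = float(np.exp(loga))
        self.exponent_ = float(b)
        pred = loga + b * lx
        ss_res = float(((ly - pred) ** 2).sum())
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.amplitude_ * x ** self.exponent_


def power_law_fit(doses, relative_sds) -> TrendFit:
    """Fit rel_SD = a * D^b in log-log space (see :class:`PowerLawTrend`)."""
    est = PowerLawTrend().fit(doses, relative_sds)
    return TrendFit(est.amplitude_, est.exponent_, est.r_squared_)
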