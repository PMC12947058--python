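"""Voxel geometry of micron-scale scoring volumes.

Rectangular-box targets inside the ~28 um active layer of radiochromic
film.  Two presets mirror the scoring volumes used for the two readout
modalities: ``vx-sm`` (0.8862 x 0.8862 x 6 um, the confocal Raman sampling
volume) and ``vx-lg`` (1.436 x 1.436 x 9.4 um, the average LiPCDA monomer
crystal size).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidGeometryError

#: Default mass density of the film's active layer (g/cm^3); configurable.
DEFAULT_DENSITY = 1.2


@dataclass(frozen=True)
class VoxelGeometry:
    """A rectangular scoring voxel.

    Parameters
    ----------
    dx, dy, dz : float
        Edge lengths in micrometres.
    density : float
        Mass density in g/cm^3 (default 1.2, the active-layer default).
    """

    dx: float
    dy: float
    dz: float
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise InvalidGeometryError(
                f"voxel dimensions must be positive, got {(self.dx, self.dy, self.dz)}"
            )
        if self.density <= 0:
            raise InvalidGeometryError(f"density must be positive, got {self.density}")

    @property
    def volume(self) -> float:
        """Voxel volume in um^3."""
        return self.dx * self.dy * self.dz

    @property
    def surface_area(self) -> float:
        """Surface area in um^2."""
        a, b, c = self.dx, self.dy, self.dz
        return 2.0 * (a * b + b * c + a * c)

    @property
    def mean_chord(self) -> float:
        """Cauchy mean chord length 4V/S (um) of the convex box."""
        return 4.0 * self.volume / self.surface_area

    @property
    def mass_kg(self) -> float:
        """Voxel mass in kg (volume um^3 x density g/cm^3)."""
        # 1 um^3 = 1e-12 cm^3; 1 g = 1e-3 kg
        return self.volume * 1e-12 * self.density * 1e-3

    @classmethod
    def from_preset(cls, name: str, density: float = DEFAULT_DENSITY) -> "VoxelGeometry":
        try:
            dx, dy, dz = _PRESETS[name]
        except KeyError:
            raise KeyError(f"unknown geometry preset {name!r}; known: {sorted(_PRESETS)}")
        return cls(dx, dy, dz, density)


_PRESETS: dict[str, tuple[float, float, float]] = {
    "vx-sm": (0.8862, 0.8862, 6.0),
    "vx-lg": (1.436, 1.436, 9.4),
}

#: Raman-sampling-volume voxel preset.
VX_SM = VoxelGeometry.from_preset("vx-sm")
#: Monomer-crystal-sized voxel preset.
VX_LG = VoxelGeometry.from_preset("vx-lg")


def mean_chord_length(geom: VoxelGeometry) -> float:
    """Mean chord length (um) of a convex voxel, Cauchy's 4V/S."""
    return geom.mean_chord
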