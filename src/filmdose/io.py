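"""File formats and run configuration.

Formats: EGSnrc-style 3ddose ASCII voxel fields, RFC-4180 dose-response
CSV (header mandatory), 16-bit grayscale TIFF/PNG transmission scans, and
stacked-column spectra CSV (shift column plus one column per spectrum).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SpecificEnergyField
from .errors import DomainError, ParseError
from .geometry import DEFAULT_DENSITY, VoxelGeometry
from .onehit import DoseResponseCurve
from .response_maps import ODScan

__all__ = [
    "read_3ddose",
    "write_3ddose",
    "read_curve_csv",
    "write_curve_csv",
    "read_scan",
    "write_scan",
    "read_spectra_stack",
    "write_spectra_stack",
    "RunConfig",
]

_UM_PER_CM = 1e4


def write_3ddose(field: SpecificEnergyField, path) -> None:
    """Write a field in 3ddose ASCII.

    Line 1: ``nx ny nz``; then the nx+1, ny+1 and nz+1 voxel boundary
    coordinates (cm); then the nx*ny*nz specific energies (Gy) in
    x-fastest order; then relative uncertainties (0 when absent).
    """
    nx, ny, nz = field.values.shape
    geom = field.geom
    lines = [f"{nx} {ny} {nz}"]
    for n, d in ((nx, geom.dx), (ny, geom.dy), (nz, geom.dz)):
        bounds = np.arange(n + 1) * d / _UM_PER_CM
        lines.append(" ".join(f"{b:.8g}" for b in bounds))
    # x-fastest: transpose so ravel order is x, then y, then z
    flat = field.values.transpose(2, 1, 0).ravel()
    lines.append(" ".join(f"{v:.10g}" for v in flat))
    unc = field.uncertainties
    ufla = np.zeros_like(flat) if unc is None else np.asarray(unc).transpose(2, 1, 0).ravel()
    lines.append(" ".join(f"{u:.6g}" for u in ufla))
    Path(path).write_text("\n".join(lines) + "\n")


class _TokenReader:
    """Whitespace token stream that remembers line numbers for errors."""

    def __init__(self, text: str):
        self.tokens: list[tuple[str, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            for tok in line.split():
                self.tokens.append((tok, lineno))
        self.pos = 0

    def take(self, n: int, what: str) -> tuple[np.ndarray, int]:
        if self.pos + n > len(self.tokens):
            last = self.tokens[-1][1] if self.tokens else 1
            raise ParseError(
                f"expected {n} values for {what}, found {len(self.tokens) - self.pos}",
                line=last,
            )
        chunk = self.tokens[self.pos : self.pos + n]
        self.pos += n
        try:
            vals = np.array([float(t) for t, _ in chunk])
        except ValueError as exc:
            raise ParseError(f"non-numeric value in {what}: {exc}", line=chunk[0][1])
        return vals, chunk[0][1]


def read_3ddose(path, density: float = DEFAULT_DENSITY) -> SpecificEnergyField:
    """Read a 3ddose ASCII field (dialect of :func:`write_3ddose`)."""
    reader = _TokenReader(Path(path).read_text())
    dims, line = reader.take(3, "grid dimensions")
    nx, ny, nz = (int(d) for d in dims)
    if min(nx, ny, nz) < 1:
        raise ParseError(f"grid dimensions must be >= 1, got {nx} {ny} {nz}", line=line)
    bounds = []
    for n, name in ((nx, "x boundaries"), (ny, "y boundaries"), (nz, "z boundaries")):
        b, line = reader.take(n + 1, name)
        if (np.diff(b) <= 0).any():
            raise ParseError(f"{name} must be strictly increasing", line=line)
        bounds.append(b)
    nvox = nx * ny * nz
    values, _ = reader.take(nvox, f"{nvox} specific energies")
    unc, _ = reader.take(nvox, f"{nvox} relative uncertainties")
    geom = VoxelGeometry(
        dx=float(np.diff(bounds[0]).mean() * _UM_PER_CM),
        dy=float(np.diff(bounds[1]).mean() * _UM_PER_CM),
        dz=float(np.diff(bounds[2]).mean() * _UM_PER_CM),
        density=density,
    )
    shaped = values.reshape(nz, ny, nx).transpose(2, 1, 0)
    u = unc.reshape(nz, ny, nx).transpose(2, 1, 0)
    return SpecificEnergyField(shaped, geom, float(shaped.mean()),
                               provenance="file", uncertainties=u)


def write_curve_csv(curve: DoseResponseCurve, path) -> None:
    data = {"dose": curve.doses, "response": curve.responses}
    if curve.uncertainties is not None:
        data["uncertainty"] = curve.uncertainties
    pd.DataFrame(data).to_csv(path, index=False)


def read_curve_csv(path, modality: str = "OD") -> DoseResponseCurve:
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "dose" not in cols or "response" not in cols:
        raise ParseError(f"curve CSV needs 'dose' and 'response' columns, got {list(df.columns)}")
    unc = df[cols["uncertainty"]].to_numpy() if "uncertainty" in cols else None
    return DoseResponseCurve(df[cols["dose"]].to_numpy(), df[cols["response"]].to_numpy(),
                             uncertainties=unc, modality=modality)


def write_scan(scan: ODScan, path) -> None:
    """Write a 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr = scan.values.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported scan format {path.suffix!r}")


def read_scan(path, channel: str = "red", dpi: float = 300.0,
              dose: float | None = None) -> ODScan:
    """Read a 16-bit grayscale TIFF/PNG transmission scan."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.array(Image.open(path))
    else:
        raise ValueError(f"unsupported scan format {path.suffix!r}")
    if arr.ndim == 3:  # multi-channel: pick the requested one
        idx = {"red": 0, "green": 1, "blue": 2}[channel]
        arr = arr[..., idx]
    return ODScan(arr.astype(np.uint16), channel=channel, dpi=dpi, dose=dose)


def write_spectra_stack(shifts: np.ndarray, spectra: np.ndarray, path) -> None:
    """CSV with a 'shift' column and one column per spectrum."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    cols = {"shift": np.asarray(shifts, dtype=float)}
    cols.update({f"spectrum_{k}": row for k, row in enumerate(spectra)})
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a stacked-spectra CSV; returns (shifts, spectra[n, channels])."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError("spectra CSV needs a shift column plus at least one spectrum")
    shifts = df.iloc[:, 0].to_numpy(dtype=float)
    if (np.diff(shifts) <= 0).any():
        raise ParseError("shift axis must be strictly increasing")
    return shifts, df.iloc[:, 1:].to_numpy(dtype=float).T


@dataclass
class RunConfig:
    """Workflow configuration; round-trips losslessly through YAML."""

    doses: list = dc_field(default_factory=list)
    geometry: str = "vx-lg"
    family: str = "gamma"
    anchor_dose: float = 0.003
    anchor_zero_fraction: float = 0.35
    anchor_spread: float = 2.05
    modality: str = "OD"
    film: dict = dc_field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParseError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON form, logged with each run."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
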