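"""Synthetic study-condition generator.

Produces every input the analysis chain consumes with the statistical
structure it assumes: compound-Poisson specific-energy fields, 16-bit OD
transmission scans rendered through the one-hit response, and Raman ROI
spectra with dose-dependent polymer bands, a dose-independent monomer
reference band, a smooth baseline and cosmic-ray spikes.

Defaults reproduce the reference film conditions: one-hit parameters
(0.19, 1.2 / Gy, 0.026) for OD and (8.6, 1.02 / Gy, 1.96) for Raman, the
15-dose 0.003-0.5 Gy series, vx-sm sampling volumes for Raman pixels and
many-voxel aggregation for the ~85 um scanner pixels.  Per-pixel film
sensitivity is lognormal-multiplicative on the scaling factor m only
(crystal density varies spatially; the offset is chemistry-wide).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .engine import (SingleEventModel, SpecificEnergyField, calibrate_from_anchor,
                     sample_field, _rng_from_seed)
from .errors import DomainError
from .geometry import VX_LG, VX_SM, VoxelGeometry
from .raman import (BAND_WIDTH, REFERENCE_BAND, RESPONSE_BAND, RamanROISet,
                    band_area, default_shift_axis)
from .reference import (ANCHOR_VX_LG, ANCHOR_VX_SM, DOSES_DELIVERED,
                        OD_FIT_PARAMS, RS_FIT_PARAMS)
from .response_maps import ODScan

__all__ = [
    "FilmModel",
    "SynthDataset",
    "DoseSeries",
    "synth_response_map",
    "render_od_scan",
    "synth_raman_roiset",
    "synth_dose_series",
    "inject_offset_signal",
]

#: Active-layer thickness (um) used to aggregate voxels into scan pixels.
ACTIVE_LAYER_UM = 28.0

#: Dose-dependent Raman bands (center 1/cm -> amplitude relative to 1445).
DEFAULT_PEAKS = {696.0: 0.30, 1086.0: 0.45, 1445.0: 1.0, 2060.0: 0.25}


@dataclass(frozen=True)
class FilmModel:
    """Response model of one film modality used for data generation.

    ``m``, ``alpha`` (1/Gy) and ``c`` are the one-hit response parameters;
    ``inhomogeneity_cv`` the lognormal coefficient of variation of
    per-pixel sensitivity applied to m; ``noise_sd`` the additive noise
    (OD units for OD; spectral counts for RS, defaulting to 1% of the
    1445 peak height at 0.5 Gy when None).
    """

    modality: str = "OD"
    m: float = OD_FIT_PARAMS[0]
    alpha: float = OD_FIT_PARAMS[1]
    c: float = OD_FIT_PARAMS[2]
    inhomogeneity_cv: float = 0.05
    noise_sd: float | None = 0.003
    i0: int = 48000
    peaks: dict = dc_field(default_factory=lambda: dict(DEFAULT_PEAKS))
    reference_peak: float = REFERENCE_BAND
    peak_fwhm: float = 10.0
    baseline_amplitude: float = 0.0
    baseline_tau: float = 800.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0

    def __post_init__(self):
        if self.m <= 0 or self.alpha <= 0:
            raise DomainError("m and alpha must be positive")
        if self.inhomogeneity_cv < 0:
            raise DomainError("inhomogeneity_cv must be >= 0")

    @classmethod
    def od_default(cls) -> "FilmModel":
        return cls(modality="OD")

    @classmethod
    def rs_default(cls) -> "FilmModel":
        m, alpha, c = RS_FIT_PARAMS
        return cls(modality="RS", m=m, alpha=alpha, c=c,
                   inhomogeneity_cv=0.12, noise_sd=None,
                   baseline_amplitude=2.0, spike_rate=0.02, spike_amplitude=5.0)

    def nominal_response(self, dose: float) -> float:
        """Noise-free response with z pinned at its mean (z = D)."""
        return self.m * (1.0 - math.exp(-self.alpha * dose)) + self.c


def synth_response_map(film: FilmModel, event_model: SingleEventModel, dose: float,
                       shape: tuple[int, int], rng, aggregate: int = 1,
                       noise_sd: float | None = None) -> np.ndarray:
    """Per-pixel film response s_px * m * (1 - exp(-alpha z_px)) + c + noise.

    ``aggregate`` > 1 makes each pixel the mean of that many scoring
    voxels (compound-Poisson algebra: rate x n, event size / n), emulating
    a scanner pixel that spans many crystals.
    """
    rng = _rng_from_seed(rng)
    if event_model is None:  # zero-spread limit: every pixel receives z = D
        z = np.full(shape, dose)
    else:
        model = event_model if aggregate == 1 else event_model.scaled(1.0 / aggregate)
        z = sample_field(model, VX_SM, dose, (shape[0], shape[1], 1), seed=rng).values[:, :, 0]
    resp = film.m * (1.0 - np.exp(-film.alpha * z)) + 0.0
    if film.inhomogeneity_cv > 0:
        sigma = math.sqrt(math.log(1.0 + film.inhomogeneity_cv**2))
        resp *= rng.lognormal(-0.5 * sigma**2, sigma, size=shape)
    resp += film.c
    if noise_sd is None:
        noise_sd = film.noise_sd if film.modality == "OD" and film.noise_sd else 0.0
    if noise_sd:
        resp += rng.normal(0.0, noise_sd, size=shape)
    return resp


def render_od_scan(response: np.ndarray, film: FilmModel, dose: float | None = None,
                   dpi: float = 300.0) -> ODScan:
    """Render a response map as a 16-bit transmission scan I = I0 10^-OD."""
    i = np.rint(film.i0 * np.power(10.0, -np.asarray(response, dtype=float)))
    return ODScan(np.clip(i, 1, 65535).astype(np.uint16), dpi=dpi, dose=dose)


def white_scan(film: FilmModel, shape: tuple[int, int], dpi: float = 300.0) -> ODScan:
    """Unattenuated reference scan at the scanner white level I0."""
    return ODScan(np.full(shape, film.i0, dtype=np.uint16), dpi=dpi, dose=None)


def _unit_band_peak(shifts: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Gaussian at ``center`` scaled to unit area over its 14 1/cm band."""
    sigma = fwhm / 2.3548200450309493
    g = np.exp(-0.5 * ((shifts - center) / sigma) ** 2)
    return g / band_area(shifts, g, center, BAND_WIDTH)


def rs_channel_noise_sd(film: FilmModel, shifts: np.ndarray) -> float:
    """Default spectral noise: 1% of the 1445 peak height at 0.5 Gy."""
    if film.noise_sd is not None:
        return film.noise_sd
    peak = _unit_band_peak(shifts, RESPONSE_BAND, film.peak_fwhm)
    return 0.01 * film.nominal_response(0.5) * float(peak.max())


def synth_raman_roiset(film: FilmModel, response: np.ndarray, dose: float, rng,
                       shifts: np.ndarray | None = None, n_repeats: int = 5,
                       pitch: float = 10.0) -> RamanROISet:
    """Render a response map as repeat Raman spectra per ROI pixel.

    Dose-dependent bands scale with the pixel response; the monomer
    reference band at 2260 1/cm has fixed unit band area, so the
    1445/2260 band-area ratio of a noise-free spectrum equals the pixel
    response exactly.  A smooth exponential baseline and Poisson-rate
    cosmic-ray spikes are superimposed.
    """
    rng = _rng_from_seed(rng)
    if shifts is None:
        shifts = default_shift_axis()
    ny, nx = response.shape
    signal = np.zeros((ny, nx, shifts.size))
    for center, rel in film.peaks.items():
        signal += rel * np.multiply.outer(response, _unit_band_peak(shifts, center, film.peak_fwhm))
    signal += _unit_band_peak(shifts, film.reference_peak, film.peak_fwhm)
    if film.baseline_amplitude:
        baseline = film.baseline_amplitude * np.exp(-(shifts - shifts[0]) / film.baseline_tau)
        signal += baseline
    stack = np.repeat(signal[:, :, None, :], n_repeats, axis=2)
    noise = rs_channel_noise_sd(film, shifts)
    if noise:
        stack += rng.normal(0.0, noise, size=stack.shape)
    if film.spike_rate > 0 and film.spike_amplitude > 0:
        spectra = stack.reshape(-1, shifts.size)
        hit = rng.random(spectra.shape[0]) < film.spike_rate
        for k in np.flatnonzero(hit):
            chan = rng.integers(0, shifts.size)
            spectra[k, chan] += film.spike_amplitude * (1.0 + rng.random())
        stack = spectra.reshape(stack.shape)
    return RamanROISet(shifts, stack, dose=dose, pitch=pitch)


@dataclass
class SynthDataset:
    """Everything generated for one dose of one modality."""

    dose: float
    film: FilmModel
    response: np.ndarray
    field: SpecificEnergyField | None = None
    scan: ODScan | None = None
    roiset: RamanROISet | None = None


@dataclass
class DoseSeries:
    """Generated datasets across a dose list plus the 0 Gy control."""

    film: FilmModel
    datasets: list
    control: SynthDataset
    white: ODScan | None = None

    @property
    def doses(self) -> np.ndarray:
        return np.array([d.dose for d in self.datasets])


def synth_dose_series(doses=DOSES_DELIVERED, film: FilmModel | None = None,
                      event_model: SingleEventModel | None = None,
                      geom: VoxelGeometry | None = None, seed: int = 0,
                      map_shape: tuple[int, int] = (10, 10),
                      field_shape: tuple[int, int, int] = (100, 100, 1),
                      sample_fields: bool = False) -> DoseSeries:
    """Generate a full dose series for one modality, plus the control.

    OD pixels aggregate ``pixel_area x active-layer depth / voxel volume``
    scoring voxels (vx-lg geometry by default); Raman pixels are single
    vx-sm sampling volumes.  Reproducible for a fixed seed.
    """
    film = film or FilmModel.od_default()
    zero_spread = event_model == "zero-spread"
    if film.modality == "OD":
        geom = geom or VX_LG
        event_model = event_model or calibrate_from_anchor(ANCHOR_VX_LG)
        pitch = 25400.0 / 300.0
        aggregate = max(1, round(pitch**2 * ACTIVE_LAYER_UM / geom.volume))
    else:
        geom = geom or VX_SM
        event_model = event_model or calibrate_from_anchor(ANCHOR_VX_SM)
        aggregate = 1
    if zero_spread:
        event_model = None
    rng = _rng_from_seed(seed)

    def build(dose: float) -> SynthDataset:
        resp = synth_response_map(film, event_model, dose, map_shape, rng,
                                  aggregate=aggregate)
        ds = SynthDataset(dose=dose, film=film, response=resp)
        if sample_fields and event_model is not None:
            ds.field = sample_field(event_model, geom, dose, field_shape, seed=rng)
        if film.modality == "OD":
            ds.scan = render_od_scan(resp, film, dose=dose)
        else:
            ds.roiset = synth_raman_roiset(film, resp, dose, rng)
        return ds

    datasets = [build(float(d)) for d in doses]
    control = build(0.0)
    white = white_scan(film, map_shape) if film.modality == "OD" else None
    return DoseSeries(film=film, datasets=datasets, control=control, white=white)


def inject_offset_signal(dataset: SynthDataset, c: float) -> SynthDataset:
    """Shift a dataset's response by a constant intrinsic offset and
    re-render its measurement-side data deterministically."""
    resp = dataset.response + (c - dataset.film.c)
    film = replace(dataset.film, c=c)
    out = SynthDataset(dose=dataset.dose, film=film, response=resp, field=dataset.field)
    if dataset.scan is not None:
        out.scan = render_od_scan(resp, film, dose=dataset.dose, dpi=dataset.scan.dpi)
    if dataset.roiset is not None:
        noiseless = replace(film, noise_sd=0.0, spike_rate=0.0)
        out.roiset = synth_raman_roiset(noiseless, resp, dataset.dose, rng=0,
                                        shifts=dataset.roiset.shifts,
                                        n_repeats=dataset.roiset.stack.shape[2],
                                        pitch=dataset.roiset.pitch)
    return out
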