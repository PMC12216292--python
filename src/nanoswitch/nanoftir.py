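"""Interferogram-to-spectrum processing for asymmetric-Michelson acquisition.

The stored abscissa is the single-pass reference-mirror displacement; the
optical path difference is twice that, which is where the factor 2 in the
wavenumber axis ``nu_k = k / (2 dx N)`` and in the nominal resolution
``1 / (2 scan_length)`` comes from. The complex one-sided DFT is used
directly — the asymmetric geometry delivers amplitude and phase without
symmetrization or Mertz-style phase correction.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ValidationError

__all__ = [
    "Interferogram",
    "ComplexSpectrum",
    "interferogram_to_spectrum",
    "reference_spectrum",
    "average_spectra",
    "white_light_value",
]

UM_TO_CM = 1e-4


@dataclasses.dataclass
class Interferogram:
    """Uniformly sampled detector signal versus mirror displacement (µm)."""

    opd: np.ndarray  # mirror displacement grid, µm
    detector: np.ndarray  # arb. units
    scan_length: float  # µm; grid spans [0, scan_length) with step scan_length/n

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=float)
        self.detector = np.asarray(self.detector, dtype=float)
        if self.opd.shape != self.detector.shape or self.opd.ndim != 1:
            raise ValidationError("opd and detector must be equal-length 1-D arrays")
        steps = np.diff(self.opd)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("OPD grid must be uniform")
        if self.scan_length <= 0:
            raise ValidationError("scan_length must be > 0")

    @property
    def n_points(self) -> int:
        return self.opd.size

    @property
    def step_um(self) -> float:
        return self.scan_length / self.n_points


@dataclasses.dataclass
class ComplexSpectrum:
    """One-sided complex spectrum split into amplitude and phase (degrees)."""

    wavenumber: np.ndarray  # cm^-1, increasing
    sigma: np.ndarray  # complex spectral values
    harmonic_n: int
    resolution_nominal: float  # cm^-1, 1/(2 scan_length)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=complex)
        if self.wavenumber.shape != self.sigma.shape:
            raise ValidationError("wavenumber and sigma must share a shape")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValidationError("wavenumber axis must be increasing")

    @property
    def s_n(self) -> np.ndarray:
        return np.abs(self.sigma)

    @property
    def phi_n(self) -> np.ndarray:
        return np.degrees(np.angle(self.sigma))


def interferogram_to_spectrum(
    ig: Interferogram,
    apodization: str = "none",
    zero_fill_factor: int = 1,
    harmonic_n: int = 2,
    band: tuple[float, float] | None = None,
) -> ComplexSpectrum:
    """Mean-subtract, optionally apodize/zero-fill, and Fourier transform.

    The returned axis is ``nu_k = k / (2 dx N_padded)`` for k = 0 .. N/2,
    with ``dx`` the mirror step in cm. ``band=(lo, hi)`` crops to a stated
    wavenumber window.
    """
    n = ig.n_points
    if n < 64:
        raise ValidationError("need at least 64 interferogram points")
    if zero_fill_factor < 1 or int(zero_fill_factor) != zero_fill_factor:
        raise ValidationError("zero_fill_factor must be a positive integer")
    y = ig.detector - np.mean(ig.detector)
    if apodization == "hann":
        y = y * np.hanning(n)
    elif apodization != "none":
        raise ValidationError(f"unknown apodization {apodization!r}")
    n_pad = n * int(zero_fill_factor)
    spectrum = np.fft.fft(y, n=n_pad)
    dx_cm = ig.step_um * UM_TO_CM
    k = np.arange(n_pad // 2 + 1)
    nu = k / (2.0 * dx_cm * n_pad)
    sigma = spectrum[: n_pad // 2 + 1]
    resolution = 1.0 / (2.0 * ig.scan_length * UM_TO_CM)
    if band is not None:
        lo, hi = band
        sel = (nu >= lo) & (nu <= hi)
        nu, sigma = nu[sel], sigma[sel]
    return ComplexSpectrum(nu, sigma, harmonic_n, resolution)


def reference_spectrum(
    sample: ComplexSpectrum,
    reference: ComplexSpectrum,
    amplitude_floor: float = 0.0,
) -> ComplexSpectrum:
    """Per-point complex ratio sample/reference on identical grids.

    Grid points where the reference amplitude does not exceed
    ``amplitude_floor`` are masked to NaN (typically the band edges).
    """
    if sample.wavenumber.shape != reference.wavenumber.shape or not np.allclose(
        sample.wavenumber, reference.wavenumber, rtol=1e-12, atol=1e-9
    ):
        raise ValidationError("sample and reference wavenumber grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample.sigma / reference.sigma
    ratio = np.where(np.abs(reference.sigma) > amplitude_floor, ratio, np.nan)
    return ComplexSpectrum(
        sample.wavenumber.copy(), ratio, sample.harmonic_n, sample.resolution_nominal
    )


def average_spectra(spectra: list[ComplexSpectrum]) -> ComplexSpectrum:
    """Complex mean of repeat spectra on a shared grid."""
    if not spectra:
        raise ValidationError("cannot average an empty list of spectra")
    first = spectra[0]
    for spec in spectra[1:]:
        if spec.wavenumber.shape != first.wavenumber.shape or not np.allclose(
            spec.wavenumber, first.wavenumber, rtol=1e-12, atol=1e-9
        ):
            raise ValidationError("spectra must share a wavenumber grid")
    mean_sigma = np.mean([spec.sigma for spec in spectra], axis=0)
    return ComplexSpectrum(
        first.wavenumber.copy(), mean_sigma, first.harmonic_n, first.resolution_nominal
    )


def white_light_value(
    spectrum: ComplexSpectrum, band: tuple[float, float] | None = None
) -> float:
    """Spectrally integrated amplitude over the source band (trapezoid rule)."""
    nu, s = spectrum.wavenumber, spectrum.s_n
    if band is not None:
        sel = (nu >= band[0]) & (nu <= band[1])
        nu, s = nu[sel], s[sel]
    if nu.size < 2:
        raise ValidationError("band contains fewer than 2 grid points")
    return float(np.trapezoid(s, nu))
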