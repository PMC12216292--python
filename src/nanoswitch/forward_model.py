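"""Quasi-static finite-dipole model of a tapping tip above a layered sample.

The sample is an ordered stack of planar media. Its momentum-dependent
quasi-static reflection coefficient ``beta(q)`` is built by a downward
transfer-matrix recursion, weighted into an effective value at the relevant
evaluation height, and inserted into the spheroid (finite-dipole) closed form
for the scattered field. Harmonic demodulation of the tapping motion then
yields the background-suppressed amplitude/phase contrast that the imaging
and spectroscopy modules consume.

Lengths are nanometres, spectroscopic frequencies are wavenumbers (cm^-1),
phases are degrees unless stated otherwise.
"""
from __future__ import annotations

import cmath
import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import SingularInterfaceError, ValidationError

__all__ = [
    "TipModel",
    "Layer",
    "LayerStack",
    "PermittivitySpectrum",
    "DemodResult",
    "NormalizedContrast",
    "make_permittivity",
    "beta_layers",
    "beta_effective",
    "fdm_contrast",
    "demodulate",
    "normalized_spectrum",
    "sphere_profile",
    "disc_profile",
    "profile_fwhm_crossing",
    "wrap_phase_deg",
]

#: default momentum grid for the weighted reflection coefficient (1/nm)
Q_MIN = 1e-5
Q_MAX = 10.0
N_Q = 400


def wrap_phase_deg(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap a phase in degrees into (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(phi, dtype=float) + 180.0, 360.0) - 180.0)
    if np.isscalar(phi):
        return float(wrapped)
    return wrapped


@dataclasses.dataclass(frozen=True)
class TipModel:
    """Geometry and response of the tapping probe.

    Parameters
    ----------
    tapping_amplitude_a:
        Peak-to-centre tapping amplitude ``a`` in nm.
    apex_radius_r:
        Apex curvature radius ``r`` in nm.
    spheroid_length_L:
        Full length ``L`` of the model spheroid in nm.
    g_factor:
        Complex empirical factor for the charge induced in the tip;
        its phase is interpreted in radians.
    min_height:
        Closest tip-surface approach at the bottom of the tapping cycle (nm).
    tapping_frequency_Ohm:
        Tapping frequency in kHz; metadata only, never enters the model.
    """

    tapping_amplitude_a: float = 80.0
    apex_radius_r: float = 60.0
    spheroid_length_L: float = 300.0
    g_factor: complex = 0.7 * cmath.exp(0.06j)
    min_height: float = 0.0
    tapping_frequency_Ohm: float = 250.0

    def __post_init__(self) -> None:
        if self.tapping_amplitude_a <= 0:
            raise ValidationError("tapping_amplitude_a must be > 0")
        if self.apex_radius_r <= 0:
            raise ValidationError("apex_radius_r must be > 0")
        if self.spheroid_length_L <= self.apex_radius_r:
            raise ValidationError("spheroid_length_L must exceed apex_radius_r")
        if not 0.0 < abs(complex(self.g_factor)) < 2.0:
            raise ValidationError("|g_factor| must lie in (0, 2)")
        if self.min_height < 0:
            raise ValidationError("min_height must be >= 0")


@dataclasses.dataclass(frozen=True)
class PermittivitySpectrum:
    """Complex permittivity on a wavenumber grid, optionally oscillator-backed.

    When ``oscillators`` is non-empty, ``eps_at`` evaluates the Lorentz sum
    exactly at any wavenumber; otherwise it interpolates the tabulated grid.
    """

    wavenumber_grid: np.ndarray
    epsilon: np.ndarray
    oscillators: tuple[tuple[float, float, float], ...] = ()
    eps_infinity: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavenumber_grid, dtype=float)
        eps = np.asarray(self.epsilon, dtype=complex)
        if grid.ndim != 1 or grid.size < 1:
            raise ValidationError("wavenumber grid must be a non-empty 1-D array")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("wavenumber grid must be strictly increasing")
        if eps.shape != grid.shape:
            raise ValidationError("epsilon must match the wavenumber grid shape")
        if np.any(eps.imag < -1e-12):
            raise ValidationError("Im(eps) must be >= 0 on the grid (passive medium)")
        object.__setattr__(self, "wavenumber_grid", grid)
        object.__setattr__(self, "epsilon", eps)

    def eps_at(self, wavenumber: float) -> complex:
        if self.oscillators:
            return _lorentz_eps(self.oscillators, self.eps_infinity, wavenumber)
        re = np.interp(wavenumber, self.wavenumber_grid, self.epsilon.real)
        im = np.interp(wavenumber, self.wavenumber_grid, self.epsilon.imag)
        return complex(re, im)


def _lorentz_eps(oscillators, eps_infinity, nu):
    eps = complex(eps_infinity)
    for center, strength, damping in oscillators:
        eps += strength * center**2 / (center**2 - nu**2 - 1j * damping * nu)
    return eps


def make_permittivity(
    oscillators: Sequence[tuple[float, float, float]],
    eps_infinity: float,
    grid: np.ndarray,
) -> PermittivitySpectrum:
    """Build a Lorentz-oscillator permittivity spectrum.

    ``eps(nu) = eps_inf + sum_j S_j nu_j^2 / (nu_j^2 - nu^2 - i gamma_j nu)``
    with oscillators given as ``(center_cm1, strength, damping_cm1)`` tuples.
    """
    grid = np.asarray(grid, dtype=float)
    oscs = tuple((float(c), float(s), float(g)) for c, s, g in oscillators)
    for center, strength, damping in oscs:
        if strength < 0:
            raise ValidationError("oscillator strengths must be >= 0")
        if damping <= 0:
            raise ValidationError("oscillator dampings must be > 0 (passivity)")
        if center <= 0:
            raise ValidationError("oscillator centers must be > 0")
    eps = np.array([_lorentz_eps(oscs, eps_infinity, nu) for nu in grid])
    return PermittivitySpectrum(grid, eps, oscs, float(eps_infinity))


@dataclasses.dataclass(frozen=True)
class Layer:
    """One planar medium: a permittivity and a thickness in nm.

    ``thickness=None`` marks a semi-infinite half-space. Zero thickness is
    legal and acts as the identity in the stack recursion.
    """

    permittivity: complex | PermittivitySpectrum
    thickness: float | None = None

    def __post_init__(self) -> None:
        if self.thickness is not None and self.thickness < 0:
            raise ValidationError("layer thickness must be >= 0 or None")
        if isinstance(self.permittivity, PermittivitySpectrum):
            return
        if complex(self.permittivity).imag < -1e-12:
            raise ValidationError("Im(permittivity) must be >= 0 (passive medium)")

    @property
    def semi_infinite(self) -> bool:
        return self.thickness is None

    def eps_at(self, wavenumber: float | None) -> complex:
        if isinstance(self.permittivity, PermittivitySpectrum):
            if wavenumber is None:
                raise ValidationError(
                    "a wavenumber is required for spectrum-valued layers"
                )
            return self.permittivity.eps_at(wavenumber)
        return complex(self.permittivity)


@dataclasses.dataclass(frozen=True)
class LayerStack:
    """Ordered media below the tip: ambient half-space first, substrate last."""

    layers: tuple[Layer, ...]

    def __init__(self, layers: Sequence[Layer]):
        layers = tuple(layers)
        if len(layers) < 2:
            raise ValidationError("a stack needs at least ambient + substrate")
        if not layers[0].semi_infinite or not layers[-1].semi_infinite:
            raise ValidationError(
                "first (ambient) and last (substrate) layers must be half-spaces"
            )
        if any(layer.semi_infinite for layer in layers[1:-1]):
            raise ValidationError("interior layers must have finite thickness")
        object.__setattr__(self, "layers", layers)

    def __len__(self) -> int:
        return len(self.layers)

    @classmethod
    def from_media(
        cls,
        permittivities: Sequence[complex | PermittivitySpectrum],
        thicknesses: Sequence[float],
    ) -> "LayerStack":
        """Ambient + interior layers + substrate from parallel sequences.

        ``thicknesses`` lists only the interior layers, so it must be two
        entries shorter than ``permittivities``.
        """
        if len(thicknesses) != len(permittivities) - 2:
            raise ValidationError("need len(thicknesses) == len(permittivities) - 2")
        layers = [Layer(permittivities[0], None)]
        layers += [Layer(e, t) for e, t in zip(permittivities[1:-1], thicknesses)]
        layers.append(Layer(permittivities[-1], None))
        return cls(layers)

    def eps_profile(self, wavenumber: float | None) -> list[complex]:
        return [layer.eps_at(wavenumber) for layer in self.layers]


def beta_layers(
    stack: LayerStack,
    q: float | np.ndarray,
    wavenumber: float | None = None,
) -> complex | np.ndarray:
    """Quasi-static reflection coefficient ``beta(q)`` of the stack.

    Downward recursion over interfaces: with ``r_j`` the bare coefficient of
    interface ``j`` and ``beta_below`` the composite value of everything
    underneath across the finite thickness ``d``,

        beta_j = (r_j + beta_below e^{-2 q d}) / (1 + r_j beta_below e^{-2 q d})

    For a two-layer stack the result is the q-independent Fresnel-like value
    ``(eps_2 - eps_1) / (eps_2 + eps_1)``.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0):
        raise ValidationError("q must be > 0")
    eps = stack.eps_profile(wavenumber)
    n = len(eps)

    def iface(j):
        denom = eps[j + 1] + eps[j]
        if denom == 0:
            raise SingularInterfaceError(
                f"interface {j}: eps_above + eps_below == 0"
            )
        return (eps[j + 1] - eps[j]) / denom

    beta = np.full(q_arr.shape, iface(n - 2), dtype=complex)
    for j in range(n - 3, -1, -1):
        r_j = iface(j)
        decay = np.exp(-2.0 * q_arr * stack.layers[j + 1].thickness)
        beta = (r_j + beta * decay) / (1.0 + r_j * beta * decay)
    if np.isscalar(q) or q_arr.ndim == 0:
        return complex(beta)
    return beta


def beta_effective(
    stack: LayerStack,
    z: float | np.ndarray,
    wavenumber: float | None = None,
    *,
    q_min: float = Q_MIN,
    q_max: float = Q_MAX,
    n_q: int = N_Q,
) -> complex | np.ndarray:
    """Momentum-weighted reflection coefficient at evaluation height ``z`` (nm).

    ``beta_eff(z) = int beta(q) q e^{-2qz} dq / int q e^{-2qz} dq`` evaluated
    by trapezoid quadrature on a log-spaced q grid. A two-layer stack returns
    its exact q-independent value.
    """
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z_arr <= 0):
        raise ValidationError("z must be > 0 (the q-weight diverges at z = 0)")
    if len(stack) == 2:
        val = beta_layers(stack, 1.0, wavenumber)
        out = np.full(z_arr.shape, val, dtype=complex)
    else:
        q = np.logspace(math.log10(q_min), math.log10(q_max), n_q)
        beta_q = np.asarray(beta_layers(stack, q, wavenumber))
        weight = q[None, :] * np.exp(-2.0 * np.outer(z_arr, q))
        num = np.trapezoid(beta_q[None, :] * weight, q, axis=1)
        den = np.trapezoid(weight, q, axis=1)
        out = num / den
    if np.isscalar(z) or np.asarray(z).ndim == 0:
        return complex(out[0])
    return out


def fdm_contrast(
    tip: TipModel,
    stack: LayerStack,
    H: float | np.ndarray,
    wavenumber: float | None = None,
) -> complex | np.ndarray:
    """Scattered-field contrast ``sigma(H)`` at instantaneous tip height H (nm).

    Spheroid closed form with two evaluation depths:

        sigma = 1 + beta_0 f_0 / (2 (1 - beta_1 f_1))
        f_i = (g - (r + 2H + W_i)/(2L)) ln(4L/(r + 4H + 2W_i)) / ln(4L/r)

    with ``W_0 = 1.31 r L / (L + 2r)``, ``W_1 = r/2``, and ``beta_i`` the
    momentum-weighted stack response evaluated at ``z = H + W_i``. A stack
    with zero reflection gives sigma = 1 identically.
    """
    H_arr = np.atleast_1d(np.asarray(H, dtype=float))
    if np.any(H_arr < 0):
        raise ValidationError("H must be >= 0")
    r, L, g = tip.apex_radius_r, tip.spheroid_length_L, complex(tip.g_factor)
    w0 = 1.31 * r * L / (L + 2.0 * r)
    w1 = r / 2.0
    log_norm = math.log(4.0 * L / r)

    def f_of(w):
        return (g - (r + 2.0 * H_arr + w) / (2.0 * L)) * np.log(
            4.0 * L / (r + 4.0 * H_arr + 2.0 * w)
        ) / log_norm

    beta0 = np.atleast_1d(beta_effective(stack, H_arr + w0, wavenumber))
    beta1 = np.atleast_1d(beta_effective(stack, H_arr + w1, wavenumber))
    sigma = 1.0 + beta0 * f_of(w0) / (2.0 * (1.0 - beta1 * f_of(w1)))
    if np.isscalar(H) or np.asarray(H).ndim == 0:
        return complex(sigma[0])
    return sigma


@dataclasses.dataclass(frozen=True)
class DemodResult:
    """Complex demodulated contrast at one harmonic of the tapping frequency."""

    harmonic_n: int
    sigma_n: complex

    @property
    def s_n(self) -> float:
        return abs(self.sigma_n)

    @property
    def phi_n(self) -> float:
        return wrap_phase_deg(math.degrees(cmath.phase(self.sigma_n)))


def demodulate(
    tip: TipModel,
    stack: LayerStack,
    wavenumber: float | None = None,
    harmonic_n: int = 2,
    n_theta_samples: int = 256,
) -> DemodResult:
    """Demodulate the tapping-cycle contrast at harmonic ``n``.

    The tip height follows ``H(theta) = min_height + a (1 + cos theta)``; the
    n-th Fourier coefficient ``sigma_n = (1/2pi) \\oint sigma(H) e^{-i n theta}``
    is evaluated by uniform sampling and an FFT, which is spectrally accurate
    for this smooth periodic integrand.
    """
    if harmonic_n < 1:
        raise ValidationError("harmonic_n must be >= 1")
    n = int(n_theta_samples)
    if n < 64 or (n & (n - 1)) != 0:
        raise ValidationError("n_theta_samples must be a power of two >= 64")
    if harmonic_n >= n // 2:
        raise ValidationError("n_theta_samples too small to resolve the harmonic")
    theta = 2.0 * np.pi * np.arange(n) / n
    H = tip.min_height + tip.tapping_amplitude_a * (1.0 + np.cos(theta))
    sigma = np.asarray(fdm_contrast(tip, stack, H, wavenumber))
    coeffs = np.fft.fft(sigma) / n
    return DemodResult(harmonic_n, complex(coeffs[harmonic_n]))


@dataclasses.dataclass(frozen=True)
class NormalizedContrast:
    """Sample-over-reference demodulated contrast at one wavenumber."""

    wavenumber: float
    eta_n: complex
    reference_label: str = ""

    @property
    def s_ratio(self) -> float:
        return abs(self.eta_n)

    @property
    def phi_diff(self) -> float:
        return wrap_phase_deg(math.degrees(cmath.phase(self.eta_n)))


def normalized_spectrum(
    tip: TipModel,
    sample_stack: LayerStack,
    reference_stack: LayerStack,
    grid: Sequence[float],
    harmonic_n: int = 2,
    *,
    n_theta_samples: int = 256,
    reference_label: str = "",
) -> list[NormalizedContrast]:
    """Demodulated sample contrast referenced to a second stack, per wavenumber.

    A vanishing reference coefficient at a grid point yields ``eta = nan+nanj``
    for that point rather than aborting the sweep.
    """
    out = []
    for nu in np.asarray(grid, dtype=float):
        s = demodulate(tip, sample_stack, nu, harmonic_n, n_theta_samples).sigma_n
        r = demodulate(tip, reference_stack, nu, harmonic_n, n_theta_samples).sigma_n
        eta = s / r if r != 0 else complex(float("nan"), float("nan"))
        out.append(NormalizedContrast(float(nu), eta, reference_label))
    return out


def _chord_stack(
    ambient_stack: LayerStack,
    material_eps: complex | PermittivitySpectrum,
    top_depth: float,
    thickness: float,
) -> LayerStack:
    """Insert a material slab at ``top_depth`` below the stack's substrate top."""
    layers = list(ambient_stack.layers)
    substrate = layers.pop()
    if top_depth > 0:
        layers.append(Layer(substrate.permittivity, top_depth))
    layers.append(Layer(material_eps, thickness))
    layers.append(substrate)
    return LayerStack(layers)


def sphere_profile(
    tip: TipModel,
    sphere_diameter: float,
    material_eps: complex | PermittivitySpectrum,
    ambient_stack: LayerStack,
    lateral_offsets: Sequence[float],
    wavenumber: float | None = None,
    harmonic_n: int = 2,
    *,
    visibility_depth: float = 200.0,
    n_theta_samples: int = 128,
) -> dict:
    """Predicted lateral amplitude/phase profile over a hanging sphere.

    The sphere hangs tangent to the underside of the last finite layer; at
    each lateral offset the sample is approximated by the local vertical chord
    of the sphere inserted into the substrate half-space, truncated below the
    visibility depth. Returns offsets, ``s_n``, ``phi_n`` arrays plus the
    sphere-free background values.
    """
    if sphere_diameter <= 0:
        raise ValidationError("sphere_diameter must be > 0")
    offsets = np.asarray(lateral_offsets, dtype=float)
    if not np.allclose(np.sort(offsets), np.sort(-offsets), atol=1e-9):
        raise ValidationError("lateral_offsets must be symmetric about 0")
    radius = sphere_diameter / 2.0
    sigma_bg = demodulate(
        tip, ambient_stack, wavenumber, harmonic_n, n_theta_samples
    ).sigma_n
    sigmas = np.empty(offsets.shape, dtype=complex)
    for i, x in enumerate(offsets):
        if abs(x) >= radius:
            sigmas[i] = sigma_bg
            continue
        half_chord = math.sqrt(radius**2 - x**2)
        top = radius - half_chord
        bottom = radius + half_chord
        top_c = min(top, visibility_depth)
        bottom_c = min(bottom, visibility_depth)
        if bottom_c - top_c <= 0:
            sigmas[i] = sigma_bg
            continue
        stack = _chord_stack(ambient_stack, material_eps, top_c, bottom_c - top_c)
        sigmas[i] = demodulate(
            tip, stack, wavenumber, harmonic_n, n_theta_samples
        ).sigma_n
    return {
        "offsets_nm": offsets,
        "s_n": np.abs(sigmas),
        "phi_n_deg": wrap_phase_deg(np.degrees(np.angle(sigmas))),
        "background_s_n": abs(sigma_bg),
        "background_phi_deg": wrap_phase_deg(math.degrees(cmath.phase(sigma_bg))),
    }


def disc_profile(
    tip: TipModel,
    disc_diameter: float,
    thickness: float,
    material_eps: complex | PermittivitySpectrum,
    ambient_stack: LayerStack,
    lateral_offsets: Sequence[float],
    wavenumber: float | None = None,
    harmonic_n: int = 2,
    *,
    n_theta_samples: int = 128,
) -> dict:
    """Profile over a flattened disc of constant thickness adhered to the membrane."""
    if disc_diameter <= 0 or thickness <= 0:
        raise ValidationError("disc_diameter and thickness must be > 0")
    offsets = np.asarray(lateral_offsets, dtype=float)
    radius = disc_diameter / 2.0
    sigma_bg = demodulate(
        tip, ambient_stack, wavenumber, harmonic_n, n_theta_samples
    ).sigma_n
    disc_stack = _chord_stack(ambient_stack, material_eps, 0.0, thickness)
    sigma_disc = demodulate(
        tip, disc_stack, wavenumber, harmonic_n, n_theta_samples
    ).sigma_n
    sigmas = np.where(np.abs(offsets) < radius, sigma_disc, sigma_bg)
    return {
        "offsets_nm": offsets,
        "s_n": np.abs(sigmas),
        "phi_n_deg": wrap_phase_deg(np.degrees(np.angle(sigmas))),
        "background_s_n": abs(sigma_bg),
        "background_phi_deg": wrap_phase_deg(math.degrees(cmath.phase(sigma_bg))),
    }


def profile_fwhm_crossing(x: np.ndarray, y: np.ndarray, baseline: float) -> float:
    """FWHM of a single-peaked profile by linear interpolation of the
    half-maximum crossings above ``baseline``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float) - baseline
    i_max = int(np.argmax(y))
    half = y[i_max] / 2.0
    if y[i_max] <= 0:
        raise ValidationError("profile has no peak above the baseline")

    def cross(idx_range, forward):
        prev = i_max
        for i in idx_range:
            if y[i] < half:
                x0, x1 = x[i], x[prev]
                y0, y1 = y[i], y[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        raise ValidationError("profile does not fall below half maximum")

    left = cross(range(i_max - 1, -1, -1), False)
    right = cross(range(i_max + 1, len(y)), True)
    return float(right - left)
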