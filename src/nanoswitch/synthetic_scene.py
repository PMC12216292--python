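"""Seeded generators for images, switching traces, and interferograms.

Every generator returns the artifact together with a plain-dict ground-truth
record whose analytic values (areas, circularities, plateau means) are
computed from the continuous model, never from the raster or the sampled
trace, so downstream estimator error is attributable to the estimator.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import AliasingError, ValidationError
from .image_analysis import NearFieldImage
from .nanoftir import UM_TO_CM, Interferogram
from .transient_analysis import SignalTrace, sigmoid_step

__all__ = [
    "VesicleSpec",
    "SceneSpec",
    "EpochSpec",
    "TraceSpec",
    "render_image",
    "render_topography",
    "render_state_pair",
    "render_trace",
    "render_interferogram",
    "harmonic_boundary_metrics",
    "alternating_epochs",
]


@dataclasses.dataclass(frozen=True)
class VesicleSpec:
    """One flat-top vesicle disc with a raised-cosine fringe annulus."""

    cx_nm: float
    cy_nm: float
    radius_nm: float
    interior_phase_deg: float = 30.0
    interior_amplitude: float = 20.0
    fringe_width_nm: float = 100.0
    topography_bump_nm: float = 0.0  # optional mechanical-footprint channel


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Full image scene: geometry, channel values, noise, and a seed."""

    image_size: tuple[int, int]  # (ny, nx) pixels
    pixel_size_nm: float
    vesicles: tuple[VesicleSpec, ...]
    background_amplitude: float = 5.0
    background_phase_deg: float = 10.0
    noise_sigma_amplitude: float = 0.0
    noise_sigma_phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be > 0")
        for v in self.vesicles:
            if v.fringe_width_nm <= 0:
                raise ValidationError("fringe_width_nm must be > 0")
            if v.radius_nm <= self.pixel_size_nm:
                raise ValidationError("vesicle radius must exceed the pixel size")


def _pixel_grid(scene: SceneSpec):
    ny, nx = scene.image_size
    ps = scene.pixel_size_nm
    y = (np.arange(ny) + 0.5) * ps
    x = (np.arange(nx) + 0.5) * ps
    return np.meshgrid(y, x, indexing="ij")


def _raised_cosine_weight(offset: np.ndarray, fringe_width: float) -> np.ndarray:
    """1 inside the boundary, smooth ramp to 0 across [0, fringe_width]."""
    w = np.zeros_like(offset)
    w[offset <= 0] = 1.0
    ramp = (offset > 0) & (offset < fringe_width)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * offset[ramp] / fringe_width))
    return w


def _overlap_warnings(scene: SceneSpec) -> list[str]:
    notes = []
    vs = scene.vesicles
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            d = math.hypot(vs[i].cx_nm - vs[j].cx_nm, vs[i].cy_nm - vs[j].cy_nm)
            reach = (
                vs[i].radius_nm
                + vs[j].radius_nm
                + max(vs[i].fringe_width_nm, vs[j].fringe_width_nm)
            )
            if d < reach:
                notes.append(f"vesicles {i} and {j} overlap (separation {d:.1f} nm)")
    return notes


def render_image(scene: SceneSpec) -> tuple[NearFieldImage, dict]:
    """Render amplitude/phase rasters plus the ground-truth record."""
    yy, xx = _pixel_grid(scene)
    amp = np.full(scene.image_size, scene.background_amplitude, dtype=float)
    phase = np.full(scene.image_size, scene.background_phase_deg, dtype=float)
    for v in scene.vesicles:
        d = np.hypot(xx - v.cx_nm, yy - v.cy_nm)
        w = _raised_cosine_weight(d - v.radius_nm, v.fringe_width_nm)
        amp = np.where(
            w > 0, scene.background_amplitude + (v.interior_amplitude - scene.background_amplitude) * w, amp
        )
        phase = np.where(
            w > 0, scene.background_phase_deg + (v.interior_phase_deg - scene.background_phase_deg) * w, phase
        )
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma_amplitude > 0:
        amp = amp + rng.normal(0.0, scene.noise_sigma_amplitude, scene.image_size)
    if scene.noise_sigma_phase > 0:
        phase = phase + rng.normal(0.0, scene.noise_sigma_phase, scene.image_size)
    truth = {
        "scene": dataclasses.asdict(scene),
        "vesicles": [
            {
                "center_nm": [v.cx_nm, v.cy_nm],
                "radius_nm": v.radius_nm,
                "area_nm2": math.pi * v.radius_nm**2,
                "perimeter_nm": 2.0 * math.pi * v.radius_nm,
                "circularity": 1.0,
            }
            for v in scene.vesicles
        ],
        "warnings": _overlap_warnings(scene),
    }
    image = NearFieldImage(
        amp,
        phase,
        scene.pixel_size_nm,
        metadata={"seed": scene.seed, "normalization": "raw"},
    )
    return image, truth


def render_topography(scene: SceneSpec) -> np.ndarray:
    """Optional mechanical-footprint channel: one Gaussian bump per vesicle.

    Bump heights of 1-2 nm emulate the slight upward membrane displacement a
    vesicle causes; the channel is documentation parity only and feeds no
    estimator.
    """
    yy, xx = _pixel_grid(scene)
    topo = np.zeros(scene.image_size, dtype=float)
    for v in scene.vesicles:
        if v.topography_bump_nm <= 0:
            continue
        d2 = (xx - v.cx_nm) ** 2 + (yy - v.cy_nm) ** 2
        topo += v.topography_bump_nm * np.exp(-d2 / (2.0 * (v.radius_nm / 2.0) ** 2))
    return topo


def harmonic_boundary_metrics(
    alpha: float, harmonic_order: int, n_phi: int = 4096
) -> tuple[float, float, float]:
    """(area, perimeter, circularity) of r(phi) = 1 + alpha cos(m phi).

    Evaluated for unit mean radius by dense trapezoid quadrature of the exact
    boundary integrals; scale-invariant, so usable as the analytic truth for
    any absolute radius.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi + 1)
    r = 1.0 + alpha * np.cos(harmonic_order * phi)
    if np.any(r <= 0):
        raise ValidationError("boundary radius must stay positive")
    dr = -alpha * harmonic_order * np.sin(harmonic_order * phi)
    area = 0.5 * np.trapezoid(r**2, phi)
    perimeter = np.trapezoid(np.sqrt(r**2 + dr**2), phi)
    return float(area), float(perimeter), float(4.0 * math.pi * area / perimeter**2)


def _solve_deformation(circularity_factor: float, harmonic_order: int) -> float:
    """Bisection for the harmonic amplitude hitting a target circularity ratio."""
    if not 0.0 < circularity_factor <= 1.0:
        raise ValidationError("circularity_factor must lie in (0, 1]")
    if circularity_factor == 1.0:
        return 0.0
    alpha_max = 0.9 / max(1, harmonic_order)  # keep the boundary star-shaped
    _, _, circ_min = harmonic_boundary_metrics(alpha_max, harmonic_order)
    if circularity_factor < circ_min:
        raise ValidationError(
            f"circularity_factor {circularity_factor} unreachable with harmonic "
            f"order {harmonic_order}; feasible range is [{circ_min:.3f}, 1]"
        )
    lo, hi = 0.0, alpha_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        _, _, circ = harmonic_boundary_metrics(mid, harmonic_order)
        if circ > circularity_factor:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def render_state_pair(
    scene: SceneSpec,
    area_factor: float,
    circularity_factor: float,
    seed: int | None = None,
    harmonic_order: int = 3,
) -> tuple[NearFieldImage, NearFieldImage, dict]:
    """Render a round reference state and a deformed, rescaled second state.

    The second state's boundary is ``r(phi) = R_c (1 + alpha cos(m phi))``
    with ``alpha`` bisected against the analytic boundary so its true
    circularity is ``circularity_factor`` times the disc's, and ``R_c`` chosen
    so its true area is ``area_factor`` times the disc's.
    """
    if area_factor <= 0:
        raise ValidationError("area_factor must be > 0")
    if len(scene.vesicles) != 1:
        raise ValidationError("state pairs are defined for single-vesicle scenes")
    v = scene.vesicles[0]
    alpha = _solve_deformation(circularity_factor, harmonic_order)
    area_unit, _, circ_cis = harmonic_boundary_metrics(alpha, harmonic_order)
    radius_cis = v.radius_nm * math.sqrt(area_factor * math.pi / area_unit)

    seed = scene.seed if seed is None else seed
    scene_trans = dataclasses.replace(scene, seed=seed)
    image_trans, _ = render_image(scene_trans)

    yy, xx = _pixel_grid(scene)
    d = np.hypot(xx - v.cx_nm, yy - v.cy_nm)
    phi = np.arctan2(yy - v.cy_nm, xx - v.cx_nm)
    boundary = radius_cis * (1.0 + alpha * np.cos(harmonic_order * phi))
    w = _raised_cosine_weight(d - boundary, v.fringe_width_nm)
    amp = scene.background_amplitude + (v.interior_amplitude - scene.background_amplitude) * w
    phase = scene.background_phase_deg + (v.interior_phase_deg - scene.background_phase_deg) * w
    rng = np.random.default_rng(seed + 1)
    if scene.noise_sigma_amplitude > 0:
        amp = amp + rng.normal(0.0, scene.noise_sigma_amplitude, scene.image_size)
    if scene.noise_sigma_phase > 0:
        phase = phase + rng.normal(0.0, scene.noise_sigma_phase, scene.image_size)
    image_cis = NearFieldImage(
        amp, phase, scene.pixel_size_nm, metadata={"seed": seed + 1, "normalization": "raw"}
    )

    area_trans = math.pi * v.radius_nm**2
    truth = {
        "area_factor": area_factor,
        "circularity_factor": circularity_factor,
        "harmonic_order": harmonic_order,
        "alpha": alpha,
        "trans": {"area_nm2": area_trans, "circularity": 1.0, "radius_nm": v.radius_nm},
        "cis": {
            "area_nm2": area_factor * area_trans,
            "circularity": circ_cis,
            "radius_nm": radius_cis,
        },
    }
    return image_trans, image_cis, truth


@dataclasses.dataclass(frozen=True)
class EpochSpec:
    """One illumination epoch of the continuous switching model."""

    illumination_nm: int  # 365 or 465
    duration_s: float
    delay_t_d: float
    growth_tau: float
    amp_baseline: float
    amp_step: float
    phase_baseline: float
    phase_step: float


@dataclasses.dataclass(frozen=True)
class TraceSpec:
    """Sampled switching trace: epochs, sampling time, noise, drift, seed."""

    epochs: tuple[EpochSpec, ...]
    sampling_time_t_p: float
    noise_sigma_amplitude: float = 0.0
    noise_sigma_phase: float = 0.0
    drift_slope: float = 0.0  # per s, applied to the amplitude channel
    seed: int = 0
    sampling: str = "boxcar"  # or "midpoint"
    subsamples: int = 64

    def __post_init__(self) -> None:
        if self.sampling_time_t_p <= 0:
            raise ValidationError("sampling_time_t_p must be > 0")
        if not self.epochs:
            raise ValidationError("need at least one epoch")
        for e in self.epochs:
            if e.duration_s <= e.delay_t_d:
                raise ValidationError("epoch duration must exceed delay_t_d")
            if e.duration_s < self.sampling_time_t_p:
                raise ValidationError("t_p longer than an epoch")
            if e.growth_tau <= 0:
                raise ValidationError("growth_tau must be > 0")
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if prev.illumination_nm == cur.illumination_nm:
                raise ValidationError("illumination labels must alternate")
        if self.sampling not in ("boxcar", "midpoint"):
            raise ValidationError("sampling must be 'boxcar' or 'midpoint'")
        if self.subsamples < 32:
            raise ValidationError("boxcar integration needs >= 32 sub-samples")


def alternating_epochs(
    n_epochs: int,
    duration_s: float,
    delay_t_d: float,
    growth_tau: float,
    amp_start: float,
    amp_step: float,
    phase_start: float,
    phase_step: float,
    first_label: int = 365,
) -> tuple[EpochSpec, ...]:
    """Convenience builder: alternating labels with sign-flipping steps so
    each epoch starts where the previous one plateaued."""
    labels = {365: 465, 465: 365}
    epochs = []
    amp, phase, label, sign = amp_start, phase_start, first_label, 1.0
    for _ in range(n_epochs):
        epochs.append(
            EpochSpec(
                label,
                duration_s,
                delay_t_d,
                growth_tau,
                amp,
                sign * amp_step,
                phase,
                sign * phase_step,
            )
        )
        amp += sign * amp_step
        phase += sign * phase_step
        label = labels[label]
        sign = -sign
    return tuple(epochs)


def render_trace(spec: TraceSpec) -> tuple[SignalTrace, dict]:
    """Sample the continuous epoch model with boxcar window integration.

    Each sample is the average of the continuous sigmoid over its sampling
    window (>= 32 sub-samples) — the same convolution-with-t_p that limits
    the real acquisition — time-stamped at the window midpoint.
    """
    rng = np.random.default_rng(spec.seed)
    t_p = spec.sampling_time_t_p
    times, amps, phases, labels = [], [], [], []
    epoch_records = []
    t_offset = 0.0
    for e in spec.epochs:
        n_win = int(math.floor(e.duration_s / t_p + 1e-9))
        mid = (np.arange(n_win) + 0.5) * t_p
        if spec.sampling == "midpoint":
            amp_vals = sigmoid_step(mid, e.amp_step, e.delay_t_d, e.growth_tau, e.amp_baseline)
            phase_vals = sigmoid_step(mid, e.phase_step, e.delay_t_d, e.growth_tau, e.phase_baseline)
        else:
            # boxcar: average over each window by midpoint sub-sampling
            offsets = (np.arange(spec.subsamples) + 0.5) / spec.subsamples - 0.5
            sub = mid[:, None] + offsets[None, :] * t_p
            amp_vals = sigmoid_step(
                sub, e.amp_step, e.delay_t_d, e.growth_tau, e.amp_baseline
            ).mean(axis=1)
            phase_vals = sigmoid_step(
                sub, e.phase_step, e.delay_t_d, e.growth_tau, e.phase_baseline
            ).mean(axis=1)
        times.append(t_offset + mid)
        amps.append(amp_vals)
        phases.append(phase_vals)
        labels.append(np.full(n_win, e.illumination_nm))
        epoch_records.append(
            {
                "illumination_nm": e.illumination_nm,
                "switch_time_s": t_offset,
                "delay_t_d": e.delay_t_d,
                "growth_tau": e.growth_tau,
                "amp_baseline": e.amp_baseline,
                "amp_step": e.amp_step,
                "phase_baseline": e.phase_baseline,
                "phase_step": e.phase_step,
                "amp_plateau_final": e.amp_baseline + e.amp_step,
                "phase_plateau_final": e.phase_baseline + e.phase_step,
            }
        )
        t_offset += n_win * t_p
    time = np.concatenate(times)
    s2 = np.concatenate(amps)
    phi2 = np.concatenate(phases)
    if spec.drift_slope:
        s2 = s2 + spec.drift_slope * time
    if spec.noise_sigma_amplitude > 0:
        s2 = s2 + rng.normal(0.0, spec.noise_sigma_amplitude, time.size)
    if spec.noise_sigma_phase > 0:
        phi2 = phi2 + rng.normal(0.0, spec.noise_sigma_phase, time.size)
    trace = SignalTrace(time, s2, phi2, np.concatenate(labels), t_p)
    truth = {
        "spec": dataclasses.asdict(spec),
        "epochs": epoch_records,
        "t_p_s": t_p,
    }
    return trace, truth


def render_interferogram(
    components: Sequence[tuple[float, float, float]],
    scan_length_um: float,
    n_points: int,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Interferogram:
    """Synthesize a detector trace for spectral components (nu_cm1, A, phase_rad).

    The abscissa is the single-pass mirror displacement; each component
    contributes ``A cos(2 pi nu * 2x + phase)`` with the optical path
    difference ``2x``. Components beyond the OPD Nyquist limit raise.
    """
    if n_points < 64:
        raise ValidationError("n_points must be >= 64")
    if scan_length_um <= 0:
        raise ValidationError("scan_length_um must be > 0")
    dx_cm = (scan_length_um / n_points) * UM_TO_CM
    nyquist = 1.0 / (4.0 * dx_cm)  # OPD doubles the effective step
    x_cm = np.arange(n_points) * dx_cm
    detector = np.zeros(n_points)
    for nu, amplitude, phase in components:
        if nu >= nyquist:
            raise AliasingError(
                f"component at {nu} cm^-1 exceeds the OPD Nyquist limit "
                f"{nyquist:.1f} cm^-1"
            )
        detector += amplitude * np.cos(2.0 * np.pi * nu * 2.0 * x_cm + phase)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        detector = detector + rng.normal(0.0, noise_sigma, n_points)
    return Interferogram(x_cm / UM_TO_CM, detector, scan_length_um)
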