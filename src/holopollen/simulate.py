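"""Synthetic pollen phantoms and off-axis image-plane holograms.

The forward model is image-plane off-axis holography: the in-focus complex
image field ``O`` of a (mostly transparent) pollen grain interferes with a
tilted plane reference ``R`` on the detector, producing the intensity

    H = |O + R|^2 = |O|^2 + |R|^2 + O R* + O* R .

A pollen grain acts as a pure phase object: its phase map is the projection
of refractive-index contrast along the optical axis, so a cytoplasm-filled
(viable) grain shows a nearly hemispherical phase dome while an aborted
(non-viable) grain shows a nearly flat, low phase plateau with a residual
wall at the exine.

Everything here carries ground truth, so downstream reconstruction,
unwrapping and morphometry can be validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


import numpy as np
from scipy import integrate
from scipy.ndimage import gaussian_filter

__all__ = [
    "PollenClass",
    "OpticsMeta",
    "PollenPhantom",
    "ReferenceWave",
    "ComplexField",
    "FieldRole",
    "Hologram",
    "make_phantom",
    "make_reference",
    "forward_hologram",
    "generate_population",
]


class PollenClass(str, Enum):
    VIABLE = "viable"
    NONVIABLE = "nonviable"


class FieldRole(str, Enum):
    OBJECT = "object"
    REFERENCE = "reference"
    RECONSTRUCTION = "reconstruction"


# fraction of the disk radius occupied by the interior plateau of a
# non-viable grain; the remainder is the exine wall (rim)
_NONVIABLE_PLATEAU_RHO = 0.7
# plateau height as a fraction of the rim (wall) height
_NONVIABLE_PLATEAU_FRAC = 0.85


@dataclass(frozen=True)
class OpticsMeta:
    """Acquisition metadata for a holographic microscope.

    wavelength_nm
        Illumination wavelength in nanometres (650 nm diode laser default).
    pixel_pitch_um
        Detector pixel pitch in micrometres; the object-plane sampling is
        ``pixel_pitch_um / magnification``.
    magnification, numerical_aperture
        Imaging objective parameters (40x / 0.75 NA default).
    """

    wavelength_nm: float = 650.0
    pixel_pitch_um: float = 5.2
    magnification: float = 40.0
    numerical_aperture: float = 0.75

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if not 0 < self.numerical_aperture <= 1:
            raise ValueError("numerical_aperture must be in (0, 1]")
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")

    @property
    def object_pixel_um(self) -> float:
        """Object-plane size of one detector pixel in micrometres."""
        return self.pixel_pitch_um / self.magnification

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "pixel_pitch_um": self.pixel_pitch_um,
            "magnification": self.magnification,
            "numerical_aperture": self.numerical_aperture,
        }


@dataclass
class PollenPhantom:
    """Ground-truth synthetic pollen grain.

    ``true_phase`` is the projected phase map in radians (zero outside
    ``true_mask``); ``peak_phase`` its maximum, ``rim_phase`` the exine wall
    height (non-viable grains only, else 0).
    """

    label: PollenClass
    center: tuple[float, float]
    radius: float
    peak_phase: float
    rim_phase: float
    true_phase: np.ndarray
    true_mask: np.ndarray

    @property
    def mask_mean_phase(self) -> float:
        """Mean of the true phase over the true mask (radians)."""
        return float(self.true_phase[self.true_mask].mean())


@dataclass(frozen=True)
class ReferenceWave:
    """Tilted plane reference wave ``R = A exp(i 2π (f_r·row + f_c·col))``.

    ``tilt`` is the spatial-frequency pair in cycles/pixel; both components
    must be below Nyquist (0.5).
    """

    tilt: tuple[float, float]
    amplitude: float = 1.0
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if abs(self.tilt[0]) >= 0.5 or abs(self.tilt[1]) >= 0.5:
            raise ValueError("reference tilt components must be below Nyquist (|f| < 0.5)")
        if self.amplitude <= 0:
            raise ValueError("reference amplitude must be > 0")

    def field(self, shape: tuple[int, int] | None = None) -> "ComplexField":
        shape = shape or self.shape
        if shape is None:
            raise ValueError("shape required to render the reference field")
        return make_reference(shape, self.tilt, self.amplitude)


@dataclass
class ComplexField:
    """A 2D complex optical field (object, reference or reconstruction)."""

    values: np.ndarray
    role: FieldRole = FieldRole.OBJECT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("ComplexField expects a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ComplexField entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Hologram:
    """Recorded off-axis hologram intensity plus acquisition metadata."""

    values: np.ndarray
    meta: OpticsMeta = field(default_factory=OpticsMeta)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("Hologram expects a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _radial_map(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rows, cols)


def _nonviable_unit_profile(rho: np.ndarray) -> np.ndarray:
    """Unit-height phase profile of an aborted grain vs normalized radius.

    A low plateau across the interior, rising smoothly to the exine wall
    (height 1) over the outer annulus, then falling to zero at the edge.
    """
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    p = _NONVIABLE_PLATEAU_RHO
    crest = 0.9  # wall crest; the exine boundary falls abruptly beyond it
    inner = rho <= p
    out[inner] = _NONVIABLE_PLATEAU_FRAC
    rise = (rho > p) & (rho <= crest)
    s = (rho[rise] - p) / (crest - p)
    out[rise] = _NONVIABLE_PLATEAU_FRAC + (1.0 - _NONVIABLE_PLATEAU_FRAC) * 0.5 * (
        1 - np.cos(np.pi * s)
    )
    fall = (rho > crest) & (rho <= 1.0)
    out[fall] = 0.5 * (1 + np.cos(np.pi * (rho[fall] - crest) / (1.0 - crest)))
    return out


def _viable_unit_profile(rho: np.ndarray) -> np.ndarray:
    """Unit-height hemispherical cap profile sqrt(1 - rho^2)."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    inside = rho <= 1.0
    out[inside] = np.sqrt(np.clip(1.0 - rho[inside] ** 2, 0.0, None))
    return out


def _unit_disk_mean(profile) -> float:
    """Area mean of a radial unit profile over the unit disk (2∫ f(ρ)ρ dρ)."""
    val, _ = integrate.quad(lambda r: 2.0 * r * float(profile(np.array([r]))[0]), 0.0, 1.0)
    return val


# analytic mask-means of the unit-height profiles; the hemisphere's is 2/3
_VIABLE_UNIT_MEAN = 2.0 / 3.0
_NONVIABLE_UNIT_MEAN = _unit_disk_mean(_nonviable_unit_profile)


def make_phantom(
    label: PollenClass | str,
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    peak_phase: float,
    texture_sd: float = 0.0,
    seed: int | None = None,
    edge_sigma_px: float = 0.0,
) -> PollenPhantom:
    """Build a ground-truth pollen phantom phase map.

    Viable grains get a hemispherical cap ``peak_phase * sqrt(1-(r/R)^2)``;
    non-viable grains a low plateau with a raised exine wall whose crest is
    ``peak_phase``. ``texture_sd`` adds smoothed zero-mean phase texture
    inside the mask; ``edge_sigma_px`` softens the profile with a Gaussian
    blur (the rescaled map keeps the analytic mask-mean).

    Raises ``ValueError`` when the disk does not fit inside the image or the
    geometry/phase parameters are invalid.
    """
    label = PollenClass(label)
    if radius < 3:
        raise ValueError("phantom radius must be >= 3 px")
    if peak_phase < 0:
        raise ValueError("peak_phase must be >= 0")
    margin = radius + 3.0 * edge_sigma_px
    if (
        center[0] - margin < 0
        or center[1] - margin < 0
        or center[0] + margin > shape[0] - 1
        or center[1] + margin > shape[1] - 1
    ):
        raise ValueError("phantom disk does not fit inside the image bounds")

    r = _radial_map(shape, center)
    rho = r / radius
    if label is PollenClass.VIABLE:
        phase = peak_phase * _viable_unit_profile(rho)
        rim_phase = 0.0
        unit_mean = _VIABLE_UNIT_MEAN
    else:
        phase = peak_phase * _nonviable_unit_profile(rho)
        rim_phase = peak_phase
        unit_mean = _NONVIABLE_UNIT_MEAN
    mask = r <= radius

    if texture_sd > 0:
        rng = np.random.default_rng(seed)
        tex = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=2.0)
        inside = mask & (rho < 0.9)
        if inside.any():
            tex = tex - tex[inside].mean()
            scale = texture_sd / max(tex[inside].std(), 1e-12)
            phase = phase + np.where(inside, tex * scale, 0.0)
            phase = np.clip(phase, 0.0, None)

    if edge_sigma_px > 0:
        phase = gaussian_filter(phase, sigma=edge_sigma_px)
        phase = np.where(mask, phase, 0.0)
        # restore the analytic mask-mean lost to smoothing leakage
        target_mean = peak_phase * unit_mean
        cur = phase[mask].mean()
        if cur > 0:
            phase = phase * (target_mean / cur)
    else:
        phase = np.where(mask, phase, 0.0)

    return PollenPhantom(
        label=label,
        center=(float(center[0]), float(center[1])),
        radius=float(radius),
        peak_phase=float(peak_phase),
        rim_phase=float(rim_phase),
        true_phase=phase,
        true_mask=mask,
    )


def make_reference(
    shape: tuple[int, int],
    tilt: tuple[float, float],
    amplitude: float = 1.0,
) -> ComplexField:
    """Render a tilted plane reference wave as a complex field."""
    ref = ReferenceWave(tilt=(float(tilt[0]), float(tilt[1])), amplitude=float(amplitude))
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    carrier = 2.0 * np.pi * (ref.tilt[0] * rows + ref.tilt[1] * cols)
    values = ref.amplitude * np.exp(1j * carrier)
    return ComplexField(values=values, role=FieldRole.REFERENCE)


def forward_hologram(
    phase: np.ndarray,
    object_amplitude: np.ndarray | float,
    reference: ReferenceWave,
    noise_sd: float = 0.0,
    seed: int | None = None,
    meta: OpticsMeta | None = None,
) -> Hologram:
    """Render the off-axis hologram ``H = |O + R|^2`` (+ detector noise).

    ``phase`` is the object phase map in radians and ``object_amplitude``
    the transmitted amplitude (scalar or per-pixel); the object field is
    ``O = amplitude * exp(i*phase)``. Gaussian intensity noise of standard
    deviation ``noise_sd`` is added and the result clipped at zero.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase must be a 2D array")
    amp = np.broadcast_to(np.asarray(object_amplitude, dtype=np.float64), phase.shape)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ref_field = make_reference(phase.shape, reference.tilt, reference.amplitude).values
    obj = amp * np.exp(1j * phase)
    values = np.abs(obj + ref_field) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, phase.shape), 0.0, None)
    return Hologram(values=values, meta=meta or OpticsMeta(), noise_sd=float(noise_sd))


_DEFAULT_TILT = (0.125, 0.125)


def generate_population(
    n: int = 508,
    viable_fraction: float = 0.5,
    mean_phase_centers: tuple[float, float] = (8.72, 4.26),
    mean_phase_sd: float = 0.8,
    radius_range: tuple[float, float] = (80.0, 100.0),
    image_shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int | None = None,
    tilt: tuple[float, float] = _DEFAULT_TILT,
    reference_amplitude: float = 1.0,
    texture_sd: float = 0.0,
    edge_sigma_px: float = 1.0,
    meta: OpticsMeta | None = None,
) -> list[tuple[Hologram, PollenPhantom]]:
    """Simulate a two-class pollen population, one ROI hologram per grain.

    Each grain draws a viability label (probability ``viable_fraction``) and
    a target mask-mean phase from the class normal (centers default to the
    viable/non-viable population means 8.72 / 4.26 rad, sd 0.8 rad). The
    phantom peak is set so its analytic mask-mean equals the target
    (``peak = 1.5 * target`` for the hemispherical viable profile). Radii
    are uniform in ``radius_range`` scaled to the image size. Fully
    reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("population size n must be >= 1")
    if not 0.0 <= viable_fraction <= 1.0:
        raise ValueError("viable_fraction must be in [0, 1]")
    meta = meta or OpticsMeta()
    ref = ReferenceWave(tilt=tilt, amplitude=reference_amplitude, shape=image_shape)
    # scale the default radius range (set for 256^2 ROIs) to the actual ROI
    scale = min(image_shape) / 256.0
    r_lo, r_hi = radius_range[0] * scale, radius_range[1] * scale
    root = np.random.SeedSequence(seed if seed is not None else np.random.SeedSequence().entropy)
    out: list[tuple[Hologram, PollenPhantom]] = []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        viable = rng.random() < viable_fraction
        label = PollenClass.VIABLE if viable else PollenClass.NONVIABLE
        center_mean = mean_phase_centers[0] if viable else mean_phase_centers[1]
        target = max(rng.normal(center_mean, mean_phase_sd), 0.05)
        unit_mean = _VIABLE_UNIT_MEAN if viable else _NONVIABLE_UNIT_MEAN
        peak = target / unit_mean
        radius = rng.uniform(r_lo, r_hi)
        jitter = 0.015 * min(image_shape)
        center = (
            image_shape[0] / 2.0 + rng.uniform(-jitter, jitter),
            image_shape[1] / 2.0 + rng.uniform(-jitter, jitter),
        )
        phantom = make_phantom(
            label,
            image_shape,
            center,
            radius,
            peak,
            texture_sd=texture_sd,
            seed=int(rng.integers(2**31)),
            edge_sigma_px=edge_sigma_px,
        )
        holo = forward_hologram(
            phantom.true_phase,
            1.0,
            ref,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            meta=meta,
        )
        out.append((holo, phantom))
    return out
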