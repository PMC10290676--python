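"""Synthetic in-line holography scenes and forward hologram formation.

A scene is a complex transmission object ``u = A * exp(i*phi)`` with
amplitude ``A`` in [0, 1] (1 = fully transmitting background) and phase in
radians.  A plane-wave in-line hologram is the propagated intensity
``I = |P_z(u)|^2``; measurement noise is modelled as additive white
Gaussian noise at a stated SNR.

Patterns available: block letters (sharp, "flat"-boundary objects),
USAF-style three-bar groups, and cell-like blobs (smoothed random ellipse
unions with interior phase gradients, standing in for real cell images).
``boundary="random"`` replaces the sharp geometric footprint by an
irregular blob footprint derived from thresholded smoothed noise.

The geometry of the reference simulation study is exposed by
:func:`paper_geometry` / :func:`standard_scene`: wavelength 500 nm, pixel
pitch 5.86 um, 500x500 hologram padded to 1000x1000 for reconstruction,
recording distance 6 cm, and a 0.5 mm plane interval for multi-distance
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import ComplexField, Hologram, InvalidParameterError
from .propagation import crop_to, pad_constant, propagate

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_object",
    "forward_hologram",
    "mpr_holograms",
    "add_gaussian_noise",
    "paper_geometry",
    "standard_scene",
    "opaque_disk_object",
]

# 5x7 block glyphs for letter scenes (1 = object pixel)
_GLYPHS = {
    "H": ["10001", "10001", "10001", "11111", "10001", "10001", "10001"],
    "M": ["10001", "11011", "10101", "10101", "10001", "10001", "10001"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    "R": ["11110", "10001", "10001", "11110", "10100", "10010", "10001"],
    "O": ["01110", "10001", "10001", "10001", "10001", "10001", "01110"],
    "A": ["01110", "10001", "10001", "11111", "10001", "10001", "10001"],
}


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a synthetic complex transmission object."""

    shape: tuple[int, int] = (500, 500)
    pitch: float = 5.86e-6
    wavelength: float = 500e-9
    amp_pattern: str = "letters"  # letters | bars | blobs
    amp_range: tuple[float, float] = (0.3, 1.0)
    amp_text: str = "HM"
    phase_pattern: str = "letters"
    phase_range: tuple[float, float] = (0.0, 1.0)
    phase_text: str = "PR"
    boundary: str = "flat"  # flat | random
    seed: int = 0

    def __post_init__(self) -> None:
        a0, a1 = self.amp_range
        if not (0 <= a0 <= a1 <= 1):
            raise InvalidParameterError("amplitude range must be ordered within [0, 1]")
        if self.phase_range[0] > self.phase_range[1]:
            raise InvalidParameterError("phase range must be ordered")
        if self.boundary not in ("flat", "random"):
            raise InvalidParameterError(f"unknown boundary style {self.boundary!r}")


@dataclass
class GroundTruth:
    """Reference images accompanying a synthetic object."""

    amplitude: np.ndarray
    phase: np.ndarray
    amp_footprint: np.ndarray
    phase_footprint: np.ndarray


def _rasterize_text(shape, text, scale, offset):
    """Render block glyphs into a boolean image."""
    if not text:
        raise InvalidParameterError("empty pattern text")
    canvas = np.zeros(shape, dtype=bool)
    r0, c0 = offset
    for k, ch in enumerate(text):
        if ch not in _GLYPHS:
            raise InvalidParameterError(f"no glyph for character {ch!r}")
        bitmap = np.array(
            [[cell == "1" for cell in row] for row in _GLYPHS[ch]], dtype=bool
        )
        big = np.kron(bitmap, np.ones((scale, scale), dtype=bool))
        rr = slice(r0, r0 + big.shape[0])
        cc = slice(c0 + k * (big.shape[1] + scale), c0 + k * (big.shape[1] + scale) + big.shape[1])
        canvas[rr, cc] |= big
    return canvas


def _rasterize_bars(shape, offset, bar_w, n_groups=2):
    """USAF-style three-bar groups (horizontal + vertical) at shrinking scales."""
    canvas = np.zeros(shape, dtype=bool)
    r0, c0 = offset
    w = bar_w
    for _ in range(n_groups):
        length = 5 * w
        for i in range(3):  # vertical bars
            c = c0 + i * 2 * w
            canvas[r0 : r0 + length, c : c + w] = True
        rh = r0 + length + w
        for i in range(3):  # horizontal bars
            r = rh + i * 2 * w
            canvas[r : r + w, c0 : c0 + length] = True
        c0 += 6 * w
        w = max(1, w // 2)
    return canvas


def _rasterize_blobs(shape, rng, n_blobs, r_px):
    """Union of random ellipses, smoothed into cell-like blobs."""
    rows, cols = shape
    canvas = np.zeros(shape, dtype=float)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for _ in range(n_blobs):
        cy = rng.uniform(0.3 * rows, 0.7 * rows)
        cx = rng.uniform(0.3 * cols, 0.7 * cols)
        a = rng.uniform(0.6, 1.4) * r_px
        b = rng.uniform(0.6, 1.4) * r_px
        th = rng.uniform(0, np.pi)
        x = (cc - cx) * np.cos(th) + (rr - cy) * np.sin(th)
        y = -(cc - cx) * np.sin(th) + (rr - cy) * np.cos(th)
        canvas = np.maximum(canvas, ((x / a) ** 2 + (y / b) ** 2 <= 1).astype(float))
    return ndimage.gaussian_filter(canvas, r_px / 6) > 0.5


def _random_footprint(shape, rng, n_blobs=3, band=(0.32, 0.68)):
    """Compact blobs with irregular (noise-deformed) boundaries.

    Each blob is an ellipse whose radius is modulated azimuthally by
    random harmonics, giving the jagged, non-geometric outline of a
    "random"-boundary object while keeping the object compact.  ``band``
    restricts the blob centres to a row band so that, as in the sharp
    letter scenes, the amplitude and phase patterns occupy distinct parts
    of the field of view.
    """
    rows, cols = shape
    r_base = 0.06 * min(rows, cols)
    rr, cc = np.mgrid[0:rows, 0:cols]
    canvas = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        cy = rng.uniform(band[0] * rows, band[1] * rows)
        cx = rng.uniform(0.32 * cols, 0.68 * cols)
        # azimuthal radius modulation: band-limited random harmonics
        n_harm = 6
        amps = rng.normal(0, 0.18, n_harm)
        phases = rng.uniform(0, 2 * np.pi, n_harm)
        theta = np.arctan2(rr - cy, cc - cx)
        modulation = np.ones(shape)
        for m in range(n_harm):
            modulation += amps[m] * np.cos((m + 2) * theta + phases[m])
        radius = r_base * rng.uniform(0.8, 1.3) * np.clip(modulation, 0.3, 2.0)
        canvas |= np.hypot(rr - cy, cc - cx) <= radius
    return canvas


def _footprint(spec: SceneSpec, which: str, rng) -> np.ndarray:
    rows, cols = spec.shape
    scale = max(2, min(rows, cols) // 36)
    if which == "amp":
        pattern, text = spec.amp_pattern, spec.amp_text
        offset = (int(0.26 * rows), int(0.28 * cols))
    else:
        pattern, text = spec.phase_pattern, spec.phase_text
        offset = (int(0.52 * rows), int(0.38 * cols))
    if spec.boundary == "random":
        band = (0.24, 0.46) if which == "amp" else (0.54, 0.76)
        return _random_footprint(spec.shape, rng, band=band)
    if pattern == "letters":
        return _rasterize_text(spec.shape, text, scale, offset)
    if pattern == "bars":
        return _rasterize_bars(spec.shape, offset, bar_w=scale)
    if pattern == "blobs":
        return _rasterize_blobs(spec.shape, rng, n_blobs=4, r_px=4 * scale)
    raise InvalidParameterError(f"unknown pattern {pattern!r}")


def make_object(spec: SceneSpec) -> tuple[ComplexField, GroundTruth]:
    """Rasterize a scene into a complex field plus its ground-truth images.

    The amplitude is ``amp_range[1]`` (background) with the amplitude
    footprint set to ``amp_range[0]``; the phase is ``phase_range[0]``
    background with the phase footprint stepped to ``phase_range[1]``
    (blob patterns get a smooth interior gradient instead of a step).
    Deterministic for a fixed spec (seeded).
    """
    rng = np.random.default_rng(spec.seed)
    amp_fp = _footprint(spec, "amp", rng)
    phase_fp = _footprint(spec, "phase", rng)

    a_lo, a_hi = spec.amp_range
    amplitude = np.full(spec.shape, a_hi, dtype=np.float64)
    amplitude[amp_fp] = a_lo

    p_lo, p_hi = spec.phase_range
    phase = np.full(spec.shape, p_lo, dtype=np.float64)
    if spec.phase_pattern == "blobs" and spec.boundary == "flat":
        # smooth interior relief instead of a hard phase step
        interior = ndimage.gaussian_filter(phase_fp.astype(float), 6.0)
        interior = interior / interior.max() if interior.max() > 0 else interior
        phase = p_lo + (p_hi - p_lo) * interior
    else:
        phase[phase_fp] = p_hi

    field = ComplexField(
        amplitude * np.exp(1j * phase), pitch=spec.pitch, wavelength=spec.wavelength
    )
    return field, GroundTruth(amplitude, phase, amp_fp, phase_fp)


def forward_hologram(
    obj: ComplexField, z: float, pad_shape: tuple[int, int] | None = None
) -> Hologram:
    """Form the in-line hologram ``I = |P_z(u)|^2`` at distance ``z`` (m).

    The object field is padded with its border-level complex value to
    ``pad_shape`` (default 2x per axis) before propagation so wraparound
    from the circular convolution stays out of the cropped sensor window.
    """
    if not (z > 0):
        raise InvalidParameterError("recording distance must be > 0")
    rows, cols = obj.shape
    if pad_shape is None:
        pad_shape = (2 * rows, 2 * cols)
    ring = np.concatenate(
        [obj.values[0, :], obj.values[-1, :], obj.values[:, 0], obj.values[:, -1]]
    )
    fill = complex(np.median(ring.real) + 1j * np.median(ring.imag))
    padded, offset = pad_constant(obj.values, pad_shape, fill)
    prop = propagate(
        ComplexField(padded, pitch=obj.pitch, wavelength=obj.wavelength), z
    )
    intensity = crop_to(np.abs(prop.values) ** 2, (rows, cols), offset)
    return Hologram(
        intensity, pitch=obj.pitch, wavelength=obj.wavelength, z=z
    )


def mpr_holograms(
    obj: ComplexField, z0: float, dz: float, n_planes: int = 3
) -> tuple[list[Hologram], list[float]]:
    """Holograms at ``z0, z0 + dz, ...`` for multi-distance phase retrieval."""
    zs = [z0 + k * dz for k in range(n_planes)]
    return [forward_hologram(obj, z) for z in zs], zs


def add_gaussian_noise(h: Hologram, snr_db: float, seed: int) -> Hologram:
    """Add zero-mean white Gaussian noise at the requested SNR (dB).

    Signal power is taken as the mean squared clean intensity, so the noise
    variance is ``mean(I^2) / 10^(snr_db/10)``.  The noisy intensity is
    clipped at 0 (negative photon counts are unphysical); at SNR >= 15 dB
    clipping touches a negligible pixel fraction.
    """
    if not np.isfinite(snr_db):
        raise InvalidParameterError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    signal_power = float(np.mean(h.intensity**2))
    sigma = np.sqrt(signal_power / 10 ** (snr_db / 10))
    noisy = h.intensity + rng.normal(0.0, sigma, size=h.shape)
    out = Hologram(
        np.clip(noisy, 0.0, None),
        pitch=h.pitch,
        wavelength=h.wavelength,
        z=h.z,
        meta={**h.meta, "snr_db": snr_db, "noise_seed": seed},
    )
    return out


def paper_geometry() -> dict:
    """Geometry of the reference simulation study."""
    return {
        "wavelength": 500e-9,
        "pitch": 5.86e-6,
        "shape": (500, 500),
        "pad_shape": (1000, 1000),
        "z": 0.06,
        "mpr_dz": 0.5e-3,
        "mpr_planes": 3,
    }


def standard_scene(boundary: str = "flat", seed: int = 0) -> SceneSpec:
    """Scene spec in the reference geometry with the given boundary style."""
    geo = paper_geometry()
    return SceneSpec(
        shape=geo["shape"],
        pitch=geo["pitch"],
        wavelength=geo["wavelength"],
        boundary=boundary,
        seed=seed,
    )


def opaque_disk_object(
    shape: tuple[int, int], radius_px: float, pitch: float, wavelength: float
) -> ComplexField:
    """Unit plane wave blocked by a centred opaque disk (Poisson-spot scene)."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    disk = (rr - rows // 2) ** 2 + (cc - cols // 2) ** 2 <= radius_px**2
    values = np.where(disk, 0.0, 1.0).astype(np.complex128)
    return ComplexField(values, pitch=pitch, wavelength=wavelength)
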