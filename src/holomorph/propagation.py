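"""Band-limited angular-spectrum propagation and Tamura-coefficient autofocus.

The angular spectrum method (ASM) propagates a scalar monochromatic field
``u`` over a distance ``z`` by filtering its spatial-frequency spectrum with
the free-space transfer function

    H(fx, fy, z) = exp(i 2*pi*z * sqrt(1/lambda^2 - fx^2 - fy^2))

inside the propagating band ``fx^2 + fy^2 <= 1/lambda^2`` and exactly zero
outside it (evanescent components are discarded rather than attenuated).
|H| = 1 in-band, so propagation is unitary for band-limited fields and
``z -> -z`` is its exact inverse.

DFT conventions: unnormalized forward / 1/N-scaled inverse (numpy default),
frequency grids in standard DFT ordering, transfer function built unshifted.
Padding helpers suppress the circular-convolution wraparound inherent to
FFT-based propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import ComplexField, DegenerateInputError, Hologram, InvalidParameterError

__all__ = [
    "FrequencyGrid",
    "frequency_grid",
    "transfer_function",
    "propagate",
    "pad_constant",
    "crop_to",
    "tamura_coefficient",
    "autofocus",
    "autofocus_two_stage",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Spatial-frequency coordinates (cycles/m) in DFT sample ordering."""

    fx: np.ndarray  # varies along axis 1 (columns)
    fy: np.ndarray  # varies along axis 0 (rows)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fy.shape


def frequency_grid(shape: tuple[int, int], pitch: float) -> FrequencyGrid:
    """Build the DFT-ordered spatial-frequency grid for a given sampling."""
    if not (pitch > 0):
        raise InvalidParameterError(f"pitch must be > 0, got {pitch}")
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=pitch)[None, :]
    fy2d = np.broadcast_to(fy, (rows, cols))
    fx2d = np.broadcast_to(fx, (rows, cols))
    return FrequencyGrid(fx=fx2d, fy=fy2d)


def transfer_function(
    grid: FrequencyGrid, z: float, wavelength: float
) -> np.ndarray:
    """Free-space ASM transfer function with hard evanescent cutoff.

    Returns a complex array of the grid's shape: unit-modulus phase factor
    inside the propagating band, exactly 0 where ``fx^2 + fy^2 > 1/lambda^2``.
    ``z`` may be negative (back-propagation).
    """
    if not (wavelength > 0):
        raise InvalidParameterError(f"wavelength must be > 0, got {wavelength}")
    f2 = grid.fx**2 + grid.fy**2
    band = f2 <= 1.0 / wavelength**2
    kz = np.sqrt(np.maximum(1.0 / wavelength**2 - f2, 0.0))
    H = np.exp(1j * 2.0 * np.pi * z * kz)
    H[~band] = 0.0
    return H


def propagate(field: ComplexField, z: float) -> ComplexField:
    """Angular-spectrum propagation of ``field`` over distance ``z`` (m).

    Positive ``z`` moves toward the sensor, negative ``z`` back-propagates.
    The grid, pitch and wavelength are unchanged.  Energy is conserved for
    fields without evanescent spectral content; ``propagate(u, 0)`` is the
    identity up to FFT round-trip error.
    """
    if not np.isfinite(z):
        raise InvalidParameterError("propagation distance must be finite")
    grid = frequency_grid(field.shape, field.pitch)
    if 0.5 / field.pitch > 1.0 / field.wavelength:
        warnings.warn(
            "sampling admits spatial frequencies beyond 1/wavelength; "
            "part of the DFT grid is evanescent and will be zeroed",
            stacklevel=2,
        )
    H = transfer_function(grid, z, field.wavelength)
    out = np.fft.ifft2(np.fft.fft2(field.values) * H)
    return field.with_values(out)


def pad_constant(
    image: np.ndarray, target_shape: tuple[int, int], fill
) -> tuple[np.ndarray, tuple[int, int]]:
    """Center ``image`` in a constant-filled array of ``target_shape``.

    For odd size differences the extra row/column goes to the bottom/right.
    Returns ``(padded, (row_offset, col_offset))``; cropping the padded array
    at the offset with the original shape inverts the operation exactly.
    """
    image = np.asarray(image)
    rows, cols = image.shape
    trows, tcols = target_shape
    if trows < rows or tcols < cols:
        raise InvalidParameterError(
            f"target shape {target_shape} smaller than input {image.shape}"
        )
    r0 = (trows - rows) // 2
    c0 = (tcols - cols) // 2
    out = np.full(target_shape, fill, dtype=np.result_type(image.dtype, type(fill)))
    out[r0 : r0 + rows, c0 : c0 + cols] = image
    return out, (r0, c0)


def crop_to(
    image: np.ndarray, shape: tuple[int, int], offset: tuple[int, int]
) -> np.ndarray:
    """Inverse of :func:`pad_constant`: extract the original window."""
    r0, c0 = offset
    return image[r0 : r0 + shape[0], c0 : c0 + shape[1]]


def tamura_coefficient(intensity: np.ndarray) -> float:
    """Tamura coefficient ``sqrt(std/mean)`` of a nonnegative image.

    Scale-invariant (std and mean scale together), zero for a constant
    image; used as the autofocus sharpness criterion.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    m = intensity.mean()
    if m <= 0:
        raise DegenerateInputError("Tamura coefficient needs mean(intensity) > 0")
    return float(np.sqrt(intensity.std() / m))


def _tc_curve(holo: Hologram, zs: np.ndarray, metric: str = "tog") -> np.ndarray:
    # pad before back-propagating: circular-convolution wraparound otherwise
    # varies smoothly with z and swamps the focus feature of the TC curve
    from scipy import ndimage

    amp = np.sqrt(holo.intensity)
    ring = np.ones(amp.shape, dtype=bool)
    ring[5:-5, 5:-5] = False
    padded, offset = pad_constant(
        amp, (2 * amp.shape[0], 2 * amp.shape[1]), float(amp[ring].mean())
    )
    field = ComplexField(
        padded.astype(np.complex128), pitch=holo.pitch, wavelength=holo.wavelength
    )
    tc = []
    for z in zs:
        rec = crop_to(propagate(field, -z).amplitude, amp.shape, offset)
        if metric == "tog":
            img = np.hypot(ndimage.sobel(rec, 0), ndimage.sobel(rec, 1))
        elif metric == "tc":
            img = rec
        else:
            raise InvalidParameterError(f"unknown focus metric {metric!r}")
        tc.append(tamura_coefficient(img))
    return np.array(tc)


def autofocus(
    hologram: Hologram,
    z_min: float,
    z_max: float,
    step: float,
    polarity: str = "auto",
    metric: str = "tog",
) -> float:
    """Scan reconstruction distances and return the best-focus distance.

    The hologram amplitude is padded and back-propagated to each candidate
    ``z``; a Tamura-coefficient sharpness functional of the reconstruction
    is evaluated.  ``metric="tog"`` (default) uses the Tamura coefficient
    of the gradient magnitude, whose focus extremum is a single sharp peak
    even when the plain amplitude TC is shallow; ``metric="tc"`` is the
    Tamura coefficient of the amplitude itself.  ``polarity`` selects
    which extremum marks focus: ``"min"``, ``"max"``, or ``"auto"`` (the
    global extremum farthest from the median TC — the focus polarity
    depends on whether the object is amplitude- or phase-dominated, which
    the metric itself cannot know).
    """
    if not (z_min < z_max) or not (step > 0):
        raise InvalidParameterError("need z_min < z_max and step > 0")
    zs = np.arange(z_min, z_max + 0.5 * step, step)
    if zs.size == 0:
        raise InvalidParameterError("empty focus scan range")
    if zs.size == 1:
        return float(zs[0])
    tc = _tc_curve(hologram, zs, metric)
    if polarity == "min":
        idx = int(np.argmin(tc))
    elif polarity == "max":
        idx = int(np.argmax(tc))
    elif polarity == "auto":
        # the focus extremum is interior to the scan; an extremum sitting on
        # the scan edge is a truncated monotone branch, so prefer the
        # interior one, then the larger deviation from the median TC
        med = np.median(tc)
        lo, hi = int(np.argmin(tc)), int(np.argmax(tc))
        candidates = [i for i in (lo, hi) if 0 < i < tc.size - 1] or [lo, hi]
        idx = max(candidates, key=lambda i: abs(tc[i] - med))
    else:
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    return float(zs[idx])


def autofocus_two_stage(
    hologram: Hologram,
    z_min: float,
    z_max: float,
    coarse_step: float,
    fine_step: float,
    polarity: str = "auto",
    metric: str = "tog",
) -> float:
    """Coarse TC scan followed by a fine scan around the coarse optimum."""
    z0 = autofocus(hologram, z_min, z_max, coarse_step, polarity, metric)
    lo = max(z_min, z0 - coarse_step)
    hi = min(z_max, z0 + coarse_step)
    return autofocus(hologram, lo, hi, fine_step, polarity, metric)
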