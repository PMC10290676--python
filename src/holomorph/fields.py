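"""Core container types: sampled complex wavefronts and recorded holograms.

A :class:`ComplexField` is a 2-D complex amplitude sampled on a uniform grid
with physical pixel pitch and illumination wavelength attached, so that
propagation routines never need side-channel metadata.  A :class:`Hologram`
is the nonnegative intensity actually recorded on the sensor, together with
the acquisition geometry (pitch, wavelength, nominal recording distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a physical or geometric parameter is out of its domain."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal."""


@dataclass
class ComplexField:
    """A sampled 2-D complex wavefront.

    Parameters
    ----------
    values : ndarray, complex, shape (rows, cols)
        Complex transmission / field amplitude, dimensionless.
    pitch : float
        Pixel pitch in metres (> 0).
    wavelength : float
        Illumination wavelength in metres (> 0).
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise InvalidParameterError(
                f"field must be 2-D with both dims >= 2, got shape {self.values.shape}"
            )
        if not (self.pitch > 0):
            raise InvalidParameterError(f"pitch must be > 0, got {self.pitch}")
        if not (self.wavelength > 0):
            raise InvalidParameterError(
                f"wavelength must be > 0, got {self.wavelength}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Phase in radians, wrapped to (-pi, pi]."""
        return np.angle(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def with_values(self, values: np.ndarray) -> "ComplexField":
        return replace(self, values=values)

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


@dataclass
class Hologram:
    """A recorded in-line hologram: nonnegative intensity plus geometry.

    ``z`` is the nominal object-to-sensor distance in metres; ``bit_depth``
    records the integer depth of the source file when the hologram was read
    from disk (None for synthetic / float data).
    """

    intensity: np.ndarray
    pitch: float
    wavelength: float
    z: float
    bit_depth: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise InvalidParameterError("hologram intensity must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidParameterError("hologram intensity must be finite")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("hologram intensity must be nonnegative")
        if not (self.pitch > 0) or not (self.wavelength > 0):
            raise InvalidParameterError("pitch and wavelength must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def amplitude_field(self) -> ComplexField:
        """Square-root amplitude with zero phase, on the hologram grid."""
        return ComplexField(
            np.sqrt(self.intensity).astype(np.complex128),
            pitch=self.pitch,
            wavelength=self.wavelength,
        )
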