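"""Adaptive and static object-plane support constraints.

The adaptive support mask is re-estimated at every iteration from the
current object-plane reconstruction by a morphological pipeline:

1. binarize the image at a parameter-free Poisson minimum-error threshold;
2. average the open-closing and close-opening cascades,
   ``Fbar = (OC(B) + CO(B)) / 2``  (values in {0, 0.5, 1});
3. Gaussian-smooth ``Fbar``;
4. re-binarize at a threshold derived from the Sobel edge map of the
   smoothed image.

Separate masks are generated for the amplitude image and for a
median-centred phase-deviation image, and applied to the complex field
either as a literal elementwise (Hadamard) product or — the default — by
filling the outside-support amplitude with the estimated background level
while zeroing the outside-support phase, which models a transmitting
(bright) background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import ComplexField, DegenerateInputError, InvalidParameterError
from .morphology import (
    StructuringElement,
    close_open,
    disk_se,
    open_close,
    square_se,
)

__all__ = [
    "MaskGenConfig",
    "ConstraintState",
    "DegenerateMaskWarning",
    "poisson_threshold",
    "generate_adaptive_mask",
    "make_constraint_state",
    "apply_constraint",
    "static_support_mask",
]


class DegenerateMaskWarning(UserWarning):
    """Emitted when a mask degenerates to all-false (constraint skipped)."""


@dataclass(frozen=True)
class MaskGenConfig:
    """Parameters of the adaptive mask generator.

    ``g1``/``g2`` are the cascade SEs (defaults: disk of radius 1 and a
    2x2 square).  ``polarity`` names which intensity class is the object:
    ``"bright"``, ``"dark"``, or ``"auto"`` = the minority class after
    thresholding (objects are assumed sparse in the field of view).
    ``combine_mode="union"`` replaces the amplitude and phase masks by
    their union.
    """

    g1: StructuringElement = dc_field(default_factory=lambda: disk_se(1))
    g2: StructuringElement = dc_field(default_factory=lambda: square_se(2))
    gaussian_sigma: float = 1.0
    polarity: str = "auto"
    combine_mode: str = "separate"
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise InvalidParameterError("gaussian_sigma must be >= 0")
        if self.polarity not in ("auto", "bright", "dark"):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")
        if self.combine_mode not in ("separate", "union"):
            raise InvalidParameterError(f"unknown combine_mode {self.combine_mode!r}")


@dataclass
class ConstraintState:
    """Masks and background level for one object-plane constraint step."""

    amp_mask: np.ndarray
    phase_mask: np.ndarray
    background_amplitude: float = 1.0
    iteration: int = 0


def poisson_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Parameter-free two-class minimum-error threshold with Poisson models.

    The image is linearly mapped onto integer count levels ``0..n_bins-1``;
    for every candidate split the two class means are fitted and the
    threshold minimizing the total negative log-likelihood under the
    two-Poisson mixture is selected.  The returned threshold is on the
    original intensity scale, strictly between the two class populations.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateInputError("constant image has no threshold")
    counts = np.rint((image - lo) / (hi - lo) * (n_bins - 1)).astype(np.int64)
    hist = np.bincount(counts.ravel(), minlength=n_bins).astype(np.float64)
    levels = np.arange(n_bins, dtype=np.float64)
    n = hist.sum()

    cum_n = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)
    # candidate t: class 0 = levels <= t, class 1 = levels > t
    n0, n1 = cum_n, n - cum_n
    s0, s1 = cum_s, cum_s[-1] - cum_s
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / n0
        mu1 = s1 / n1
        p0 = n0 / n
        p1 = n1 / n
        # Poisson NLL up to terms independent of the split (sum of log k!);
        # a zero class mean contributes nothing (P(0)=1 under Poisson(0))
        t0 = np.where(s0 > 0, s0 * np.log(np.maximum(mu0, 1e-300)), 0.0)
        t1 = np.where(s1 > 0, s1 * np.log(np.maximum(mu1, 1e-300)), 0.0)
        j = -(
            n0 * np.log(p0) + t0 - n0 * mu0 + n1 * np.log(p1) + t1 - n1 * mu1
        )
    j[~valid] = np.inf
    if not np.isfinite(j).any():
        raise DegenerateInputError("no valid two-class split found")
    t_level = int(np.argmin(j))
    # return the midpoint between the last level of class 0 and the first of
    # class 1, mapped back to intensity units
    thr_counts = t_level + 0.5
    return lo + thr_counts / (n_bins - 1) * (hi - lo)


def _sobel_threshold(smoothed: np.ndarray) -> float:
    """Binarization level from the Sobel edge map of the smoothed image.

    Edge pixels are those whose gradient magnitude exceeds 4x the mean
    magnitude; the threshold is the mean smoothed value over those pixels
    (the half-height of the transition).  Falls back to 0.5 when the image
    has no edges.
    """
    smoothed = np.ascontiguousarray(smoothed, dtype=np.float32)
    gx = ndimage.sobel(smoothed, axis=1)
    gy = ndimage.sobel(smoothed, axis=0)
    mag = np.hypot(gx, gy)
    mean_mag = mag.mean()
    if mean_mag <= 0:
        return 0.5
    edges = mag > 4.0 * mean_mag
    if not edges.any():
        return 0.5
    return float(smoothed[edges].mean())


def generate_adaptive_mask(
    image: np.ndarray, cfg: MaskGenConfig | None = None
) -> np.ndarray:
    """Run the full mask-generation pipeline on one nonnegative image.

    Returns the boolean support mask.  A degenerate (near-constant) image
    yields an all-false mask and a :class:`DegenerateMaskWarning`; the
    retrieval loop treats an all-false mask as "skip the constraint".
    """
    cfg = cfg or MaskGenConfig()
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise InvalidParameterError("mask-generation input must be finite")
    try:
        thr = poisson_threshold(image, cfg.n_bins)
    except DegenerateInputError:
        warnings.warn(
            "degenerate image: no threshold, returning empty mask",
            DegenerateMaskWarning,
            stacklevel=2,
        )
        return np.zeros(image.shape, dtype=bool)

    bright = image > thr
    if cfg.polarity == "bright":
        b = bright
    elif cfg.polarity == "dark":
        b = ~bright
    else:  # minority class is the object
        b = bright if bright.sum() <= bright.size / 2 else ~bright

    fbar = 0.5 * (
        open_close(b, cfg.g1, cfg.g2).astype(np.float32)
        + close_open(b, cfg.g1, cfg.g2).astype(np.float32)
    )
    smoothed = (
        ndimage.gaussian_filter(fbar, cfg.gaussian_sigma)
        if cfg.gaussian_sigma > 0
        else fbar
    )
    mask = smoothed > _sobel_threshold(smoothed)
    if not mask.any():
        warnings.warn(
            "adaptive mask degenerated to all-false",
            DegenerateMaskWarning,
            stacklevel=2,
        )
    return mask


def make_constraint_state(
    field: ComplexField, cfg: MaskGenConfig | None = None, iteration: int = 0
) -> ConstraintState:
    """Generate amplitude and phase support masks from an object-plane field.

    The amplitude mask is estimated from ``|field|``; the phase mask from
    the phase-deviation image ``|angle(field) - median(angle(field))|``,
    which makes both signs of phase excursion count as foreground and
    removes any global phase offset.
    """
    cfg = cfg or MaskGenConfig()
    amp = field.amplitude
    phase = field.phase
    phase_dev = np.abs(phase - np.median(phase))
    amp_mask = generate_adaptive_mask(amp, cfg)
    phase_mask = generate_adaptive_mask(phase_dev, cfg)
    if cfg.combine_mode == "union":
        union = amp_mask | phase_mask
        amp_mask = union
        phase_mask = union
    outside = ~amp_mask
    background = float(np.median(amp[outside])) if outside.any() else float(amp.mean())
    return ConstraintState(
        amp_mask=amp_mask,
        phase_mask=phase_mask,
        background_amplitude=max(background, 0.0),
        iteration=iteration,
    )


def apply_constraint(
    field: ComplexField, state: ConstraintState, mode: str = "background_fill"
) -> ComplexField:
    """Apply the object-plane support constraint to a complex field.

    ``mode="hadamard"``: amplitude and phase each multiplied elementwise by
    their mask (outside-support amplitude and phase go to 0).
    ``mode="background_fill"`` (default): outside-support amplitude is
    replaced by ``state.background_amplitude`` and outside-support phase by
    0, modelling a uniformly transmitting background.

    An all-false mask skips the corresponding constraint (with a warning)
    rather than annihilating the field.
    """
    if state.amp_mask.shape != field.shape or state.phase_mask.shape != field.shape:
        raise InvalidParameterError("mask shape does not match field shape")
    amp = field.amplitude
    phase = field.phase
    ma = state.amp_mask
    mp = state.phase_mask
    skip_amp = not ma.any()
    skip_phase = not mp.any()
    if skip_amp or skip_phase:
        warnings.warn(
            "all-false mask: constraint skipped for this iteration",
            DegenerateMaskWarning,
            stacklevel=2,
        )
    if mode == "hadamard":
        new_amp = amp if skip_amp else amp * ma
        new_phase = phase if skip_phase else phase * mp
    elif mode == "background_fill":
        new_amp = (
            amp if skip_amp else np.where(ma, amp, state.background_amplitude)
        )
        new_phase = phase if skip_phase else phase * mp
    else:
        raise InvalidParameterError(f"unknown constraint mode {mode!r}")
    return field.with_values(new_amp * np.exp(1j * new_phase))


def static_support_mask(
    shape: tuple[int, int],
    geometry: str,
    *,
    bounds: tuple[int, int, int, int] | None = None,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Fixed aperture mask: ``geometry="rect"`` with ``bounds=(r0, r1, c0, c1)``
    (half-open row/col ranges) or ``geometry="circle"`` with ``center`` and
    ``radius`` in pixels (default centre: image centre)."""
    rows, cols = shape
    if geometry == "rect":
        if bounds is None:
            raise InvalidParameterError("rect support needs bounds=(r0, r1, c0, c1)")
        r0, r1, c0, c1 = bounds
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise InvalidParameterError(f"rect bounds {bounds} outside shape {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask
    if geometry == "circle":
        if radius is None or radius < 0:
            raise InvalidParameterError("circle support needs radius >= 0")
        cr, cc = center if center is not None else ((rows - 1) / 2, (cols - 1) / 2)
        if not (0 <= cr < rows and 0 <= cc < cols):
            raise InvalidParameterError("circle centre outside image")
        rr, ccg = np.mgrid[0:rows, 0:cols]
        return (rr - cr) ** 2 + (ccg - cc) ** 2 <= radius**2
    raise InvalidParameterError(f"unknown support geometry {geometry!r}")
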