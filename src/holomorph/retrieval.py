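"""Iterative phase-retrieval engines for single-shot in-line holography.

All engines alternate between the sensor plane, where the measured
intensity constrains the field modulus, and the object plane, reached by
angular-spectrum back-propagation:

1. pad the hologram and initialize ``U_s = sqrt(I0) * exp(i*phi0)``;
2. back-propagate to the object plane;
3. apply the object-plane constraint — an adaptive morphological support
   regenerated from the current amplitude and phase each iteration, a
   static support aperture, or none;
4. forward-propagate and replace the sensor amplitude with ``sqrt(I0)``,
   keeping the phase.

The final reconstruction is the back-propagation of the last sensor field,
cropped to the original hologram extent.  A multi-distance variant
(``retrieve_mpr``) cycles amplitude updates through several measurement
planes instead of applying any object-plane mask.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .constraints import (
    ConstraintState,
    MaskGenConfig,
    apply_constraint,
    make_constraint_state,
)
from .fields import ComplexField, Hologram, InvalidParameterError
from .metrics import mse as _mse, phase_mse as _phase_mse
from .propagation import crop_to, pad_constant, propagate

__all__ = [
    "RetrievalConfig",
    "RetrievalResult",
    "initialize",
    "sensor_amplitude_update",
    "retrieve",
    "retrieve_mpr",
]


@dataclass
class RetrievalConfig:
    """Settings of one retrieval run.

    ``pad_shape=None`` doubles the hologram per axis; ``pad_fill=None``
    fills with the mean of the hologram's 5-pixel border ring so the
    padded background matches the unscattered-beam level.  ``constraint``
    selects the object-plane prior: ``"adaptive"`` (morphological masks,
    regenerated every ``mask_every`` iterations), ``"support"`` (the fixed
    boolean ``support`` mask, given on the hologram grid), or ``"none"``.
    """

    z: float = 0.06
    iterations: int = 100
    pad_shape: tuple[int, int] | None = None
    pad_fill: float | None = None
    initial_phase: str = "zeros"  # zeros | random
    seed: int = 0
    constraint: str = "adaptive"  # adaptive | support | none
    mask_cfg: MaskGenConfig = dc_field(default_factory=MaskGenConfig)
    support: np.ndarray | None = None
    mode: str = "background_fill"  # background_fill | hadamard
    mask_every: int = 1
    record_every: int = 1
    record_masks: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise InvalidParameterError("iterations must be >= 0")
        if self.constraint not in ("adaptive", "support", "none"):
            raise InvalidParameterError(f"unknown constraint {self.constraint!r}")
        if self.initial_phase not in ("zeros", "random"):
            raise InvalidParameterError(f"unknown initial_phase {self.initial_phase!r}")
        if self.record_every < 1 or self.mask_every < 1:
            raise InvalidParameterError("record_every and mask_every must be >= 1")
        if self.constraint == "support" and self.support is None:
            raise InvalidParameterError("support constraint needs a support mask")


@dataclass
class RetrievalResult:
    """Reconstruction plus per-iteration diagnostics.

    Traces are sampled at the recorded iteration indices in ``iterations``
    (multiples of ``record_every`` plus the final iteration); MSE traces
    are present only when ground truth was supplied.
    """

    object_field: ComplexField
    method: str
    iterations: list[int]
    runtime_trace: list[float]
    mse_amp_trace: list[float] | None = None
    mse_phase_trace: list[float] | None = None
    mask_area_trace: list[int] | None = None
    mask_snapshots: list[np.ndarray] | None = None

    def final_mse(self) -> tuple[float | None, float | None]:
        if self.mse_amp_trace is None:
            return None, None
        return self.mse_amp_trace[-1], self.mse_phase_trace[-1]


def _border_ring_mean(image: np.ndarray, width: int = 5) -> float:
    ring = np.ones(image.shape, dtype=bool)
    ring[width:-width, width:-width] = False
    return float(image[ring].mean())


def initialize(hologram: Hologram, cfg: RetrievalConfig):
    """Pad the hologram and build the initial sensor-plane field.

    Returns ``(field, sqrt_I0, offset)`` where ``sqrt_I0`` is the square
    root of the padded hologram (enforced at every sensor update, padding
    margin included) and ``offset`` locates the original window.
    """
    pad_shape = cfg.pad_shape or (2 * hologram.shape[0], 2 * hologram.shape[1])
    fill = (
        cfg.pad_fill
        if cfg.pad_fill is not None
        else _border_ring_mean(hologram.intensity)
    )
    if fill < 0:
        raise InvalidParameterError("padding fill must be nonnegative intensity")
    I0, offset = pad_constant(hologram.intensity, pad_shape, fill)
    sqrt_I0 = np.sqrt(I0)
    if cfg.initial_phase == "zeros":
        phi0 = np.zeros(pad_shape)
    else:
        rng = np.random.default_rng(cfg.seed)
        phi0 = rng.uniform(-np.pi, np.pi, size=pad_shape)
    field = ComplexField(
        sqrt_I0 * np.exp(1j * phi0),
        pitch=hologram.pitch,
        wavelength=hologram.wavelength,
    )
    return field, sqrt_I0, offset


def sensor_amplitude_update(
    field: ComplexField, sqrt_hologram: np.ndarray
) -> ComplexField:
    """Replace the field modulus with the measured amplitude, keep the phase.

    Where the field is exactly zero the phase is taken as 0 (the output is
    real there).  After the update ``|field| == sqrt_hologram`` exactly.
    """
    if field.shape != sqrt_hologram.shape:
        raise InvalidParameterError("sqrt-hologram shape does not match field")
    phase = np.angle(field.values)
    return field.with_values(sqrt_hologram * np.exp(1j * phase))


class _Recorder:
    """Accumulates per-iteration diagnostics on the cropped object window."""

    def __init__(self, cfg, ground_truth, crop_shape, offset):
        self.cfg = cfg
        self.gt = ground_truth
        self.crop_shape = crop_shape
        self.offset = offset
        self.t0 = time.perf_counter()
        self.iterations: list[int] = []
        self.runtime: list[float] = []
        self.mse_amp: list[float] = []
        self.mse_phase: list[float] = []
        self.mask_area: list[int] = []
        self.snapshots: list[np.ndarray] = []

    def want(self, k: int, total: int) -> bool:
        return k == total or (k % self.cfg.record_every == 0)

    def record(self, k: int, obj_field: ComplexField, state: ConstraintState | None):
        self.iterations.append(k)
        self.runtime.append(time.perf_counter() - self.t0)
        if self.gt is not None:
            amp = crop_to(obj_field.amplitude, self.crop_shape, self.offset)
            ph = crop_to(obj_field.phase, self.crop_shape, self.offset)
            self.mse_amp.append(_mse(amp, self.gt.amplitude))
            self.mse_phase.append(_phase_mse(ph, self.gt.phase))
        if state is not None:
            self.mask_area.append(int(state.amp_mask.sum()))
            if self.cfg.record_masks:
                self.snapshots.append(
                    crop_to(state.amp_mask, self.crop_shape, self.offset).copy()
                )

    def result(self, obj_field: ComplexField, method: str) -> RetrievalResult:
        cropped = ComplexField(
            crop_to(obj_field.values, self.crop_shape, self.offset).copy(),
            pitch=obj_field.pitch,
            wavelength=obj_field.wavelength,
        )
        has_gt = self.gt is not None
        return RetrievalResult(
            object_field=cropped,
            method=method,
            iterations=self.iterations,
            runtime_trace=self.runtime,
            mse_amp_trace=self.mse_amp if has_gt else None,
            mse_phase_trace=self.mse_phase if has_gt else None,
            mask_area_trace=self.mask_area if self.mask_area else None,
            mask_snapshots=self.snapshots if self.snapshots else None,
        )


def retrieve(
    hologram: Hologram, cfg: RetrievalConfig, ground_truth=None
) -> RetrievalResult:
    """Run the single-hologram iterative retrieval loop.

    ``ground_truth`` (amplitude/phase images on the hologram grid, e.g. a
    :class:`~holomorph.simulate.GroundTruth`) enables the MSE traces.
    ``cfg.iterations == 0`` returns the plain back-propagation
    reconstruction.
    """
    field, sqrt_I0, offset = initialize(hologram, cfg)
    rec = _Recorder(cfg, ground_truth, hologram.shape, offset)

    static_state = None
    if cfg.constraint == "support":
        if cfg.support.shape == hologram.shape:
            padded_support, _ = pad_constant(cfg.support, field.shape, False)
        elif cfg.support.shape == field.shape:
            padded_support = np.asarray(cfg.support, dtype=bool)
        else:
            raise InvalidParameterError(
                "support mask must match the hologram or padded grid"
            )
        static_state = ConstraintState(
            amp_mask=padded_support, phase_mask=padded_support
        )

    z = cfg.z
    state: ConstraintState | None = None
    for k in range(1, cfg.iterations + 1):
        obj = propagate(field, -z)
        if k > 1 and rec.want(k - 1, cfg.iterations):
            rec.record(k - 1, obj, state)
        if cfg.constraint == "adaptive":
            if state is None or (k - 1) % cfg.mask_every == 0:
                state = make_constraint_state(obj, cfg.mask_cfg, iteration=k)
            obj = apply_constraint(obj, state, cfg.mode)
        elif cfg.constraint == "support":
            state = static_state
            outside = ~state.amp_mask
            state.background_amplitude = (
                float(np.median(obj.amplitude[outside])) if outside.any() else 1.0
            )
            obj = apply_constraint(obj, state, cfg.mode)
        field = propagate(obj, z)
        field = sensor_amplitude_update(field, sqrt_I0)

    final_obj = propagate(field, -z)
    if cfg.iterations == 0 or rec.want(cfg.iterations, cfg.iterations):
        rec.record(cfg.iterations, final_obj, state)
    method = {"adaptive": "adaptive", "support": "support", "none": "none"}[
        cfg.constraint
    ]
    return rec.result(final_obj, method)


def retrieve_mpr(
    holograms: list[Hologram],
    z_list: list[float],
    cfg: RetrievalConfig,
    ground_truth=None,
) -> RetrievalResult:
    """Multi-distance phase retrieval (MPR) baseline.

    Each iteration visits the measurement planes nearest-to-farthest,
    replacing the amplitude with the measured ``sqrt(I_k)`` at each plane
    and keeping the phase, then back-propagates to the object plane for
    readout.  No object-plane mask is applied.
    """
    if len(holograms) != len(z_list):
        raise InvalidParameterError("holograms and z_list lengths differ")
    if len(holograms) < 1:
        raise InvalidParameterError("need at least one hologram")
    if any(b <= a for a, b in zip(z_list, z_list[1:])):
        raise InvalidParameterError("distances must be strictly increasing")

    base = holograms[0]
    pad_shape = cfg.pad_shape or (2 * base.shape[0], 2 * base.shape[1])
    sqrt_planes = []
    offset = None
    for h in holograms:
        if h.shape != base.shape:
            raise InvalidParameterError("all holograms must share one shape")
        fill = cfg.pad_fill if cfg.pad_fill is not None else _border_ring_mean(h.intensity)
        Ik, offset = pad_constant(h.intensity, pad_shape, fill)
        sqrt_planes.append(np.sqrt(Ik))

    cfg0 = RetrievalConfig(
        z=z_list[0],
        iterations=cfg.iterations,
        pad_shape=pad_shape,
        pad_fill=cfg.pad_fill,
        initial_phase=cfg.initial_phase,
        seed=cfg.seed,
        constraint="none",
        record_every=cfg.record_every,
    )
    field, _, offset = initialize(base, cfg0)
    rec = _Recorder(cfg, ground_truth, base.shape, offset)

    obj = propagate(field, -z_list[0])
    for k in range(1, cfg.iterations + 1):
        u = obj
        prev_z = 0.0
        for zk, sq in zip(z_list, sqrt_planes):
            u = propagate(u, zk - prev_z)
            u = sensor_amplitude_update(u, sq)
            prev_z = zk
        obj = propagate(u, -prev_z)
        if rec.want(k, cfg.iterations):
            rec.record(k, obj, None)
    if cfg.iterations == 0:
        rec.record(0, obj, None)
    return rec.result(obj, "mpr")
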