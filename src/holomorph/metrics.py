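"""Reconstruction-quality metrics.

The primary figure of merit is the reference-normalized mean square error

    E = sum |rho - rho0|^2 / sum |rho0|^2

applied separately to amplitude and phase images.  Phase images are
compared after removing the global piston (the mean wrapped phase
difference over the reference support): retrieval from a single intensity
is blind to a global phase offset, so the raw comparison would penalize a
physically unrecoverable degree of freedom.  Raw comparison remains
available via ``remove_piston=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DegenerateInputError, InvalidParameterError

__all__ = ["MetricReport", "mse", "phase_mse", "pearson", "jaccard", "compare_runs"]


@dataclass(frozen=True)
class MetricReport:
    """Final comparison metrics for one reconstruction."""

    method: str
    mse_amp: float
    mse_phase: float
    correlation_amp: float
    jaccard: float | None = None


def mse(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Normalized MSE ``sum|est - ref|^2 / sum|ref|^2``."""
    estimate = np.asarray(estimate, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if estimate.shape != reference.shape:
        raise InvalidParameterError(
            f"shape mismatch {estimate.shape} vs {reference.shape}"
        )
    denom = np.sum(reference**2)
    if denom <= 0:
        raise DegenerateInputError("reference has zero energy")
    return float(np.sum((estimate - reference) ** 2) / denom)


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.angle(np.exp(1j * phase))


def phase_mse(
    estimate: np.ndarray, reference: np.ndarray, remove_piston: bool = True
) -> float:
    """Normalized MSE between phase images in radians.

    The difference is compared on the wrapped scale; with
    ``remove_piston=True`` the circular mean of the difference over the
    reference support (``reference != 0``) is subtracted first, modulo 2*pi.
    """
    estimate = np.asarray(estimate, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if estimate.shape != reference.shape:
        raise InvalidParameterError("phase image shapes differ")
    diff = _wrap(estimate - reference)
    if remove_piston:
        support = reference != 0
        if not support.any():
            support = np.ones_like(reference, dtype=bool)
        piston = np.angle(np.mean(np.exp(1j * diff[support])))
        diff = _wrap(diff - piston)
    denom = np.sum(_wrap(reference) ** 2)
    if denom <= 0:
        raise DegenerateInputError("phase reference has zero energy")
    return float(np.sum(diff**2) / denom)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two flattened images."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant image has undefined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def compare_runs(results, amp_truth: np.ndarray, phase_truth: np.ndarray):
    """Tabulate final metrics for several retrieval runs against one truth.

    ``results`` is a list of objects exposing ``method``, and an
    ``object_field`` with ``amplitude``/``phase`` on the truth grid.
    Returns a list of :class:`MetricReport`, one per run, in input order.
    """
    reports = []
    for res in results:
        fld = res.object_field
        if fld.shape != amp_truth.shape:
            raise InvalidParameterError("result grid does not match ground truth")
        reports.append(
            MetricReport(
                method=getattr(res, "method", "unknown"),
                mse_amp=mse(fld.amplitude, amp_truth),
                mse_phase=phase_mse(fld.phase, phase_truth),
                correlation_amp=pearson(fld.amplitude, amp_truth),
            )
        )
    return reports


def traces_to_csv(results, path, include_runtime: bool = True) -> None:
    """Write per-iteration MSE curves of several runs to one CSV file.

    Columns: method, iteration, seconds, mse_amp, mse_phase, mask_area.
    ``include_runtime=False`` drops the wall-time column, leaving only the
    deterministic columns (byte-identical across identical seeded runs).
    """
    import csv

    header = ["method", "iteration", "seconds", "mse_amp", "mse_phase", "mask_area"]
    if not include_runtime:
        header.remove("seconds")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for res in results:
            method = getattr(res, "method", "unknown")
            for i in range(len(res.iterations)):
                row = [method, res.iterations[i]]
                if include_runtime:
                    row.append(f"{res.runtime_trace[i]:.6f}")
                row += [
                    _fmt(res.mse_amp_trace, i),
                    _fmt(res.mse_phase_trace, i),
                    _fmt(res.mask_area_trace, i),
                ]
                w.writerow(row)


def _fmt(trace, i):
    if trace is None or i >= len(trace):
        return ""
    return f"{trace[i]:.8e}"
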