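"""Binary mathematical morphology built directly from the set definitions.

Erosion of a set F by a structuring element (SE) G keeps the points whose
translated SE fits entirely inside F; dilation keeps the points whose
reflected, translated SE touches F.  Opening = erosion then dilation,
closing = dilation then erosion; the open-closing (OC) and close-opening
(CO) cascades compose the two with two different SEs:

    OC(F) = (F o G1) . G2        CO(F) = (F . G1) o G2

(``o`` opening, ``.`` closing).  Conventions, fixed here because library
defaults differ:

* outside-image samples are background (False) for both erosion and
  dilation — the set-theoretic reading;
* even-sized SEs anchor their origin at the top-left cell (a 2x2 square has
  no centre cell), odd-sized SEs at the centre;
* the reflection used by dilation is taken about the origin cell.

The primitives are evaluated by explicit SE-offset shifting with logical
AND/OR accumulation, which is exact and fast for the small SEs used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import InvalidParameterError

__all__ = [
    "StructuringElement",
    "disk_se",
    "square_se",
    "erode",
    "dilate",
    "binary_open",
    "binary_close",
    "open_close",
    "close_open",
]


@dataclass(frozen=True)
class StructuringElement:
    """Small boolean footprint with an origin cell inside it."""

    footprint: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2 or not fp.any():
            raise InvalidParameterError("footprint must be 2-D with >= 1 true cell")
        r, c = self.origin
        if not (0 <= r < fp.shape[0] and 0 <= c < fp.shape[1]):
            raise InvalidParameterError(
                f"origin {self.origin} outside footprint {fp.shape}"
            )

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) integer offsets of true cells relative to the origin."""
        rr, cc = np.nonzero(self.footprint)
        return np.stack([rr - self.origin[0], cc - self.origin[1]], axis=1)

    def reflected(self) -> "StructuringElement":
        """Reflection about the origin cell (offsets negated)."""
        off = -self.offsets
        rmin, cmin = off.min(axis=0)
        fp = np.zeros(
            (off[:, 0].max() - rmin + 1, off[:, 1].max() - cmin + 1), dtype=bool
        )
        fp[off[:, 0] - rmin, off[:, 1] - cmin] = True
        return StructuringElement(fp, (-rmin, -cmin))


def disk_se(radius: int) -> StructuringElement:
    """Disk SE: cells with ``r^2 + c^2 <= radius^2`` about a centre origin.

    Radius 1 is the 5-cell plus shape; radius 0 a single cell.
    """
    if radius < 0:
        raise InvalidParameterError(f"radius must be >= 0, got {radius}")
    n = 2 * radius + 1
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return StructuringElement(rr**2 + cc**2 <= radius**2, (n // 2, n // 2))


def square_se(n: int) -> StructuringElement:
    """n x n all-true SE; origin at centre for odd n, top-left for even n."""
    if n < 1:
        raise InvalidParameterError(f"square SE size must be >= 1, got {n}")
    origin = ((n - 1) // 2, (n - 1) // 2) if n % 2 == 1 else (0, 0)
    return StructuringElement(np.ones((n, n), dtype=bool), origin)


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """``out[i, j] = mask[i + dr, j + dc]``, False outside the image."""
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    src_r = slice(max(dr, 0), min(rows + dr, rows))
    src_c = slice(max(dc, 0), min(cols + dc, cols))
    dst_r = slice(max(-dr, 0), max(-dr, 0) + (src_r.stop - src_r.start))
    dst_c = slice(max(-dc, 0), max(-dc, 0) + (src_c.stop - src_c.start))
    if src_r.stop > src_r.start and src_c.stop > src_c.start:
        out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: true where the translated SE fits inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    out = np.ones_like(mask)
    for dr, dc in se.offsets:
        out &= _shift(mask, dr, dc)
    return out


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: true where the reflected translated SE meets the mask."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for dr, dc in se.offsets:
        out |= _shift(mask, -dr, -dc)
    return out


def binary_open(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Opening (erode then dilate): removes speckle smaller than the SE."""
    return dilate(erode(mask, se), se)


def binary_close(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Closing (dilate then erode): fills holes smaller than the SE."""
    return erode(dilate(mask, se), se)


def open_close(
    mask: np.ndarray, g1: StructuringElement, g2: StructuringElement
) -> np.ndarray:
    """OC cascade: open with G1 then close with G2."""
    return binary_close(binary_open(mask, g1), g2)


def close_open(
    mask: np.ndarray, g1: StructuringElement, g2: StructuringElement
) -> np.ndarray:
    """CO cascade: close with G1 then open with G2."""
    return binary_open(binary_close(mask, g1), g2)
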