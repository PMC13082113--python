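"""Region-of-interest geometry: mask algebra at 1H resolution and
mutually exclusive downsampling of ROIs onto the coarse 13C grid.

The anatomical masks (brain, T2-hyperintense lesion T2L, contrast-enhancing
lesion CEL, white matter WM) live on the high-resolution 1H grid.  Two
derived regions are pure set arithmetic:

* NEL (non-enhancing lesion) = T2L minus CEL
* NAWM (normal-appearing white matter) = WM minus any T2L overlap

ROIs are mapped onto the coarse 13C grid by block overlap fractions with a
mutually exclusive labeling: a 13C voxel whose volume is at least 30% T2L
is labeled T2L; of the remaining voxels, those with at least 50% NAWM
overlap are labeled NAWM.  The 30% criterion is read as fraction of the
13C voxel's volume (a per-voxel criterion), not fraction of the total
lesion volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "MaskSet",
    "RoiLabel",
    "RoiLabelMap",
    "GeometryError",
    "derive_rois",
    "block_fractions",
    "downsample_rois",
    "volume_cc",
    "volume_percent_change",
]


class GeometryError(ValueError):
    """Raised when mask grids are inconsistent."""


class RoiLabel(IntEnum):
    """Mutually exclusive per-voxel region labels on the 13C grid."""

    NONE = 0
    T2L = 1
    NAWM = 2


@dataclass
class MaskSet:
    """Binary anatomical volumes at 1H resolution plus derived regions.

    ``voxel_mm`` is the (dx, dy, dz) voxel size in millimetres.  ``nel``
    and ``nawm`` are filled by :func:`derive_rois`.
    """

    brain: np.ndarray
    t2l: np.ndarray
    cel: np.ndarray
    wm: np.ndarray
    voxel_mm: tuple[float, float, float]
    nel: np.ndarray | None = None
    nawm: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = np.asarray(self.brain).shape
        for name in ("brain", "t2l", "cel", "wm"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise GeometryError(
                    f"mask {name!r} shape {arr.shape} does not match brain shape {shape}"
                )
            setattr(self, name, arr.astype(bool))
        if any(d <= 0 for d in self.voxel_mm):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_mm}")


def derive_rois(masks: MaskSet) -> MaskSet:
    """Return a new :class:`MaskSet` with NEL and NAWM filled.

    NEL = T2L AND NOT CEL; NAWM = WM AND NOT T2L.  Inputs are not modified.
    """
    nel = masks.t2l & ~masks.cel
    nawm = masks.wm & ~masks.t2l
    return replace(masks, nel=nel, nawm=nawm)


def block_fractions(mask_1h: np.ndarray, factor: int) -> np.ndarray:
    """Per-13C-voxel overlap fraction of a 1H mask.

    The 1H grid must be an exact ``factor``-fold block refinement of the
    13C grid along every axis; the fraction is the mean of the binary mask
    over each ``factor**3`` block.
    """
    mask_1h = np.asarray(mask_1h).astype(bool)
    if factor < 1 or int(factor) != factor:
        raise GeometryError(f"refinement factor must be a positive integer, got {factor}")
    factor = int(factor)
    if any(s % factor for s in mask_1h.shape):
        raise GeometryError(
            f"1H shape {mask_1h.shape} is not an exact {factor}-fold block "
            "refinement of a 13C grid"
        )
    nx, ny, nz = (s // factor for s in mask_1h.shape)
    blocks = mask_1h.reshape(nx, factor, ny, factor, nz, factor)
    return blocks.mean(axis=(1, 3, 5))


@dataclass
class RoiLabelMap:
    """Mutually exclusive ROI labels on the 13C grid with audit fractions."""

    labels: np.ndarray  # integer codes from RoiLabel
    t2l_fraction: np.ndarray
    nawm_fraction: np.ndarray
    factor: int

    @property
    def t2l(self) -> np.ndarray:
        return self.labels == RoiLabel.T2L

    @property
    def nawm(self) -> np.ndarray:
        return self.labels == RoiLabel.NAWM


def downsample_rois(
    t2l_1h: np.ndarray,
    nawm_1h: np.ndarray,
    factor: int,
    t2l_threshold: float = 0.30,
    nawm_threshold: float = 0.50,
) -> RoiLabelMap:
    """Map 1H-resolution T2L and NAWM masks onto the 13C grid.

    A 13C voxel containing at least ``t2l_threshold`` (default 30%) T2L by
    volume is labeled T2L.  Of the remaining voxels, those with at least
    ``nawm_threshold`` (default 50%) NAWM overlap are labeled NAWM.  Both
    thresholds are inclusive, and T2L takes precedence so labels are
    mutually exclusive by construction.
    """
    if np.asarray(t2l_1h).shape != np.asarray(nawm_1h).shape:
        raise GeometryError("T2L and NAWM masks must share the 1H grid")
    t2l_frac = block_fractions(t2l_1h, factor)
    nawm_frac = block_fractions(nawm_1h, factor)
    labels = np.full(t2l_frac.shape, int(RoiLabel.NONE), dtype=np.int8)
    is_t2l = t2l_frac >= t2l_threshold
    labels[is_t2l] = int(RoiLabel.T2L)
    labels[~is_t2l & (nawm_frac >= nawm_threshold)] = int(RoiLabel.NAWM)
    return RoiLabelMap(labels=labels, t2l_fraction=t2l_frac, nawm_fraction=nawm_frac, factor=int(factor))


def volume_cc(mask: np.ndarray, voxel_mm: tuple[float, float, float]) -> float:
    """Volume of a binary mask in cubic centimetres."""
    if any(d <= 0 for d in voxel_mm):
        raise ValueError(f"voxel dimensions must be positive, got {voxel_mm}")
    voxel_mm3 = float(np.prod(voxel_mm))
    return float(np.count_nonzero(np.asarray(mask).astype(bool)) * voxel_mm3 / 1000.0)


def volume_percent_change(v: float, v0: float) -> float:
    """Percent change ``100 * (v - v0) / v0``; NaN when the baseline is zero.

    A zero baseline volume (e.g. a patient with no contrast-enhancing
    lesion) yields a missing value rather than an infinite change.
    """
    if v0 == 0 or not np.isfinite(v0):
        return float("nan")
    return float(100.0 * (v - v0) / v0)
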