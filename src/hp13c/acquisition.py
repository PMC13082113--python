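"""Acquisition timing, flip-angle and relaxation constants for dynamic HP-13C EPI.

The dynamic acquisition excites each metabolite independently with a
constant flip angle at every timepoint, so the measured transverse signal
at excitation ``m`` is ``Mz[m] * sin(flip)`` and the longitudinal pool is
depleted by ``cos(flip)`` immediately afterwards.  Apparent longitudinal
relaxation times (T1) are not identifiable from a single-shot bolus study
and are treated as fixed constants of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: canonical metabolite ordering used throughout the package
METABOLITES = ("pyruvate", "lactate", "bicarbonate")


@dataclass(frozen=True)
class AcquisitionParams:
    """Constants of the dynamic HP-13C acquisition and the relaxation model.

    Parameters
    ----------
    flip_pyr, flip_lac, flip_bic:
        Constant per-excitation flip angles in degrees, one per metabolite.
        Defaults follow the 20/30/30 degree scheme of frequency-selective
        metabolite-specific EPI.
    n_timepoints:
        Number of dynamic timepoints acquired per metabolite.
    dt:
        Temporal resolution in seconds (interval between successive
        excitations of the same metabolite).
    t1_pyr, t1_lac, t1_bic:
        Apparent longitudinal relaxation times in seconds.  These are model
        constants, not fitted quantities.
    """

    flip_pyr: float = 20.0
    flip_lac: float = 30.0
    flip_bic: float = 30.0
    n_timepoints: int = 20
    dt: float = 3.0
    t1_pyr: float = 30.0
    t1_lac: float = 25.0
    t1_bic: float = 25.0

    def __post_init__(self) -> None:
        # flip = 0 is allowed so the forward model can express an unexcited
        # (unmeasured) metabolite; fitting requires nonzero flips
        for name in ("flip_pyr", "flip_lac", "flip_bic"):
            flip = getattr(self, name)
            if not 0.0 <= flip <= 90.0:
                raise ValueError(f"{name} must be in [0, 90] degrees, got {flip}")
        if self.n_timepoints < 2:
            raise ValueError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        for name in ("t1_pyr", "t1_lac", "t1_bic"):
            t1 = getattr(self, name)
            if t1 <= 0:
                raise ValueError(f"{name} must be positive, got {t1}")

    # -- convenience views -------------------------------------------------

    def flip_rad(self, metabolite: str) -> float:
        """Flip angle of ``metabolite`` in radians."""
        return math.radians(
            {"pyruvate": self.flip_pyr, "lactate": self.flip_lac, "bicarbonate": self.flip_bic}[metabolite]
        )

    def t1(self, metabolite: str) -> float:
        """Apparent T1 of ``metabolite`` in seconds."""
        return {"pyruvate": self.t1_pyr, "lactate": self.t1_lac, "bicarbonate": self.t1_bic}[metabolite]

    @property
    def times(self) -> np.ndarray:
        """Excitation times in seconds, ``t_k = k * dt``, k = 0..T-1."""
        return np.arange(self.n_timepoints) * self.dt


@dataclass
class DynamicMetaboliteImage:
    """A 4D dynamic image for one metabolite on the 13C grid.

    ``data`` has shape ``(nx, ny, nz, n_timepoints)``; ``voxel_mm`` is the
    isotropic 13C voxel size in millimetres.
    """

    data: np.ndarray
    metabolite: str
    voxel_mm: float
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic image must be 4D, got shape {self.data.shape}")
        if self.metabolite not in METABOLITES:
            raise ValueError(f"unknown metabolite {self.metabolite!r}")
        if self.data.shape[-1] != self.params.n_timepoints:
            raise ValueError(
                f"time axis length {self.data.shape[-1]} does not match "
                f"n_timepoints={self.params.n_timepoints}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]
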