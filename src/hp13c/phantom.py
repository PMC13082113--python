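"""Synthetic dynamic-13C phantom studies with known kinetic ground truth.

The phantom emulates a bolus-driven three-pool exchange experiment: a
gamma-variate inflow feeds the pyruvate pool, which converts irreversibly
to lactate (rate kPL) and bicarbonate (rate kPB) while all three pools
relax with apparent T1s and lose longitudinal magnetization to the RF
excitations.  Between excitations the longitudinal magnetizations evolve
by the linear system

    dP/dt = -(1/T1P + kPL + kPB) P + g(t)
    dL/dt = kPL P - L/T1L
    dB/dt = kPB P - B/T1B

which is stepped exactly per dt with a matrix exponential (the inflow
g(t) is treated as constant within each inter-excitation interval).  At
each excitation the measured signal is Mz*sin(flip) and the pool is
depleted by cos(flip).

Anatomy is a set of nested ellipsoids (brain > white matter, brain >
T2-lesion > contrast-enhancing core) rasterized on a 1H grid that is an
integer block refinement of the 13C grid, so lesion borders carry partial
volume and exercise the ROI downsampling thresholds.  Voxel noise is
additive i.i.d. Gaussian, matching a background-estimated noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .acquisition import METABOLITES, AcquisitionParams, DynamicMetaboliteImage
from .rois import MaskSet

__all__ = [
    "PhantomConfig",
    "SyntheticStudy",
    "ConfigError",
    "simulate_bolus",
    "simulate_voxel_dynamics",
    "generate_phantom",
]


class ConfigError(ValueError):
    """Raised for inconsistent phantom configurations."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic dynamic-13C study.

    Rates are apparent first-order conversion rates in 1/s; the lesion
    kPL must exceed the background kPL to emulate the Warburg-driven
    lactate elevation of tumor tissue.  The 1H mask grid is the 13C grid
    refined by ``upsample_factor`` per axis.  Geometry fields position
    the nested ellipsoids as fractions of the grid extent.
    """

    grid_13c: tuple[int, int, int] = (16, 16, 8)
    voxel_13c: float = 15.0  # mm, isotropic
    upsample_factor: int = 8
    kpl_background: float = 0.012
    kpl_lesion: float = 0.024
    kpb_background: float = 0.008
    kpb_lesion: float = 0.006
    bolus_amplitude: float = 100.0  # a.u. of magnetization per second
    bolus_alpha: float = 2.0
    bolus_beta: float = 4.0  # s
    bolus_delay: float = 3.0  # s
    noise_sigma: float = 4.0  # a.u., additive Gaussian per voxel per timepoint
    seed: int = 0
    # ellipsoid geometry, as fractions of the grid extent per axis
    brain_axes_frac: tuple[float, float, float] = (0.425, 0.425, 0.45)
    wm_scale: float = 0.78  # WM ellipsoid semi-axes relative to brain
    lesion_center_frac: tuple[float, float, float] = (0.65, 0.41, 0.52)
    lesion_axes_frac: tuple[float, float, float] = (0.175, 0.16, 0.24)
    cel_scale: float = 0.45  # CEL semi-axes relative to lesion

    def __post_init__(self) -> None:
        if len(self.grid_13c) != 3 or any(int(n) != n or n < 1 for n in self.grid_13c):
            raise ConfigError(f"grid_13c must be three positive integers, got {self.grid_13c}")
        if self.upsample_factor < 1 or int(self.upsample_factor) != self.upsample_factor:
            raise ConfigError(f"upsample_factor must be a positive integer, got {self.upsample_factor}")
        for name in ("kpl_background", "kpl_lesion", "kpb_background", "kpb_lesion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.kpl_lesion <= self.kpl_background:
            raise ConfigError("lesion kPL must exceed background kPL")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be nonnegative")
        if self.bolus_alpha <= 0 or self.bolus_beta <= 0:
            raise ConfigError("gamma-variate shape and scale must be positive")
        if self.voxel_13c <= 0:
            raise ConfigError("voxel_13c must be positive")

    @property
    def grid_1h(self) -> tuple[int, int, int]:
        f = int(self.upsample_factor)
        return tuple(int(n) * f for n in self.grid_13c)

    @property
    def voxel_1h_mm(self) -> tuple[float, float, float]:
        d = self.voxel_13c / self.upsample_factor
        return (d, d, d)


@dataclass
class SyntheticStudy:
    """A complete synthetic scan: dynamics, masks, ground truth, metadata."""

    dynamics: dict[str, DynamicMetaboliteImage]
    masks: MaskSet
    truth_kpl: np.ndarray
    truth_kpb: np.ndarray
    clinical_row: dict
    config: PhantomConfig
    params: AcquisitionParams

    def __post_init__(self) -> None:
        shapes = {m: img.data.shape for m, img in self.dynamics.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"dynamic arrays disagree on shape: {shapes}")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def simulate_bolus(config: PhantomConfig, params: AcquisitionParams) -> np.ndarray:
    """Gamma-variate pyruvate inflow sampled at the excitation times.

    g(t) = A * ((t - d)/beta)**alpha * exp(-(t - d)/beta) for t > d, else 0.
    Returned in signal units per second, length ``n_timepoints``.
    """
    if config.bolus_alpha <= 0 or config.bolus_beta <= 0:
        raise ConfigError("gamma-variate shape and scale must be positive")
    t = params.times
    tau = (t - config.bolus_delay) / config.bolus_beta
    with np.errstate(invalid="ignore"):
        g = np.where(tau > 0, config.bolus_amplitude * tau ** config.bolus_alpha * np.exp(-tau), 0.0)
    return np.nan_to_num(g, nan=0.0)


def _interval_propagators(kpl: float, kpb: float, params: AcquisitionParams):
    """Exact one-interval propagators: Mz' = F @ Mz + G * g.

    F = expm(A dt); G is the response to a unit inflow held constant over
    the interval, G = A^{-1} (F - I) e1.
    """
    a = np.array(
        [
            [-(1.0 / params.t1_pyr + kpl + kpb), 0.0, 0.0],
            [kpl, -1.0 / params.t1_lac, 0.0],
            [kpb, 0.0, -1.0 / params.t1_bic],
        ]
    )
    f = expm(a * params.dt)
    g = np.linalg.solve(a, (f - np.eye(3)) @ np.array([1.0, 0.0, 0.0]))
    return f, g


def simulate_voxel_dynamics(
    kpl: float,
    kpb: float,
    inflow: np.ndarray,
    params: AcquisitionParams,
    initial_mz: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless measured signal curves (pyruvate, lactate, bicarbonate).

    The inflow curve gives the pyruvate source rate, held constant over
    each inter-excitation interval; ``inflow[k]`` applies on
    ``[t_k, t_{k+1})``.  Signals are ``Mz * sin(flip)`` at each excitation.
    """
    if kpl < 0 or kpb < 0:
        raise ValueError(f"conversion rates must be nonnegative, got kpl={kpl}, kpb={kpb}")
    inflow = np.asarray(inflow, dtype=float)
    if inflow.shape != (params.n_timepoints,):
        raise ValueError(
            f"inflow must have length n_timepoints={params.n_timepoints}, got shape {inflow.shape}"
        )
    mz = np.zeros(3) if initial_mz is None else np.asarray(initial_mz, dtype=float).copy()
    sines = np.array([np.sin(params.flip_rad(m)) for m in METABOLITES])
    cosines = np.array([np.cos(params.flip_rad(m)) for m in METABOLITES])
    f, g = _interval_propagators(kpl, kpb, params)

    signals = np.zeros((3, params.n_timepoints))
    for k in range(params.n_timepoints):
        signals[:, k] = mz * sines
        mz = mz * cosines  # RF depletion
        if k + 1 < params.n_timepoints:
            mz = f @ mz + g * inflow[k]
    signals = np.clip(signals, 0.0, None)
    return signals[0], signals[1], signals[2]


# ---------------------------------------------------------------------------
# anatomy and study generation
# ---------------------------------------------------------------------------

def _ellipsoid(coords, center, axes) -> np.ndarray:
    """Boolean mask of points inside an axis-aligned ellipsoid."""
    x, y, z = coords
    return (
        ((x - center[0]) / axes[0]) ** 2
        + ((y - center[1]) / axes[1]) ** 2
        + ((z - center[2]) / axes[2]) ** 2
    ) <= 1.0


def _grid_centers(shape, step: float):
    """Voxel-center coordinates in units of 13C voxels, as a meshgrid."""
    ax = [(np.arange(n) + 0.5) * step for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _geometry(config: PhantomConfig):
    nx, ny, nz = config.grid_13c
    extent = np.array([nx, ny, nz], dtype=float)
    brain_c = extent / 2.0
    brain_a = extent * np.asarray(config.brain_axes_frac)
    wm_a = brain_a * config.wm_scale
    les_c = extent * np.asarray(config.lesion_center_frac)
    les_a = extent * np.asarray(config.lesion_axes_frac)
    cel_a = les_a * config.cel_scale
    return brain_c, brain_a, wm_a, les_c, les_a, cel_a


def generate_phantom(config: PhantomConfig, params: AcquisitionParams | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study with known kPL/kPB truth.

    The lesion carries ``kpl_lesion``/``kpb_lesion``, the rest of the brain
    the background rates, and voxels outside the brain carry no signal.
    Gaussian noise of sd ``noise_sigma`` corrupts every voxel and
    timepoint.  All randomness is governed by ``config.seed``.
    """
    if params is None:
        params = AcquisitionParams()
    brain_c, brain_a, wm_a, les_c, les_a, cel_a = _geometry(config)

    # 1H masks: rasterize ellipsoids at fine voxel centers
    coords_1h = _grid_centers(config.grid_1h, 1.0 / config.upsample_factor)
    brain_1h = _ellipsoid(coords_1h, brain_c, brain_a)
    lesion_1h = _ellipsoid(coords_1h, les_c, les_a)
    if np.any(lesion_1h & ~brain_1h):
        raise ConfigError("lesion extends outside the brain; shrink or recenter it")
    wm_1h = _ellipsoid(coords_1h, brain_c, wm_a) & brain_1h
    cel_1h = _ellipsoid(coords_1h, les_c, cel_a) & lesion_1h
    masks = MaskSet(
        brain=brain_1h, t2l=lesion_1h, cel=cel_1h, wm=wm_1h, voxel_mm=config.voxel_1h_mm
    )

    # 13C tissue classes: brain by majority overlap of the 1H mask (so the
    # non-brain background is pure noise), lesion by voxel-center membership
    from .rois import block_fractions

    coords_13c = _grid_centers(config.grid_13c, 1.0)
    brain_13c = block_fractions(brain_1h, config.upsample_factor) >= 0.5
    lesion_13c = _ellipsoid(coords_13c, les_c, les_a) & brain_13c
    truth_kpl = np.where(lesion_13c, config.kpl_lesion, np.where(brain_13c, config.kpl_background, 0.0))
    truth_kpb = np.where(lesion_13c, config.kpb_lesion, np.where(brain_13c, config.kpb_background, 0.0))

    # one clean curve per tissue class, broadcast to voxels
    inflow = simulate_bolus(config, params)
    zero = np.zeros(params.n_timepoints)
    curves = {
        "background": simulate_voxel_dynamics(config.kpl_background, config.kpb_background, inflow, params),
        "lesion": simulate_voxel_dynamics(config.kpl_lesion, config.kpb_lesion, inflow, params),
        "outside": (zero, zero, zero),
    }
    shape4 = (*config.grid_13c, params.n_timepoints)
    clean = {m: np.zeros(shape4) for m in METABOLITES}
    for im, m in enumerate(METABOLITES):
        clean[m][lesion_13c] = curves["lesion"][im]
        clean[m][brain_13c & ~lesion_13c] = curves["background"][im]

    rng = np.random.default_rng(config.seed)
    dynamics: dict[str, DynamicMetaboliteImage] = {}
    for m in METABOLITES:  # fixed draw order: pyruvate, lactate, bicarbonate
        data = clean[m]
        if config.noise_sigma > 0:
            data = data + rng.normal(0.0, config.noise_sigma, size=shape4)
        dynamics[m] = DynamicMetaboliteImage(
            data=data, metabolite=m, voxel_mm=config.voxel_13c, params=params
        )

    clinical_row = {
        "patient_id": "SYN01",
        "age": 55,
        "sex": "M",
        "diagnosis": "rGBM",
        "treatment": "TMZ",
        "pfs6_flag": 0,
        "os_years": 1.0,
        "baseline_acquired": "Yes",
        "followup_months": "",
    }
    return SyntheticStudy(
        dynamics=dynamics,
        masks=masks,
        truth_kpl=truth_kpl,
        truth_kpb=truth_kpb,
        clinical_row=clinical_row,
        config=config,
        params=params,
    )
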