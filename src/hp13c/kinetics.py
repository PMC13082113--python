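"""Inputless kinetic modeling of pyruvate-to-lactate and
pyruvate-to-bicarbonate conversion from dynamic metabolite curves.

The "inputless" model sidesteps the unknown arterial input function by
using the measured pyruvate signal itself as the driving term.  The
measured pyruvate signal at excitation m is converted back to
longitudinal magnetization, P[m] = S_pyr[m]/sin(flip_pyr), and each
product pool (lactate, bicarbonate) is propagated between excitations:

    L[m+1] = L[m] * cos(flip_L) * exp(-dt/T1L) + kPL * I[m]

where I[m] integrates the pyruvate magnetization over the interval,
weighted by the product pool's T1 decay of label converted mid-interval.
Pyruvate between its post-flip value P[m]*cos(flip_P) and the next
measurement P[m+1] is interpolated exponentially (its true evolution in
the absence of inflow), giving the closed form

    I[m] = (P[m+1] - P[m] cos(flip_P) e^{-dt/T1L}) / (rho + 1/T1L),
    rho  = log(P[m+1] / (P[m] cos(flip_P))) / dt,

with a linear-interpolation fallback when noise drives an endpoint
nonpositive.  The prediction is linear in the rate, so the nonnegative
least-squares estimate and its standard error are closed-form.  The two
product channels are fitted independently; T1s are fixed constants.

"Modeling error" of a fitted rate is its relative standard error from
the linearized least-squares covariance; rate maps are filtered at 30%
(kPL) and 50% (kPB) of the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams, DynamicMetaboliteImage

__all__ = [
    "KineticFitResult",
    "KineticMaps",
    "NoSignalError",
    "fit_voxel_inputless",
    "fit_map",
    "KPL_ERROR_THRESHOLD",
    "KPB_ERROR_THRESHOLD",
    "RATE_BOUNDS",
]

#: default modeling-error thresholds (relative standard error of the estimate)
KPL_ERROR_THRESHOLD = 0.30
KPB_ERROR_THRESHOLD = 0.50
#: physiological bounds on apparent conversion rates, 1/s
RATE_BOUNDS = (0.0, 1.0)

_TINY = 1e-12


class NoSignalError(ValueError):
    """Raised when the driving pyruvate curve carries no signal."""


@dataclass
class KineticFitResult:
    """Fitted conversion rates and their uncertainty for one voxel."""

    kpl: float
    kpb: float
    kpl_relerr: float
    kpb_relerr: float
    converged: bool
    n_points_used: int


@dataclass
class KineticMaps:
    """Voxel-wise rate maps with modeling-error masks on the 13C grid.

    Unfitted voxels are NaN (invalid), never zero.  The error masks keep
    voxels whose relative standard error is at or below the threshold;
    they are subsets of the converged-fit voxels by construction.
    """

    kpl_map: np.ndarray
    kpb_map: np.ndarray
    kpl_relerr_map: np.ndarray
    kpb_relerr_map: np.ndarray
    kpl_error_mask: np.ndarray
    kpb_error_mask: np.ndarray
    fitted_mask: np.ndarray


def _drive_integrals(p_mz: np.ndarray, params: AcquisitionParams, r: float) -> np.ndarray:
    """Per-interval integral of the pyruvate drive with product-T1 weighting.

    ``p_mz`` has shape (V, T); returns shape (V, T-1).  ``r`` is the decay
    rate 1/T1 of the receiving pool.
    """
    dt = params.dt
    cphi = np.cos(params.flip_rad("pyruvate"))
    p_post = p_mz[:, :-1] * cphi
    p_next = p_mz[:, 1:]
    e = np.exp(-r * dt)

    ok = (p_post > _TINY) & (p_next > _TINY)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(ok, np.log(np.where(ok, p_next / np.where(ok, p_post, 1.0), 1.0)) / dt, 0.0)
        denom = rho + r
        i_exp = np.where(np.abs(denom) > 1e-9, (p_next - p_post * e) / np.where(denom == 0, 1.0, denom), dt * p_next)
    # linear interpolation of clipped endpoints: int (a + c s) e^{-r(dt-s)} ds
    a = np.clip(p_post, 0.0, None)
    b = np.clip(p_next, 0.0, None)
    c = (b - a) / dt
    i_lin = b * (1.0 - e) / r - c * (1.0 - e - r * dt * e) / r**2
    return np.where(ok, i_exp, i_lin)


def _fit_channel(
    p_mz: np.ndarray,
    prod_signal: np.ndarray,
    params: AcquisitionParams,
    metabolite: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form NNLS fit of one product channel, vectorized over voxels.

    Returns (rate, relative standard error, converged) each of shape (V,).
    """
    n_t = p_mz.shape[1]
    sphi = np.sin(params.flip_rad(metabolite))
    decay = np.cos(params.flip_rad(metabolite)) * np.exp(-params.dt / params.t1(metabolite))
    prod_mz = prod_signal / sphi

    drive = _drive_integrals(p_mz, params, 1.0 / params.t1(metabolite))

    # prediction is linear in the rate: L_pred[m] = H[m] + k * G[m]
    h = np.empty_like(prod_mz)
    g = np.zeros_like(prod_mz)
    h[:, 0] = prod_mz[:, 0]
    for m in range(n_t - 1):
        h[:, m + 1] = decay * h[:, m]
        g[:, m + 1] = decay * g[:, m] + drive[:, m]

    x = g[:, 1:]
    y = prod_mz[:, 1:] - h[:, 1:]
    sxx = np.einsum("vt,vt->v", x, x)
    sxy = np.einsum("vt,vt->v", x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.clip(sxy / sxx, *RATE_BOUNDS)
    converged = np.isfinite(k) & (sxx > _TINY)
    k = np.where(converged, k, np.nan)

    resid = y - k[:, None] * x
    dof = max(n_t - 2, 1)  # (T-1) residuals, one parameter
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.einsum("vt,vt->v", resid, resid) / dof
        se = np.sqrt(sigma2 / sxx)
        relerr = np.where(k > 0, se / k, np.inf)
    relerr = np.where(converged, relerr, np.nan)
    return k, relerr, converged


def fit_voxel_inputless(
    pyr_curve: np.ndarray,
    lac_curve: np.ndarray,
    bic_curve: np.ndarray,
    params: AcquisitionParams,
) -> KineticFitResult:
    """Fit kPL and kPB for a single voxel's dynamic curves.

    The measured pyruvate drives both product channels; lactate and
    bicarbonate are fitted independently.  Raises :class:`NoSignalError`
    when the pyruvate curve carries no positive signal.
    """
    curves = [np.asarray(c, dtype=float).ravel() for c in (pyr_curve, lac_curve, bic_curve)]
    n_t = curves[0].size
    if any(c.size != n_t for c in curves):
        raise ValueError("pyruvate, lactate and bicarbonate curves must have equal length")
    if n_t < 3:
        raise ValueError(f"need at least 3 timepoints to fit, got {n_t}")
    if n_t != params.n_timepoints:
        raise ValueError(f"curve length {n_t} does not match n_timepoints={params.n_timepoints}")
    if not np.any(curves[0] > 0):
        raise NoSignalError("pyruvate curve has no positive signal; cannot drive the model")
    for m in ("pyruvate", "lactate", "bicarbonate"):
        if params.flip_rad(m) <= 0:
            raise ValueError(f"fitting requires a nonzero {m} flip angle")

    p_mz = (curves[0] / np.sin(params.flip_rad("pyruvate")))[None, :]
    kpl, kpl_err, conv_l = _fit_channel(p_mz, curves[1][None, :], params, "lactate")
    kpb, kpb_err, conv_b = _fit_channel(p_mz, curves[2][None, :], params, "bicarbonate")
    converged = bool(conv_l[0] and conv_b[0])
    return KineticFitResult(
        kpl=float(kpl[0]),
        kpb=float(kpb[0]),
        kpl_relerr=float(kpl_err[0]),
        kpb_relerr=float(kpb_err[0]),
        converged=converged,
        n_points_used=n_t - 1,
    )


def fit_map(
    dynamics: dict[str, DynamicMetaboliteImage | np.ndarray],
    fit_mask: np.ndarray,
    params: AcquisitionParams,
    kpl_error_threshold: float = KPL_ERROR_THRESHOLD,
    kpb_error_threshold: float = KPB_ERROR_THRESHOLD,
    snr_mask: np.ndarray | None = None,
) -> KineticMaps:
    """Fit every voxel of ``fit_mask`` and build rate and error-mask maps.

    ``dynamics`` maps metabolite name to a 4D array (or
    :class:`~hp13c.acquisition.DynamicMetaboliteImage`).  ``snr_mask``, if
    given, is intersected with ``fit_mask`` (typically the pyruvate
    aSNR >= 5 mask).  Voxels whose driving pyruvate curve has no positive
    signal are left unfitted rather than raising.
    """
    arrs = {
        m: (img.data if isinstance(img, DynamicMetaboliteImage) else np.asarray(img, dtype=float))
        for m, img in dynamics.items()
    }
    shape = arrs["pyruvate"].shape[:3]
    mask = np.asarray(fit_mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"fit_mask shape {mask.shape} does not match image grid {shape}")
    if snr_mask is not None:
        mask = mask & np.asarray(snr_mask, dtype=bool)

    nan_map = np.full(shape, np.nan)
    maps = KineticMaps(
        kpl_map=nan_map.copy(),
        kpb_map=nan_map.copy(),
        kpl_relerr_map=nan_map.copy(),
        kpb_relerr_map=nan_map.copy(),
        kpl_error_mask=np.zeros(shape, dtype=bool),
        kpb_error_mask=np.zeros(shape, dtype=bool),
        fitted_mask=np.zeros(shape, dtype=bool),
    )
    if not mask.any():
        warnings.warn("fit mask is empty; returning empty kinetic maps", stacklevel=2)
        return maps

    pyr = arrs["pyruvate"][mask]
    has_signal = np.any(pyr > 0, axis=1)
    if not has_signal.any():
        warnings.warn("no voxel in the fit mask has pyruvate signal", stacklevel=2)
        return maps
    idx = np.flatnonzero(mask.ravel())[has_signal]
    sel = np.zeros(mask.size, dtype=bool)
    sel[idx] = True
    sel = sel.reshape(shape)

    p_mz = arrs["pyruvate"][sel] / np.sin(params.flip_rad("pyruvate"))
    kpl, kpl_err, conv_l = _fit_channel(p_mz, arrs["lactate"][sel], params, "lactate")
    kpb, kpb_err, conv_b = _fit_channel(p_mz, arrs["bicarbonate"][sel], params, "bicarbonate")

    maps.kpl_map[sel] = kpl
    maps.kpb_map[sel] = kpb
    maps.kpl_relerr_map[sel] = kpl_err
    maps.kpb_relerr_map[sel] = kpb_err
    maps.fitted_mask[sel] = conv_l & conv_b
    maps.kpl_error_mask[sel] = conv_l & (np.nan_to_num(kpl_err, nan=np.inf) <= kpl_error_threshold)
    maps.kpb_error_mask[sel] = conv_b & (np.nan_to_num(kpb_err, nan=np.inf) <= kpb_error_threshold)
    return maps
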