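"""AUC, noise, aSNR, metabolite-ratio and percentile-rank maps.

Dynamic metabolite images are temporally summed into area-under-the-curve
(AUC) maps.  The background noise standard deviation is estimated from
non-brain voxels, propagated to the AUC by i.i.d. summation
(sd_AUC = sigma * sqrt(T)), and used to form apparent-SNR maps; voxels
with aSNR below 5 are filtered before ratio maps are computed.  Percentile
rank maps re-express each metabolite's AUC within the brain (no SNR
filtering) on a 0-100 scale using average ranks for ties, giving
patient-internal, scanner-scale-free parameters (Pyr%, Lac%, Bic%).

Invalid voxels are carried as NaN throughout, never zero, so downstream
medians are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .acquisition import DynamicMetaboliteImage

__all__ = [
    "RatioMaps",
    "NoiseEstimationError",
    "ASNR_THRESHOLD",
    "compute_auc",
    "estimate_noise_sigma",
    "compute_asnr",
    "snr_mask",
    "ratio_maps",
    "percentile_rank_map",
]

#: default aSNR cutoff: voxels with aSNR < 5 are filtered out
ASNR_THRESHOLD = 5.0

#: minimum number of background voxels for a usable noise estimate
MIN_BACKGROUND_VOXELS = 100


class NoiseEstimationError(ValueError):
    """Raised when the background region is too small to estimate noise."""


def _as_array(dynamic) -> np.ndarray:
    if isinstance(dynamic, DynamicMetaboliteImage):
        return dynamic.data
    arr = np.asarray(dynamic, dtype=float)
    if arr.ndim != 4:
        raise ValueError(f"dynamic image must be 4D, got shape {arr.shape}")
    return arr


def compute_auc(dynamic) -> np.ndarray:
    """Area under the dynamic curve: voxel-wise sum over the time axis."""
    arr = _as_array(dynamic)
    if arr.shape[-1] < 1:
        raise ValueError("dynamic image needs at least one timepoint")
    return arr.sum(axis=-1)


def estimate_noise_sigma(dynamic, brain_mask: np.ndarray) -> float:
    """Noise sd from background (non-brain) voxels pooled across timepoints."""
    arr = _as_array(dynamic)
    background = ~np.asarray(brain_mask, dtype=bool)
    if background.shape != arr.shape[:3]:
        raise ValueError(f"brain mask shape {background.shape} does not match grid {arr.shape[:3]}")
    n_bg = int(background.sum())
    if n_bg < MIN_BACKGROUND_VOXELS:
        raise NoiseEstimationError(
            f"only {n_bg} background voxels (need >= {MIN_BACKGROUND_VOXELS}) to estimate noise"
        )
    samples = arr[background].ravel()
    return float(np.std(samples, ddof=1))


def compute_asnr(auc: np.ndarray, sigma: float, n_timepoints: int) -> np.ndarray:
    """Apparent SNR of an AUC map: AUC / (sigma * sqrt(T)).

    Under i.i.d. additive noise the sd of a T-point temporal sum is
    sigma * sqrt(T), so this is the AUC in units of its own noise sd.
    """
    if sigma <= 0:
        raise ValueError(f"noise sigma must be positive, got {sigma}")
    if n_timepoints < 1:
        raise ValueError(f"n_timepoints must be >= 1, got {n_timepoints}")
    return np.asarray(auc, dtype=float) / (sigma * np.sqrt(n_timepoints))


def snr_mask(asnr: np.ndarray, threshold: float = ASNR_THRESHOLD) -> np.ndarray:
    """Keep voxels with aSNR >= threshold (aSNR below threshold is filtered)."""
    return np.asarray(asnr, dtype=float) >= threshold


@dataclass
class RatioMaps:
    """SNR-masked metabolite AUC ratios; invalid voxels are NaN."""

    lac_pyr: np.ndarray
    bic_pyr: np.ndarray
    bic_lac: np.ndarray
    lac_pyr_valid: np.ndarray
    bic_pyr_valid: np.ndarray
    bic_lac_valid: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"lac_pyr": self.lac_pyr, "bic_pyr": self.bic_pyr, "bic_lac": self.bic_lac}


def _masked_ratio(num, den, valid) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=valid & (den != 0))
    return out


def ratio_maps(aucs: dict[str, np.ndarray], snr_masks: dict[str, np.ndarray]) -> RatioMaps:
    """Metabolite ratio maps, valid only where both constituents pass SNR.

    ``aucs`` and ``snr_masks`` are keyed by metabolite name.  Ratios are
    Lac/Pyr, Bic/Pyr and Bic/Lac; voxels failing either constituent's SNR
    mask are NaN.
    """
    masks = {m: np.asarray(v, dtype=bool) for m, v in snr_masks.items()}
    pairs = {
        "lac_pyr": ("lactate", "pyruvate"),
        "bic_pyr": ("bicarbonate", "pyruvate"),
        "bic_lac": ("bicarbonate", "lactate"),
    }
    values, valids = {}, {}
    for name, (num, den) in pairs.items():
        valid = masks[num] & masks[den]
        values[name] = _masked_ratio(np.asarray(aucs[num], float), np.asarray(aucs[den], float), valid)
        valids[name] = valid & np.isfinite(values[name])
    return RatioMaps(
        lac_pyr=values["lac_pyr"],
        bic_pyr=values["bic_pyr"],
        bic_lac=values["bic_lac"],
        lac_pyr_valid=valids["lac_pyr"],
        bic_pyr_valid=valids["bic_pyr"],
        bic_lac_valid=valids["bic_lac"],
    )


def percentile_rank_map(auc: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Tied-rank percentile map over brain voxels, scaled to (0, 100].

    Brain-masked AUC values are ranked with average ranks for ties,
    normalized by the total number of brain voxels (no SNR filtering) and
    scaled by 100.  Non-brain voxels are NaN.
    """
    auc = np.asarray(auc, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != auc.shape:
        raise ValueError(f"brain mask shape {mask.shape} does not match AUC shape {auc.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("brain mask is empty; cannot rank")
    out = np.full(auc.shape, np.nan)
    out[mask] = 100.0 * rankdata(auc[mask], method="average") / n
    return out
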