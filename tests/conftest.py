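"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by the most naive
route available (fine-step ODE integration, O(n^2) ranking, explicit
per-block counting) so they stay independent of the library's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hp13c import AcquisitionParams, PhantomConfig
from hp13c.phantom import simulate_bolus


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    """Default acquisition: 20 timepoints at 3 s, flips 20/30/30."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Desk-scale phantom for fast tests: 8x8x4 13C grid, 4x refinement."""
    return PhantomConfig(grid_13c=(8, 8, 4), upsample_factor=4, seed=7)


@pytest.fixture(scope="session")
def inflow(default_config, params) -> np.ndarray:
    return simulate_bolus(default_config, params)


# ---------------------------------------------------------------------------
# oracle: fine-step forward-Euler integration of the three-pool model
# ---------------------------------------------------------------------------

def euler_voxel_oracle(
    kpl: float,
    kpb: float,
    inflow: np.ndarray,
    params: AcquisitionParams,
    n_sub: int = 1000,
    track_losses: bool = False,
    initial_mz: np.ndarray | None = None,
):
    """Forward-Euler integration at dt/n_sub of the three-pool exchange model.

    The inflow is piecewise constant per inter-excitation interval,
    matching the discrete model's convention.  Optionally tracks the
    cumulative T1 and RF losses for mass-balance checks.
    """
    t1 = np.array([params.t1_pyr, params.t1_lac, params.t1_bic])
    sines = np.array([np.sin(params.flip_rad(m)) for m in ("pyruvate", "lactate", "bicarbonate")])
    cosines = np.array([np.cos(params.flip_rad(m)) for m in ("pyruvate", "lactate", "bicarbonate")])
    h = params.dt / n_sub
    mz = np.zeros(3) if initial_mz is None else np.asarray(initial_mz, dtype=float).copy()
    signals = np.zeros((3, params.n_timepoints))
    t1_loss = 0.0
    rf_loss = 0.0
    total_in = 0.0
    for k in range(params.n_timepoints):
        signals[:, k] = mz * sines
        rf_loss += float(np.sum(mz * (1.0 - cosines)))
        mz = mz * cosines
        if k + 1 < params.n_timepoints:
            g = inflow[k]
            for _ in range(n_sub):
                dp = -(1.0 / t1[0] + kpl + kpb) * mz[0] + g
                dl = kpl * mz[0] - mz[1] / t1[1]
                db = kpb * mz[0] - mz[2] / t1[2]
                t1_loss += h * float(np.sum(mz / t1))
                total_in += h * g
                mz = mz + h * np.array([dp, dl, db])
    if track_losses:
        return signals, {"mz_final": mz, "t1_loss": t1_loss, "rf_loss": rf_loss, "total_in": total_in}
    return signals


# ---------------------------------------------------------------------------
# oracle: O(n^2) tied-rank percentiles
# ---------------------------------------------------------------------------

def percentile_oracle(values: np.ndarray) -> np.ndarray:
    """Average-rank percentile of each value, by explicit counting."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    out = np.empty(n)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        rank = less + (equal + 1) / 2.0
        out[i] = 100.0 * rank / n
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive per-block overlap counting for ROI downsampling
# ---------------------------------------------------------------------------

def downsample_oracle(t2l_1h, nawm_1h, factor, t2l_thr=0.30, nawm_thr=0.50):
    """Label each 13C voxel by explicit loops over its 1H block."""
    t2l_1h = np.asarray(t2l_1h, dtype=bool)
    nawm_1h = np.asarray(nawm_1h, dtype=bool)
    nx, ny, nz = (s // factor for s in t2l_1h.shape)
    labels = np.zeros((nx, ny, nz), dtype=int)
    block = factor**3
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                sl = (
                    slice(i * factor, (i + 1) * factor),
                    slice(j * factor, (j + 1) * factor),
                    slice(k * factor, (k + 1) * factor),
                )
                ft = t2l_1h[sl].sum() / block
                fn = nawm_1h[sl].sum() / block
                if ft >= t2l_thr:
                    labels[i, j, k] = 1
                elif fn >= nawm_thr:
                    labels[i, j, k] = 2
    return labels


def masked_median_oracle(values: np.ndarray, mask: np.ndarray) -> float:
    """Median over masked finite voxels via explicit sort."""
    vals = sorted(float(v) for v, m in zip(np.ravel(values), np.ravel(mask)) if m and np.isfinite(v))
    n = len(vals)
    if n == 0:
        return float("nan")
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])
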