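"""Voxelwise DSC perfusion quantification.

Converts a 4D dynamic susceptibility contrast (DSC) signal series into
contrast-agent concentration-time curves, fits the LDRW indicator-dilution
model per voxel, and derives the four perfusion parameter maps:

* CBV  - cerebral blood volume, the fitted curve area ``A`` (conversion
  constant fixed at 1, so values are semi-quantitative: no arterial input
  function is used and no deconvolution is performed);
* MTT  - mean transit time, the first moment of the fitted density,
  ``mu * (1 + 1/lam)`` (seconds);
* CBF  - cerebral blood flow via the central volume theorem,
  ``60 * CBV / MTT`` (per minute);
* TTP  - time to peak of the fitted model curve from acquisition start,
  located by dense-grid argmax (0.01 s grid).

The baseline window drops the first two volumes (T1-saturation convention)
and ends just before the bolus-start image.  Negative concentration samples
produced by noise are kept unclipped so the least-squares noise model stays
unbiased.  Slice-time correction is implicit: each slice's curves are fitted
on that slice's own acquisition time grid, so the fitted ``t0`` and TTP are
on a common absolute clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ldrw import (
    fit_ldrw_batch,
    fit_ldrw_curve,
    ldrw_first_moment,
    ldrw_mode,
)
from .protocol import AcquisitionProtocol

__all__ = [
    "AcquisitionProtocol",
    "LDRWFit",
    "LDRWFitVolume",
    "PerfusionMaps",
    "estimate_baseline",
    "signal_to_concentration",
    "slice_timebase",
    "fit_ldrw_voxel",
    "quantify_series",
    "perfusion_maps",
    "fit_quality_mask",
]

#: first volume used for baseline estimation and fitting (saturation dropped)
FIT_START = 2


@dataclass
class LDRWFit:
    """Fitted LDRW parameters for one voxel."""

    A: float
    mu: float
    lam: float
    t0: float
    r_squared: float
    converged: bool


@dataclass
class LDRWFitVolume:
    """Voxelwise LDRW fit results on a 3D grid (NaN outside the fit mask)."""

    A: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    t0: np.ndarray
    r_squared: np.ndarray
    converged: np.ndarray


@dataclass
class PerfusionMaps:
    """CBV/CBF/MTT/TTP volumes plus the valid-fit mask."""

    cbv: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    valid_mask: np.ndarray


def estimate_baseline(signal, protocol: AcquisitionProtocol):
    """Pre-bolus baseline signal S0.

    Mean of volumes ``FIT_START .. bolus_start_index - 1`` (0-based).
    Accepts a single series (length ``n_volumes``) or an array whose last
    axis is time.  Returns NaN where S0 is non-positive; raises if the
    window has fewer than 3 samples (a protocol configuration error).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != protocol.n_volumes:
        raise ValueError("series length does not match protocol.n_volumes")
    window = signal[..., FIT_START:protocol.bolus_start_index]
    if window.shape[-1] < 3:
        raise ValueError("fewer than 3 usable baseline volumes")
    s0 = window.mean(axis=-1)
    return np.where(s0 > 0, s0, np.nan) if s0.ndim else (float(s0) if s0 > 0 else np.nan)


def signal_to_concentration(signal, s0, te):
    """Convert signal to concentration: C(t) = -(1/te) * ln(S(t)/S0).

    Negative values (noise) are retained.  Voxels with any non-positive
    signal sample are invalid; for a single curve a ValueError is raised,
    for stacked curves the caller should pre-screen (see quantify_series).
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        raise ValueError("non-positive signal sample; voxel invalid")
    if not np.all(np.asarray(s0) > 0):
        raise ValueError("S0 must be positive")
    s0 = np.asarray(s0, dtype=float)
    return -np.log(signal / s0[..., None] if s0.ndim else signal / s0) / te


def slice_timebase(protocol: AcquisitionProtocol, slice_index: int):
    """Acquisition times of one slice: t_k = k*tr + slice_index*(tr/n_slices)."""
    if not 0 <= slice_index < protocol.n_slices:
        raise ValueError(f"slice index {slice_index} out of range")
    k = np.arange(protocol.n_volumes, dtype=float)
    return k * protocol.tr + slice_index * (protocol.tr / protocol.n_slices)


def fit_ldrw_voxel(concentration, t) -> LDRWFit:
    """Bounded nonlinear least-squares LDRW fit of one concentration curve.

    Initialization is by moments of the positive part of the curve; bounds
    are A in (0, 100*A0], mu and lam in [0.1, 100], t0 in [0, t_peak].
    A voxel with no usable signal (e.g. all-zero curve) returns
    ``converged=False``.
    """
    concentration = np.asarray(concentration, dtype=float)
    t = np.asarray(t, dtype=float)
    if concentration.shape != t.shape:
        raise ValueError("concentration and time grid must have equal length")
    res = fit_ldrw_curve(concentration, t)
    return LDRWFit(**res)


def quantify_series(series, protocol: AcquisitionProtocol, fit_mask) -> LDRWFitVolume:
    """Fit the LDRW model to every voxel of ``fit_mask`` in a 4D series.

    Parameters
    ----------
    series : (nx, ny, nz, n_volumes) array
        DSC signal series.
    protocol : AcquisitionProtocol
    fit_mask : (nx, ny, nz) bool array
        Voxels to quantify (typically the thresholded white-matter mask).

    Voxels with a non-positive baseline or any non-positive signal sample
    in the fit window are flagged ``converged=False`` without fitting.
    """
    series = np.asarray(series)
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if series.shape[:3] != fit_mask.shape:
        raise ValueError("series and fit_mask grids differ")
    if series.shape[3] != protocol.n_volumes:
        raise ValueError("series length does not match protocol.n_volumes")
    shape = fit_mask.shape
    nan = np.full(shape, np.nan)
    out = LDRWFitVolume(A=nan.copy(), mu=nan.copy(), lam=nan.copy(),
                        t0=nan.copy(), r_squared=np.zeros(shape),
                        converged=np.zeros(shape, dtype=bool))

    # gather all masked voxels with their slice-specific time grids
    ix, iy, iz = np.nonzero(fit_mask)
    if ix.size == 0:
        return out
    sig = series[ix, iy, iz, :].astype(float)
    s0 = estimate_baseline(sig, protocol)
    usable = np.isfinite(np.atleast_1d(s0)) & np.all(sig[:, FIT_START:] > 0, axis=1)
    tbase = np.stack([slice_timebase(protocol, z) for z in range(protocol.n_slices)])
    t_vox = tbase[iz][:, FIT_START:]
    conc = np.zeros_like(t_vox)
    u = np.flatnonzero(usable)
    conc[u] = -np.log(sig[u, FIT_START:] / s0[u, None]) / protocol.te

    fit = fit_ldrw_batch(conc[u], t_vox[u])
    for name in ("A", "mu", "lam", "t0"):
        getattr(out, name)[ix[u], iy[u], iz[u]] = fit[name]
    out.r_squared[ix[u], iy[u], iz[u]] = fit["r_squared"]
    out.converged[ix[u], iy[u], iz[u]] = fit["converged"]
    return out


def _ttp_grid_argmax(mu, lam, t0, step=0.01, halfwidth=0.5):
    """Time-to-peak by dense-grid argmax of the fitted curve.

    The LDRW curve is unimodal, so a +-halfwidth second window (floored at
    the support edge) around the analytic mode is guaranteed to bracket
    the maximum; the returned value is the grid argmax at ``step``
    resolution measured from acquisition start.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    t0 = np.atleast_1d(np.asarray(t0, dtype=float))
    mode = ldrw_mode(mu, lam)
    half = np.full_like(mode, float(halfwidth))
    lo = np.maximum(mode - half, step)
    npts = int(np.ceil(2 * half.max() / step)) + 1
    offs = np.arange(npts) * step
    tau = lo[:, None] + offs[None, :]
    logf = (0.5 * (np.log(lam) - np.log(mu))[:, None]
            - 0.5 * np.log(tau)
            - (lam[:, None] / 2.0) * (tau / mu[:, None] + mu[:, None] / tau))
    best = np.argmax(logf, axis=1)
    return t0 + lo + best * step


def perfusion_maps(fits: LDRWFitVolume, protocol: AcquisitionProtocol) -> PerfusionMaps:
    """Derive CBV/CBF/MTT/TTP maps from a voxelwise LDRW fit volume.

    The central volume identity ``cbf = 60 * cbv / mtt`` holds exactly by
    construction on every valid voxel.
    """
    valid = fits.converged.astype(bool)
    shape = valid.shape
    cbv = np.full(shape, np.nan)
    mtt = np.full(shape, np.nan)
    cbf = np.full(shape, np.nan)
    ttp = np.full(shape, np.nan)
    if valid.any():
        m = valid
        cbv[m] = fits.A[m]
        mtt[m] = ldrw_first_moment(fits.mu[m], fits.lam[m])
        cbf[m] = 60.0 * cbv[m] / mtt[m]
        ttp[m] = _ttp_grid_argmax(fits.mu[m], fits.lam[m], fits.t0[m])
    return PerfusionMaps(cbv=cbv, cbf=cbf, mtt=mtt, ttp=ttp, valid_mask=valid)


def fit_quality_mask(fits: LDRWFitVolume, r2_min: float = 0.5):
    """Voxels kept for analysis: converged and r_squared >= r2_min."""
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must lie in [0, 1]")
    return fits.converged.astype(bool) & (fits.r_squared >= r2_min)
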