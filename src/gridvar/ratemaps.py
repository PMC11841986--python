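"""Occupancy maps, smoothed firing-rate maps, and spatial autocorrelograms.

Conventions
-----------
Maps are 2D arrays of shape ``(nx, ny)`` indexed ``[ix, iy]`` with
``ix = floor(x / bin_size)`` from the arena corner; binning is half-open
``[lo, hi)`` with the far edge folded into the last bin.  Unvisited bins are
``NaN`` in ``values`` (never 0 Hz) and ``False`` in ``visited_mask``.

The spatial autocorrelogram (SAC) is the Pearson correlation of the rate map
with itself at every 2D lag, computed over bin pairs where both bins were
visited; lags with fewer than ``min_overlap`` overlapping pairs are missing.
All correlation sums are evaluated with FFT convolutions, so a full
``(2n-1) x (2n-1)`` SAC of a 50 x 50 map costs a few milliseconds.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .io_core import Recording

logger = logging.getLogger("gridvar")

__all__ = [
    "RateMap",
    "SAC",
    "n_bins_for",
    "compute_occupancy",
    "compute_rate_map",
    "compute_sac",
    "mask_center",
    "default_mask_radius",
    "masked_smooth",
]


@dataclasses.dataclass
class RateMap:
    """Occupancy-normalized, smoothed firing map.

    ``values`` are Hz on visited bins and NaN elsewhere; ``occupancy`` is
    seconds per bin; all arrays share one shape.
    """

    values: np.ndarray
    occupancy: np.ndarray
    bin_size: float
    visited_mask: np.ndarray
    n_spikes: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass
class SAC:
    """Spatial autocorrelogram over all 2D lags; NaN marks missing lags."""

    values: np.ndarray
    bin_size: float
    center_masked: bool = False
    mask_radius_bins: int = 0
    degenerate: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def n_bins_for(length: float, bin_size: float) -> int:
    return int(np.ceil(length / bin_size - 1e-9))


def _bin_index(coord: np.ndarray, bin_size: float, n_bins: int) -> np.ndarray:
    idx = np.floor(np.asarray(coord) / bin_size).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _sample_dwell(rec: Recording) -> np.ndarray:
    """Per-sample dwell: the following inter-sample interval; the last sample
    contributes the median interval.  Restricted recordings carry their own."""
    if rec.sample_dwell is not None:
        return np.asarray(rec.sample_dwell, dtype=float)
    dt = np.diff(rec.t)
    if dt.size == 0:
        return np.array([0.0])
    return np.append(dt, np.median(dt))


def compute_occupancy(rec: Recording, bin_size: float) -> np.ndarray:
    """Seconds spent per spatial bin; sums to the total trajectory duration."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if rec.t.size == 0:
        raise ValueError("empty trajectory")
    nx = n_bins_for(rec.arena[0], bin_size)
    ny = n_bins_for(rec.arena[1], bin_size)
    ix = _bin_index(rec.x, bin_size, nx)
    iy = _bin_index(rec.y, bin_size, ny)
    dwell = _sample_dwell(rec)
    occ = np.zeros((nx, ny))
    np.add.at(occ, (ix, iy), dwell)
    return occ


def masked_smooth(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that renormalizes by the smoothed mask, so missing
    bins neither leak mass in nor bias boundary bins low.  NaN outside mask."""
    if sigma <= 0:
        out = np.where(mask, values, np.nan)
        return out.astype(float)
    filled = np.where(mask, values, 0.0).astype(float)
    weight = gaussian_filter(mask.astype(float), sigma)
    smoothed = gaussian_filter(filled, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = smoothed / weight
    out[~mask] = np.nan
    return out


def compute_rate_map(
    rec: Recording,
    unit: str,
    bin_size: float,
    smooth_sigma_bins: float = 1.0,
) -> RateMap:
    """Spike count / occupancy per visited bin, then mask-aware smoothing.

    The animal's position at each spike time is linearly interpolated from
    the trajectory.  A unit with zero spikes yields a valid all-zero map.
    """
    if unit not in rec.spikes:
        raise KeyError(f"unknown unit {unit!r}")
    occ = compute_occupancy(rec, bin_size)
    visited = occ > 0.0
    nx, ny = occ.shape
    st = rec.spikes[unit]
    counts = np.zeros_like(occ)
    if st.size:
        sx = np.interp(st, rec.t, rec.x)
        sy = np.interp(st, rec.t, rec.y)
        ix = _bin_index(sx, bin_size, nx)
        iy = _bin_index(sy, bin_size, ny)
        np.add.at(counts, (ix, iy), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = counts / occ
    raw[~visited] = 0.0
    values = masked_smooth(raw, visited, smooth_sigma_bins)
    if st.size == 0:
        logger.info("unit %s: zero spikes, all-zero rate map", unit)
    return RateMap(values=values, occupancy=occ, bin_size=bin_size,
                   visited_mask=visited, n_spikes=int(st.size))


def _xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full cross-correlation sum C[d] = sum_u a[u+d] * b[u] via FFT."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def compute_sac(rmap: RateMap, min_overlap: int = 20) -> SAC:
    """Masked Pearson autocorrelation of the rate map at every 2D lag.

    Only pairs of visited bins contribute; the correlation at lag ``d`` uses
    means and variances computed on the overlap, so SAC(0, 0) = 1 exactly.
    An all-constant map has no defined correlation anywhere and is flagged
    ``degenerate`` instead of silently returning NaNs.
    """
    mask = rmap.visited_mask
    if int(mask.sum()) < 2:
        raise ValueError("need at least 2 visited bins")
    f = np.where(mask, rmap.values, 0.0).astype(float)
    m = mask.astype(float)
    n = np.rint(_xcorr(m, m))
    sxy = _xcorr(f, f)
    sx = _xcorr(f, m)
    sy = _xcorr(m, f)
    sxx = _xcorr(f * f, m)
    syy = _xcorr(m, f * f)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        den = np.sqrt(np.clip(varx, 0.0, None) * np.clip(vary, 0.0, None))
    scale = float(np.nanmax(np.abs(f))) or 1.0
    eps = 1e-9 * scale**2  # variance floor relative to map magnitude
    vals = np.full(n.shape, np.nan)
    good = (n >= max(min_overlap, 2)) & (den > eps * n)
    vals[good] = num[good] / den[good]
    vals = np.clip(vals, -1.0, 1.0)
    degenerate = not np.any(np.isfinite(vals))
    if degenerate:
        logger.warning("degenerate SAC: correlation undefined at every lag")
    return SAC(values=vals, bin_size=rmap.bin_size, degenerate=degenerate)


def _lag_radii(shape: tuple[int, int]) -> np.ndarray:
    ci, cj = shape[0] // 2, shape[1] // 2
    ii, jj = np.meshgrid(np.arange(shape[0]) - ci, np.arange(shape[1]) - cj, indexing="ij")
    return np.hypot(ii, jj)


def default_mask_radius(sac: SAC) -> int:
    """Center-mask radius adapted to the module scale.

    Uses the first local minimum of the radially averaged SAC profile,
    clamped to ``[2, 0.3 * half_width]`` bins, so the central peak is removed
    without hand tuning per module.
    """
    r = _lag_radii(sac.shape)
    half = (sac.shape[0] - 1) // 2
    prof = np.array([
        np.nanmean(sac.values[(r >= k) & (r < k + 1)]) for k in range(half)
    ])
    lo, hi = 2, max(2, int(0.3 * half))
    radius = hi
    for k in range(1, prof.size - 1):
        if np.isfinite(prof[k]) and prof[k] <= prof[k - 1] and prof[k] <= prof[k + 1]:
            radius = k
            break
    return int(np.clip(radius, lo, hi))


def mask_center(sac: SAC, radius_bins: int | None = None) -> SAC:
    """Mark lags within ``radius_bins`` of the zero lag as missing.

    ``radius_bins=None`` chooses the radius from the radial profile (see
    :func:`default_mask_radius`).  Masking is idempotent; an over-large
    radius is applied but logged as a warning.
    """
    if radius_bins is None:
        radius_bins = default_mask_radius(sac)
    half = (sac.shape[0] - 1) // 2
    if radius_bins >= half:
        raise ValueError("mask radius must be below half the SAC side")
    if radius_bins > 0.5 * half:
        logger.warning("mask radius %d may cover the inner peaks", radius_bins)
    r = _lag_radii(sac.shape)
    vals = sac.values.copy()
    vals[r <= radius_bins] = np.nan
    return SAC(values=vals, bin_size=sac.bin_size, center_masked=True,
               mask_radius_bins=int(radius_bins), degenerate=sac.degenerate)
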