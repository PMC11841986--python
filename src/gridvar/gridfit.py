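"""Grid-property estimation from the spatial autocorrelogram (SAC).

The estimator follows the field-standard recipe: smooth the center-masked
SAC, find the local maxima, keep the six nearest the zero lag (three
antipodal pairs), reduce each pair to its representative closest to the
x-axis, and read off per-axis spacing (peak radius x bin size) and
orientation (peak angle).  The overall orientation is a circular mean on the
60-degree-periodic domain; the overall spacing is the arithmetic mean of the
three axis spacings.

A fit is *valid* only if the hexagonal geometry checks pass: consecutive
angular gaps between the three axes within [30, 90] degrees and pairwise
spacing ratios within (0.5, 2).  The rotational grid score contrasts the
SAC annulus correlation at 60/120 degrees with 30/90/150 degrees.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .ratemaps import RateMap, SAC, default_mask_radius, mask_center, masked_smooth

logger = logging.getLogger("gridvar")

__all__ = [
    "GridFit",
    "find_sac_peaks",
    "fit_grid",
    "check_inclusion",
    "grid_score",
    "spacing_from_ratemap",
]

REJECTION_REASONS = (
    "none",
    "too_few_peaks",
    "angle_lt_30",
    "angle_gt_90",
    "spacing_ratio",
    "degenerate_sac",
)


@dataclasses.dataclass
class GridFit:
    """Per-cell grid geometry estimated from one SAC."""

    peaks: np.ndarray  # (k, 2) inner peaks as (radius_bins, angle_deg)
    axis_spacing: np.ndarray  # (3,) cm
    axis_orientation: np.ndarray  # (3,) deg, representatives in [-90, 90)
    spacing: float  # cm, mean of the three axes
    orientation: float  # deg in [0, 60)
    grid_score: float = np.nan
    valid: bool = False
    rejection_reason: str = "none"


def _invalid(reason: str) -> GridFit:
    nan3 = np.full(3, np.nan)
    return GridFit(
        peaks=np.empty((0, 2)), axis_spacing=nan3, axis_orientation=nan3,
        spacing=np.nan, orientation=np.nan, valid=False, rejection_reason=reason,
    )


def find_sac_peaks(
    sac: SAC,
    smooth_sigma: float = 1.0,
    threshold: float = 0.1,
    min_distance: int = 2,
) -> np.ndarray:
    """Local maxima of the smoothed, center-masked SAC.

    Returns integer ``(row, col)`` coordinates sorted by radial distance from
    the center lag.  Maxima closer than ``min_distance`` bins are merged,
    keeping the larger one (plateau suppression).
    """
    finite = np.isfinite(sac.values)
    if not finite.any():
        return np.empty((0, 2), dtype=int)
    sm = masked_smooth(sac.values, finite, smooth_sigma)
    filled = np.where(np.isfinite(sm), sm, -np.inf)
    local_max = filled == ndimage.maximum_filter(filled, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere(local_max & np.isfinite(sm) & (sm > threshold))
    if cand.size == 0:
        return np.empty((0, 2), dtype=int)
    vals = sm[cand[:, 0], cand[:, 1]]
    order = np.argsort(-vals)
    kept: list[np.ndarray] = []
    for idx in order:
        p = cand[idx]
        if all(np.hypot(*(p - q)) >= min_distance for q in kept):
            kept.append(p)
    kept_arr = np.array(kept)
    ci, cj = sac.center
    radii = np.hypot(kept_arr[:, 0] - ci, kept_arr[:, 1] - cj)
    return kept_arr[np.argsort(radii)]


def _refine_peak(values: np.ndarray, ij: np.ndarray) -> np.ndarray:
    """Sub-bin 3x3 quadratic refinement of a peak location (offsets in [-1, 1])."""
    i, j = int(ij[0]), int(ij[1])
    if i < 1 or j < 1 or i > values.shape[0] - 2 or j > values.shape[1] - 2:
        return ij.astype(float)
    w = values[i - 1 : i + 2, j - 1 : j + 2]
    if not np.all(np.isfinite(w)):
        return ij.astype(float)
    gi = (w[2, 1] - w[0, 1]) / 2.0
    gj = (w[1, 2] - w[1, 0]) / 2.0
    hii = w[2, 1] - 2 * w[1, 1] + w[0, 1]
    hjj = w[1, 2] - 2 * w[1, 1] + w[1, 0]
    hij = (w[2, 2] - w[2, 0] - w[0, 2] + w[0, 0]) / 4.0
    det = hii * hjj - hij * hij
    if det <= 0:  # require a proper maximum
        if hii >= 0 or hjj >= 0:
            return ij.astype(float)
    try:
        delta = -np.linalg.solve(np.array([[hii, hij], [hij, hjj]]), np.array([gi, gj]))
    except np.linalg.LinAlgError:
        return ij.astype(float)
    delta = np.clip(delta, -1.0, 1.0)
    return ij + delta


def _axis_representative(angle_deg: float) -> float:
    """Reduce a peak angle to its axis representative in [-90, 90)."""
    return float(((angle_deg + 90.0) % 180.0) - 90.0)


def check_inclusion(
    axis_angles: np.ndarray, axis_radii: np.ndarray
) -> tuple[bool, str]:
    """Hexagonal-geometry inclusion rules on three axis peaks.

    Rule order: consecutive angular gap < 30 deg; gap > 90 deg; pairwise
    spacing ratio outside (0.5, 2).  Gaps are the three successive
    differences of the axis angles on the 180-degree circle (they sum to
    180; an ideal grid gives 60/60/60).
    """
    a = np.sort(np.mod(np.asarray(axis_angles, dtype=float), 180.0))
    gaps = np.diff(np.append(a, a[0] + 180.0))
    if np.any(gaps < 30.0):
        return False, "angle_lt_30"
    if np.any(gaps > 90.0):
        return False, "angle_gt_90"
    r = np.asarray(axis_radii, dtype=float)
    if r.max() / r.min() >= 2.0:
        return False, "spacing_ratio"
    return True, "none"


def _circular_mean_60(angles_deg: np.ndarray) -> float:
    """Circular mean on the 60-degree-periodic orientation domain, in [0, 60)."""
    phases = np.deg2rad(np.asarray(angles_deg, dtype=float) * 6.0)
    mean = np.arctan2(np.sin(phases).mean(), np.cos(phases).mean())
    return float(np.rad2deg(mean) / 6.0 % 60.0)


def fit_grid(
    sac: SAC,
    smooth_sigma: float = 1.0,
    threshold: float = 0.1,
    refine_peaks: bool = False,
    compute_score: bool = True,
) -> GridFit:
    """Estimate spacing, orientation (overall and per axis), and validity.

    The six SAC peaks nearest the zero lag are grouped into antipodal pairs
    via their axis representative; one peak per nominal axis (0/60/120 deg)
    is selected by angular proximity.  ``refine_peaks`` switches on 3x3
    quadratic sub-bin interpolation of the peak coordinates.
    """
    if sac.degenerate:
        return _invalid("degenerate_sac")
    if not sac.center_masked:
        sac = mask_center(sac)
    peaks = find_sac_peaks(sac, smooth_sigma=smooth_sigma, threshold=threshold)
    if len(peaks) < 6:
        return _invalid("too_few_peaks")
    ci, cj = sac.center
    inner = peaks[:6].astype(float)
    if refine_peaks:
        finite = np.isfinite(sac.values)
        sm = masked_smooth(sac.values, finite, smooth_sigma)
        inner = np.array([_refine_peak(sm, p) for p in inner])
    d = inner - np.array([ci, cj], dtype=float)
    radii = np.hypot(d[:, 0], d[:, 1])
    angles = np.rad2deg(np.arctan2(d[:, 1], d[:, 0]))
    reps = np.array([_axis_representative(a) for a in angles])
    # nominal axis representatives on [-90, 90): 0, 60, 120->-60
    sm_vals = sac.values[peaks[:6, 0], peaks[:6, 1]]
    axis_idx: list[int] = []
    for nominal in (0.0, 60.0, -60.0):
        dist = np.abs(reps - nominal)
        cand = np.where(dist < 30.0)[0]
        if cand.size == 0:
            return _invalid("too_few_peaks")
        best = cand[np.lexsort((-np.nan_to_num(sm_vals[cand]), dist[cand]))[0]]
        axis_idx.append(int(best))
    if len(set(axis_idx)) < 3:
        return _invalid("too_few_peaks")
    axis_idx_arr = np.array(axis_idx)
    axis_radii = radii[axis_idx_arr]
    axis_angles = reps[axis_idx_arr]
    ok, reason = check_inclusion(axis_angles, axis_radii)
    axis_spacing = axis_radii * sac.bin_size
    fit = GridFit(
        peaks=np.column_stack([radii, angles]),
        axis_spacing=axis_spacing,
        axis_orientation=axis_angles,
        spacing=float(axis_spacing.mean()),
        orientation=_circular_mean_60(axis_angles),
        valid=ok,
        rejection_reason=reason,
    )
    if compute_score:
        try:
            fit.grid_score = grid_score(sac, peak_radii=radii)
        except ValueError:
            fit.grid_score = np.nan
    return fit


def grid_score(sac: SAC, peak_radii: np.ndarray | None = None) -> float:
    """Rotational-symmetry score of the SAC annulus.

    Correlates the annulus (mask radius out to just beyond the inner peaks)
    with itself rotated by 30..150 degrees and returns
    ``min(corr60, corr120) - max(corr30, corr90, corr150)``.  Invariant to
    affine rescaling of the firing rates.
    """
    if not sac.center_masked:
        sac = mask_center(sac)
    half = (sac.shape[0] - 1) // 2
    inner_r = max(sac.mask_radius_bins, 2)
    if peak_radii is None:
        peaks = find_sac_peaks(sac)
        peak_radii = (
            np.hypot(*(peaks[:6] - np.array(sac.center)).T) if len(peaks) else None
        )
    if peak_radii is not None and len(peak_radii) > 0:
        outer_r = min(1.25 * float(np.max(peak_radii)), 0.95 * half)
    else:
        outer_r = 0.95 * half
    if outer_r <= inner_r + 2:
        raise ValueError("degenerate annulus")
    ci, cj = sac.center
    ii, jj = np.meshgrid(
        np.arange(sac.shape[0]) - ci, np.arange(sac.shape[1]) - cj, indexing="ij"
    )
    r = np.hypot(ii, jj)
    annulus = (r >= inner_r) & (r <= outer_r)
    base = sac.values
    base_ok = np.isfinite(base)
    filled = np.where(base_ok, base, 0.0)
    corrs = {}
    for ang in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(filled, ang, reshape=False, order=1, mode="constant", cval=0.0)
        rot_ok = (
            ndimage.rotate(base_ok.astype(float), ang, reshape=False, order=1,
                           mode="constant", cval=0.0) > 0.99
        )
        sel = annulus & base_ok & rot_ok
        if sel.sum() < 20:
            raise ValueError("degenerate annulus")
        a, b = base[sel], rot[sel]
        sa, sb = a.std(), b.std()
        if sa <= 0 or sb <= 0:
            raise ValueError("degenerate annulus")
        corrs[ang] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])


def spacing_from_ratemap(
    rmap: RateMap, smooth_sigma: float = 1.5, min_distance: int = 3
) -> float:
    """Spacing (cm) from the three firing fields nearest the arena center.

    A boundary-insensitive control for the SAC estimate: smooth the rate map,
    locate field centers as local maxima, keep the three closest to the arena
    center, and return the mean of their pairwise distances.  Returns NaN
    (and logs) when fewer than three fields are detectable.
    """
    sm = masked_smooth(rmap.values, rmap.visited_mask, smooth_sigma)
    filled = np.where(np.isfinite(sm), sm, 0.0)
    top = np.nanmax(sm) if np.isfinite(sm).any() else 0.0
    if top <= 0:
        logger.info("rate-map spacing undefined: empty or flat map")
        return np.nan
    coords = peak_local_max(
        filled, min_distance=min_distance, threshold_abs=0.2 * top, exclude_border=False
    )
    if len(coords) < 3:
        logger.info("rate-map spacing undefined: %d field(s) found", len(coords))
        return np.nan
    centers_cm = (coords + 0.5) * rmap.bin_size
    arena_center = np.array(rmap.shape) * rmap.bin_size / 2.0
    center_dist = np.hypot(*(centers_cm - arena_center).T)
    order = np.argsort(center_dist)[: min(6, len(coords))]

    def pairwise(tri: np.ndarray) -> list[float]:
        return [
            float(np.hypot(*(tri[a] - tri[b]))) for a, b in ((0, 1), (0, 2), (1, 2))
        ]

    # the central triangle: the most central triple of fields that is
    # approximately equilateral.  An adjacent lattice triple has three sides
    # ~lambda; when the arena center falls on a lattice vertex the three
    # nearest fields can include two *non*-adjacent neighbours (side ratio
    # sqrt(3)), so triples that are far from equilateral are skipped.
    from itertools import combinations

    triples = sorted(
        combinations(order, 3), key=lambda s: float(center_dist[list(s)].sum())
    )
    for subset in triples:
        sides = pairwise(centers_cm[list(subset)])
        if max(sides) / min(sides) <= 1.4:
            return float(np.mean(sides))
    return float(np.mean(pairwise(centers_cm[list(triples[0])])))
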