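"""Split-half estimation of within- vs between-cell grid-property variability.

The statistic asks whether the spread of spacing (lambda) and orientation
(theta) seen across cells of one module is a robust feature or mere
estimation noise.  The session timeline is cut into fixed-length bins
(default 30 s) that are randomly assigned, balanced, to two halves A and B;
grid properties are fit on each half for every cell.  Within-cell
variability of cell *i* is ``|prop_A(i) - prop_B(i)|``; between-cell
variability pairs each cell with a random distinct partner *j* and takes
``|prop_A(i) - prop_B(j)|``.  Orientation differences are measured on the
60-degree-periodic circle (so they lie in [0, 30] deg).  The procedure is
repeated over shuffles (default 100), and per-cell means are compared: if
between-cell exceeds within-cell variability, the module's heterogeneity
exceeds what noise alone can explain.

Cells whose half-session SACs fail the hexagonal-geometry inclusion rules on
too many shuffles (default: >= 5%) are deemed unreliable and excluded.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gridfit import fit_grid
from .io_core import AnalysisConfig, Recording
from .ratemaps import compute_rate_map, compute_sac, mask_center

logger = logging.getLogger("gridvar")

__all__ = [
    "VariabilityResult",
    "split_halves",
    "shuffle_analysis",
    "reliability_filter",
    "summarize",
    "angle_diff_60",
]


def angle_diff_60(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute orientation difference on the 60-deg circle, in [0, 30]."""
    d = np.mod(np.asarray(a) - np.asarray(b), 60.0)
    return np.minimum(d, 60.0 - d)


@dataclasses.dataclass
class VariabilityResult:
    """Per-cell split-half variability summary plus run bookkeeping.

    ``per_cell`` columns: unit_id, mean_within_dtheta (deg),
    mean_between_dtheta (deg), mean_within_dlambda (cm),
    mean_between_dlambda (cm), n_poor_fits, n_within, n_between, accepted.
    ``pairings`` records, per shuffle, the between-cell partner of every
    surviving cell (-1 where undefined).
    """

    per_cell: pd.DataFrame
    n_shuffles: int
    split_bin_seconds: float
    max_poor_frac: float
    pairings: np.ndarray  # (n_shuffles, n_cells) partner index or -1
    within_theta: np.ndarray  # (n_shuffles, n_cells) per-shuffle values, NaN if poor
    within_lambda: np.ndarray
    between_theta: np.ndarray
    between_lambda: np.ndarray


def split_halves(
    rec: Recording, bin_seconds: float, rng: np.random.Generator
) -> tuple[Recording, Recording]:
    """Random balanced split of a session into two half-recordings.

    Time is cut into consecutive ``bin_seconds`` bins from the first
    timestamp; an odd trailing bin is dropped (logged).  Each half keeps the
    position samples and spikes of its bins; per-sample dwell times are
    inherited from the full trajectory so gaps between retained segments add
    no occupancy.
    """
    duration = rec.duration
    n_bins = int(np.floor(duration / bin_seconds))
    if n_bins < 2:
        raise ValueError("recording shorter than two split bins")
    if n_bins % 2 == 1:
        logger.info("odd split-bin count %d: dropping the final bin", n_bins)
        n_bins -= 1
    choice = rng.permutation(n_bins)
    bins_a = np.sort(choice[: n_bins // 2])
    bins_b = np.sort(choice[n_bins // 2 :])

    t0 = rec.t[0]
    dt = np.diff(rec.t)
    dwell = np.append(dt, np.median(dt) if dt.size else 0.0)
    sample_bin = np.floor((rec.t - t0) / bin_seconds).astype(int)

    def build(bins: np.ndarray) -> Recording:
        member = np.zeros(n_bins + 1, dtype=bool)
        member[bins] = True
        keep = (sample_bin < n_bins) & member[np.minimum(sample_bin, n_bins)]
        spikes = {}
        for uid, st in rec.spikes.items():
            sb = np.floor((st - t0) / bin_seconds).astype(int)
            ok = (sb >= 0) & (sb < n_bins)
            spikes[uid] = st[ok & member[np.clip(sb, 0, n_bins)]]
        return Recording(
            t=rec.t[keep], x=rec.x[keep], y=rec.y[keep], spikes=spikes,
            arena=rec.arena, module_id=rec.module_id, session_id=rec.session_id,
            sample_dwell=dwell[keep],
        )

    return build(bins_a), build(bins_b)


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed points (n >= 2)."""
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def _fit_half(half: Recording, unit: str, config: AnalysisConfig):
    rmap = compute_rate_map(
        half, unit, config.bin_size_cm, config.ratemap_smooth_sigma_bins
    )
    sac = compute_sac(rmap, min_overlap=config.sac_min_overlap)
    if sac.degenerate:
        return None
    fit = fit_grid(
        mask_center(sac),
        smooth_sigma=config.sac_smooth_sigma_bins,
        threshold=config.peak_threshold,
        compute_score=False,
    )
    return fit if fit.valid else None


def shuffle_analysis(
    rec: Recording,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    units: Sequence[str] | None = None,
) -> VariabilityResult:
    """Run the full split-half resampling analysis on one session.

    Per shuffle the session is split once (one behavioural timeline shared by
    all simultaneously recorded cells).  A cell is *poor* on a shuffle if the
    grid fit on either half fails inclusion; poor cells contribute nothing to
    that shuffle.  Between-cell partners are drawn as a fresh random
    derangement of the surviving cells each shuffle, so no cell is ever
    paired with itself.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    units = list(units) if units is not None else rec.unit_ids
    n_cells = len(units)
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    S = config.n_shuffles
    wt = np.full((S, n_cells), np.nan)
    wl = np.full((S, n_cells), np.nan)
    bt = np.full((S, n_cells), np.nan)
    bl = np.full((S, n_cells), np.nan)
    pairings = np.full((S, n_cells), -1, dtype=int)

    for s in range(S):
        half_a, half_b = split_halves(rec, config.split_bin_seconds, rng)
        theta_a = np.full(n_cells, np.nan)
        theta_b = np.full(n_cells, np.nan)
        lam_a = np.full(n_cells, np.nan)
        lam_b = np.full(n_cells, np.nan)
        for c, uid in enumerate(units):
            fa = _fit_half(half_a, uid, config)
            fb = _fit_half(half_b, uid, config)
            if fa is None or fb is None:
                continue
            theta_a[c], lam_a[c] = fa.orientation, fa.spacing
            theta_b[c], lam_b[c] = fb.orientation, fb.spacing
        alive = np.where(np.isfinite(lam_a) & np.isfinite(lam_b))[0]
        wt[s, alive] = angle_diff_60(theta_a[alive], theta_b[alive])
        wl[s, alive] = np.abs(lam_a[alive] - lam_b[alive])
        if alive.size >= 2:
            partner = alive[_random_derangement(alive.size, rng)]
            pairings[s, alive] = partner
            bt[s, alive] = angle_diff_60(theta_a[alive], theta_b[partner])
            bl[s, alive] = np.abs(lam_a[alive] - lam_b[partner])
        else:
            logger.info("shuffle %d: <2 surviving cells, no between values", s)

    n_poor = np.sum(np.isnan(wl), axis=0)
    import warnings

    with warnings.catch_warnings():
        # cells poor on every shuffle yield all-NaN columns; report NaN means
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_cell = pd.DataFrame(
            {
                "unit_id": units,
                "mean_within_dtheta": np.nanmean(wt, axis=0),
                "mean_between_dtheta": np.nanmean(bt, axis=0),
                "mean_within_dlambda": np.nanmean(wl, axis=0),
                "mean_between_dlambda": np.nanmean(bl, axis=0),
                "n_poor_fits": n_poor,
                "n_within": S - n_poor,
                "n_between": np.sum(np.isfinite(bl), axis=0),
                "accepted": (n_poor / S) < config.reliability_max_poor_frac,
            }
        )
    return VariabilityResult(
        per_cell=per_cell,
        n_shuffles=S,
        split_bin_seconds=config.split_bin_seconds,
        max_poor_frac=config.reliability_max_poor_frac,
        pairings=pairings,
        within_theta=wt,
        within_lambda=wl,
        between_theta=bt,
        between_lambda=bl,
    )


def reliability_filter(
    result: VariabilityResult, max_poor_frac: float | None = None
) -> pd.DataFrame:
    """Accepted-cell subset: poor-fit fraction strictly below the threshold."""
    frac = max_poor_frac if max_poor_frac is not None else result.max_poor_frac
    df = result.per_cell
    accepted = df[(df["n_poor_fits"] / result.n_shuffles) < frac].reset_index(drop=True)
    pct = 100.0 * len(accepted) / len(df) if len(df) else 0.0
    logger.info("reliability filter: %d/%d cells accepted (%.1f%%)", len(accepted), len(df), pct)
    return accepted


def summarize(
    result: VariabilityResult,
    grid_scores: pd.DataFrame | None = None,
    min_cells: int = 5,
) -> dict:
    """Population summary over accepted cells.

    Reports the four population means, the percentage of cells with
    between > within (orientation and spacing separately), and one-sided
    paired Wilcoxon signed-rank p-values for between > within.  When
    ``grid_scores`` (columns unit_id, grid_score) is given, adds OLS
    regressions of within-cell variability on grid score (R^2, Wald p).
    Returns explicit NaNs when fewer than ``min_cells`` cells are accepted.
    """
    acc = reliability_filter(result)
    out: dict = {"n_accepted": int(len(acc)), "n_cells": int(len(result.per_cell))}
    if len(acc) < min_cells:
        for key in (
            "mean_within_dtheta", "mean_between_dtheta", "mean_within_dlambda",
            "mean_between_dlambda", "pct_between_gt_within_theta",
            "pct_between_gt_within_lambda", "wilcoxon_p_theta", "wilcoxon_p_lambda",
        ):
            out[key] = float("nan")
        return out
    for col in (
        "mean_within_dtheta", "mean_between_dtheta",
        "mean_within_dlambda", "mean_between_dlambda",
    ):
        out[col] = float(acc[col].mean())
    for prop, wcol, bcol in (
        ("theta", "mean_within_dtheta", "mean_between_dtheta"),
        ("lambda", "mean_within_dlambda", "mean_between_dlambda"),
    ):
        diff = acc[bcol].to_numpy() - acc[wcol].to_numpy()
        out[f"pct_between_gt_within_{prop}"] = float(100.0 * np.mean(diff > 0))
        if np.allclose(diff, 0.0):
            out[f"wilcoxon_p_{prop}"] = 1.0
        else:
            out[f"wilcoxon_p_{prop}"] = float(
                stats.wilcoxon(diff, alternative="greater").pvalue
            )
    if grid_scores is not None:
        import statsmodels.api as sm

        merged = acc.merge(grid_scores, on="unit_id", how="inner")
        for prop, col in (("theta", "mean_within_dtheta"), ("lambda", "mean_within_dlambda")):
            ols = sm.OLS(
                merged[col].to_numpy(),
                sm.add_constant(merged["grid_score"].to_numpy()),
            ).fit()
            out[f"score_regression_r2_{prop}"] = float(ols.rsquared)
            out[f"score_regression_p_{prop}"] = float(ols.pvalues[1])
    return out
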