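"""Linear template decoding of position from grid-cell population activity.

The decoder is deliberately simple.  Each cell *i* has a template map
``T_i(y)`` (the average of its training rate maps).  Given test activity
``a_i(x)`` at an unknown position ``x``, the decoded position is

    y_hat(x) = argmax_y  sum_i a_i(x) * T_i(y)

i.e. the location whose template population vector has the largest inner
product with the observed activity.  The error at ``x`` is the Euclidean
distance ``|x - y_hat(x)|`` in cm between bin centers.

Experiments: cross-validated decoding of Poisson-noisy synthetic maps
(10 noisy maps per cell, leave-one-out over maps, averaged over 25
independent populations), population-size sweeps, a grid search over the
spacing/orientation variability (sigma_lambda, sigma_theta), two-module
decoding with the empirically motivated sqrt(2) (consecutive) or 2
(module-skipping) spacing ratios, and the matching protocol for recorded
sessions (temporal-bin cross-validation over real rate maps).

Chance level for a square arena of side L is the mean distance between two
independent uniform points, ``c * L`` with ``c = (2 + sqrt(2) +
5*asinh(1)) / 15 ~= 0.5214``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .gridsim import GridCellParams, GridPopulationSpec, ideal_rate_map, sample_population
from .io_core import Recording, derive_rng
from .ratemaps import compute_rate_map

logger = logging.getLogger("gridvar")

__all__ = [
    "DecodingResult",
    "SigmaGrid",
    "chance_error",
    "grid_centers",
    "decode_fold",
    "population_maps",
    "decode_population",
    "population_size_sweep",
    "sigma_grid_search",
    "two_module_decode",
    "decode_recorded",
]


@dataclasses.dataclass
class DecodingResult:
    """Decoding error as a function of population size."""

    population_sizes: np.ndarray
    mean_error: np.ndarray  # cm, mean over positions, folds, populations
    error_sd: np.ndarray  # cm, SD across populations
    per_population: np.ndarray  # (n_populations, n_sizes)
    chance_error: float
    config: dict


@dataclasses.dataclass
class SigmaGrid:
    """Decoding error over a grid of grid-property variability values."""

    sigma_lambda_values: np.ndarray  # cm
    sigma_theta_values: np.ndarray  # deg
    error_matrix: np.ndarray  # (n_sigma_lambda, n_sigma_theta), cm
    config: dict


_UNIFORM_DIST_COEF = (2.0 + np.sqrt(2.0) + 5.0 * np.arcsinh(1.0)) / 15.0


def chance_error(arena_side_cm: float) -> float:
    """Mean distance between two independent uniform points in the square."""
    return float(_UNIFORM_DIST_COEF * arena_side_cm)


def grid_centers(arena: tuple[float, float], resolution: int) -> np.ndarray:
    """(n_bins, 2) bin-center coordinates in cm, row-major over [ix, iy]."""
    lx, ly = arena
    cx = (np.arange(resolution) + 0.5) * (lx / resolution)
    cy = (np.arange(resolution) + 0.5) * (ly / resolution)
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def population_maps(
    cells: Sequence[GridCellParams],
    arena: tuple[float, float],
    resolution: int,
    n_noisy_maps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson-noisy rate maps for a population: shape (n_cells, n_maps, n_bins)."""
    n = len(cells)
    nb = resolution * resolution
    out = np.empty((n, n_noisy_maps, nb), dtype=np.float32)
    for i, p in enumerate(cells):
        ideal = ideal_rate_map(p, arena, resolution).ravel()
        out[i] = rng.poisson(ideal, size=(n_noisy_maps, nb)).astype(np.float32)
    return out


def decode_fold(
    noisy_maps: np.ndarray,
    held_out_index: int,
    centers: np.ndarray,
    shuffle_templates_rng: np.random.Generator | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-position decoding error for one cross-validation fold.

    Templates are the mean of all maps except ``held_out_index``; the held-out
    maps are the test activity.  ``shuffle_templates_rng`` spatially permutes
    each cell's template independently (a chance control that destroys the
    spatial code while preserving per-cell statistics).  ``valid`` restricts
    both the decoded candidates and the evaluated positions.
    """
    n_cells, n_maps, nb = noisy_maps.shape
    if n_maps < 2:
        raise ValueError("need at least 2 maps per cell")
    if centers.shape[0] != nb:
        raise ValueError("map grid and centers disagree")
    sel = np.arange(n_maps) != held_out_index
    templates = noisy_maps[:, sel, :].mean(axis=1)
    if shuffle_templates_rng is not None:
        templates = np.stack(
            [t[shuffle_templates_rng.permutation(nb)] for t in templates]
        )
    test = noisy_maps[:, held_out_index, :]
    return _decode_maps(test, templates, centers, valid=valid)


def _decode_maps(
    test: np.ndarray,
    templates: np.ndarray,
    centers: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Argmax-of-inner-product decoding; returns error per (valid) position."""
    test = np.ascontiguousarray(test, dtype=np.float32)
    templates = np.ascontiguousarray(templates, dtype=np.float32)
    if valid is None:
        scores = test.T @ templates  # (positions, candidates)
        decoded = np.argmax(scores, axis=1)
        return np.linalg.norm(centers - centers[decoded], axis=1)
    vidx = np.where(valid.ravel())[0]
    scores = test[:, vidx].T @ templates[:, vidx]
    decoded = vidx[np.argmax(scores, axis=1)]
    return np.linalg.norm(centers[vidx] - centers[decoded], axis=1)


def decode_population(
    noisy_maps: np.ndarray,
    centers: np.ndarray,
    sizes: Sequence[int] | None = None,
    shuffle_templates_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean decoding error for nested leading subsets of one population.

    The score matrix is a sum over cells, so for sorted ``sizes`` it is
    accumulated block-wise and each fold costs one pass over the largest
    subset.  Returns mean error (cm) per size, averaged over positions and
    all ``n_maps`` leave-one-out folds.
    """
    n_cells, n_maps, nb = noisy_maps.shape
    sizes = [n_cells] if sizes is None else list(sizes)
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    if sizes[-1] > n_cells:
        raise ValueError("subset larger than population")
    errors = np.zeros(len(sizes))
    for fold in range(n_maps):
        sel = np.arange(n_maps) != fold
        templates = noisy_maps[:, sel, :].mean(axis=1, dtype=np.float32)
        if shuffle_templates_rng is not None:
            templates = np.stack(
                [t[shuffle_templates_rng.permutation(nb)] for t in templates]
            )
        test = np.ascontiguousarray(noisy_maps[:, fold, :], dtype=np.float32)
        scores = np.zeros((nb, nb), dtype=np.float32)
        prev = 0
        for k, size in enumerate(sizes):
            blk = slice(prev, size)
            scores += test[blk].T @ np.ascontiguousarray(templates[blk])
            prev = size
            decoded = np.argmax(scores, axis=1)
            errors[k] += np.linalg.norm(centers - centers[decoded], axis=1).mean()
    return errors / n_maps


def population_size_sweep(
    spec: GridPopulationSpec,
    sizes: Sequence[int],
    n_noisy_maps: int = 10,
    n_populations: int = 25,
    resolution: int = 50,
    seed: int = 0,
    shuffle_templates: bool = False,
) -> DecodingResult:
    """Decoding error vs population size, averaged over independent populations.

    Each population draws ``max(sizes)`` cells from *spec* and decodes every
    ascending subset; the reported mean and SD are across the
    ``n_populations`` populations.
    """
    sizes = sorted(int(s) for s in sizes)
    centers = grid_centers(spec.arena, resolution)
    per_pop = np.zeros((n_populations, len(sizes)))
    for p in range(n_populations):
        rng = derive_rng(seed, 1, p)
        pop_spec = dataclasses.replace(spec, n=sizes[-1])
        cells = sample_population(pop_spec, rng)
        maps = population_maps(cells, spec.arena, resolution, n_noisy_maps, rng)
        shuf = derive_rng(seed, 2, p) if shuffle_templates else None
        per_pop[p] = decode_population(maps, centers, sizes, shuffle_templates_rng=shuf)
    return DecodingResult(
        population_sizes=np.array(sizes),
        mean_error=per_pop.mean(axis=0),
        error_sd=per_pop.std(axis=0),
        per_population=per_pop,
        chance_error=chance_error(spec.arena[0]),
        config={
            "spec": dataclasses.asdict(spec), "n_noisy_maps": n_noisy_maps,
            "n_populations": n_populations, "resolution": resolution,
            "seed": seed, "shuffle_templates": shuffle_templates,
        },
    )


def sigma_grid_search(
    lambda_hat: float,
    theta_hat: float,
    sigma_lambda_values: Sequence[float],
    sigma_theta_values: Sequence[float],
    n: int = 1024,
    n_noisy_maps: int = 10,
    n_populations: int = 25,
    resolution: int = 50,
    arena: tuple[float, float] = (150.0, 150.0),
    seed: int = 0,
) -> SigmaGrid:
    """Decoding error over a (sigma_lambda, sigma_theta) grid at fixed N."""
    sl = np.asarray(list(sigma_lambda_values), dtype=float)
    st = np.asarray(list(sigma_theta_values), dtype=float)
    mat = np.zeros((sl.size, st.size))
    for a, sig_l in enumerate(sl):
        for b, sig_t in enumerate(st):
            spec = GridPopulationSpec(
                n=n, lambda_hat=lambda_hat, theta_hat=theta_hat,
                sigma_lambda=float(sig_l), sigma_theta=float(sig_t), arena=arena,
            )
            res = population_size_sweep(
                spec, [n], n_noisy_maps=n_noisy_maps,
                n_populations=n_populations, resolution=resolution,
                seed=int(seed + 1000 * a + b),
            )
            mat[a, b] = res.mean_error[0]
    return SigmaGrid(
        sigma_lambda_values=sl, sigma_theta_values=st, error_matrix=mat,
        config={
            "lambda_hat": lambda_hat, "theta_hat": theta_hat, "n": n,
            "n_noisy_maps": n_noisy_maps, "n_populations": n_populations,
            "resolution": resolution, "seed": seed,
        },
    )


def two_module_decode(
    spec1: GridPopulationSpec,
    relation: str,
    sizes: Sequence[int],
    orientation_offset_deg: float = 15.0,
    second_module_fraction: float = 0.5,
    n_noisy_maps: int = 10,
    n_populations: int = 25,
    resolution: int = 50,
    seed: int = 0,
) -> DecodingResult:
    """Joint decoding from two modules with the empirical spacing relation.

    ``relation='consecutive'`` sets the second module's mean spacing to
    ``sqrt(2) * lambda_hat1`` (adjacent modules); ``relation='skip'`` sets it
    to ``2 * lambda_hat1`` (modules two apart), where the larger module's
    lattice nests inside the smaller one's up to the orientation offset.
    Cell membership follows ``second_module_fraction`` (default an even
    split) and is interleaved so nested subsets stay balanced; a fraction of
    0 reduces exactly to single-module decoding of module 1.
    """
    if relation not in ("consecutive", "skip"):
        raise ValueError("relation must be 'consecutive' or 'skip'")
    if not 0.0 <= second_module_fraction <= 1.0:
        raise ValueError("second_module_fraction must lie in [0, 1]")
    ratio = np.sqrt(2.0) if relation == "consecutive" else 2.0
    spec2 = dataclasses.replace(
        spec1,
        lambda_hat=ratio * spec1.lambda_hat,
        theta_hat=spec1.theta_hat + orientation_offset_deg,
    )
    sizes = sorted(int(s) for s in sizes)
    centers = grid_centers(spec1.arena, resolution)
    per_pop = np.zeros((n_populations, len(sizes)))
    n_total = sizes[-1]
    # balanced interleaving: cell i belongs to module 2 iff the cumulative
    # fraction crosses an integer at i
    cum = np.floor((np.arange(n_total) + 1) * second_module_fraction)
    is_m2 = np.diff(np.r_[0.0, cum]).astype(bool)
    n2 = int(is_m2.sum())
    for p in range(n_populations):
        rng = derive_rng(seed, 3, p)
        cells1 = iter(sample_population(dataclasses.replace(spec1, n=n_total - n2), rng))
        cells2 = iter(sample_population(dataclasses.replace(spec2, n=n2), rng))
        interleaved = [next(cells2) if m2 else next(cells1) for m2 in is_m2]
        maps = population_maps(interleaved, spec1.arena, resolution, n_noisy_maps, rng)
        per_pop[p] = decode_population(maps, centers, sizes)
    return DecodingResult(
        population_sizes=np.array(sizes),
        mean_error=per_pop.mean(axis=0),
        error_sd=per_pop.std(axis=0),
        per_population=per_pop,
        chance_error=chance_error(spec1.arena[0]),
        config={
            "relation": relation, "ratio": float(ratio),
            "orientation_offset_deg": orientation_offset_deg,
            "second_module_fraction": second_module_fraction,
            "spec1": dataclasses.asdict(spec1), "n_noisy_maps": n_noisy_maps,
            "n_populations": n_populations, "resolution": resolution, "seed": seed,
        },
    )


def _time_bin_maps(
    rec: Recording,
    units: Sequence[str],
    n_time_bins: int,
    resolution: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell rate maps for contiguous temporal tenths of a session.

    Returns ``(maps, visited)`` with maps of shape (n_cells, n_time_bins,
    n_bins); per-cell maps are max-normalized; unvisited bins are zero.
    ``visited`` is the full-session visited mask at decoding resolution.
    """
    lx, ly = rec.arena
    bin_size = lx / resolution
    t0, t1 = rec.t[0], rec.t[-1]
    edges = np.linspace(t0, t1, n_time_bins + 1)
    dt = np.diff(rec.t)
    dwell = np.append(dt, np.median(dt) if dt.size else 0.0)
    nb = resolution * resolution
    maps = np.zeros((len(units), n_time_bins, nb), dtype=np.float32)
    full_occ = None
    for k in range(n_time_bins):
        lo, hi = edges[k], edges[k + 1]
        keep = (rec.t >= lo) & (rec.t < hi if k < n_time_bins - 1 else rec.t <= hi)
        sub = Recording(
            t=rec.t[keep], x=rec.x[keep], y=rec.y[keep],
            spikes={
                u: rec.spikes[u][(rec.spikes[u] >= lo) & (rec.spikes[u] < hi)]
                for u in units
            },
            arena=rec.arena, sample_dwell=dwell[keep],
        )
        for c, u in enumerate(units):
            rmap = compute_rate_map(sub, u, bin_size, smooth_sigma_bins=1.0)
            vals = np.where(np.isfinite(rmap.values), rmap.values, 0.0)
            maps[c, k] = vals.ravel()
        occ = compute_rate_map(sub, units[0], bin_size, 0.0).occupancy
        full_occ = occ if full_occ is None else full_occ + occ
    peak = maps.reshape(len(units), -1).max(axis=1)
    peak[peak <= 0] = 1.0
    maps /= peak[:, None, None]
    visited = (full_occ > 0).ravel()
    return maps, visited


def decode_recorded(
    rec: Recording,
    subpop_sizes: Sequence[int] = (1, 2, 4, 8, 16, 32, 64),
    units: Sequence[str] | None = None,
    n_time_bins: int = 10,
    n_splits: int = 10,
    n_subpops: int = 25,
    resolution: int = 50,
    seed: int = 0,
) -> DecodingResult:
    """Template decoding of a recorded (or simulated) session.

    The session is cut into ``n_time_bins`` contiguous temporal bins with one
    max-normalized rate map per cell per bin.  Each split draws half the bins
    as training (template = their mean map) and tests on the mean of the
    rest; errors average over visited bins, splits, and random
    subpopulations.  Sizes beyond the available cell count are capped (with
    a warning).
    """
    units = list(units) if units is not None else rec.unit_ids
    sizes = sorted(int(s) for s in subpop_sizes)
    if sizes[-1] > len(units):
        logger.warning(
            "subpopulation size %d exceeds %d available cells; capping",
            sizes[-1], len(units),
        )
        sizes = sorted({min(s, len(units)) for s in sizes})
    maps, visited = _time_bin_maps(rec, units, n_time_bins, resolution)
    centers = grid_centers(rec.arena, resolution)
    per_subpop = np.zeros((n_subpops, len(sizes)))
    for sp in range(n_subpops):
        rng = derive_rng(seed, 4, sp)
        order = rng.permutation(len(units))
        split_errs = np.zeros(len(sizes))
        for s in range(n_splits):
            train = rng.choice(n_time_bins, size=n_time_bins // 2, replace=False)
            test_bins = np.setdiff1d(np.arange(n_time_bins), train)
            templates = maps[:, train, :].mean(axis=1)
            testmap = maps[:, test_bins, :].mean(axis=1)
            for k, size in enumerate(sizes):
                idx = order[:size]
                errs = _decode_maps(testmap[idx], templates[idx], centers, valid=visited)
                split_errs[k] += errs.mean()
        per_subpop[sp] = split_errs / n_splits
    return DecodingResult(
        population_sizes=np.array(sizes),
        mean_error=per_subpop.mean(axis=0),
        error_sd=per_subpop.std(axis=0),
        per_population=per_subpop,
        chance_error=chance_error(rec.arena[0]),
        config={
            "n_time_bins": n_time_bins, "n_splits": n_splits,
            "n_subpops": n_subpops, "resolution": resolution, "seed": seed,
        },
    )
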