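"""Synthetic grid-cell populations, rate maps, trajectories, and spike trains.

The ideal grid response is the classic three-plane-wave construction: the
rate of cell *i* at centered position ``x`` is

    X(x) = Xmax * (2/3) * [ (1/3) * sum_j cos(k_j . (x + phi)) + 1/2 ]

with the three wave vectors ``k_j`` at 60 deg angular separations and common
magnitude ``|k| = 4*pi / (sqrt(3) * lambda)``, which places the nearest-
neighbour firing-field distance exactly at the grid spacing ``lambda``.  The
rate is bounded in ``[0, Xmax]``, reaching ``Xmax`` on the lattice and 0 at
the deepest troughs.

Populations draw per-cell spacing and orientation from Gaussians
``lambda ~ N(lambda_hat, sigma_lambda)``, ``theta ~ N(theta_hat, sigma_theta)``
(SDs, not variances), phases uniformly over the arena, and peak rates from
``N(13, 8)`` Hz saturated into [2, 30] Hz — the regime of a large open-field
medial entorhinal cortex module.  Defaults mirror that module:
``lambda_hat = 85 cm``, ``theta_hat = 6 deg``, ``sigma_lambda = 5 cm``,
``sigma_theta = 1 deg`` in a 1.5 m x 1.5 m arena.

Full synthetic recordings combine a smooth random foraging trajectory with
inhomogeneous-Poisson spike trains generated by thinning, producing session
directories identical in structure to recorded data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_core import Recording

logger = logging.getLogger("gridvar")

__all__ = [
    "GridPopulationSpec",
    "GridCellParams",
    "sample_population",
    "ideal_rate",
    "ideal_rate_map",
    "poisson_noisy_map",
    "simulate_trajectory",
    "generate_spikes",
    "make_synthetic_session",
]

SQRT3 = np.sqrt(3.0)


@dataclasses.dataclass
class GridPopulationSpec:
    """Distributional description of one synthetic grid module."""

    n: int
    lambda_hat: float = 85.0  # cm
    theta_hat: float = 6.0  # deg
    sigma_lambda: float = 5.0  # cm (SD)
    sigma_theta: float = 1.0  # deg (SD)
    arena: tuple[float, float] = (150.0, 150.0)  # cm
    xmax_mean: float = 13.0  # Hz
    xmax_sd: float = 8.0  # Hz
    xmax_clip: tuple[float, float] = (2.0, 30.0)  # Hz

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.lambda_hat <= 0:
            raise ValueError("lambda_hat must be positive")
        if self.sigma_lambda < 0 or self.sigma_theta < 0:
            raise ValueError("sigmas must be >= 0")
        if self.xmax_clip[0] > self.xmax_clip[1]:
            raise ValueError("xmax_clip bounds out of order")


@dataclasses.dataclass
class GridCellParams:
    """Ground-truth parameters of a single synthetic grid cell."""

    lam: float  # spacing, cm
    theta: float  # orientation, deg
    phase: tuple[float, float]  # cm offsets
    xmax: float  # peak rate, Hz


def sample_population(
    spec: GridPopulationSpec, rng: np.random.Generator
) -> list[GridCellParams]:
    """Draw per-cell (lambda, theta, phase, xmax) for a module.

    Spacing draws <= 0 (possible only for extreme ``sigma_lambda``) are
    redrawn and logged.  Peak rates are saturated at the clip bounds rather
    than redrawn, leaving point masses at 2 and 30 Hz.
    """
    lx, ly = spec.arena
    lam = rng.normal(spec.lambda_hat, spec.sigma_lambda, size=spec.n)
    n_redraw = 0
    while np.any(lam <= 0):
        bad = lam <= 0
        n_redraw += int(bad.sum())
        lam[bad] = rng.normal(spec.lambda_hat, spec.sigma_lambda, size=int(bad.sum()))
    if n_redraw:
        logger.warning("redrew %d non-positive spacing draws", n_redraw)
    theta = rng.normal(spec.theta_hat, spec.sigma_theta, size=spec.n)
    phase_x = rng.uniform(0.0, lx, size=spec.n)
    phase_y = rng.uniform(0.0, ly, size=spec.n)
    xmax = np.clip(rng.normal(spec.xmax_mean, spec.xmax_sd, size=spec.n), *spec.xmax_clip)
    return [
        GridCellParams(float(lam[i]), float(theta[i]), (float(phase_x[i]), float(phase_y[i])), float(xmax[i]))
        for i in range(spec.n)
    ]


def _wave_vectors(lam: float, theta_deg: float) -> np.ndarray:
    """Three wave vectors (3, 2) at 60 deg separations for spacing lam."""
    k = 4.0 * np.pi / (SQRT3 * lam)
    ang = np.deg2rad(theta_deg) + np.deg2rad([30.0, 90.0, 150.0])
    return k * np.column_stack([np.cos(ang), np.sin(ang)])


def ideal_rate(
    params: GridCellParams,
    x: np.ndarray,
    y: np.ndarray,
    arena: tuple[float, float],
) -> np.ndarray:
    """Noiseless firing rate (Hz) at corner-origin positions (x, y) in cm."""
    lx, ly = arena
    xc = np.asarray(x, dtype=float) - lx / 2.0
    yc = np.asarray(y, dtype=float) - ly / 2.0
    kv = _wave_vectors(params.lam, params.theta)
    px, py = params.phase
    acc = np.zeros_like(xc, dtype=float)
    for j in range(3):
        acc += np.cos(kv[j, 0] * (xc + px) + kv[j, 1] * (yc + py))
    return params.xmax * (2.0 / 3.0) * (acc / 3.0 + 0.5)


def _bin_centers(length: float, n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * (length / n_bins)


def ideal_rate_map(
    params: GridCellParams,
    arena: tuple[float, float],
    n_bins: int | tuple[int, int],
) -> np.ndarray:
    """Noiseless rate map sampled at bin centers; shape (nx, ny), index [ix, iy]."""
    if np.isscalar(n_bins):
        n_bins = (int(n_bins), int(n_bins))
    lx, ly = arena
    cx = _bin_centers(lx, n_bins[0])
    cy = _bin_centers(ly, n_bins[1])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    return ideal_rate(params, gx, gy, arena)


def poisson_noisy_map(
    ideal: np.ndarray, rng: np.random.Generator, dwell: float = 1.0
) -> np.ndarray:
    """Independent Poisson counts per bin with mean ``ideal * dwell``."""
    if np.any(np.asarray(ideal) < 0):
        raise ValueError("ideal rates must be >= 0")
    return rng.poisson(np.asarray(ideal, dtype=float) * dwell).astype(float)


def _fold(p: np.ndarray, length: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [0, length] (billiard walls)."""
    m = np.mod(p, 2.0 * length)
    return length - np.abs(m - length)


def simulate_trajectory(
    duration_s: float,
    dt_s: float = 0.02,
    arena: tuple[float, float] = (150.0, 150.0),
    mean_speed_cm_s: float = 15.0,
    speed_tau_s: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth random foraging path with reflective walls.

    Velocity components follow an Ornstein-Uhlenbeck process whose stationary
    SD is set so the mean (Rayleigh) speed equals ``mean_speed_cm_s``; the
    free path is then folded into the arena, which is equivalent to specular
    reflection at the walls.  Returns ``(t, x, y)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n = int(np.floor(duration_s / dt_s)) + 1
    alpha = np.exp(-dt_s / speed_tau_s)
    sigma_stat = mean_speed_cm_s / np.sqrt(np.pi / 2.0)
    sigma_step = sigma_stat * np.sqrt(1.0 - alpha**2)
    # AR(1) velocity via a linear filter over the innovation sequence
    eps = rng.normal(0.0, sigma_step, size=(n, 2))
    eps[0] = rng.normal(0.0, sigma_stat, size=2)
    from scipy.signal import lfilter

    v = lfilter([1.0], [1.0, -alpha], eps, axis=0)
    free = np.cumsum(v * dt_s, axis=0)
    lx, ly = arena
    x0 = rng.uniform(0.2 * lx, 0.8 * lx)
    y0 = rng.uniform(0.2 * ly, 0.8 * ly)
    x = _fold(x0 + free[:, 0], lx)
    y = _fold(y0 + free[:, 1], ly)
    t = np.arange(n) * dt_s
    return t, x, y


def generate_spikes(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    params: GridCellParams,
    arena: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning at rate ``X(x(t))``.

    Candidate events are drawn from a homogeneous Poisson process at the
    cell's peak rate and accepted with probability ``X(x(t)) / Xmax``; the
    position at a candidate time is linearly interpolated.
    """
    span = float(t[-1] - t[0])
    if params.xmax <= 0:
        return np.empty(0)
    n_cand = rng.poisson(params.xmax * span)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t[0], t[-1], size=n_cand))
    cx = np.interp(cand, t, x)
    cy = np.interp(cand, t, y)
    rate = ideal_rate(params, cx, cy, arena)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate / params.xmax
    return cand[keep]


def make_synthetic_session(
    spec: GridPopulationSpec,
    duration_s: float,
    rng: np.random.Generator,
    dt_s: float = 0.02,
    session_id: str = "synthetic",
    module_id: str = "M1",
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one full session: trajectory + spikes for every cell in *spec*.

    Returns the :class:`~gridvar.io_core.Recording` and a ground-truth table of
    per-cell ``(lambda, theta, phase_x, phase_y, xmax)`` for recovery tests.
    """
    cells = sample_population(spec, rng)
    t, x, y = simulate_trajectory(duration_s, dt_s=dt_s, arena=spec.arena, rng=rng)
    spikes: dict[str, np.ndarray] = {}
    rows = []
    for i, params in enumerate(cells):
        uid = f"cell_{i:03d}"
        spikes[uid] = generate_spikes(t, x, y, params, spec.arena, rng)
        rows.append(
            {
                "unit_id": uid,
                "lambda_cm": params.lam,
                "theta_deg": params.theta,
                "phase_x_cm": params.phase[0],
                "phase_y_cm": params.phase[1],
                "xmax_hz": params.xmax,
                "n_spikes": spikes[uid].size,
            }
        )
    rec = Recording(
        t=t, x=x, y=y, spikes=spikes, arena=spec.arena,
        module_id=module_id, session_id=session_id,
    ).validate()
    return rec, pd.DataFrame(rows)
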