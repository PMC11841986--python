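"""Data model, on-disk session layout, configuration, and RNG plumbing.

A *session* is one continuous open-field recording: a sampled 2D trajectory
plus a list of point-process spike trains (one per unit), all sharing a common
clock, together with the arena geometry and an opaque module label.  On disk a
session is a flat directory::

    session_dir/
      positions.csv        # columns t,x,y  (seconds, cm, cm)
      spikes/<unit_id>.csv # single column t (seconds), one file per unit
      meta.json            # arena_cm [Lx, Ly], module_id, session_id, unit order

The layout is deliberately diff-able and trivially writable both by the
synthetic generator and by converters for externally deposited data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

logger = logging.getLogger("gridvar")

__all__ = [
    "Recording",
    "AnalysisConfig",
    "LoadError",
    "ValidationError",
    "load_recording",
    "save_recording",
    "save_results",
    "load_config",
    "derive_rng",
]


class LoadError(RuntimeError):
    """A session directory is missing a required component."""


class ValidationError(ValueError):
    """A recording violates a structural invariant."""


@dataclasses.dataclass
class Recording:
    """One session: trajectory, spike trains, arena, labels.

    Parameters
    ----------
    t, x, y
        Position samples. ``t`` in seconds (strictly increasing), ``x``/``y``
        in cm with the origin at the arena corner, so ``0 <= x <= Lx``.
    spikes
        Mapping unit_id -> sorted spike times (seconds).  Insertion order is
        the unit order and is preserved by all loaders and savers.
    arena
        ``(Lx, Ly)`` side lengths in cm.
    sample_dwell
        Optional per-sample dwell times (seconds).  When absent, dwell is
        derived from inter-sample intervals; time-restricted recordings (see
        :func:`gridvar.variability.split_halves`) carry their dwell explicitly
        so that gaps between retained segments are not counted as occupancy.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spikes: dict[str, np.ndarray]
    arena: tuple[float, float]
    module_id: str = ""
    session_id: str = ""
    sample_dwell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.spikes = {str(k): np.asarray(v, dtype=float) for k, v in self.spikes.items()}

    @property
    def unit_ids(self) -> list[str]:
        return list(self.spikes.keys())

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        """Total trajectory span in seconds."""
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def validate(self) -> "Recording":
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        if self.t.size == 0:
            raise ValidationError("empty trajectory")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError("t/x/y length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("position timestamps must be strictly increasing")
        lx, ly = self.arena
        tol = 1e-9
        if (
            np.any(self.x < -tol)
            or np.any(self.x > lx + tol)
            or np.any(self.y < -tol)
            or np.any(self.y > ly + tol)
        ):
            raise ValidationError("positions outside the arena")
        t0, t1 = self.t[0], self.t[-1]
        for uid, st in self.spikes.items():
            if st.size == 0:
                logger.info("unit %s has zero spikes", uid)
                continue
            if np.any(np.diff(st) < 0):
                raise ValidationError(f"unit {uid}: spike times not sorted")
            if st[0] < t0 - tol or st[-1] > t1 + tol:
                raise ValidationError(f"unit {uid}: spikes outside trajectory span")
        return self


@dataclasses.dataclass
class AnalysisConfig:
    """Pipeline parameters with the defaults used throughout.

    All spatial quantities are in cm, temporal in seconds, angles in degrees.
    """

    bin_size_cm: float = 3.0
    ratemap_smooth_sigma_bins: float = 1.0
    sac_smooth_sigma_bins: float = 1.0
    ratemap_spacing_smooth_sigma_bins: float = 1.5
    sac_min_overlap: int = 20
    peak_threshold: float = 0.1
    split_bin_seconds: float = 30.0
    n_shuffles: int = 100
    reliability_max_poor_frac: float = 0.05
    grid_score_threshold: float = 0.85
    rng_seed: int = 0
    # decoder settings
    n_noisy_maps: int = 10
    n_populations: int = 25
    resolution: int = 50

    def __post_init__(self) -> None:
        for name in (
            "bin_size_cm",
            "split_bin_seconds",
            "n_shuffles",
            "n_noisy_maps",
            "n_populations",
            "resolution",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.reliability_max_poor_frac < 1.0:
            raise ValueError("reliability_max_poor_frac must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return AnalysisConfig(**data)


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent RNG stream from a global seed and integer keys.

    Streams are spawned via :class:`numpy.random.SeedSequence` with the keys
    appended to the entropy, so ``derive_rng(seed, 3, 7)`` is reproducible in
    isolation and statistically independent of any other key path.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# ---------------------------------------------------------------------------
# session directory I/O


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a session directory in the documented flat layout."""
    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)
    arr = np.column_stack([rec.t, rec.x, rec.y])
    header = "t,x,y"
    np.savetxt(path / "positions.csv", arr, delimiter=",", header=header, comments="", fmt="%.10g")
    for uid, st in rec.spikes.items():
        np.savetxt(path / "spikes" / f"{uid}.csv", st, header="t", comments="", fmt="%.10g")
    meta = {
        "arena_cm": [rec.arena[0], rec.arena[1]],
        "module_id": rec.module_id,
        "session_id": rec.session_id,
        "unit_ids": rec.unit_ids,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_recording(path: str | Path) -> Recording:
    """Load and validate a session directory.

    Units are returned in the order listed in ``meta.json``; units with zero
    spikes are retained (and logged), never dropped.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    pos_path = path / "positions.csv"
    if not meta_path.is_file():
        raise LoadError(f"missing meta.json in {path}")
    if not pos_path.is_file():
        raise LoadError(f"missing positions.csv in {path}")
    meta = json.loads(meta_path.read_text())
    pos = np.loadtxt(pos_path, delimiter=",", skiprows=1, ndmin=2)
    spikes: dict[str, np.ndarray] = {}
    for uid in meta["unit_ids"]:
        spath = path / "spikes" / f"{uid}.csv"
        if not spath.is_file():
            raise LoadError(f"missing spike file for unit {uid}: {spath}")
        import warnings

        with warnings.catch_warnings():
            # a zero-spike unit is a legitimate header-only file
            warnings.simplefilter("ignore", category=UserWarning)
            st = np.loadtxt(spath, skiprows=1, ndmin=1)
        spikes[str(uid)] = st
    rec = Recording(
        t=pos[:, 0],
        x=pos[:, 1],
        y=pos[:, 2],
        spikes=spikes,
        arena=(float(meta["arena_cm"][0]), float(meta["arena_cm"][1])),
        module_id=str(meta.get("module_id", "")),
        session_id=str(meta.get("session_id", "")),
    )
    return rec.validate()


def save_results(
    tables: Mapping[str, "pandas.DataFrame"],  # noqa: F821 - forward ref
    path: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    extra_meta: Mapping | None = None,
) -> None:
    """Write result tables as CSV plus a JSON run-metadata sidecar.

    Each entry of *tables* becomes ``<name>.csv`` (full float precision so a
    re-read reproduces values to >= 12 significant digits); ``run_meta.json``
    records the config, the seed, and the package version for exact reruns.
    """
    from . import __version__

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.17g")
    sidecar = {
        "package_version": __version__,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
    }
    if extra_meta:
        sidecar.update(extra_meta)
    (path / "run_meta.json").write_text(json.dumps(sidecar, indent=2, default=str))
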