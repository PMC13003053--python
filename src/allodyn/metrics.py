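"""Extension, RMSD, RMSF, per-residue displacement, and convergence
diagnostics (block averaging, percentile bootstrap, RMSF window differences).

All lengths are nm, all times ns.  The extension observable is measured in
the pulling frame (no superposition): it is the displacement along the
pulling axis of the ligand-binding-site group centroid relative to the
transmembrane reference group, zeroed at frame 0.  RMSD/RMSF use uniform
Cα weights and, by default, Kabsch superposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import EmptyInputError, MetricError, SelectionError
from .io import Trajectory, kabsch, superpose, superpose_to_mean


@dataclasses.dataclass
class MetricSeries:
    """A per-frame scalar observable (nm) with its time base (ns)."""

    times: np.ndarray
    values: np.ndarray
    name: str
    condition: str | None = None
    replica: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")


@dataclasses.dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    level: float
    n_resamples: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclasses.dataclass
class BlockStats:
    block_length: float  # ns
    block_means: np.ndarray
    sem: float

    @property
    def n_blocks(self) -> int:
        return len(self.block_means)


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: np.ndarray,
    fit: bool = True,
    condition: str | None = None,
) -> MetricSeries:
    """Per-frame Cα RMSD (nm) with respect to a reference conformation.

    With ``fit`` (default) each frame is Kabsch-superposed onto the
    reference first; ``fit=False`` gives the lab-frame RMSD, relevant when
    the pulling-induced rigid displacement is itself of interest.
    """
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != (trajectory.n_residues, 3):
        raise MetricError("reference residue set does not match trajectory")
    coords = trajectory.coords
    if fit:
        coords = superpose(trajectory, ref).coords
    disp = coords - ref[None]
    values = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=1))
    return MetricSeries(
        trajectory.times, values, "rmsd",
        condition=condition or trajectory.condition, replica=trajectory.replica,
    )


def rmsf_profile(trajectory: Trajectory, fit: bool = True) -> np.ndarray:
    """Per-residue RMSF (nm) about the mean structure.

    Frames are superposed onto the trajectory mean first (two-pass fit), so
    the fluctuation is internal motion, not rigid-body drift.
    RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²).
    """
    if trajectory.n_frames < 2:
        raise MetricError("RMSF undefined for a single frame")
    traj = superpose_to_mean(trajectory) if fit else trajectory
    mean = traj.coords.mean(axis=0)
    disp2 = np.sum((traj.coords - mean[None]) ** 2, axis=2)
    return np.sqrt(disp2.mean(axis=0))


def average_rmsf(trajectory: Trajectory) -> float:
    """Mean of the per-residue RMSF profile over all residues (nm)."""
    return float(rmsf_profile(trajectory).mean())


def per_residue_displacement(
    first_frame: np.ndarray, last_frame: np.ndarray, fit: bool = True
) -> np.ndarray:
    """Per-residue distance (nm) between two conformations.

    With ``fit`` the final conformation is superposed onto the initial one
    before measuring, so rigid-body motion does not count as displacement.
    """
    a = np.asarray(first_frame, dtype=float)
    b = np.asarray(last_frame, dtype=float)
    if a.shape != b.shape:
        raise MetricError("conformations have different residue sets")
    if fit:
        r, t = kabsch(b, a)
        b = b @ r.T + t
    return np.sqrt(np.sum((b - a) ** 2, axis=1))


def extension_series(
    trajectory: Trajectory,
    pull_group: np.ndarray,
    ref_group: np.ndarray,
    axis: np.ndarray = (0.0, 0.0, 1.0),
) -> MetricSeries:
    """Extension e(t) along the pulling axis, zeroed at frame 0 (nm).

    e(t) = [centroid(pull) − centroid(ref)] · axis  −  (same at t=0).
    Centroids are uniform-weight Cα centroids; no superposition is applied
    (the observable lives in the pulling frame, where the reference group
    mimics membrane confinement).
    """
    pull = np.asarray(pull_group, dtype=int)
    ref = np.asarray(ref_group, dtype=int)
    if pull.size == 0 or ref.size == 0:
        raise SelectionError("pull and reference groups must be non-empty")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    sep = trajectory.coords[:, pull].mean(axis=1) - trajectory.coords[:, ref].mean(axis=1)
    proj = sep @ axis
    return MetricSeries(
        trajectory.times, proj - proj[0], "extension",
        condition=trajectory.condition, replica=trajectory.replica,
    )


def block_means(series: MetricSeries, block_length: float) -> BlockStats:
    """Consecutive-block means and their SEM, a convergence diagnostic.

    ``block_length`` is in ns; the trailing partial block is discarded.
    SEM = sd(block means, ddof=1) / sqrt(n_blocks); a plateau of the SEM as
    the block length grows signals converged sampling.
    """
    if len(series.times) < 2:
        raise MetricError("series too short for block analysis")
    dt = float(np.diff(series.times).mean())
    per_block = int(round(block_length / dt))
    if per_block < 1:
        raise MetricError("block length shorter than one frame")
    n_blocks = len(series.values) // per_block
    if n_blocks < 1:
        raise MetricError("block length exceeds series duration")
    trimmed = series.values[: n_blocks * per_block]
    means = trimmed.reshape(n_blocks, per_block).mean(axis=1)
    sem = 0.0 if n_blocks < 2 else float(np.std(means, ddof=1) / np.sqrt(n_blocks))
    return BlockStats(block_length=block_length, block_means=means, sem=sem)


def bootstrap_ci(
    values: np.ndarray,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI of the mean (2.5th/97.5th at level 0.95).

    ``n_resamples`` samples of the same size are drawn with replacement;
    the CI is read off the percentiles of the resampled-mean distribution.
    Deterministic for a fixed ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise MetricError("need at least 2 values to bootstrap")
    if n_resamples < 1:
        raise MetricError("n_resamples must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        point=float(values.mean()), lower=float(lo), upper=float(hi),
        level=level, n_resamples=n_resamples, seed=seed,
    )


def bootstrap_ci_pooled(
    replica_values: list[np.ndarray],
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Pooled-replica bootstrap: resample within each replica, then combine
    all resampled means into a single distribution before taking the
    percentile CI.  The point estimate is the grand mean of all values.
    """
    if not replica_values:
        raise EmptyInputError("no replicas supplied")
    rng = np.random.default_rng(seed)
    pooled = []
    for vals in replica_values:
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise MetricError("each replica needs at least 2 values")
        idx = rng.integers(0, vals.size, size=(n_resamples, vals.size))
        pooled.append(vals[idx].mean(axis=1))
    dist = np.concatenate(pooled)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(dist, [100 * alpha, 100 * (1 - alpha)])
    grand = float(np.concatenate([np.asarray(v, float) for v in replica_values]).mean())
    return BootstrapCI(point=grand, lower=float(lo), upper=float(hi),
                       level=level, n_resamples=n_resamples, seed=seed)


def rmsf_window_differences(
    trajectory: Trajectory, window_length: float = 10.0
) -> dict[str, np.ndarray]:
    """Per-residue |ΔRMSF| between successive equal-length time windows.

    The trajectory is cut into consecutive ``window_length``-ns windows
    (trailing partial window discarded); RMSF is computed independently per
    window, each window superposed to its own mean.  Differences are taken
    between non-overlapping successive pairs — (w1 vs w2), (w3 vs w4), … —
    so a shrinking difference distribution from early to late pairs
    indicates converged residue fluctuations.
    """
    if trajectory.n_frames < 2:
        raise MetricError("trajectory too short")
    dt = float(np.diff(trajectory.times).mean())
    per_window = int(round(window_length / dt))
    if per_window < 2:
        raise MetricError("window shorter than two frames")
    n_windows = trajectory.n_frames // per_window
    if n_windows < 2:
        raise MetricError("need at least two full windows")
    profiles = []
    for w in range(n_windows):
        sub = trajectory.slice_frames(w * per_window, (w + 1) * per_window)
        profiles.append(rmsf_profile(sub))
    diffs = {}
    for w in range(0, n_windows - 1, 2):
        diffs[f"w{w + 1}_vs_w{w + 2}"] = np.abs(profiles[w + 1] - profiles[w])
    return diffs
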