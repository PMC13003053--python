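"""Principal component analysis of Cα coordinate covariance: dominant
modes, porcupine vector fields, and domain centre-of-geometry displacement.

PCA is computed on superposed coordinates by default; without superposition
a rigid drift (e.g. pulling-driven extension) dominates the first mode,
which is sometimes the point — a flag disables the fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import MetricError, SelectionError
from .io import DomainMap, Trajectory, superpose_to_mean


@dataclasses.dataclass
class ModeSet:
    """Top-k eigenpairs of the 3n × 3n coordinate covariance."""

    eigenvalues: np.ndarray  # nm², descending
    eigenvectors: np.ndarray  # (k, 3n), unit norm rows
    mean_structure: np.ndarray  # (n, 3) nm
    total_variance: float  # trace of the covariance, nm²

    @property
    def explained_variance(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    @property
    def n_residues(self) -> int:
        return self.mean_structure.shape[0]


@dataclasses.dataclass
class PorcupineField:
    """Per-residue arrows depicting one mode's direction and amplitude."""

    vectors: np.ndarray  # (n, 3) nm, scaled
    mode_index: int
    scale: float
    base: np.ndarray  # (n, 3) arrow anchor points (mean structure)


def coordinate_covariance(trajectory: Trajectory, superpose: bool = True) -> np.ndarray:
    """3n × 3n covariance (nm²) of Cα coordinates about the mean.

    Sample covariance (ddof=1) of the flattened coordinates after the
    two-pass fit to the trajectory mean.
    """
    if trajectory.n_frames < 2:
        raise MetricError("covariance undefined for a single frame")
    traj = superpose_to_mean(trajectory) if superpose else trajectory
    x = traj.coords.reshape(traj.n_frames, -1)
    return np.cov(x, rowvar=False, ddof=1)


def principal_modes(
    covariance: np.ndarray,
    k: int,
    orient: np.ndarray | None = None,
) -> "ModeSet":
    """Top-k eigenpairs of a symmetric PSD covariance, descending.

    The sign of each eigenvector is fixed deterministically: non-negative
    projection onto ``orient`` (typically the last-minus-first-frame
    displacement) when given; a zero or absent projection falls back to
    making the first nonzero component positive.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if not (1 <= k <= cov.shape[0]):
        raise ValueError(f"k must be in [1, {cov.shape[0]}]")
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    eigvals = w[order]
    if eigvals.min() < -1e-10 * max(1.0, abs(w).max()):
        raise ValueError("covariance is not positive semi-definite")
    eigvals = np.clip(eigvals, 0.0, None)
    vecs = v[:, order].T.copy()
    for m in range(k):
        proj = 0.0 if orient is None else float(vecs[m] @ np.asarray(orient, float).ravel())
        if proj < 0:
            vecs[m] = -vecs[m]
        elif proj == 0.0:
            nz = np.nonzero(vecs[m])[0]
            if nz.size and vecs[m][nz[0]] < 0:
                vecs[m] = -vecs[m]
    n3 = cov.shape[0]
    return ModeSet(
        eigenvalues=eigvals,
        eigenvectors=vecs,
        mean_structure=np.zeros((n3 // 3, 3)),
        total_variance=float(np.trace(cov)),
    )


def trajectory_modes(trajectory: Trajectory, k: int = 3, superpose: bool = True) -> ModeSet:
    """Convenience wrapper: covariance + modes, oriented along the net
    first-to-last frame displacement, with the mean structure attached."""
    traj = superpose_to_mean(trajectory) if superpose else trajectory
    cov = coordinate_covariance(traj, superpose=False)
    orient = (traj.coords[-1] - traj.coords[0]).ravel()
    modes = principal_modes(cov, k, orient=orient)
    modes.mean_structure = traj.coords.mean(axis=0)
    return modes


def porcupine(mode_set: ModeSet, mode_index: int = 0, scale: float = 1.0) -> PorcupineField:
    """Amplitude-weighted arrow field for one mode.

    Arrow for residue i = mode components × scale × sqrt(eigenvalue), so
    length reflects both direction and motion amplitude along the mode.
    """
    if not (0 <= mode_index < len(mode_set.eigenvalues)):
        raise ValueError(f"mode {mode_index} out of range")
    amp = float(np.sqrt(mode_set.eigenvalues[mode_index]))
    vecs = mode_set.eigenvectors[mode_index].reshape(-1, 3) * scale * amp
    return PorcupineField(
        vectors=vecs, mode_index=mode_index, scale=scale,
        base=mode_set.mean_structure,
    )


def domain_cog_displacement(
    trajectory: Trajectory, domain_map: DomainMap, superpose: bool = True
) -> dict[str, np.ndarray]:
    """Centre-of-geometry displacement (last − first frame) per domain, nm.

    Both endpoint frames are taken after superposing the whole trajectory
    onto its mean, so rigid-body motion is removed before measuring.
    """
    traj = superpose_to_mean(trajectory) if superpose else trajectory
    out = {}
    for name, idx in domain_map.domains.items():
        if len(idx) == 0:
            raise SelectionError(f"domain {name!r} is empty")
        out[name] = traj.coords[-1, idx].mean(axis=0) - traj.coords[0, idx].mean(axis=0)
    return out
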