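"""Synthetic Cα trajectories with designed correlation structure.

Real input to this kind of analysis is a set of equilibrium / steered-MD
replicas of a large multi-domain protein (here, the integrin ectodomain:
~1000 frames over 100 ns, three replicas per condition).  This module
generates stand-ins with the same *statistical* anatomy so every estimator
downstream can be tested against known ground truth:

* block-structured residue-residue displacement correlations emulating
  domain-level coupling (an applied force raises global coupling, a bound
  ligand decorrelates the binding-site block),
* an optional cumulative drift of a residue group along a pulling axis,
  emulating force-driven extension,
* i.i.d. Gaussian noise frames — no temporal autocorrelation.  Every
  estimator exercised here is a frame-average, so independence only makes
  the sampling theory exact; it is a documented non-feature.

Units are nm throughout; PDB output converts to Å.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, InvalidSpecError

#: Fixed Cα-Cα spacing of the linear reference chain (nm), the canonical
#: virtual-bond length of a polypeptide backbone.
CA_SPACING_NM = 0.38

#: Default frame spacing: 1000 frames spanning 100 ns.
DEFAULT_FRAME_DT_NS = 0.1


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-replica trajectory ensemble.

    ``domain_blocks`` are ``(name, start, end)`` with ``end`` exclusive,
    0-based.  ``intra_block_corr`` is the designed displacement correlation
    between residues of the same block, ``inter_block_corr`` between
    residues of different blocks; residues outside every block are
    uncorrelated with everything.  ``drift_vector`` (nm/frame) accumulates
    linearly on ``drift_group`` starting from frame 0.
    """

    n_residues: int
    n_frames: int = 1000
    frame_dt: float = DEFAULT_FRAME_DT_NS
    domain_blocks: tuple[tuple[str, int, int], ...] = ()
    intra_block_corr: float = 0.0
    inter_block_corr: float = 0.0
    noise_sd: float = 0.1
    drift_vector: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drift_group: tuple[int, ...] = ()
    pull_group: tuple[int, ...] = ()
    ref_group: tuple[int, ...] = ()
    n_replicas: int = 3
    seed: int = 0
    layout: str = "linear"  # "linear" | "dumbbell"

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise InvalidSpecError("need at least 2 residues")
        if self.n_frames < 1:
            raise InvalidSpecError("need at least 1 frame")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if not (0.0 <= self.intra_block_corr < 1.0):
            raise InvalidSpecError("intra_block_corr must be in [0, 1)")
        if abs(self.inter_block_corr) > self.intra_block_corr:
            raise InvalidSpecError(
                "|inter_block_corr| must not exceed intra_block_corr"
            )
        if self.layout not in ("linear", "dumbbell"):
            raise InvalidSpecError(f"unknown layout {self.layout!r}")
        covered = np.zeros(self.n_residues, dtype=bool)
        for name, start, end in self.domain_blocks:
            if not (0 <= start < end <= self.n_residues):
                raise InvalidSpecError(
                    f"block {name!r} [{start}, {end}) outside [0, {self.n_residues})"
                )
            if covered[start:end].any():
                raise InvalidSpecError(f"block {name!r} overlaps a previous block")
            covered[start:end] = True
        for grp_name in ("drift_group", "pull_group", "ref_group"):
            idx = getattr(self, grp_name)
            if idx and not all(0 <= i < self.n_residues for i in idx):
                raise InvalidSpecError(f"{grp_name} index out of range")


@dataclasses.dataclass(frozen=True)
class ReferenceStructure:
    """Mean (noise-free) Cα conformation the frames fluctuate about."""

    coordinates: np.ndarray  # (n_residues, 3) nm
    resids: np.ndarray  # author residue numbers, 1-based
    chain_ids: np.ndarray  # single-letter chain per residue
    layout: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise InvalidSpecError("reference coordinates must be finite")
        # pairwise min-distance check; reference sizes are small
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.1:
            raise InvalidSpecError("residues closer than 0.1 nm in reference")


def build_reference(spec: SyntheticSpec) -> ReferenceStructure:
    """Deterministic reference layout for ``spec``.

    ``linear``: an extended chain along x with 0.38 nm Cα spacing.
    ``dumbbell``: two compact cubic-lattice lobes (half the residues each)
    joined along x — a coarse head/leg geometry whose inter-lobe distances
    exceed any contact cutoff, so the residue graph splits into two
    communities connected only through the linker residues.
    """
    n = spec.n_residues
    if spec.layout == "linear":
        coords = np.zeros((n, 3))
        coords[:, 0] = CA_SPACING_NM * np.arange(n)
    else:
        coords = _dumbbell_coords(n)
    resids = np.arange(1, n + 1)
    chains = np.full(n, "A")
    return ReferenceStructure(coords, resids, chains, spec.layout)


def _dumbbell_coords(n: int) -> np.ndarray:
    half = n // 2
    lobe1 = _cubic_lattice(half)
    lobe2 = _cubic_lattice(n - half)
    span = lobe1[:, 0].max() if half else 0.0
    lobe2 = lobe2 + np.array([span + 10 * CA_SPACING_NM, 0.0, 0.0])
    return np.vstack([lobe1, lobe2])


def _cubic_lattice(m: int) -> np.ndarray:
    side = int(np.ceil(m ** (1 / 3)))
    pts = []
    for i in range(m):
        x, rem = divmod(i, side * side)
        y, z = divmod(rem, side)
        pts.append((x, y, z))
    return CA_SPACING_NM * np.asarray(pts, dtype=float)


def build_covariance(spec: SyntheticSpec) -> np.ndarray:
    """Designed residue-residue displacement correlation matrix.

    Unit diagonal; ``intra_block_corr`` within each block;
    ``inter_block_corr`` between residues of different blocks; zero for
    residues outside every block.  The same matrix is applied independently
    per Cartesian axis, which makes it the analytic expectation of the
    normalized dynamic cross-correlation estimator (see
    :func:`allodyn.network.ndcc_matrix`) — the anchor for the
    parameter-recovery tests.

    Raises :class:`InvalidSpecError` naming the smallest eigenvalue when
    the requested block pattern is not positive semi-definite.
    """
    n = spec.n_residues
    corr = np.eye(n)
    membership = np.full(n, -1)
    for b, (_, start, end) in enumerate(spec.domain_blocks):
        membership[start:end] = b
    in_block = membership >= 0
    same = (membership[:, None] == membership[None, :]) & in_block[:, None] & in_block[None, :]
    cross = (membership[:, None] != membership[None, :]) & in_block[:, None] & in_block[None, :]
    off = ~np.eye(n, dtype=bool)
    corr[same & off] = spec.intra_block_corr
    corr[cross] = spec.inter_block_corr
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin < -1e-10:
        raise InvalidSpecError(
            f"designed correlation matrix is not PSD (smallest eigenvalue {eigmin:.3e})"
        )
    return corr


def _correlated_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix square root L with L L^T = corr, tolerant of PSD rank deficiency."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def replica_rngs(spec: SyntheticSpec) -> list[np.random.Generator]:
    """One independent, reproducible generator per replica.

    The master seed spawns one child seed sequence per replica, so adding a
    replica never perturbs the earlier ones.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    return [np.random.default_rng(c) for c in children]


def sample_trajectory(
    spec: SyntheticSpec,
    reference: ReferenceStructure,
    correlation_model: np.ndarray,
    replica: int = 0,
) -> "Trajectory":
    """Draw one replica: reference + correlated Gaussian displacement + drift.

    Frames are i.i.d.: frame ``t`` is ``reference + noise_sd * L z_t`` with
    ``L L^T`` the designed correlation, the same residue correlation applied
    independently along x, y, z, plus ``t * drift_vector`` on
    ``drift_group``.  Reproducible for a given ``(spec, replica)``.
    """
    from .io import Trajectory  # local import to avoid a cycle

    n = spec.n_residues
    if correlation_model.shape != (n, n):
        raise InvalidSpecError("correlation model does not match n_residues")
    rng = replica_rngs(spec)[replica]
    factor = _correlated_factor(correlation_model)
    # z: (frames, residues, 3) standard normal; correlate along residue axis
    z = rng.standard_normal((spec.n_frames, n, 3))
    disp = spec.noise_sd * np.einsum("ij,fjk->fik", factor, z)
    coords = reference.coordinates[None, :, :] + disp
    if spec.drift_group and any(spec.drift_vector):
        ramp = np.arange(spec.n_frames, dtype=float)[:, None]
        idx = np.asarray(spec.drift_group)
        coords[:, idx, :] += ramp[:, :, None] * np.asarray(spec.drift_vector)
    times = spec.frame_dt * np.arange(spec.n_frames)
    return Trajectory(
        coords=coords,
        times=times,
        resids=reference.resids.copy(),
        chain_ids=reference.chain_ids.copy(),
        replica=f"rep{replica + 1}",
    )


def domain_map_dict(spec: SyntheticSpec, reference: ReferenceStructure) -> dict:
    """Domain-map JSON payload (chain + author-resid ranges) for ``spec``."""
    domains = {}
    for name, start, end in spec.domain_blocks:
        chain = str(reference.chain_ids[start])
        domains[name] = [[chain, int(reference.resids[start]), int(reference.resids[end - 1])]]

    def _group(idx: Sequence[int]) -> list[list]:
        return [[str(reference.chain_ids[i]), int(reference.resids[i])] for i in idx]

    return {
        "domains": domains,
        "pull_group": _group(spec.pull_group),
        "ref_group": _group(spec.ref_group),
        "axis": "z",
    }


def write_fixture(
    trajectories: "Trajectory | Sequence[Trajectory]",
    reference: ReferenceStructure,
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
    formats: Sequence[str] = ("pdb",),
) -> dict[str, list[Path]]:
    """Write reference PDB, per-replica trajectories, and the domain map.

    ``formats`` may include ``pdb`` (multi-model), ``xtc`` and ``dcd``.
    Returns the written paths keyed by kind.  Round-tripping the multi-model
    PDB reproduces coordinates within the format's 0.001 Å precision.
    """
    import MDAnalysis as mda

    from .io import Trajectory

    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise EmptyInputError("no trajectories to write")
    for traj in trajectories:
        if traj.n_frames == 0:
            raise EmptyInputError("refusing to write an empty trajectory")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[Path]] = {"reference": [], "trajectories": [], "domain_map": []}

    ref_u = _universe_from_coords(reference.coordinates[None], reference)
    ref_path = out / "reference.pdb"
    ref_u.atoms.write(str(ref_path))
    paths["reference"].append(ref_path)

    for k, traj in enumerate(trajectories, start=1):
        u = _universe_from_coords(traj.coords, reference, dt_ps=1000.0 * float(np.diff(traj.times).mean()) if traj.n_frames > 1 else 1.0)
        for fmt in formats:
            tp = out / f"replica{k}.{fmt}"
            if fmt == "pdb":
                with mda.Writer(str(tp), multiframe=True) as w:
                    for _ in u.trajectory:
                        w.write(u.atoms)
            else:
                with mda.Writer(str(tp), n_atoms=u.atoms.n_atoms) as w:
                    for _ in u.trajectory:
                        w.write(u.atoms)
            paths["trajectories"].append(tp)

    if spec is not None:
        dm_path = out / "domains.json"
        dm_path.write_text(json.dumps(domain_map_dict(spec, reference), indent=1))
        paths["domain_map"].append(dm_path)
    return paths


def _universe_from_coords(coords_nm: np.ndarray, reference: ReferenceStructure, dt_ps: float = 1.0):
    """In-memory MDAnalysis Universe of Cα pseudo-atoms (coords nm → Å)."""
    import MDAnalysis as mda

    n = reference.coordinates.shape[0]
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n, n_segments=1,
        atom_resindex=np.arange(n), residue_segindex=np.zeros(n, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", ["CA"] * n)
    u.add_TopologyAttr("resname", ["ALA"] * n)
    u.add_TopologyAttr("resid", reference.resids)
    u.add_TopologyAttr("chainID", list(reference.chain_ids))
    u.add_TopologyAttr("segid", [str(reference.chain_ids[0])])
    u.load_new(10.0 * np.asarray(coords_nm, dtype=np.float64), format="memory", dt=dt_ps)
    return u


def generate_ensemble(spec: SyntheticSpec) -> tuple[ReferenceStructure, np.ndarray, list]:
    """Reference, designed correlation, and all replica trajectories."""
    reference = build_reference(spec)
    corr = build_covariance(spec)
    trajs = [sample_trajectory(spec, reference, corr, r) for r in range(spec.n_replicas)]
    return reference, corr, trajs
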