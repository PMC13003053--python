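"""Structure/trajectory reading, Cα selection, domain maps, Kabsch fitting.

File parsing is delegated to MDAnalysis (PDB single- and multi-model, GRO,
XTC, DCD); this module converts everything to nm and to plain numpy arrays
ordered by (chain, author resid, insertion code).  Internal residue
indexing is 0-based and contiguous over the Cα selection; author numbering
is preserved for reports because the source structures are addressed that
way (e.g. β-I MIDAS residue E220).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    FormatError,
    SelectionError,
    TopologyMismatchError,
)

ANGSTROM_PER_NM = 10.0


@dataclasses.dataclass
class Structure:
    """All-atom (or Cα-only) topology with per-atom metadata, coords in nm."""

    coords: np.ndarray  # (n_atoms, 3) nm
    atom_names: np.ndarray
    resids: np.ndarray  # author residue numbers
    icodes: np.ndarray  # insertion codes, '' if none
    resnames: np.ndarray
    chain_ids: np.ndarray
    source_path: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_label(self, atom_index: int) -> str:
        ic = self.icodes[atom_index]
        return f"{self.chain_ids[atom_index]}:{self.resids[atom_index]}{ic}"


@dataclasses.dataclass
class Trajectory:
    """Frames × residues × 3 Cα coordinates (nm) with residue metadata."""

    coords: np.ndarray  # (n_frames, n_residues, 3) nm
    times: np.ndarray  # (n_frames,) ns
    resids: np.ndarray
    chain_ids: np.ndarray
    icodes: np.ndarray | None = None
    replica: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, residues, 3)")
        if self.coords.shape[0] < 1:
            raise EmptyInputError("trajectory needs at least one frame")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.icodes is None:
            self.icodes = np.full(self.n_residues, "", dtype=object)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def residue_labels(self) -> list[str]:
        return [
            f"{c}:{r}{i}"
            for c, r, i in zip(self.chain_ids, self.resids, self.icodes)
        ]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return dataclasses.replace(self, coords=coords)

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return dataclasses.replace(
            self, coords=self.coords[start:stop], times=self.times[start:stop]
        )


@dataclasses.dataclass
class DomainMap:
    """Named domains plus pull/reference groups as 0-based residue indices."""

    domains: dict[str, np.ndarray]
    pull_group: np.ndarray
    ref_group: np.ndarray
    axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        for name, idx in self.domains.items():
            if len(idx) == 0:
                raise SelectionError(f"domain {name!r} selects no residues")


# ---------------------------------------------------------------------------
# loading


def _universe(path: str | Path, *args, **kwargs):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), *args, **kwargs)
    except (ValueError, OSError, EOFError, StopIteration, IndexError, KeyError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def load_structure(path: str | Path) -> Structure:
    """Read a PDB/GRO topology into a :class:`Structure` (coords → nm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _universe(path)
    atoms = u.atoms
    if atoms.n_atoms == 0:
        raise EmptyInputError(f"{path} contains no atoms")

    def _attr(name: str, default: str) -> np.ndarray:
        if hasattr(atoms, name):
            return np.asarray(getattr(atoms, name), dtype=object)
        return np.full(atoms.n_atoms, default, dtype=object)

    chain = _attr("chainIDs", "")
    if not any(str(c).strip() for c in chain):
        chain = _attr("segids", "A")
    icodes = _attr("icodes", "")
    icodes = np.array([str(i).strip() for i in icodes], dtype=object)
    return Structure(
        coords=atoms.positions.astype(float) / ANGSTROM_PER_NM,
        atom_names=np.asarray(atoms.names, dtype=object),
        resids=np.asarray(atoms.resids),
        icodes=icodes,
        resnames=np.asarray(atoms.resnames, dtype=object),
        chain_ids=np.array([str(c).strip() or "A" for c in chain], dtype=object),
        source_path=str(path),
    )


def select_calpha(structure: Structure) -> np.ndarray:
    """Indices of one CA atom per residue, ordered by (chain, resid, icode).

    Raises :class:`SelectionError` if a residue carries more than one CA
    record (alternate locations must be resolved upstream).
    """
    is_ca = structure.atom_names == "CA"
    keys = {}
    for i in np.nonzero(is_ca)[0]:
        key = (str(structure.chain_ids[i]), int(structure.resids[i]), str(structure.icodes[i]))
        if key in keys:
            raise SelectionError(f"duplicate CA atom for residue {structure.residue_label(i)}")
        keys[key] = i
    if not keys:
        raise SelectionError("structure has no CA atoms")
    ordered = sorted(keys)
    return np.array([keys[k] for k in ordered], dtype=int)


def load_trajectory(
    path: str | Path,
    topology: Structure,
    selection: np.ndarray | None = None,
    frame_dt: float | None = None,
    replica: str | None = None,
    condition: str | None = None,
) -> Trajectory:
    """Read a coordinate trajectory against ``topology``, keep ``selection``.

    ``selection`` defaults to the Cα selection.  Frame times come from the
    file when present (ps → ns), otherwise they are synthesized as
    ``frame_dt`` (ns) multiples; if neither is available the frame index in
    ns is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if selection is None:
        selection = select_calpha(topology)
    top_path = topology.source_path
    if top_path:
        try:
            u = _universe(top_path, str(path))
        except FormatError:
            # a count mismatch surfaces as a parse failure inside the
            # reader; disambiguate by opening the trajectory standalone
            try:
                n_alt = _universe(path).atoms.n_atoms
            except FormatError:
                raise
            if n_alt != topology.n_atoms:
                raise TopologyMismatchError(
                    f"trajectory has {n_alt} atoms, topology {topology.n_atoms}"
                ) from None
            raise
    else:
        u = _universe(path)
    if u.atoms.n_atoms != topology.n_atoms:
        raise TopologyMismatchError(
            f"trajectory has {u.atoms.n_atoms} atoms, topology {topology.n_atoms}"
        )
    coords = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers without dt metadata warn
        for ts in u.trajectory:
            coords.append(u.atoms.positions[selection].astype(float) / ANGSTROM_PER_NM)
            times.append(ts.time / 1000.0)  # ps → ns
    coords = np.asarray(coords)
    times = np.asarray(times)
    if frame_dt is not None or not np.all(np.diff(times) > 0):
        dt = frame_dt if frame_dt is not None else 1.0
        times = dt * np.arange(len(coords))
    return Trajectory(
        coords=coords,
        times=times,
        resids=topology.resids[selection],
        chain_ids=topology.chain_ids[selection],
        icodes=topology.icodes[selection],
        replica=replica,
        condition=condition,
    )


def load_domain_map(path: str | Path, trajectory: Trajectory) -> DomainMap:
    """Parse the domain-map JSON against a trajectory's residue labels.

    Schema: ``{"domains": {name: [[chain, start, end], ...]},
    "pull_group": [[chain, resid], ...] or [[chain, start, end], ...],
    "ref_group": ..., "axis": "z"|[x,y,z]}``.
    """
    payload = json.loads(Path(path).read_text())
    index = {}
    for i, (c, r) in enumerate(zip(trajectory.chain_ids, trajectory.resids)):
        index.setdefault(str(c), {})[int(r)] = i

    def _resolve(entries) -> np.ndarray:
        out: list[int] = []
        for entry in entries:
            chain = str(entry[0])
            if len(entry) == 2:
                lo = hi = int(entry[1])
            else:
                lo, hi = int(entry[1]), int(entry[2])
            chain_idx = index.get(chain, {})
            hits = [chain_idx[r] for r in range(lo, hi + 1) if r in chain_idx]
            if not hits:
                raise SelectionError(f"selection {entry} matches no residue")
            out.extend(hits)
        return np.array(sorted(set(out)), dtype=int)

    domains = {name: _resolve(spans) for name, spans in payload.get("domains", {}).items()}
    pull = _resolve(payload["pull_group"]) if payload.get("pull_group") else np.array([], dtype=int)
    ref = _resolve(payload["ref_group"]) if payload.get("ref_group") else np.array([], dtype=int)
    axis = payload.get("axis", "z")
    if isinstance(axis, str):
        axis = {"x": [1.0, 0, 0], "y": [0, 1.0, 0], "z": [0, 0, 1.0]}[axis.lower()]
    return DomainMap(domains=domains, pull_group=pull, ref_group=ref, axis=np.asarray(axis, float))


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ mobile + t ≈ reference.

    Least-squares rigid fit: centroids matched, rotation from the SVD of the
    cross-covariance with the determinant sign correction, so R is always a
    proper rotation.  Uniform weights.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("need matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    p = mobile - mc
    q = reference - rc
    # collinearity: second singular value of the centered cloud ~ 0
    if np.linalg.svd(p, compute_uv=False)[1] < 1e-10:
        raise DegenerateFitError("fit atoms are collinear")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - r @ mc
    return r, t


def superpose(
    trajectory: Trajectory,
    reference_frame: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> Trajectory:
    """Rigid-fit every frame onto ``reference_frame`` over ``fit_indices``."""
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != (trajectory.n_residues, 3):
        raise ValueError("reference frame shape mismatch")
    idx = np.arange(trajectory.n_residues) if fit_indices is None else np.asarray(fit_indices)
    out = np.empty_like(trajectory.coords)
    for f in range(trajectory.n_frames):
        r, t = kabsch(trajectory.coords[f, idx], ref[idx])
        out[f] = trajectory.coords[f] @ r.T + t
    return trajectory.with_coords(out)


def superpose_to_mean(trajectory: Trajectory, fit_indices: np.ndarray | None = None) -> Trajectory:
    """Two-pass fit to the trajectory-mean structure.

    Pass 1 fits every frame to frame 0 and takes the mean; pass 2 refits the
    original frames to that mean.  Standard iteration used before RMSF,
    covariance and cross-correlation estimation.
    """
    first = superpose(trajectory, trajectory.coords[0], fit_indices)
    mean = first.coords.mean(axis=0)
    return superpose(trajectory, mean, fit_indices)


def frame_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two (n, 3) coordinate sets (nm)."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


def trajectory_from_structure(structure: Structure, selection: np.ndarray | None = None) -> Trajectory:
    """Single-frame trajectory over the Cα selection of a structure."""
    if selection is None:
        selection = select_calpha(structure)
    return Trajectory(
        coords=structure.coords[None, selection],
        times=np.array([0.0]),
        resids=structure.resids[selection],
        chain_ids=structure.chain_ids[selection],
        icodes=structure.icodes[selection],
    )
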