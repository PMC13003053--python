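"""Normalized dynamic cross-correlation (nDCC), residue-pair coupling
classification, and the correlation-weighted residue interaction network
with betweenness-centrality aggregation.

The estimator at the heart of the analysis is

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i²⟩ ⟨Δr_j²⟩)

with Δr_i(t) = r_i(t) − ⟨r_i⟩ the 3-vector displacement of residue i from
its time-averaged position.  C_ij ∈ [−1, 1]: values approaching +1 mean the
residues move together, −1 opposite, and the band (−0.25, 0.25) is treated
as minimally coupled.  The residue graph links residues whose motions are
both strongly coupled (|C_ij| > 0.30) and spatially close (d_ij < 7 Å, the
range of noncovalent contacts); edge weights w_ij = −log|C_ij| make strong
coupling cheap to traverse, so weighted betweenness centrality
CB(v) = Σ_{s≠v≠t} σ_st(v)/σ_st ranks residues by how often they mediate
the strongest communication paths.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GraphError, SelectionError
from .io import DomainMap, Trajectory, superpose_to_mean

#: Coupling band edge for pair classification (|C| ≥ 0.25 → coupled).
CLASSIFY_EDGE = 0.25
#: Correlation threshold for a network edge (|C| must exceed it).
DEFAULT_C_MIN = 0.30
#: Distance cutoff for a network edge, Å (d must be below it).
DEFAULT_D_MAX = 7.0
#: A residue is a communication hub if CB ≥ this factor × control mean.
HIGH_BC_FACTOR = 2.0

ANGSTROM_PER_NM = 10.0


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric nDCC matrix over the selected residues."""

    matrix: np.ndarray
    labels: list[str]  # chain:resid residue labels
    n_frames: int
    replicas: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation diagonal must be 1")
        if np.abs(m).max() > 1.0 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class PairClassification:
    """Fractions of unordered residue pairs in the three coupling bands."""

    correlated: float  # C ≥ +0.25
    non_correlated: float  # −0.25 < C < +0.25
    anti_correlated: float  # C ≤ −0.25
    edge: float = CLASSIFY_EDGE

    def __post_init__(self) -> None:
        total = self.correlated + self.non_correlated + self.anti_correlated
        if abs(total - 1.0) > 1e-12:
            raise ValueError("pair fractions must sum to 1")


@dataclasses.dataclass
class CentralityProfile:
    """Normalized betweenness per residue (pair-count convention)."""

    values: np.ndarray
    labels: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < -1e-15).any() or (v > 1.0 + 1e-12).any():
            raise ValueError("normalized CB must lie in [0, 1]")
        self.values = np.clip(v, 0.0, None)


def ndcc_matrix(trajectory: Trajectory, superpose: bool = True) -> CorrelationMatrix:
    """Normalized dynamic cross-correlation of Cα displacement vectors.

    With ``superpose`` (default) frames are first fit to the trajectory
    mean, removing rigid-body motion so only internal coupling remains;
    disabling it lets collective drift (e.g. under pulling) contribute.
    A residue with zero displacement variance gets zero off-diagonal
    correlation by convention (with a warning) and 1 on the diagonal.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for correlations")
    traj = superpose_to_mean(trajectory) if superpose else trajectory
    delta = traj.coords - traj.coords.mean(axis=0, keepdims=True)
    # numerator: frame-averaged dot product of 3-vector displacements
    num = np.einsum("fik,fjk->ij", delta, delta) / traj.n_frames
    var = np.diag(num).copy()
    zero = var <= 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance residue(s): correlations set to 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = num / denom
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    return CorrelationMatrix(
        matrix=c,
        labels=trajectory.residue_labels(),
        n_frames=trajectory.n_frames,
        replicas=(trajectory.replica,) if trajectory.replica else (),
    )


def average_matrices(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean nDCC across replicas (the map reported per
    condition is the average of the independent replicas)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.matrix.shape != first.matrix.shape:
            raise ValueError("correlation matrices differ in dimension")
    mean = np.mean([m.matrix for m in matrices], axis=0)
    mean = np.clip(mean, -1.0, 1.0)
    replicas = tuple(r for m in matrices for r in m.replicas)
    return CorrelationMatrix(
        matrix=mean, labels=first.labels,
        n_frames=sum(m.n_frames for m in matrices), replicas=replicas,
    )


def classify_pairs(corr: CorrelationMatrix, edge: float = CLASSIFY_EDGE) -> PairClassification:
    """Fractions of unordered off-diagonal pairs per coupling band.

    Correlated: C_ij ≥ +edge; anti-correlated: C_ij ≤ −edge; otherwise
    non-correlated.  Boundary values land in the coupled bands so the
    classification is total and deterministic.
    """
    iu = np.triu_indices(corr.n_residues, k=1)
    vals = corr.matrix[iu]
    n = vals.size
    pos = int((vals >= edge).sum())
    neg = int((vals <= -edge).sum())
    return PairClassification(
        correlated=pos / n,
        non_correlated=(n - pos - neg) / n,
        anti_correlated=neg / n,
        edge=edge,
    )


def mean_distance_matrix(trajectory: Trajectory) -> np.ndarray:
    """Frame-averaged Cα–Cα Euclidean distance matrix, in Å."""
    coords = trajectory.coords
    n = trajectory.n_residues
    acc = np.zeros((n, n))
    for f in range(trajectory.n_frames):
        diff = coords[f, :, None, :] - coords[f, None, :, :]
        acc += np.sqrt((diff**2).sum(-1))
    return ANGSTROM_PER_NM * acc / trajectory.n_frames


def build_graph(
    corr: CorrelationMatrix,
    dist: np.ndarray,
    c_min: float = DEFAULT_C_MIN,
    d_max: float = DEFAULT_D_MAX,
) -> nx.Graph:
    """Residue interaction network under the dual threshold criterion.

    Edge (i, j) exists iff |C_ij| > c_min AND d_ij < d_max; its weight is
    w_ij = −log|C_ij| ≥ 0 (shorter = more strongly coupled).  Residues
    failing every criterion stay in the graph as isolates.  ``dist`` is in
    Å.
    """
    if c_min <= 0.0:
        raise GraphError("c_min must be positive (edge weight is -log|C|)")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != corr.matrix.shape:
        raise GraphError("correlation and distance matrices differ in shape")
    n = corr.n_residues
    g = nx.Graph()
    g.add_nodes_from(range(n))
    c = corr.matrix
    iu, ju = np.triu_indices(n, k=1)
    mask = (np.abs(c[iu, ju]) > c_min) & (dist[iu, ju] < d_max)
    for i, j in zip(iu[mask], ju[mask]):
        cij = float(c[i, j])
        g.add_edge(int(i), int(j), weight=float(-np.log(abs(cij))),
                   cij=cij, dij=float(dist[i, j]))
    g.graph.update(c_min=c_min, d_max=d_max, labels=corr.labels)
    return g


def betweenness(graph: nx.Graph, condition: str | None = None) -> CentralityProfile:
    """Weighted betweenness centrality per residue (Brandes accumulation).

    Shortest paths are Dijkstra paths under w_ij; ties in path weight split
    the credit exactly.  Values are normalized by 2/((n−1)(n−2)) for the
    undirected graph; pairs in different components contribute nothing.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise GraphError("betweenness needs at least 3 nodes")
    for _, _, w in graph.edges(data="weight"):
        if w < 0:
            raise GraphError("negative edge weight")
    bc = nx.betweenness_centrality(graph, weight="weight", normalized=True)
    nodes = sorted(graph.nodes)
    labels = graph.graph.get("labels") or [str(v) for v in nodes]
    return CentralityProfile(
        values=np.array([bc[v] for v in nodes]), labels=list(labels),
        condition=condition,
    )


def average_profiles(profiles: Sequence[CentralityProfile]) -> CentralityProfile:
    """Element-wise mean of per-replica centrality profiles."""
    if not profiles:
        raise ValueError("no profiles to average")
    vals = np.mean([p.values for p in profiles], axis=0)
    return CentralityProfile(values=vals, labels=profiles[0].labels,
                             condition=profiles[0].condition)


def aggregate_centrality(
    profile: CentralityProfile,
    domain_map: DomainMap,
    control_profile: CentralityProfile,
    high_factor: float = HIGH_BC_FACTOR,
    per_residue_control: bool = False,
) -> pd.DataFrame:
    """Domain-level centrality table relative to the control condition.

    Per domain: mean CB, condition/control normalized mean, % difference vs
    control, and the count of residues whose CB is at least ``high_factor``
    times the control mean over *all* residues (the hub criterion).
    ``per_residue_control`` switches the hub test to each residue's own
    control value instead of the global control mean.
    """
    if len(profile.values) != len(control_profile.values):
        raise ValueError("profiles cover different residue sets")
    control_mean = float(control_profile.values.mean())
    threshold = (
        high_factor * control_profile.values
        if per_residue_control
        else high_factor * control_mean
    )
    high = profile.values >= threshold
    rows = []
    for name, idx in domain_map.domains.items():
        if len(idx) == 0:
            raise SelectionError(f"domain {name!r} is empty")
        dom = profile.values[idx]
        ctl = control_profile.values[idx]
        ctl_mean = float(ctl.mean())
        rows.append({
            "domain": name,
            "n_residues": len(idx),
            "mean_bc": float(dom.mean()),
            "control_mean_bc": ctl_mean,
            "normalized_mean": float(dom.mean() / ctl_mean) if ctl_mean > 0 else np.nan,
            "pct_diff_vs_control": (
                100.0 * (float(dom.mean()) - ctl_mean) / ctl_mean if ctl_mean > 0 else np.nan
            ),
            "n_high_bc": int(high[idx].sum()),
        })
    df = pd.DataFrame(rows)
    df.attrs["overall_normalized"] = (
        float(profile.values.mean() / control_mean) if control_mean > 0 else np.nan
    )
    df.attrs["n_high_bc_total"] = int(high.sum())
    df.attrs["high_bc_threshold"] = (
        float(high_factor * control_mean) if not per_residue_control else None
    )
    return df
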