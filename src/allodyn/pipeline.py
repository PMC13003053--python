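"""End-to-end orchestration of the four-condition comparison
(Control, RGD, Force, Force/RGD): per-condition metrics, averaged nDCC,
pair-coupling fractions, centrality tables and PCA summaries, written as
tidy CSV/JSON with full provenance (thresholds, seeds, flags) in every
header.  All numbers come from the analysis modules; the pipeline only
routes data and formats tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError
from .io import (
    DomainMap,
    Trajectory,
    load_domain_map,
    load_structure,
    load_trajectory,
    select_calpha,
)
from .metrics import (
    MetricSeries,
    bootstrap_ci,
    extension_series,
    per_residue_displacement,
    rmsd_series,
    rmsf_profile,
)
from .network import (
    CorrelationMatrix,
    aggregate_centrality,
    average_matrices,
    average_profiles,
    betweenness,
    build_graph,
    classify_pairs,
    mean_distance_matrix,
    ndcc_matrix,
)
from .pca import trajectory_modes

CONTROL_LABEL = "control"


@dataclasses.dataclass
class ConditionSettings:
    label: str
    topology: str
    trajectories: list[str]


@dataclasses.dataclass
class RunConfig:
    """Everything one comparison run needs, loadable from a single JSON."""

    conditions: list[ConditionSettings]
    domain_map_path: str
    c_min: float = 0.30
    d_max: float = 7.0
    classify_edge: float = 0.25
    high_bc_factor: float = 2.0
    window_length: float = 10.0
    block_length: float = 25.0
    bootstrap_resamples: int = 1000
    bootstrap_level: float = 0.95
    frame_dt: float | None = None
    superpose_ndcc: bool = True
    seed: int = 0
    out_dir: str = "allodyn_out"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        labels = [c.label.lower() for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")

    @property
    def control(self) -> ConditionSettings:
        for c in self.conditions:
            if c.label.lower() == CONTROL_LABEL:
                return c
        raise ConfigError("a condition labeled 'control' is required for normalization")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        try:
            conditions = [
                ConditionSettings(label=c["label"], topology=c["topology"],
                                  trajectories=list(c["trajectories"]))
                for c in raw["conditions"]
            ]
            kwargs = {k: v for k, v in raw.items() if k not in ("conditions", "domain_map")}
            return cls(conditions=conditions, domain_map_path=raw["domain_map"], **kwargs)
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # hash analysis parameters, not paths
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclasses.dataclass
class ConditionReport:
    """All per-condition results, ready for table export."""

    label: str
    rmsd: list[MetricSeries]
    rmsf_profiles: list[np.ndarray]
    extension: list[MetricSeries]
    final_displacement: list[np.ndarray]
    ndcc: CorrelationMatrix  # replica-averaged
    pair_fractions: "tuple[float, float, float]"
    centrality: "np.ndarray"  # replica-averaged normalized CB per residue
    centrality_labels: list[str]
    pca_eigenvalues: np.ndarray
    domain_map: DomainMap
    provenance: dict


def _load_condition(config: RunConfig, cond: ConditionSettings) -> tuple[list[Trajectory], DomainMap]:
    top_path = Path(cond.topology)
    if not top_path.exists():
        raise DataError(f"topology not found: {top_path}")
    structure = load_structure(top_path)
    sel = select_calpha(structure)
    trajs = []
    for k, traj_path in enumerate(cond.trajectories, start=1):
        p = Path(traj_path)
        if not p.exists():
            raise DataError(f"trajectory not found: {p}")
        trajs.append(load_trajectory(p, structure, sel, frame_dt=config.frame_dt,
                                     replica=f"rep{k}", condition=cond.label))
    if not trajs:
        raise DataError(f"condition {cond.label!r} has no trajectories")
    dmap = load_domain_map(config.domain_map_path, trajs[0])
    return trajs, dmap


def run_condition(config: RunConfig, label: str) -> ConditionReport:
    """Execute the full per-condition analysis chain, deterministically."""
    cond = next((c for c in config.conditions if c.label == label), None)
    if cond is None:
        raise ConfigError(f"condition {label!r} not in config")
    trajs, dmap = _load_condition(config, cond)

    rmsd = [rmsd_series(t, t.coords[0]) for t in trajs]
    rmsf = [rmsf_profile(t) for t in trajs]
    ext = [
        extension_series(t, dmap.pull_group, dmap.ref_group, dmap.axis)
        for t in trajs
    ] if dmap.pull_group.size and dmap.ref_group.size else []
    disp = [per_residue_displacement(t.coords[0], t.coords[-1]) for t in trajs]

    matrices = [ndcc_matrix(t, superpose=config.superpose_ndcc) for t in trajs]
    avg = average_matrices(matrices)
    frac = classify_pairs(avg, edge=config.classify_edge)

    profiles = []
    for t, m in zip(trajs, matrices):
        dist = mean_distance_matrix(t)
        g = build_graph(m, dist, c_min=config.c_min, d_max=config.d_max)
        profiles.append(betweenness(g, condition=label))
    bc = average_profiles(profiles)

    modes = trajectory_modes(trajs[0], k=3)

    return ConditionReport(
        label=label,
        rmsd=rmsd, rmsf_profiles=rmsf, extension=ext, final_displacement=disp,
        ndcc=avg, pair_fractions=(frac.correlated, frac.non_correlated, frac.anti_correlated),
        centrality=bc.values, centrality_labels=bc.labels,
        pca_eigenvalues=modes.eigenvalues,
        domain_map=dmap,
        provenance={
            "condition": label,
            "n_replicas": len(trajs),
            "c_min": config.c_min, "d_max": config.d_max,
            "classify_edge": config.classify_edge,
            "high_bc_factor": config.high_bc_factor,
            "superpose_ndcc": config.superpose_ndcc,
            "seed": config.seed,
            "config_hash": config.digest(),
            "version": __version__,
        },
    )


def compare_conditions(reports: Sequence[ConditionReport], config: RunConfig) -> dict[str, pd.DataFrame]:
    """Cross-condition tables: pair fractions and centrality vs control."""
    by_label = {r.label.lower(): r for r in reports}
    if CONTROL_LABEL not in by_label:
        raise ConfigError("control report required for comparison")
    control = by_label[CONTROL_LABEL]
    n = len(control.centrality)
    for r in reports:
        if len(r.centrality) != n or r.centrality_labels != control.centrality_labels:
            raise DataError(f"condition {r.label!r} has an inconsistent residue set")

    fractions = pd.DataFrame([
        {"condition": r.label,
         "correlated": r.pair_fractions[0],
         "non_correlated": r.pair_fractions[1],
         "anti_correlated": r.pair_fractions[2]}
        for r in reports
    ])

    from .network import CentralityProfile
    ctrl_profile = CentralityProfile(control.centrality, control.centrality_labels, "control")
    domain_rows = []
    overall_rows = []
    for r in reports:
        prof = CentralityProfile(r.centrality, r.centrality_labels, r.label)
        table = aggregate_centrality(prof, r.domain_map, ctrl_profile,
                                     high_factor=config.high_bc_factor)
        table.insert(0, "condition", r.label)
        domain_rows.append(table)
        overall_rows.append({
            "condition": r.label,
            "normalized_mean_bc": table.attrs["overall_normalized"],
            "n_high_bc": table.attrs["n_high_bc_total"],
        })
    return {
        "pair_fractions": fractions,
        "centrality_domains": pd.concat(domain_rows, ignore_index=True),
        "centrality_overall": pd.DataFrame(overall_rows),
    }


def _provenance_header(provenance: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in sorted(provenance.items()))


def write_report(report: ConditionReport, out_dir: str | Path, config: RunConfig) -> list[Path]:
    """Write one condition's tables as CSV with a provenance header."""
    out = Path(out_dir) / report.label
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance_header(report.provenance)
    written = []

    def _csv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, lineterminator="\n")
        written.append(p)

    series_rows = []
    for s in report.rmsd + report.extension:
        for t, v in zip(s.times, s.values):
            series_rows.append({"metric": s.name, "replica": s.replica,
                                "time_ns": t, "value_nm": v})
    _csv("timeseries.csv", pd.DataFrame(series_rows))

    labels = report.centrality_labels
    prof_rows = []
    for k, rmsf in enumerate(report.rmsf_profiles, start=1):
        for lab, v in zip(labels, rmsf):
            prof_rows.append({"metric": "rmsf", "replica": f"rep{k}",
                              "residue": lab, "value_nm": v})
    for k, disp in enumerate(report.final_displacement, start=1):
        for lab, v in zip(labels, disp):
            prof_rows.append({"metric": "final_displacement", "replica": f"rep{k}",
                              "residue": lab, "value_nm": v})
    _csv("profiles.csv", pd.DataFrame(prof_rows))

    ndcc_df = pd.DataFrame(report.ndcc.matrix, columns=labels)
    _csv("ndcc.csv", ndcc_df)
    _csv("centrality.csv", pd.DataFrame({"residue": labels, "bc": report.centrality}))

    ci_rows = []
    for s in report.rmsd:
        ci = bootstrap_ci(s.values, n_resamples=config.bootstrap_resamples,
                          level=config.bootstrap_level, seed=config.seed)
        ci_rows.append({"metric": "rmsd", "replica": s.replica, "mean_nm": ci.point,
                        "ci_lower_nm": ci.lower, "ci_upper_nm": ci.upper,
                        "level": ci.level, "n_resamples": ci.n_resamples})
    _csv("bootstrap_ci.csv", pd.DataFrame(ci_rows))
    return written


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every condition, write per-condition reports and the comparison
    tables under ``config.out_dir``; returns the comparison tables."""
    reports = [run_condition(config, c.label) for c in config.conditions]
    out = Path(config.out_dir)
    for r in reports:
        write_report(r, out, config)
    tables = compare_conditions(reports, config)
    header = _provenance_header(reports[0].provenance | {"condition": "ALL"})
    for name, df in tables.items():
        p = out / f"{name}.csv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, lineterminator="\n")
    return tables
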