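"""Configuration-driven orchestration of the three analysis campaigns.

A campaign config (one YAML file, or the equivalent :class:`AnalysisConfig`)
names a structure inventory, the pairwise comparisons to run (alignment
scheme + displacement targets), the trajectory jobs (interval, trim,
stride, state threshold) and the H-bond audits (pair list + criteria).
Every analysis constant that the conclusions depend on — classification
threshold, H-bond criteria, alignment scheme — is echoed into the report's
provenance block; silent defaults are deliberately impossible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .descriptors import (
    DEFAULT_LOCKED_THRESHOLD, SENSOR_SIDE_CHAIN_ATOMS,
    atom_displacement, catalytic_gap, gate_distance, sensor_angle,
)
from .hbond import HBondCriteria, RELAXED_DEFAULT, STRICT_DEFAULT, audit_network
from .sitemap import SiteMap
from .structure_io import AtomSelector, read_pdb_single, resolve_altlocs
from .superposition import align_structures
from .trajectory_analysis import (
    DEFAULT_SKIP_NS, DEFAULT_STRIDE_PS, density2d, descriptor_series,
    load_trajectory, replica_summary, state_populations, trim_and_subsample,
)

__all__ = ["AnalysisConfig", "Report", "run_structure_campaign",
           "run_traj_campaign", "run_hbond_campaign"]


@dataclass
class AnalysisConfig:
    structures: dict = field(default_factory=dict)   # id -> {path, site (dict)}
    comparisons: list = field(default_factory=list)  # {ref, mov, scheme, targets}
    trajectories: list = field(default_factory=list)  # {path/replicas, interval, ...}
    hbond_jobs: list = field(default_factory=list)   # {structure, pairs, criteria}
    threshold: float = DEFAULT_LOCKED_THRESHOLD
    skip_ns: float = DEFAULT_SKIP_NS
    stride_ps: float = DEFAULT_STRIDE_PS
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        raw = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Report:
    kind: str
    entries: list = field(default_factory=list)
    failures: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self) -> str:
        def _default(o):
            import numpy as np
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)
        return json.dumps({"kind": self.kind, "entries": self.entries,
                           "failures": self.failures,
                           "provenance": self.provenance},
                          indent=2, default=_default)


def _provenance(cfg: AnalysisConfig, **extra) -> dict:
    return {"version": __version__, "config_digest": cfg.digest(),
            "seed": cfg.seed, **extra}


def _load_structure(cfg: AnalysisConfig, sid: str):
    try:
        entry = cfg.structures[sid]
    except KeyError:
        raise ConfigError(f"structure id {sid!r} not in inventory") from None
    s = resolve_altlocs(read_pdb_single(Path(entry["path"]).read_text(), source_id=sid))
    site = SiteMap.from_dict(entry["site"]) if "site" in entry else None
    return s, site


def _descriptor_table(s, site) -> dict:
    out = {}
    if site is None:
        return out
    for name, fn in (("sensor_angle_deg", sensor_angle),
                     ("gate_distance_A", gate_distance),
                     ("catalytic_gap_A", catalytic_gap)):
        try:
            out[name] = fn(s, site)
        except Exception as exc:  # descriptor may be undefined for a variant
            out[name] = f"unavailable: {exc}"
    return out


def run_structure_campaign(cfg: AnalysisConfig) -> Report:
    """Pairwise structure comparisons: alignment RMSD, descriptor values for
    both partners, and the per-atom displacement table of the target atoms.
    A failing comparison is recorded and the rest proceed."""
    report = Report("structure", provenance=_provenance(cfg))
    for comp in cfg.comparisons:
        try:
            ref, site_ref = _load_structure(cfg, comp["ref"])
            mov, site_mov = _load_structure(cfg, comp["mov"])
            scheme = comp.get("scheme", "palm")
            _, fit = align_structures(ref, mov, scheme, site_ref, site_mov)
            target_cfg = comp.get("target", {})
            chain = target_cfg.get("chain") or (site_ref.protein_chain if site_ref else None)
            selector = AtomSelector(
                chain=chain,
                res_nums=tuple(target_cfg.get("res_nums", ())),
                atom_names=tuple(target_cfg.get("atom_names",
                                                SENSOR_SIDE_CHAIN_ATOMS)),
            ) if target_cfg else AtomSelector(
                chain=site_ref.protein_chain if site_ref else None,
                res_nums=(site_ref.address("sensor").res_num,) if site_ref else (),
                atom_names=(), het_policy="include")
            disp = atom_displacement(ref, mov, scheme, selector, site_ref, site_mov)
            report.entries.append({
                "ref": comp["ref"], "mov": comp["mov"], "scheme": fit.scheme,
                "fit_rmsd_A": fit.rmsd, "n_scheme_atoms": fit.n_atoms,
                "displacement_per_atom": [
                    {"atom": ":".join(map(str, addr)), "displacement_A": d}
                    for addr, d in disp.per_atom],
                "displacement_max_A": disp.max,
                "displacement_mean_A": disp.mean,
                "descriptors_ref": _descriptor_table(ref, site_ref),
                "descriptors_mov": _descriptor_table(mov, site_mov),
            })
        except Exception as exc:
            report.failures.append({"comparison": comp, "error": str(exc)})
    return report


def run_traj_campaign(cfg: AnalysisConfig) -> Report:
    """Per trajectory job: trim/stride, descriptor series, state populations,
    gate-vs-angle 2D density, and the pooled replica summary, with explicit
    frame-count bookkeeping."""
    if not cfg.trajectories:
        raise ConfigError("trajectory campaign requires at least one job")
    report = Report("trajectory", provenance=_provenance(
        cfg, threshold_deg=cfg.threshold, skip_ns=cfg.skip_ns,
        stride_ps=cfg.stride_ps))
    for job in cfg.trajectories:
        try:
            site = SiteMap.from_dict(job["site"])
            interval = float(job.get("interval_ps", 2.5))
            replicas = []
            for rep in job["replicas"]:
                traj = load_trajectory(Path(rep["path"]).read_text(), interval,
                                       replica_id=rep.get("id", rep["path"]))
                traj = trim_and_subsample(traj, cfg.skip_ns, cfg.stride_ps)
                replicas.append(traj)
            angle_series = [descriptor_series(t, site, "sensor_angle") for t in replicas]
            gate_series = [descriptor_series(t, site, "gate_distance") for t in replicas]
            pooled_frames = sum(len(s) for s in angle_series)
            import numpy as np
            all_angles = np.concatenate([s.values for s in angle_series])
            all_gates = np.concatenate([s.values for s in gate_series])
            pooled = state_populations(
                type(angle_series[0])(replica_id="pooled",
                                      times=np.arange(pooled_frames, dtype=float),
                                      values=all_angles, kind="sensor_angle"),
                cfg.threshold)
            x_edges = np.linspace(all_gates.min() - 0.1, all_gates.max() + 0.1, 41)
            y_edges = np.linspace(0.0, 180.0, 37)
            dens = density2d(
                type(gate_series[0])(replica_id="pooled",
                                     times=np.arange(pooled_frames, dtype=float),
                                     values=all_gates, kind="gate_distance"),
                type(angle_series[0])(replica_id="pooled",
                                      times=np.arange(pooled_frames, dtype=float),
                                      values=all_angles, kind="sensor_angle"),
                x_edges, y_edges)
            report.entries.append({
                "job": job.get("id", "traj"),
                "n_replicas": len(replicas),
                "frames_per_replica": [t.n_frames for t in replicas],
                "frames_per_system": pooled_frames,
                "state_summary": pooled.to_dict(),
                "angle_replica_summary": replica_summary(angle_series),
                "gate_replica_summary": replica_summary(gate_series),
                "density_n_frames": dens.n_frames,
                "density_n_clipped": dens.n_clipped,
            })
        except Exception as exc:
            report.failures.append({"job": job.get("id", str(job)), "error": str(exc)})
    return report


def _criteria_from(cfg_entry, default: HBondCriteria, label: str) -> HBondCriteria:
    if cfg_entry is None:
        return default
    return HBondCriteria(float(cfg_entry[0]), float(cfg_entry[1]), label)


def run_hbond_campaign(cfg: AnalysisConfig) -> Report:
    """Per audit job: verdict counts and the per-pair geometry table."""
    report = Report("hbond", provenance=_provenance(cfg))
    for job in cfg.hbond_jobs:
        try:
            strict = _criteria_from(job.get("strict"), STRICT_DEFAULT, "strict")
            relaxed = _criteria_from(job.get("relaxed"), RELAXED_DEFAULT, "relaxed")
            s, _ = _load_structure(cfg, job["structure"])
            pairs_df = pd.read_csv(Path(job["pairs"]), sep="\t")
            pairs = [
                ((str(r.donor_chain), int(r.donor_res), str(r.donor_atom)),
                 (str(r.acceptor_chain), int(r.acceptor_res), str(r.acceptor_atom)))
                for r in pairs_df.itertuples()
            ]
            if not pairs:
                report.entries.append({
                    "structure": job["structure"], "n_pairs": 0,
                    "counts": {"strict": 0, "relaxed_only": 0, "fail": 0,
                               "water_mediated": 0},
                    "warning": "empty pairs file",
                    "criteria": {"strict": [strict.max_da, strict.min_angle],
                                 "relaxed": [relaxed.max_da, relaxed.min_angle]},
                })
                continue
            audit = audit_network(s, pairs, strict, relaxed)
            report.entries.append({
                "structure": job["structure"],
                "n_pairs": len(pairs),
                "counts": audit.counts,
                "criteria": {"strict": [strict.max_da, strict.min_angle],
                             "relaxed": [relaxed.max_da, relaxed.min_angle]},
                "pairs": audit.to_rows(),
            })
        except Exception as exc:
            report.failures.append({"job": job.get("structure", str(job)),
                                    "error": str(exc)})
    return report
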