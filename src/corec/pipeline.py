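"""End-to-end orchestration: quantify -> motifs -> match -> network.

`analyze_experiments` is the library entry point used by the CLI and by the
simulation-recovery tests; `run_pipeline` drives a full run from a YAML
config and writes every stage artifact plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as corec_io
from .clusters import TFClusterSet, read_clusters
from .design import read_design
from .match import (ED_CONDITION, ED_REPLICATE, MIN_OVERLAP, N_NULL,
                    P_ADJ_SIGNIFICANT, ReplicateGroup, assign_cluster,
                    compare_to_reference, condition_conserved, replicate_filter)
from .motifs import CorecPPM, build_ppm, quality_filter
from .network import RecruitmentMatrix, build_matrix, call_condition_status
from .quantify import quantify, zprofile_to_frame
from .types import ArrayDesign, ReferenceMotif

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every filtering constant of the method, with its published default."""

    ms: float = 0.4
    ic: float = 1.0
    ed_replicate: float = ED_REPLICATE
    ed_condition: float = ED_CONDITION
    p_adj: float = P_ADJ_SIGNIFICANT
    delta_ms: float = 1.5
    promiscuity_ms: float = 3.0
    promiscuity_kats: int = 4
    p_floor: float = 1e-5
    min_overlap: int = MIN_OVERLAP


@dataclass
class AnalysisResult:
    ppms: list[CorecPPM]
    groups: list[ReplicateGroup]
    matrix: RecruitmentMatrix
    conserved: set[tuple[str, str]]
    calls: pd.DataFrame | None
    conserved_probesets: set[tuple[str, str]] = field(default_factory=set)


def analyze_experiments(design: ArrayDesign,
                        tables: Mapping[tuple[str, str, int], pd.DataFrame],
                        refs: Sequence[ReferenceMotif], clusters: TFClusterSet,
                        seed: int = 0, n_null: int = N_NULL,
                        thresholds: Thresholds | None = None) -> AnalysisResult:
    """Run quantification through network assembly for a set of experiments.

    ``tables`` maps (cof, condition, replicate) to fluorescence tables. When
    exactly two conditions are present, gained/lost/conserved calls are
    produced; otherwise ``calls`` is None.
    """
    th = thresholds or Thresholds()
    rng = np.random.default_rng(seed)

    # 1. z-scores and recruitment motifs per experiment
    ppms_by_group: dict[tuple[str, str, str], list[CorecPPM]] = {}
    all_ppms: list[CorecPPM] = []
    for (cof, condition, replicate), table in sorted(tables.items()):
        zp = quantify(table, design,
                      meta={"cof": cof, "condition": condition, "replicate": replicate})
        for pset in design.probesets:
            ppm = build_ppm(zp, pset)
            all_ppms.append(ppm)
            if quality_filter(ppm, th.ms, th.ic).passed:
                ppms_by_group.setdefault((pset.probeset_id, cof, condition), []).append(ppm)

    # 2. replicate filter and best-match cluster assignment
    groups: list[ReplicateGroup] = []
    for (pid, cof, condition), members in sorted(ppms_by_group.items()):
        grp = replicate_filter(members, th.ed_replicate)
        if grp.replicated:
            matches = [compare_to_reference(m, refs, th.min_overlap, n_null, rng)
                       for m in grp.members]
            assign_cluster(grp, matches, clusters)
        groups.append(grp)

    assigned = [g for g in groups if g.replicated and g.assigned_cluster is not None]
    matrix = build_matrix(assigned)

    # 3. cross-condition conservation at the probe-set level, lifted to cells
    conditions = sorted({c for (_, c, _) in tables.keys()})
    conserved: set[tuple[str, str]] = set()
    conserved_probesets: set[tuple[str, str]] = set()
    calls = None
    if len(conditions) == 2:
        c1, c2 = conditions
        by_key = {(g.probeset_id, g.cof, g.condition): g for g in assigned}
        for (pid, cof, cond) in list(by_key):
            if cond != c1:
                continue
            other = by_key.get((pid, cof, c2))
            g1 = by_key[(pid, cof, c1)]
            if other is None:
                continue
            if condition_conserved(g1, other, th.ed_condition):
                conserved_probesets.add((pid, cof))
                if g1.assigned_cluster == other.assigned_cluster:
                    conserved.add((cof, g1.assigned_cluster))
        calls = call_condition_status(matrix, conserved, conditions)

    return AnalysisResult(ppms=all_ppms, groups=groups, matrix=matrix,
                          conserved=conserved, calls=calls,
                          conserved_probesets=conserved_probesets)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run design loading, quantification, motif building, matching and
    network assembly from a config; returns (and writes) the manifest.

    Required config keys: ``design`` (directory from `corec design`),
    ``fluorescence`` (list of {cof, condition, replicate, path}), ``refs``
    (MEME/JASPAR motif library), ``clusters`` (cluster TSV). Optional:
    ``seed``, ``n_null``, ``thresholds`` (mapping onto Thresholds fields).
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        config = load_config(config_path)
    for key in ("design", "fluorescence", "refs", "clusters"):
        if key not in config:
            raise ValueError(f"config missing required field: {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = read_design(config["design"])
    refs = corec_io.read_motifs(config["refs"])
    clusters = read_clusters(config["clusters"])
    seed = int(config.get("seed", 0))
    n_null = int(config.get("n_null", N_NULL))
    th = Thresholds(**config.get("thresholds", {}))

    tables = {}
    inputs = []
    for entry in config["fluorescence"]:
        p = Path(entry["path"])
        if not p.exists():
            raise FileNotFoundError(f"fluorescence table not found: {p}")
        tables[(entry["cof"], entry["condition"], int(entry["replicate"]))] = \
            corec_io.read_fluor_table(p)
        inputs.append(p)

    result = analyze_experiments(design, tables, refs, clusters, seed=seed,
                                 n_null=n_null, thresholds=th)

    corec_io.write_meme(
        [p for p in result.ppms], out / "recruitment_motifs.meme",
        name_extra={p.id: f"MS={p.ms.ms:.3f} beta={p.beta:.2f}" for p in result.ppms})
    corec_io.write_tsv(result.matrix.table, out / "recruitment_matrix.tsv")
    group_rows = [{
        "probeset_id": g.probeset_id, "cof": g.cof, "condition": g.condition,
        "n_members": len(g.members), "replicated": g.replicated,
        "cluster": g.assigned_cluster or "",
        "best_target": g.best_match.target_id if g.best_match else "",
        "best_p_adj": g.best_match.p_adj if g.best_match else "",
    } for g in result.groups]
    corec_io.write_tsv(pd.DataFrame(group_rows), out / "replicate_groups.tsv")
    if result.calls is not None:
        corec_io.write_tsv(result.calls, out / "condition_calls.tsv")

    manifest = {
        "seed": seed,
        "n_null": n_null,
        "thresholds": th.__dict__,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "refs": str(config["refs"]),
        "n_probesets": len(design.probesets),
        "n_ppms": len(result.ppms),
        "n_replicated_groups": sum(g.replicated for g in result.groups),
        "n_interactions": len(result.matrix.table),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
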