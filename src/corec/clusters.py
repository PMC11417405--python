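"""TF motif-specificity clusters.

Reference motifs are grouped by agglomerative complete-linkage clustering of
a motif-comparison distance, d = max(15 + log10(p), 0), so perfect matches
(p <= 1e-15) are at distance 0 and unrelated motifs (p = 1) at 15. Merging
stops once every inter-cluster complete-linkage distance exceeds the cut
height. External motif collections are mapped onto the clusters by best
match below a p-value cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ReferenceMotif

P_MAP_CUTOFF = 0.0005
D_MAX = 15.0


def motif_distance(p: float) -> float:
    """max(15 + log10(p), 0) for a comparison p-value in (0, 1]."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return max(D_MAX + math.log10(p), 0.0)


@dataclass
class TFCluster:
    cluster_id: str
    name: str
    members: tuple[str, ...]


@dataclass
class TFClusterSet:
    clusters: list[TFCluster]

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.clusters:
            if not c.members:
                raise ValueError(f"cluster {c.cluster_id} is empty")
            overlap = seen & set(c.members)
            if overlap:
                raise ValueError(f"motif in multiple clusters: {sorted(overlap)[0]}")
            seen |= set(c.members)
        self._index = {m: c.cluster_id for c in self.clusters for m in c.members}

    def cluster_of(self, motif_id: str) -> Optional[str]:
        return self._index.get(motif_id)

    def __len__(self) -> int:
        return len(self.clusters)


def complete_linkage(ids: Sequence[str], dist: np.ndarray, cut_height: float) -> TFClusterSet:
    """Agglomerative complete-linkage clustering cut at ``cut_height``.

    Clusters merge while the minimal complete-linkage (maximum cross-pair)
    distance is <= cut_height. Ties break toward the pair whose combined,
    sorted member-id tuple is lexicographically smallest, making the result
    independent of input order.
    """
    dist = np.asarray(dist, float)
    if dist.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix diagonal must be zero")

    order = np.argsort(np.array(ids, dtype=object))
    groups: list[list[int]] = [[int(i)] for i in order]  # index lists, id-sorted inside logic

    def linkage(a: list[int], b: list[int]) -> float:
        return float(dist[np.ix_(a, b)].max())

    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = linkage(groups[i], groups[j])
                if d > cut_height:
                    continue
                key = tuple(sorted(ids[k] for k in groups[i] + groups[j]))
                if best is None or (d, key) < (best[0], best[1]):
                    best = (d, key, i, j)
        if best is None:
            break
        _, _, i, j = best
        merged = groups[i] + groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]

    named = sorted((tuple(sorted(ids[k] for k in g)) for g in groups), key=lambda t: t[0])
    clusters = [TFCluster(cluster_id=f"C{n + 1:03d}", name=members[0], members=members)
                for n, members in enumerate(named)]
    return TFClusterSet(clusters=clusters)


def cluster_reference_library(refs: Sequence[ReferenceMotif], cut_height: float,
                              n_null: int = 2000, seed: int = 0,
                              min_overlap: int = 5) -> TFClusterSet:
    """Cluster a reference library using this package's motif comparison p-values."""
    from .match import compare_to_reference

    rng = np.random.default_rng(seed)
    ids = [r.id for r in refs]
    n = len(refs)
    dist = np.zeros((n, n))
    for i, q in enumerate(refs):
        results = {m.target_id: m for m in compare_to_reference(
            q, refs, min_overlap=min_overlap, n_null=n_null, seed=rng)}
        for j, t in enumerate(refs):
            if j == i:
                continue
            p = results[t.id].p if t.id in results else 1.0
            dist[i, j] = max(dist[i, j], motif_distance(p))
    dist = np.maximum(dist, dist.T)  # symmetrize: comparisons are directional
    np.fill_diagonal(dist, 0.0)
    return complete_linkage(ids, dist, cut_height)


def map_motif_to_cluster(motif: ReferenceMotif, clusterset: TFClusterSet,
                         refs: Sequence[ReferenceMotif], p_cutoff: float = P_MAP_CUTOFF,
                         n_null: int = 2000, seed: int = 0,
                         min_overlap: int = 5) -> Optional[str]:
    """Best-match assignment of an external motif onto existing clusters.

    Returns the cluster id of the lowest-p clustered reference if that raw
    p-value is below ``p_cutoff``, else None.
    """
    from .match import compare_to_reference

    clustered = [r for r in refs if clusterset.cluster_of(r.id) is not None]
    matches = compare_to_reference(motif, clustered, min_overlap=min_overlap,
                                   n_null=n_null, seed=seed)
    if not matches:
        return None
    best = min(matches, key=lambda m: (m.p, m.ed, m.target_id))
    if best.p < p_cutoff:
        return clusterset.cluster_of(best.target_id)
    return None


def write_clusters(cs: TFClusterSet, path: str | Path) -> None:
    rows = [{"cluster_id": c.cluster_id, "name": c.name, "motif_id": m}
            for c in cs.clusters for m in c.members]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> TFClusterSet:
    df = pd.read_csv(path, sep="\t")
    clusters = []
    for (cid, name), grp in df.groupby(["cluster_id", "name"], sort=True):
        clusters.append(TFCluster(cluster_id=str(cid), name=str(name),
                                  members=tuple(sorted(grp["motif_id"].astype(str)))))
    return TFClusterSet(clusters=clusters)
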