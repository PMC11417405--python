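"""The COF x condition x TF-cluster recruitment network and its classifications.

Each cell of the recruitment matrix holds the maximum motif strength over
the probe sets that passed quality + replicate filtering and were assigned
to that TF cluster for that COF and condition. Downstream calls classify
interactions across a condition pair (gained / lost / conserved), clusters
across KATs (strongly induced, partially induced, diminished, KAT-specific),
constitutive promiscuous recruitment, and novelty against public PPI edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .match import ReplicateGroup

log = logging.getLogger(__name__)

DELTA_MS_THRESHOLD = 1.5
PROMISCUITY_MS_MIN = 3.0
PROMISCUITY_KAT_MIN_EXCLUSIVE = 4


@dataclass
class RecruitmentMatrix:
    """Long-format network: one row per (cof, condition, cluster) cell."""

    table: pd.DataFrame  # columns: cof, condition, cluster, ms, probesets

    def cell(self, cof: str, condition: str, cluster: str) -> float:
        t = self.table
        sel = t[(t.cof == cof) & (t.condition == condition) & (t.cluster == cluster)]
        return float(sel.ms.iloc[0]) if len(sel) else np.nan

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table.condition.unique())


def group_ms(group: ReplicateGroup) -> float:
    return max(m.ms.ms for m in group.members)


def build_matrix(groups: Iterable[ReplicateGroup]) -> RecruitmentMatrix:
    """Max motif strength per (cof, condition, cluster) over assigned groups."""
    rows = []
    for g in groups:
        if not g.replicated or g.assigned_cluster is None:
            continue
        rows.append({"cof": g.cof, "condition": g.condition,
                     "cluster": g.assigned_cluster, "ms": group_ms(g),
                     "probeset": g.probeset_id})
    if not rows:
        return RecruitmentMatrix(pd.DataFrame(
            columns=["cof", "condition", "cluster", "ms", "probesets"]))
    df = pd.DataFrame(rows)
    agg = (df.groupby(["cof", "condition", "cluster"], as_index=False)
             .agg(ms=("ms", "max"), probesets=("probeset", lambda s: ",".join(sorted(s)))))
    return RecruitmentMatrix(agg)


def call_condition_status(matrix: RecruitmentMatrix,
                          conserved: set[tuple[str, str]],
                          conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Gained / lost / conserved calls per (cof, cluster) across two conditions.

    ``conserved`` holds (cof, cluster) pairs whose motifs passed the
    cross-condition ED filter. An interaction present in both conditions
    without a conserved flag is split into one gained and one lost call (the
    two conditions recruit via motifs too dissimilar to be the same
    interaction). Delta motif strength is condition2 - condition1 with
    absence counted as 0.
    """
    conds = list(conditions) if conditions is not None else matrix.conditions
    if len(conds) != 2:
        raise ValueError(f"pairwise API: need exactly 2 conditions, got {conds}")
    c1, c2 = conds
    t = matrix.table
    piv = t.pivot_table(index=["cof", "cluster"], columns="condition", values="ms")
    rows = []
    for (cof, cluster), r in piv.iterrows():
        in1 = c1 in r and not np.isnan(r.get(c1, np.nan))
        in2 = c2 in r and not np.isnan(r.get(c2, np.nan))
        ms1 = float(r[c1]) if in1 else 0.0
        ms2 = float(r[c2]) if in2 else 0.0
        delta = ms2 - ms1
        if in1 and in2:
            if (cof, cluster) in conserved:
                rows.append({"cof": cof, "cluster": cluster, "status": "conserved",
                             "delta_ms": delta})
            else:
                rows.append({"cof": cof, "cluster": cluster, "status": "gained",
                             "delta_ms": ms2})
                rows.append({"cof": cof, "cluster": cluster, "status": "lost",
                             "delta_ms": -ms1})
        elif in2:
            rows.append({"cof": cof, "cluster": cluster, "status": "gained", "delta_ms": delta})
        else:
            rows.append({"cof": cof, "cluster": cluster, "status": "lost", "delta_ms": delta})
    return pd.DataFrame(rows, columns=["cof", "cluster", "status", "delta_ms"])


def status_fractions(calls: pd.DataFrame) -> dict[str, float]:
    total = len(calls)
    counts = calls.status.value_counts()
    return {s: counts.get(s, 0) / total for s in ("gained", "lost", "conserved")}


def classify_response(calls: pd.DataFrame, threshold: float = DELTA_MS_THRESHOLD) -> pd.DataFrame:
    """Response class per TF cluster across the recruiting KATs.

    A KAT is "constitutive" for a cluster when its interaction is conserved
    with |delta MS| <= threshold. Classes, in precedence order:
    kat_specific (exactly one recruiting KAT), strongly_induced (all KATs
    delta MS > threshold), partially_induced (>= 2 induced KATs plus >= 1
    constitutive), diminished (>= 2 KATs delta MS < -threshold plus >= 1
    constitutive), else none.
    """
    rows = []
    for cluster, grp in calls.groupby("cluster"):
        per_kat = grp.groupby("cof").agg(
            delta=("delta_ms", "max"),
            conservedf=("status", lambda s: (s == "conserved").any()))
        n = len(per_kat)
        induced = per_kat.delta > threshold
        diminished = per_kat.delta < -threshold
        constitutive = per_kat.conservedf & (per_kat.delta.abs() <= threshold)
        if n == 1:
            cls = "kat_specific"
        elif induced.all():
            cls = "strongly_induced"
        elif induced.sum() >= 2 and constitutive.any():
            cls = "partially_induced"
        elif diminished.sum() >= 2 and constitutive.any():
            cls = "diminished"
        else:
            cls = "none"
        rows.append({"cluster": cluster, "response": cls, "n_kats": n})
    return pd.DataFrame(rows, columns=["cluster", "response", "n_kats"])


def promiscuity(matrix: RecruitmentMatrix, ms_min: float = PROMISCUITY_MS_MIN,
                kat_min_exclusive: int = PROMISCUITY_KAT_MIN_EXCLUSIVE) -> list[str]:
    """Clusters with more than ``kat_min_exclusive`` KATs at MS > ms_min in
    both conditions (constitutive promiscuous recruiters)."""
    conds = matrix.conditions
    if len(conds) != 2:
        raise ValueError("promiscuity is defined over a condition pair")
    t = matrix.table
    qual = t[t.ms > ms_min]
    out = []
    for cluster, grp in qual.groupby("cluster"):
        both = grp.groupby("cof")["condition"].nunique()
        if int((both == 2).sum()) > kat_min_exclusive:
            out.append(cluster)
    return sorted(out)


def annotate_novelty(interactions: pd.DataFrame, ppi_edges: pd.DataFrame,
                     tf_to_cluster: Mapping[str, str | None]) -> pd.DataFrame:
    """Flag each (cof, cluster) interaction as previously reported or not.

    Reported iff any TF mapped to that cluster has a PPI edge with that COF.
    ``ppi_edges`` needs columns tf_gene and cof.
    """
    covered = set()
    for _, e in ppi_edges.iterrows():
        cl = tf_to_cluster.get(str(e.tf_gene))
        if cl is not None:
            covered.add((str(e.cof), cl))
    out = interactions[["cof", "cluster"]].drop_duplicates().copy()
    out["reported"] = [(c, cl) in covered for c, cl in zip(out.cof, out.cluster)]
    return out.reset_index(drop=True)


def recruitment_heatmap(matrix: RecruitmentMatrix, path: str, cmap: str = "viridis"):
    """Render the network as a clusters x (cof, condition) heatmap PNG/PDF.

    Cell intensity is the maximum motif strength; absent interactions are
    blank. Returns the pivoted frame that was drawn.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = matrix.table
    piv = t.pivot_table(index="cluster", columns=["cof", "condition"], values="ms")
    fig, ax = plt.subplots(figsize=(max(3, 0.6 * piv.shape[1] + 2),
                                    max(3, 0.3 * piv.shape[0] + 1)))
    im = ax.imshow(piv.to_numpy(float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(piv.shape[1]))
    ax.set_xticklabels([f"{c}\n{d}" for c, d in piv.columns], fontsize=7)
    ax.set_yticks(range(piv.shape[0]))
    ax.set_yticklabels(piv.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="motif strength")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return piv


def row_permutation_test(presence: pd.DataFrame, col_celltype: Mapping[str, str],
                         n_perm: int = 10000, seed: int = 0) -> dict:
    """Permutation z-score for cell-type specificity of cluster recruitment.

    ``presence`` is a binary matrix, rows = TF clusters, columns = experiment
    columns each labeled with a cell type via ``col_celltype`` (at least two
    cell types). The statistic is the number of clusters whose presences are
    confined to exactly one cell type; the null permutes each row's entries
    across columns independently and uniformly.
    """
    cols = list(presence.columns)
    cts = np.array([col_celltype[c] for c in cols])
    unique_cts = sorted(set(cts))
    if len(unique_cts) != 2:
        raise ValueError("test restricted to exactly 2 cell types")
    M = presence.to_numpy(dtype=bool)

    def stat(mat: np.ndarray) -> int:
        s = 0
        for ct in unique_cts:
            in_ct = mat[:, cts == ct].any(axis=1)
            out_ct = mat[:, cts != ct].any(axis=1)
            s += int(np.count_nonzero(in_ct & ~out_ct))
        return s

    obs = stat(M)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    perm = M.copy()
    for b in range(n_perm):
        for r in range(M.shape[0]):
            perm[r] = M[r, rng.permutation(M.shape[1])]
        null[b] = stat(perm)
    sd = float(null.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate presence matrix: null distribution has zero variance")
    return {"observed": obs, "null_mean": float(null.mean()), "null_sd": sd,
            "z": (obs - float(null.mean())) / sd}
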