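"""Ground-truth simulators for every pipeline stage.

The PBM simulator plants a PWM energy model under each consensus + SV probe
set: a probe's binding energy is the sum of per-position mismatch penalties
eps_i(k) = -log(P_ik / max_k P_ik) taken from the planted probability
matrix, and its expected fluorescence is

    B * (1 + g * exp(-E)) * eta

with B a lognormal background draw, eta multiplicative spot noise, and g a
per-(probe set, COF, condition) recruitment gain. Gain 0 probe sets are true
negatives; the gains and the seed fully determine expected outputs. The
genome simulator plants cluster consensus sites into promoter windows and
draws promoter acetylation levels that increase linearly with the number of
distinct planted recruiting clusters.

Default noise emulates a quiet array: background log-fluorescence sigma
0.3, 10% multiplicative spot CV, five replicate spots per probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_PRIMER, assemble_probe, enumerate_sv_probes
from .types import (ArrayDesign, BASES, ConsensusSite, ProbeRecord, ProbeSet,
                    ReferenceMotif)

BG_MU = math.log(300.0)  # background fluorescence ~300 a.u.
BG_SIGMA = 0.3
SPOT_CV = 0.10
GAIN_LADDER = (0.0, 1.0, 4.0, 16.0, 64.0)
HIGH_GAIN = 64.0


def random_reference_motifs(n: int, rng: np.random.Generator,
                            length_range: tuple[int, int] = (9, 14),
                            dominant_range: tuple[float, float] = (0.80, 0.95)) -> list[ReferenceMotif]:
    """Random sharp PWMs emulating curated TF core motifs.

    Each position has one dominant base with probability drawn from
    ``dominant_range`` and the remainder split evenly; consensus sequences
    are i.i.d. random, so motifs are mutually dissimilar with high
    probability.
    """
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        mat = np.empty((L, 4))
        for pos in range(L):
            dom = rng.uniform(*dominant_range)
            k = int(rng.integers(4))
            row = np.full(4, (1 - dom) / 3)
            row[k] = dom
            mat[pos] = row
        out.append(ReferenceMotif(id=f"SYN{i:03d}", name=f"SYN{i:03d}", matrix=mat))
    return out


def random_background_probes(n: int, rng: np.random.Generator,
                             primer: str = DEFAULT_PRIMER) -> list[ProbeRecord]:
    """Background probes with i.i.d. random 34-nt windows (no genome needed)."""
    out = []
    for i in range(n):
        window = "".join(rng.choice(list(BASES), size=34))
        out.append(ProbeRecord(probe_id=f"bg_{i:04d}", probeset_id=None,
                               category="background", sv_position=None, sv_base=None,
                               site34=window, full_sequence="GC" + window + primer))
    return out


def synthetic_design(motifs: Sequence[ReferenceMotif], n_background: int,
                     rng: np.random.Generator, primer: str = DEFAULT_PRIMER,
                     replicate_spots: int = 5) -> ArrayDesign:
    """In-memory array design over the given motifs' consensus sites."""
    from .design import consensus_from_ppm

    probesets = [enumerate_sv_probes(consensus_from_ppm(m), primer) for m in motifs]
    return ArrayDesign(probesets=probesets,
                       background_probes=random_background_probes(n_background, rng, primer),
                       primer=primer, replicate_spots=replicate_spots)


@dataclass
class SimTruth:
    """Planted recruitment ground truth for a PBM simulation."""

    motifs: dict[str, np.ndarray]  # probeset_id -> planted PPM (L x 4)
    gains: dict[tuple[str, str, str], float]  # (probeset, cof, condition) -> g
    bg_mu: float = BG_MU
    bg_sigma: float = BG_SIGMA
    spot_cv: float = SPOT_CV
    n_spots: int = 5

    def gain(self, probeset_id: str, cof: str, condition: str) -> float:
        return self.gains.get((probeset_id, cof, condition), 0.0)


def truth_from_motifs(motifs: Sequence[ReferenceMotif],
                      gains: Mapping[tuple[str, str, str], float]) -> SimTruth:
    for g in gains.values():
        if g < 0:
            raise ValueError("recruitment gains must be non-negative")
    return SimTruth(motifs={m.id: m.matrix for m in motifs}, gains=dict(gains))


def probe_energy(site: str, ppm: np.ndarray) -> float:
    """Mismatch-additive binding energy of a site under the planted PPM."""
    eps = -np.log(ppm / ppm.max(axis=1, keepdims=True))
    idx = [BASES.index(b) for b in site]
    return float(eps[np.arange(len(site)), idx].sum())


def _probe_site(pset: ProbeSet, probe: ProbeRecord) -> str:
    if probe.category == "consensus":
        return pset.consensus.sequence
    s = pset.consensus.sequence
    i = probe.sv_position - 1
    return s[:i] + probe.sv_base + s[i + 1:]


def simulate_pbm(design: ArrayDesign, truth: SimTruth, cof: str, condition: str,
                 replicate: int, seed: int) -> pd.DataFrame:
    """Simulate one array experiment as a probe-level fluorescence table.

    Deterministic for a given seed; the channel column carries the COF name.
    """
    rng = np.random.default_rng(seed)
    spot_sigma = math.sqrt(math.log(1.0 + truth.spot_cv ** 2))
    rows = []

    def emit(probe: ProbeRecord, mean_boost: float):
        B = rng.lognormal(truth.bg_mu, truth.bg_sigma, size=truth.n_spots)
        eta = rng.lognormal(0.0, spot_sigma, size=truth.n_spots)
        fl = B * mean_boost * eta
        for s, v in enumerate(fl, start=1):
            rows.append((probe.probe_id, s, cof, float(v)))

    for pset in design.probesets:
        g = truth.gain(pset.probeset_id, cof, condition)
        if g < 0:
            raise ValueError("negative gain")
        ppm = truth.motifs.get(pset.probeset_id)
        for probe in pset.probes:
            if g == 0 or ppm is None:
                emit(probe, 1.0)
            else:
                E = probe_energy(_probe_site(pset, probe), ppm)
                emit(probe, 1.0 + g * math.exp(-E))
    for probe in design.background_probes:
        emit(probe, 1.0)
    df = pd.DataFrame(rows, columns=["probe_id", "spot", "channel", "fluorescence"])
    df.attrs.update({"cof": cof, "condition": condition, "replicate": replicate})
    return df


def simulate_condition_shift(probeset_plan: Mapping[str, str], cof: str,
                             conditions: tuple[str, str] = ("resting", "stimulated"),
                             g_high: float = HIGH_GAIN, g_low: float = 0.0) -> dict:
    """Turn a gained/lost/conserved plan into per-condition gain assignments.

    gained: low gain in condition 1, high in condition 2; lost: the reverse;
    conserved: high in both. Unlisted probe sets stay at gain 0.
    """
    c1, c2 = conditions
    gains: dict[tuple[str, str, str], float] = {}
    for pid, label in probeset_plan.items():
        if label == "gained":
            gains[(pid, cof, c1)] = g_low
            gains[(pid, cof, c2)] = g_high
        elif label == "lost":
            gains[(pid, cof, c1)] = g_high
            gains[(pid, cof, c2)] = g_low
        elif label == "conserved":
            gains[(pid, cof, c1)] = g_high
            gains[(pid, cof, c2)] = g_high
        else:
            raise ValueError(f"unknown plan label {label!r} for {pid}")
    return gains


@dataclass
class SyntheticGenome:
    """A planted genome with promoters, peaks and differential regions."""

    sequences: dict[str, str]
    tss: pd.DataFrame  # gene, contig, tss, strand
    h3k27ac: pd.DataFrame  # chrom, start, end, name, score
    atac: pd.DataFrame
    diffbind: pd.DataFrame  # contig, start, end, log2fc, fdr
    planted: pd.DataFrame  # gene, n_clusters, clusters, positions
    acetylation_model: dict = field(default_factory=dict)


def simulate_genome(cluster_sites: Mapping[str, str], site_plan: Sequence[int],
                    seed: int, promoter_spacing: int = 2000,
                    level_base: float = 3.0, level_per_cluster: float = 2.0,
                    level_noise_sd: float = 0.5,
                    induced_fraction: float = 0.2) -> SyntheticGenome:
    """Build a synthetic genome whose promoter acetylation tracks planted sites.

    ``cluster_sites`` maps TF cluster ids to the consensus site to plant;
    ``site_plan`` gives, per promoter, the number of distinct clusters to
    plant (0 allowed). The acetylation level of each promoter's H3K27ac peak
    is level_base + level_per_cluster * k + Normal(0, level_noise_sd),
    floored at 0.1; every promoter gets an ATAC peak so k = 0 promoters with
    no H3K27ac peak would still score 0. A random subset of promoters gets a
    differential region at log2FC 2 (induced) and the rest at 0.05.
    """
    rng = np.random.default_rng(seed)
    cluster_ids = sorted(cluster_sites)
    n = len(site_plan)
    contig = "chrSim"
    length = promoter_spacing * (n + 1)
    seq = list(rng.choice(list(BASES), size=length))

    tss_rows, peak_rows, atac_rows, db_rows, planted_rows = [], [], [], [], []
    for i, k in enumerate(site_plan):
        if k > len(cluster_ids):
            raise ValueError(f"plan requests {k} clusters but only {len(cluster_ids)} available")
        tss = promoter_spacing * (i + 1)
        p_start, p_end = tss - 500, tss + 100
        chosen = list(rng.choice(cluster_ids, size=k, replace=False))
        positions = []
        occupied: list[tuple[int, int]] = []
        for cl in chosen:
            site = cluster_sites[cl]
            for _ in range(200):
                pos = int(rng.integers(p_start, p_end - len(site)))
                if all(pos + len(site) <= s or pos >= e for s, e in occupied):
                    occupied.append((pos, pos + len(site)))
                    break
            else:
                raise RuntimeError("could not place non-overlapping sites")
            seq[pos:pos + len(site)] = list(site)
            positions.append(pos)
        level = max(0.1, level_base + level_per_cluster * k + rng.normal(0, level_noise_sd))
        gene = f"gene{i:03d}"
        tss_rows.append({"gene": gene, "contig": contig, "tss": tss, "strand": "+"})
        peak_rows.append({"chrom": contig, "start": p_start - 50, "end": p_end + 50,
                          "name": f"peak_{gene}", "score": level})
        atac_rows.append({"chrom": contig, "start": p_start - 50, "end": p_end + 50,
                          "name": f"atac_{gene}", "score": 1.0})
        induced = rng.random() < induced_fraction
        db_rows.append({"contig": contig, "start": p_start, "end": p_end,
                        "log2fc": 2.0 if induced else 0.05, "fdr": 0.001 if induced else 0.9})
        planted_rows.append({"gene": gene, "n_clusters": k,
                             "clusters": ",".join(chosen),
                             "positions": ",".join(map(str, positions))})
    return SyntheticGenome(
        sequences={contig: "".join(seq)},
        tss=pd.DataFrame(tss_rows),
        h3k27ac=pd.DataFrame(peak_rows),
        atac=pd.DataFrame(atac_rows),
        diffbind=pd.DataFrame(db_rows),
        planted=pd.DataFrame(planted_rows),
        acetylation_model={"base": level_base, "per_cluster": level_per_cluster,
                           "noise_sd": level_noise_sd})
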