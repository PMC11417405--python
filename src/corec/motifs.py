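"""Recruitment motifs: delta-z matrices, motif strength, and Boltzmann PPMs.

A consensus + single-variant probe set yields an L x 4 matrix of z-scores
z_ik, one per base k at each site position i (the consensus probe's z fills
every consensus-base cell). The recruitment motif is the deviation from the
per-position median,

    dz_ik = z_ik - mu_i,        mu_i = median_k z_ik,

which behaves like a binding energy matrix: variants that hurt recruitment
drop below the position median. Aggregate recruitment for the probe set is
the motif strength (MS), the median z of the 10 top-scoring probes. For
comparison against reference PWM libraries, z-scores are converted to a
position probability matrix with a Boltzmann weight,

    P_ik = exp(beta * z_ik) / sum_k exp(beta * z_ik),

with beta adapted to the motif strength: beta = 4 for MS <= 0, linearly
decreasing to beta = 1 at MS >= 6. Weak motifs therefore get sharpened
(their z spread is small) and strong motifs are left close to raw weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BASE_INDEX, BASES, ProbeSet, ZProfile

log = logging.getLogger(__name__)

MS_TOP_N = 10
MS_THRESHOLD = 0.4
IC_THRESHOLD = 1.0
IC_WINDOW = 5


@dataclass
class DeltaZMotif:
    """z-score matrix, per-position medians, and the delta-z recruitment motif."""

    probeset_id: str
    z_matrix: np.ndarray  # L x 4, (A,C,G,T)
    mu: np.ndarray  # length L
    delta: np.ndarray  # L x 4

    @property
    def length(self) -> int:
        return self.z_matrix.shape[0]


@dataclass(frozen=True)
class MotifStrengthScore:
    """Median z of the top-scoring probes of a probe set."""

    ms: float
    contributing_probe_ids: tuple[str, ...]


@dataclass
class CorecPPM:
    """A recruitment motif as a position probability matrix with provenance."""

    id: str
    probeset_id: str
    P: np.ndarray  # L x 4
    beta: float
    ms: MotifStrengthScore
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        rows = self.P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError(f"{self.id}: PPM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.P.shape[0]


def build_delta_z(z: ZProfile, pset: ProbeSet) -> DeltaZMotif:
    """Assemble the L x 4 z matrix for a probe set and subtract row medians.

    Raises KeyError naming the first missing probe.
    """
    L = pset.length
    zm = np.empty((L, 4), float)
    cons_id = pset.consensus_probe.probe_id
    if cons_id not in z.z.index:
        raise KeyError(f"missing probe {cons_id} in z profile")
    z_cons = float(z.z.loc[cons_id])
    for i in range(L):
        cons_base = pset.consensus.sequence[i]
        for k, base in enumerate(BASES):
            if base == cons_base:
                zm[i, k] = z_cons
            else:
                probe = pset.sv_probe(i + 1, base)
                if probe.probe_id not in z.z.index:
                    raise KeyError(f"missing probe {probe.probe_id} in z profile")
                zm[i, k] = float(z.z.loc[probe.probe_id])
    mu = np.median(zm, axis=1)
    return DeltaZMotif(probeset_id=pset.probeset_id, z_matrix=zm, mu=mu,
                       delta=zm - mu[:, None])


def motif_strength(z: ZProfile, pset: ProbeSet, n_top: int = MS_TOP_N) -> MotifStrengthScore:
    """Median z-score of the n_top top-scoring probes of the probe set."""
    ids = [p.probe_id for p in pset.probes]
    if not ids:
        raise ValueError(f"{pset.probeset_id}: empty probe set")
    missing = [i for i in ids if i not in z.z.index]
    if missing:
        raise KeyError(f"missing probe {missing[0]} in z profile")
    zs = z.z.loc[ids].sort_values(ascending=False)
    if len(zs) < n_top:
        log.warning("%s: only %d probes (< %d); motif strength over all probes",
                    pset.probeset_id, len(zs), n_top)
        n_top = len(zs)
    top = zs.iloc[:n_top]
    return MotifStrengthScore(ms=float(np.median(top.to_numpy())),
                              contributing_probe_ids=tuple(top.index))


def adaptive_beta(ms: float) -> float:
    """Motif-strength-dependent Boltzmann scaling; piecewise linear in [1, 4]."""
    if np.isnan(ms):
        raise ValueError("motif strength is NaN")
    if ms <= 0:
        return 4.0
    if ms < 6:
        return 4.0 - 0.5 * ms
    return 1.0


def ppm_from_z(motif: DeltaZMotif, beta: float) -> np.ndarray:
    """Row-wise softmax of beta * z, stabilized by row-max subtraction.

    Using delta-z instead of z gives the identical matrix (shift invariance).
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    x = beta * motif.z_matrix
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


def build_ppm(z: ZProfile, pset: ProbeSet, motif_id: str | None = None) -> CorecPPM:
    """End-to-end recruitment motif for one probe set from one experiment."""
    dz = build_delta_z(z, pset)
    ms = motif_strength(z, pset)
    beta = adaptive_beta(ms.ms)
    P = ppm_from_z(dz, beta)
    mid = motif_id or "{}_{}".format(
        pset.probeset_id,
        "_".join(str(z.meta.get(k)) for k in ("cof", "condition", "replicate") if k in z.meta))
    return CorecPPM(id=mid, probeset_id=pset.probeset_id, P=P, beta=beta, ms=ms,
                    meta=dict(z.meta))


def information_content(P: np.ndarray) -> np.ndarray:
    """Per-position IC in bits against a uniform background: 2 + sum P log2 P."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(P > 0, P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    return 2.0 + term.sum(axis=1)


@dataclass(frozen=True)
class QualityResult:
    passed: bool
    reasons: tuple[str, ...]
    ms: float
    min_window_ic: float


def quality_filter(ppm: CorecPPM, ms_threshold: float = MS_THRESHOLD,
                   ic_threshold: float = IC_THRESHOLD, window: int = IC_WINDOW) -> QualityResult:
    """Motif quality filter: MS above threshold and every 5-position window
    of mean information content above the IC threshold."""
    ic = information_content(ppm.P)
    L = len(ic)
    if L < window:
        log.info("%s: motif shorter than IC window; averaging over all positions", ppm.id)
        window_means = np.array([ic.mean()])
    else:
        csum = np.concatenate([[0.0], np.cumsum(ic)])
        window_means = (csum[window:] - csum[:-window]) / window
    min_win = float(window_means.min())
    reasons = []
    if not ppm.ms.ms > ms_threshold:
        reasons.append(f"motif strength {ppm.ms.ms:.3f} <= {ms_threshold}")
    if not min_win > ic_threshold:
        reasons.append(f"min window IC {min_win:.3f} <= {ic_threshold}")
    return QualityResult(passed=not reasons, reasons=tuple(reasons),
                         ms=ppm.ms.ms, min_window_ic=min_win)


def delta_z_to_frame(dz: DeltaZMotif) -> pd.DataFrame:
    df = pd.DataFrame(dz.delta, columns=list(BASES))
    df.insert(0, "position", np.arange(1, dz.length + 1))
    df.insert(0, "probeset_id", dz.probeset_id)
    return df
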