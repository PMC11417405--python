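"""Motif scoring of genomic regions and promoter-acetylation analyses.

Scanning follows the best-occurrence convention: a PPM becomes a log-odds
model against a uniform 0.25 background, every window on both strands is
scored, and the single best window's score is converted to an exact
single-site p-value by dynamic-programming convolution of the
integer-discretized column score distributions. Regions are reported as
-log10(p) of the best occurrence, floored to 0 when the best p exceeds
1e-5. Promoters are the strand-aware -500/+100 window around the TSS;
their acetylation level is the maximum -log10 p score of overlapping
H3K27ac peaks (0 for ATAC-open but unacetylated promoters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import mannwhitneyu

log = logging.getLogger(__name__)

P_FLOOR = 1e-5
PROMOTER_UP = 500
PROMOTER_DOWN = 100
PSEUDOCOUNT = 0.01
GRANULARITY = 1e-3

_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWMModel:
    """Log-odds scanning model with an exact score-distribution DP.

    ``int_matrix`` holds column scores discretized to multiples of
    ``granularity``; the null distribution of window scores under an i.i.d.
    uniform background is the convolution of the per-column uniform score
    distributions on that integer grid.
    """

    motif_id: str
    logodds: np.ndarray  # L x 4
    granularity: float = GRANULARITY
    int_matrix: np.ndarray = field(init=False)
    _support: np.ndarray = field(init=False, repr=False)
    _tail: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.int_matrix = np.rint(self.logodds / self.granularity).astype(np.int64)
        self._build_distribution()

    @property
    def length(self) -> int:
        return self.logodds.shape[0]

    def _build_distribution(self):
        # convolve per-column score distributions, tracking the running minimum
        cur = np.array([1.0])
        cur_min = 0
        for row in self.int_matrix:
            rmin, rmax = int(row.min()), int(row.max())
            new = np.zeros(len(cur) + (rmax - rmin))
            for v in row:
                new[int(v) - rmin: int(v) - rmin + len(cur)] += 0.25 * cur
            cur = new
            cur_min += rmin
        self._support = np.arange(cur_min, cur_min + len(cur))
        # tail[i] = P(score >= support[i])
        self._tail = np.cumsum(cur[::-1])[::-1]

    def tail_p(self, int_score: int) -> float:
        """Exact P(window score >= int_score) for one position, one strand."""
        idx = np.searchsorted(self._support, int_score, side="left")
        if idx >= len(self._support):
            return 0.0
        return float(min(1.0, self._tail[idx]))


def logodds_from_ppm(ppm, pseudocount: float = PSEUDOCOUNT,
                     granularity: float = GRANULARITY) -> PWMModel:
    """log2((P + pc * 0.25) / (1 + pc) / 0.25) per cell, uniform background."""
    P = np.asarray(ppm.P if hasattr(ppm, "P") else ppm.matrix, float)
    mid = getattr(ppm, "id", getattr(ppm, "motif_id", "pwm"))
    with np.errstate(divide="ignore"):
        lo = np.log2((P + pseudocount * 0.25) / (1.0 + pseudocount) / 0.25)
    lo = np.maximum(lo, -50.0)  # floor zero-probability cells (pseudocount 0)
    return PWMModel(motif_id=mid, logodds=lo, granularity=granularity)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer scores of every window of the sequence; N scores as worst base."""
    L = int_matrix.shape[0]
    n = len(codes) - L + 1
    worst = int_matrix.min(axis=1)
    out = np.zeros(n, dtype=np.int64)
    for i in range(L):
        c = codes[i:i + n]
        col = np.where(c >= 0, int_matrix[i, np.clip(c, 0, 3)], worst[i])
        out += col
    return out


def best_occurrence(seq: str, pwm: PWMModel):
    """Best-scoring occurrence over both strands.

    Returns (score, position, strand, p): score in log2 units, position
    0-based on the forward strand, p the exact single-site tail probability
    of the score. Max-strand semantics: both strands compete per window.
    """
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    codes = _encode(seq)
    fwd = _window_scores(codes, pwm.int_matrix)
    rc_matrix = pwm.int_matrix[::-1, ::-1]  # reverse positions, complement bases
    rev = _window_scores(codes, rc_matrix)
    both = np.maximum(fwd, rev)
    pos = int(np.argmax(both))
    strand = "+" if fwd[pos] >= rev[pos] else "-"
    best_int = int(both[pos])
    return best_int * pwm.granularity, pos, strand, pwm.tail_p(best_int)


@dataclass(frozen=True)
class RegionScore:
    contig: str
    start: int
    end: int
    motif_id: str
    score: float  # -log10 p of best occurrence, 0 if best p > p_floor
    position: Optional[int]
    strand: Optional[str]


def region_score(seq: str, pwm: PWMModel, p_floor: float = P_FLOOR,
                 contig: str = ".", start: int = 0) -> RegionScore:
    """-log10(p) of the single best occurrence; 0 when best p > p_floor."""
    if len(seq) < pwm.length:
        return RegionScore(contig, start, start + len(seq), pwm.motif_id, 0.0, None, None)
    _, pos, strand, p = best_occurrence(seq, pwm)
    if p <= p_floor and p > 0:
        return RegionScore(contig, start, start + len(seq), pwm.motif_id,
                           -np.log10(p), start + pos, strand)
    if p == 0:  # beyond float tail resolution; cap at the distribution floor
        return RegionScore(contig, start, start + len(seq), pwm.motif_id,
                           300.0, start + pos, strand)
    return RegionScore(contig, start, start + len(seq), pwm.motif_id, 0.0, None, None)


def cluster_score(seq: str, pwms: Sequence[PWMModel], p_floor: float = P_FLOOR,
                  contig: str = ".", start: int = 0) -> RegionScore:
    """Max member-motif region score; the TF-cluster-level score of a region."""
    if not pwms:
        raise ValueError("empty motif cluster")
    scores = [region_score(seq, p, p_floor, contig, start) for p in pwms]
    return max(scores, key=lambda r: r.score)


def count_sites(seq: str, pwm: PWMModel, p_floor: float = P_FLOOR) -> int:
    """Greedy left-to-right count of non-overlapping occurrences with p <= p_floor."""
    L = pwm.length
    if len(seq) < L:
        return 0
    codes = _encode(seq)
    fwd = _window_scores(codes, pwm.int_matrix)
    rev = _window_scores(codes, pwm.int_matrix[::-1, ::-1])
    both = np.maximum(fwd, rev)
    count = 0
    i = 0
    while i < len(both):
        if pwm.tail_p(int(both[i])) <= p_floor:
            count += 1
            i += L
        else:
            i += 1
    return count


@dataclass
class PromoterRecord:
    gene: str
    contig: str
    start: int
    end: int
    strand: str
    acetylation: Optional[float] = None  # None = excluded (neither mark nor open)
    change_class: str = "unclassified"


def define_promoters(tss: pd.DataFrame, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN,
                     contig_lengths: Mapping[str, int] | None = None) -> list[PromoterRecord]:
    """Strand-aware promoter windows (0-based half-open) around each gene's TSS.

    Only the first TSS per gene is used; windows are clipped at contig
    bounds with a warning.
    """
    out = []
    for gene, grp in tss.groupby("gene", sort=False):
        r = grp.iloc[0]
        strand = str(r.strand)
        t = int(r.tss)
        if strand == "+":
            s, e = t - up, t + down
        elif strand == "-":
            s, e = t - down, t + up
        else:
            raise ValueError(f"gene {gene}: unknown strand {strand!r}")
        clipped_s = max(0, s)
        clipped_e = e
        if contig_lengths is not None and str(r.contig) in contig_lengths:
            clipped_e = min(e, contig_lengths[str(r.contig)])
        if (clipped_s, clipped_e) != (s, e):
            log.warning("promoter of %s clipped to contig bounds", gene)
        out.append(PromoterRecord(gene=str(gene), contig=str(r.contig),
                                  start=clipped_s, end=clipped_e, strand=strand))
    return out


def _tree(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, r in intervals.iterrows():
        if int(r.end) <= int(r.start):
            raise ValueError(f"malformed interval {r.chrom}:{r.start}-{r.end}")
        trees.setdefault(str(r.chrom), IntervalTree()).addi(int(r.start), int(r.end), r)
    return trees


def promoter_acetylation(promoters: list[PromoterRecord], h3k27ac: pd.DataFrame,
                         atac: pd.DataFrame) -> list[PromoterRecord]:
    """Assign acetylation levels: max overlapping H3K27ac peak score, 0 for
    ATAC-open unacetylated promoters, None (excluded) otherwise."""
    ac_trees = _tree(h3k27ac)
    at_trees = _tree(atac)
    for p in promoters:
        hits = ac_trees.get(p.contig, IntervalTree()).overlap(p.start, p.end)
        if hits:
            p.acetylation = max(float(h.data.score) for h in hits)
        elif at_trees.get(p.contig, IntervalTree()).overlap(p.start, p.end):
            p.acetylation = 0.0
        else:
            p.acetylation = None
    return promoters


def classify_promoter_change(promoters: list[PromoterRecord], diffbind: pd.DataFrame,
                             induced_fc: float = 1.5, unchanged_fc: float = 0.1) -> list[PromoterRecord]:
    """Induced / unchanged / unclassified by overlap with differential regions.

    Overlap with any region at log2FC >= induced_fc wins over overlap with an
    unchanged region (multi-peak rule: a partly changing gene is induced).
    """
    db = diffbind.rename(columns={"contig": "chrom"})
    trees = _tree(db)
    for p in promoters:
        hits = trees.get(p.contig, IntervalTree()).overlap(p.start, p.end)
        fcs = [float(h.data.log2fc) for h in hits]
        if any(fc >= induced_fc for fc in fcs):
            p.change_class = "induced"
        elif any(fc <= unchanged_fc for fc in fcs):
            p.change_class = "unchanged"
        else:
            p.change_class = "unclassified"
    return promoters


def motif_group_counts(seq: str, cluster_pwms: Mapping[str, Sequence[PWMModel]],
                       p_floor: float = P_FLOOR) -> tuple[int, int]:
    """(total qualifying motif hits, distinct clusters with >= 1 hit) in a region.

    A member motif "hits" when its best-occurrence region score is positive;
    heterotypic content is the number of distinct clusters hitting.
    """
    total = 0
    clusters_hit = 0
    for _, pwms in cluster_pwms.items():
        hits = sum(1 for pwm in pwms
                   if len(seq) >= pwm.length and region_score(seq, pwm, p_floor).score > 0)
        total += hits
        if hits:
            clusters_hit += 1
    return total, clusters_hit


def enrichment_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small samples without
    ties, normal approximation with tie correction otherwise)."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
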