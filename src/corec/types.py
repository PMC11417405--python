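"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceMotif:
    """A reference TF binding model: per-position base probabilities (A,C,G,T)."""

    id: str
    name: str
    matrix: np.ndarray

    def __post_init__(self):
        mat = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", mat)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError(f"motif {self.id}: matrix must be Lx4 with L >= 1")
        if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
            raise ValueError(f"motif {self.id}: probabilities outside [0, 1]")
        if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"motif {self.id}: rows must sum to 1 within 1e-6")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ConsensusSite:
    """The consensus sequence collapsed from a reference motif."""

    source_motif_id: str
    sequence: str

    def __post_init__(self):
        if set(self.sequence) - set(BASES):
            raise ValueError(f"consensus {self.source_motif_id}: non-ACGT characters")
        if len(self.sequence) < 1:
            raise ValueError("empty consensus sequence")


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe: 2-nt GC cap + 34-nt binding-site window + 24-nt primer."""

    probe_id: str
    probeset_id: Optional[str]
    category: str  # consensus | sv | background
    sv_position: Optional[int]  # 1-based within the consensus site
    sv_base: Optional[str]
    site34: str
    full_sequence: str

    def __post_init__(self):
        if len(self.full_sequence) != 60:
            raise ValueError(f"{self.probe_id}: probe must be 60 nt")
        if len(self.site34) != 34:
            raise ValueError(f"{self.probe_id}: site window must be 34 nt")
        if self.category not in ("consensus", "sv", "background"):
            raise ValueError(f"{self.probe_id}: unknown category {self.category}")


@dataclass
class ProbeSet:
    """A consensus site plus all its single-variant probes: the unit of motif inference."""

    probeset_id: str
    consensus: ConsensusSite
    probes: list[ProbeRecord]

    @property
    def length(self) -> int:
        return len(self.consensus.sequence)

    @property
    def consensus_probe(self) -> ProbeRecord:
        return next(p for p in self.probes if p.category == "consensus")

    def sv_probe(self, position: int, base: str) -> ProbeRecord:
        """The SV probe carrying ``base`` at 1-based ``position``; KeyError if absent."""
        for p in self.probes:
            if p.category == "sv" and p.sv_position == position and p.sv_base == base:
                return p
        raise KeyError(f"{self.probeset_id}: no SV probe at position {position} base {base}")


@dataclass
class ArrayDesign:
    """The full array layout: probe sets, background probes, primer, spot replication."""

    probesets: list[ProbeSet]
    background_probes: list[ProbeRecord]
    primer: str
    replicate_spots: int = 5

    def __post_init__(self):
        ids = [p.probe_id for ps in self.probesets for p in ps.probes]
        ids += [p.probe_id for p in self.background_probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe ids in design")

    @property
    def all_probes(self) -> list[ProbeRecord]:
        out = [p for ps in self.probesets for p in ps.probes]
        return out + list(self.background_probes)

    def probeset(self, probeset_id: str) -> ProbeSet:
        for ps in self.probesets:
            if ps.probeset_id == probeset_id:
                return ps
        raise KeyError(probeset_id)


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/SD of background-probe log fluorescence used for z-scoring."""

    mu_bg: float
    sigma_bg: float
    n_bg: int

    def __post_init__(self):
        if self.n_bg < 2:
            raise ValueError("need at least 2 background probes")
        if not self.sigma_bg > 0:
            raise ValueError("background log-fluorescence variance is zero")


@dataclass
class ZProfile:
    """Per-probe recruitment z-scores for one experiment (COF, condition, replicate)."""

    z: "pd.Series"  # probe_id -> z
    log_f: "pd.Series"  # probe_id -> log fluorescence
    background: BackgroundStats
    meta: dict = field(default_factory=dict)
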