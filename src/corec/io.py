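"""Readers and writers for the file formats the pipeline consumes and emits.

Motif libraries are read with Bio.motifs (MEME minimal and JASPAR text);
tables are plain TSV via pandas; genomes are FASTA via pyfaidx at query time
and Bio.SeqIO for writing.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .types import ReferenceMotif

BASES = "ACGT"

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25
"""


def _motif_matrix(m) -> np.ndarray:
    # Bio.motifs pwm is a dict base -> list over positions
    return np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)], float)


def read_meme(path: str | Path) -> list[ReferenceMotif]:
    """Read a MEME minimal format motif file into ReferenceMotifs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        base_id = getattr(m, "base_id", None)
        name = getattr(m, "name", "") or base_id or ""
        mid = base_id or name
        out.append(ReferenceMotif(id=mid, name=name or mid, matrix=_motif_matrix(m)))
    return out


def read_jaspar(path: str | Path) -> list[ReferenceMotif]:
    """Read JASPAR-format PFMs (counts are column-normalized to probabilities)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)], float)
        mat = counts / counts.sum(axis=1, keepdims=True)
        out.append(ReferenceMotif(id=m.matrix_id or m.name, name=m.name or m.matrix_id, matrix=mat))
    return out


def read_motifs(path: str | Path) -> list[ReferenceMotif]:
    """Sniff MEME minimal vs JASPAR from file content."""
    head = Path(path).read_text()[:2048]
    if re.search(r"MEME version", head):
        return read_meme(path)
    return read_jaspar(path)


def write_meme(motifs: Iterable, path: str | Path, *, name_extra: dict | None = None) -> None:
    """Write motifs (anything with .id, .name-ish and a probability matrix) as MEME minimal.

    ``name_extra`` maps motif id -> string appended to the name line, used to
    carry motif strength and beta alongside each recruitment motif.
    """
    lines = [_MEME_HEADER]
    for m in motifs:
        mat = np.asarray(m.matrix if hasattr(m, "matrix") else m.P, float)
        name = getattr(m, "name", None) or getattr(m, "probeset_id", m.id)
        extra = (name_extra or {}).get(m.id, "")
        lines.append(f"MOTIF {m.id} {name}{(' ' + extra) if extra else ''}")
        lines.append(f"letter-probability matrix: alength= 4 w= {mat.shape[0]} nsites= 1000000 E= 0")
        for row in mat:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fluor_table(path: str | Path) -> pd.DataFrame:
    """Read a probe fluorescence TSV (probe_id, spot, channel, fluorescence)."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "spot", "channel", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fluorescence table missing columns: {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4+/BED6 intervals; column 5 (``score``) holds -log10 p when present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS TSV with columns gene, contig, tss, strand (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "contig", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
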