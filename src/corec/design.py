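"""Array design: consensus collapsing, single-variant probe enumeration and assembly.

The array interrogates one canonical binding site per reference motif plus
every single-nucleotide variant (SV) of it, so a probe set of consensus
length L holds 3L+1 probes. Each probe is 60 nt: a 2-nt GC cap, a 34-nt
binding-site window, and a 24-nt common primer. Background probes sampled
from a genome estimate the fluorescence floor.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .types import (ArrayDesign, BASES, ConsensusSite, ProbeRecord, ProbeSet,
                    ReferenceMotif)

log = logging.getLogger(__name__)

SITE_WINDOW = 34
PRIMER_LEN = 24
CAP = "GC"
DEFAULT_FLANK = "TA"  # repeated to pad sub-34-nt sites; neutral low-complexity filler
DEFAULT_PRIMER = "GTCTTGATTCGCTTGACGCTGCTG"  # common primer, 24 nt


def consensus_from_ppm(motif: ReferenceMotif) -> ConsensusSite:
    """Collapse a probability matrix to its consensus sequence.

    Per position the maximally probable base is taken; ties break in the
    fixed order A < C < G < T (argmax on the A,C,G,T-ordered matrix).
    """
    idx = np.argmax(motif.matrix, axis=1)  # first max wins -> A<C<G<T tie-break
    return ConsensusSite(source_motif_id=motif.id, sequence="".join(BASES[i] for i in idx))


def _best_ungapped_identity(a: str, b: str) -> float:
    """Max over all ungapped offsets of (#matches / shorter length)."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for off in range(-len(a) + 1, len(b)):
        m = sum(1 for i, ch in enumerate(a) if 0 <= i + off < len(b) and b[i + off] == ch)
        best = max(best, m)
    return best / len(a)


def filter_equivalent(sites: list[ConsensusSite], identity_cutoff: float = 0.9,
                      *, both_strands: bool = False) -> list[ConsensusSite]:
    """Greedy de-duplication of consensus sites, first occurrence retained.

    A candidate is dropped when, versus any retained site, the best ungapped
    alignment identity exceeds the cutoff AND the shorter/longer length ratio
    exceeds the cutoff. The length condition keeps composite (A+B) site
    models alongside their half-site models.
    """
    from .types import revcomp

    if not sites:
        raise ValueError("no sites to filter")
    kept: list[ConsensusSite] = []
    for cand in sites:
        redundant = False
        for ref in kept:
            ratio = min(len(cand.sequence), len(ref.sequence)) / max(len(cand.sequence), len(ref.sequence))
            if ratio <= identity_cutoff:
                continue
            ident = _best_ungapped_identity(cand.sequence, ref.sequence)
            if both_strands:
                ident = max(ident, _best_ungapped_identity(revcomp(cand.sequence), ref.sequence))
            if ident > identity_cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return kept


def assemble_probe(site: str, primer: str = DEFAULT_PRIMER, flank: str = DEFAULT_FLANK) -> str:
    """Assemble the 60-nt probe: GC cap + centered 34-nt window + primer.

    Sites shorter than 34 nt are centered with a repeating flank; when the
    leftover is odd the extra base goes 3' of the site. The flank depends only
    on the site length, so all probes of a probe set share identical sequence
    outside the variable site.
    """
    if len(site) > SITE_WINDOW:
        raise ValueError(f"site longer than the {SITE_WINDOW}-nt window: {len(site)} nt")
    if len(primer) != PRIMER_LEN:
        raise ValueError(f"primer must be {PRIMER_LEN} nt, got {len(primer)}")
    pad = SITE_WINDOW - len(site)
    left = pad // 2
    right = pad - left
    tiled = (flank * (SITE_WINDOW // len(flank) + 2))
    window = tiled[:left] + site + tiled[:right]
    return CAP + window + primer


def enumerate_sv_probes(site: ConsensusSite, primer: str = DEFAULT_PRIMER,
                        flank: str = DEFAULT_FLANK) -> ProbeSet:
    """Enumerate the consensus probe and all 3L single-variant probes."""
    L = len(site.sequence)
    if L > SITE_WINDOW:
        raise ValueError(f"consensus of length {L} cannot fit the {SITE_WINDOW}-nt window")
    pid = site.source_motif_id
    probes = [ProbeRecord(
        probe_id=f"{pid}_consensus", probeset_id=pid, category="consensus",
        sv_position=None, sv_base=None,
        site34=assemble_probe(site.sequence, primer, flank)[2:2 + SITE_WINDOW],
        full_sequence=assemble_probe(site.sequence, primer, flank))]
    for pos in range(L):  # 0-based here, recorded 1-based
        for base in BASES:
            if base == site.sequence[pos]:
                continue
            var = site.sequence[:pos] + base + site.sequence[pos + 1:]
            full = assemble_probe(var, primer, flank)
            probes.append(ProbeRecord(
                probe_id=f"{pid}_sv_{pos + 1}{base}", probeset_id=pid, category="sv",
                sv_position=pos + 1, sv_base=base,
                site34=full[2:2 + SITE_WINDOW], full_sequence=full))
    return ProbeSet(probeset_id=pid, consensus=site, probes=probes)


def sample_background_probes(genome_fasta: str | Path, n: int = 261, seed: int = 0,
                             primer: str = DEFAULT_PRIMER) -> list[ProbeRecord]:
    """Sample n distinct 34-nt genomic windows uniformly and assemble probes.

    Windows containing non-ACGT characters are rejected and re-drawn;
    deterministic for a given seed.
    """
    fa = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    contigs = [(name, len(fa[name])) for name in fa.keys() if len(fa[name]) >= SITE_WINDOW]
    if not contigs:
        raise ValueError("no contig of at least 34 nt in genome")
    starts = np.cumsum([0] + [ln - SITE_WINDOW + 1 for _, ln in contigs])
    total = int(starts[-1])
    if total < n:
        raise ValueError(f"genome admits only {total} windows, need {n}")
    rng = np.random.default_rng(seed)
    chosen: dict[tuple, str] = {}
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100 * max(n, 1) + 1000:
            raise ValueError("could not sample enough ACGT-only background windows")
        flat = int(rng.integers(total))
        ci = int(np.searchsorted(starts, flat, side="right")) - 1
        pos = flat - int(starts[ci])
        name = contigs[ci][0]
        if (name, pos) in chosen:
            continue
        window = str(fa[name][pos:pos + SITE_WINDOW])
        if set(window) - set(BASES):
            continue
        chosen[(name, pos)] = window
    records = []
    for i, ((name, pos), window) in enumerate(chosen.items()):
        records.append(ProbeRecord(
            probe_id=f"bg_{i:04d}", probeset_id=None, category="background",
            sv_position=None, sv_base=None, site34=window,
            full_sequence=CAP + window + primer))
    return records


def build_design(motifs: list[ReferenceMotif], background_fasta: str | Path,
                 n_background: int = 261, seed: int = 0,
                 primer: str = DEFAULT_PRIMER, identity_cutoff: float = 0.9,
                 replicate_spots: int = 5) -> ArrayDesign:
    """Full design pipeline: collapse, de-duplicate, enumerate SVs, add backgrounds."""
    sites = [consensus_from_ppm(m) for m in motifs if m.length <= SITE_WINDOW]
    dropped = len(motifs) - len(sites)
    if dropped:
        log.warning("dropped %d motifs longer than the %d-nt window", dropped, SITE_WINDOW)
    sites = filter_equivalent(sites, identity_cutoff)
    probesets = [enumerate_sv_probes(s, primer) for s in sites]
    background = sample_background_probes(background_fasta, n_background, seed, primer)
    return ArrayDesign(probesets=probesets, background_probes=background,
                       primer=primer, replicate_spots=replicate_spots)


def design_to_frame(design: ArrayDesign) -> pd.DataFrame:
    rows = [{
        "probe_id": p.probe_id, "probeset_id": p.probeset_id or "",
        "category": p.category, "sv_position": p.sv_position if p.sv_position else "",
        "sv_base": p.sv_base or "", "site34": p.site34,
        "full_sequence": p.full_sequence,
    } for p in design.all_probes]
    return pd.DataFrame(rows)


def write_design(design: ArrayDesign, out_dir: str | Path) -> None:
    """Write the design as probes.tsv + probes.fasta + design.meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_to_frame(design).to_csv(out / "probes.tsv", sep="\t", index=False)
    with open(out / "probes.fasta", "w") as fh:
        for p in design.all_probes:
            fh.write(f">{p.probe_id}\n{p.full_sequence}\n")
    meta = pd.DataFrame([{"primer": design.primer, "replicate_spots": design.replicate_spots}])
    meta.to_csv(out / "design.meta.tsv", sep="\t", index=False)


def read_design(in_dir: str | Path) -> ArrayDesign:
    """Reconstruct an ArrayDesign from a directory written by :func:`write_design`."""
    out = Path(in_dir)
    df = pd.read_csv(out / "probes.tsv", sep="\t", keep_default_na=False)
    meta = pd.read_csv(out / "design.meta.tsv", sep="\t")
    primer = str(meta["primer"].iloc[0])
    probesets = []
    background = []
    for pid, grp in df.groupby("probeset_id", sort=False):
        if pid == "":
            continue
        cons_row = grp[grp.category == "consensus"].iloc[0]
        # recover the consensus site from the centered window
        probes = []
        site_len = int(grp[grp.category == "sv"]["sv_position"].astype(int).max()) \
            if (grp.category == "sv").any() else len(cons_row.site34.strip())
        pad = SITE_WINDOW - site_len
        left = pad // 2
        consensus_seq = cons_row.site34[left:left + site_len]
        for _, r in grp.iterrows():
            probes.append(ProbeRecord(
                probe_id=r.probe_id, probeset_id=pid, category=r.category,
                sv_position=int(r.sv_position) if r.sv_position != "" else None,
                sv_base=r.sv_base or None, site34=r.site34, full_sequence=r.full_sequence))
        probesets.append(ProbeSet(
            probeset_id=pid, consensus=ConsensusSite(pid, consensus_seq), probes=probes))
    for _, r in df[df.category == "background"].iterrows():
        background.append(ProbeRecord(
            probe_id=r.probe_id, probeset_id=None, category="background",
            sv_position=None, sv_base=None, site34=r.site34, full_sequence=r.full_sequence))
    return ArrayDesign(probesets=probesets, background_probes=background,
                       primer=primer, replicate_spots=int(meta["replicate_spots"].iloc[0]))
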