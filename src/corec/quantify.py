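"""Probe-level fluorescence to background-normalized recruitment z-scores.

For each experiment the per-probe fluorescence is the median over replicate
spots, natural-log transformed, and standardized against the background
probes of the same array:

    z = (f - mu_bg) / sigma_bg

where f is the probe's log fluorescence and mu_bg / sigma_bg are the mean
and sample SD of the background-probe log fluorescences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ArrayDesign, BackgroundStats, ZProfile

log = logging.getLogger(__name__)


def aggregate_spots(table: pd.DataFrame, expected_spots: int | None = None) -> pd.Series:
    """Median fluorescence over replicate spots per probe, then natural log.

    Returns a Series of log fluorescence indexed by probe_id. Probes with
    fewer spots than expected are used as-is with a warning.
    """
    if (table["fluorescence"] <= 0).any():
        bad = table.loc[table["fluorescence"] <= 0, "probe_id"].iloc[0]
        raise ValueError(f"nonpositive fluorescence (probe {bad})")
    counts = table.groupby("probe_id")["fluorescence"].size()
    if expected_spots is not None:
        short = counts[counts < expected_spots]
        if len(short):
            log.warning("%d probes have fewer than %d spots (min %d)",
                        len(short), expected_spots, int(short.min()))
    med = table.groupby("probe_id")["fluorescence"].median()
    return np.log(med)


def background_stats(log_f: pd.Series, design: ArrayDesign) -> BackgroundStats:
    """Mean and sample SD (ddof=1) of background-probe log fluorescence."""
    bg_ids = [p.probe_id for p in design.background_probes if p.probe_id in log_f.index]
    if len(bg_ids) < 2:
        raise ValueError("fewer than 2 background probes present in the data")
    vals = log_f.loc[bg_ids].to_numpy(float)
    sigma = float(np.std(vals, ddof=1))
    if sigma == 0:
        raise ValueError("background log fluorescence has zero variance")
    return BackgroundStats(mu_bg=float(np.mean(vals)), sigma_bg=sigma, n_bg=len(vals))


def compute_z(log_f: pd.Series, bg: BackgroundStats, meta: dict | None = None) -> ZProfile:
    """z = (f - mu_bg) / sigma_bg for every probe, backgrounds included."""
    z = (log_f - bg.mu_bg) / bg.sigma_bg
    return ZProfile(z=z, log_f=log_f, background=bg, meta=dict(meta or {}))


def quantify(table: pd.DataFrame, design: ArrayDesign, meta: dict | None = None) -> ZProfile:
    """Full quantification for one experiment: spots -> log f -> background z."""
    log_f = aggregate_spots(table, expected_spots=design.replicate_spots)
    bg = background_stats(log_f, design)
    return compute_z(log_f, bg, meta)


def zprofile_to_frame(zp: ZProfile) -> pd.DataFrame:
    df = pd.DataFrame({"probe_id": zp.z.index, "log_f": zp.log_f.values, "z": zp.z.values})
    for k, v in zp.meta.items():
        df[k] = v
    return df
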