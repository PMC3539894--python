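"""Strand-aware promoter nucleosome occupancy windows.

Two windows are summarized per transcript, denominated in bp upstream of
the TSS: proximal (-100..0, TSS included) and distal (-400..-150).  On
the minus strand the windows mirror to the other side of the TSS.  The
occupancy track holds interval-valued log2 ratios; points are assigned
to a window by their midpoint (or, optionally, averaged weighted by
overlap length).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import OccupancyTrack

__all__ = ["promoter_windows", "window_mean", "promoter_occupancy_table"]

logger = logging.getLogger(__name__)


def promoter_windows(strand: str, tss: int,
                     proximal: tuple[int, int] = (-100, 0),
                     distal: tuple[int, int] = (-400, -150)):
    """Genomic (1-based inclusive) proximal and distal windows for a TSS.

    Window offsets are given on the gene's own axis (negative =
    upstream); on the minus strand they mirror downstream in genomic
    coordinates.  Windows are clipped at chromosome position 1; a window
    entirely off-chromosome comes back as None.
    """
    def to_genomic(lo_off: int, hi_off: int):
        if strand == "+":
            lo, hi = tss + lo_off, tss + hi_off
        elif strand == "-":
            lo, hi = tss - hi_off, tss - lo_off
        else:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        lo = max(lo, 1)
        if hi < 1 or lo > hi:
            return None
        return (lo, hi)

    return to_genomic(*proximal), to_genomic(*distal)


def window_mean(track: OccupancyTrack, chrom: str, interval,
                assignment: str = "midpoint"):
    """Mean occupancy of track points falling in a genomic interval.

    Returns (mean, n_points); (nan, 0) when nothing overlaps.  With
    midpoint assignment a point belongs to the window iff its interval
    midpoint does; with overlap weighting each overlapping interval
    contributes proportionally to its overlap length.
    """
    if interval is None or chrom not in track:
        return np.nan, 0
    lo, hi = interval
    df = track.chroms[chrom]
    if assignment == "midpoint":
        mid = track.midpoints(chrom)
        mask = (mid >= lo) & (mid <= hi)
        n = int(mask.sum())
        if n == 0:
            return np.nan, 0
        return float(df["value"].to_numpy()[mask].mean()), n
    if assignment == "overlap_weighted":
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        ov = np.minimum(e, hi) - np.maximum(s, lo) + 1
        mask = ov > 0
        n = int(mask.sum())
        if n == 0:
            return np.nan, 0
        w = ov[mask].astype(float)
        return float(np.average(df["value"].to_numpy()[mask], weights=w)), n
    raise ValueError(f"unknown assignment {assignment!r}")


def promoter_occupancy_table(track: OccupancyTrack, transcripts: pd.DataFrame,
                             proximal: tuple[int, int] = (-100, 0),
                             distal: tuple[int, int] = (-400, -150),
                             assignment: str = "midpoint") -> pd.DataFrame:
    """Proximal/distal occupancy summary, one row per transcript."""
    missing_chroms = set()
    rows = []
    for t in transcripts.itertuples(index=False):
        prox_iv, dist_iv = promoter_windows(t.strand, int(t.tss),
                                            proximal, distal)
        if t.chrom not in track and t.chrom not in missing_chroms:
            missing_chroms.add(t.chrom)
            logger.warning("chromosome %s absent from occupancy track", t.chrom)
        p_mean, p_n = window_mean(track, t.chrom, prox_iv, assignment)
        d_mean, d_n = window_mean(track, t.chrom, dist_iv, assignment)
        rows.append({"gene_id": t.transcript_id,
                     "proximal": p_mean, "n_points_proximal": p_n,
                     "distal": d_mean, "n_points_distal": d_n})
    return pd.DataFrame(rows)
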