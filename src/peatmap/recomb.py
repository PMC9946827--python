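"""Recombination landscape: windowed cM/Mb, genome kb-per-cM, suppression flags.

A moss genetic map at ~73 kb/cM implies 10-30 cM/Mb across most chromosomes;
a chromosome whose observed map length falls far below the expectation from
its physical size (e.g. a non-recombining U/V sex chromosome) is flagged as
recombination-suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RecombTrack:
    """Per-window recombination rates for one chromosome."""

    windows: pd.DataFrame      # chrom, start, end (0-based half-open), cM_per_Mb
    total_cM: float


def windowed_rate(
    group: pd.DataFrame, chrom_length_bp: int, window_bp: int = 500_000
) -> RecombTrack:
    """Non-overlapping windowed recombination rate from a positioned group.

    cM at window edges is obtained by monotone linear interpolation between
    flanking markers; rate = delta-cM / delta-bp * 1e6. Beyond the terminal
    markers the map is flat, so the rate there is 0.
    """
    if len(group) < 2:
        raise ValueError("need >= 2 mapped markers on the chromosome")
    bp = group["pos"].to_numpy(dtype=float)
    cm = group["cM"].to_numpy(dtype=float)
    if not np.all(np.diff(bp) > 0):
        order = np.argsort(bp)
        bp, cm = bp[order], np.maximum.accumulate(cm[order])
    starts = np.arange(0, chrom_length_bp, window_bp)
    ends = np.minimum(starts + window_bp, chrom_length_bp)
    cm_start = np.interp(starts, bp, cm)
    cm_end = np.interp(ends, bp, cm)
    rate = (cm_end - cm_start) / (ends - starts) * 1e6
    chrom = group["chrom"].iloc[0]
    win = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "cM_per_Mb": rate}
    )
    return RecombTrack(windows=win, total_cM=float(cm[-1] - cm[0]))


def genome_kb_per_cM(total_bp: float, total_cM: float) -> float:
    """Genome-average physical distance per map unit, in kb/cM."""
    if total_cM <= 0:
        raise ValueError("total map length must be positive")
    return (total_bp / 1000.0) / total_cM


def flag_suppressed(
    chrom_length_bp: float,
    observed_cM: float,
    kb_per_cM: float,
    frac: float = 0.25,
) -> tuple[bool, float]:
    """Flag a chromosome as recombination-suppressed.

    Expected map length = physical size / genome-average kb-per-cM; the
    chromosome is flagged when observed < frac * expected (strict).
    Returns (flag, expected_cM).
    """
    expected = (chrom_length_bp / 1000.0) / kb_per_cM
    return bool(observed_cM < frac * expected), expected
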