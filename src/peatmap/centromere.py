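"""Repeat-cluster (putative centromere) detection by exact k-mer masking.

Dense clusters of a Copia-superfamily LTR retrotransposon (RLC5) mark
putative moss centromeres. The genome is masked with every k-mer of a query
repeat sequence (both strands), masked fractions are computed in sliding
windows, and clusters are called as runs of consecutive windows above a
masked-fraction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling integer codes of all k-mers; second array marks valid (no N) ones."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(enc[j : j + n] < 0, 0, enc[j : j + n])
    bad = enc < 0
    invalid = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    return codes, ~invalid


def _revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = rc * 4 + _COMP[code % 4]
        code //= 4
    return rc


def kmer_mask(genome: dict[str, str], query: str, k: int = 20) -> dict[str, np.ndarray]:
    """Mask every genome position covered by an exact match to a query k-mer.

    Matches are sought on both strands (query k-mers are canonicalised with
    their reverse complements). Query k-mers containing ambiguous bases are
    skipped. Returns a boolean mask per chromosome.
    """
    if len(query) < k:
        raise ValueError("query shorter than k")
    qcodes, qvalid = _kmer_codes(_encode(query), k)
    qset = set(qcodes[qvalid].tolist())
    qset |= {_revcomp_code(c, k) for c in list(qset)}
    qarr = np.fromiter(qset, dtype=np.int64) if qset else np.empty(0, dtype=np.int64)
    qarr.sort()

    masks: dict[str, np.ndarray] = {}
    for name, seq in genome.items():
        enc = _encode(seq)
        mask = np.zeros(enc.size, dtype=bool)
        codes, valid = _kmer_codes(enc, k)
        if codes.size and qarr.size:
            hit = valid & np.isin(codes, qarr)
            starts = np.flatnonzero(hit)
            if starts.size:
                # paint [s, s+k) for every hit via a difference array
                diff = np.zeros(enc.size + 1, dtype=np.int64)
                np.add.at(diff, starts, 1)
                np.add.at(diff, starts + k, -1)
                mask = np.cumsum(diff[:-1]) > 0
        masks[name] = mask
    return masks


def mask_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Merged 0-based half-open intervals of a boolean mask."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class WindowMask:
    """Sliding-window masked fractions for one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    fraction: np.ndarray


def window_masked_fraction(
    mask: np.ndarray, chrom: str, window: int = 5000, step: int = 200
) -> WindowMask:
    """Masked-base fraction in sliding windows.

    Terminal partial windows use their true length as denominator.
    """
    n = mask.size
    cum = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    starts = np.arange(0, n, step)
    ends = np.minimum(starts + window, n)
    frac = (cum[ends] - cum[starts]) / (ends - starts)
    return WindowMask(chrom=chrom, starts=starts, ends=ends, fraction=frac)


def call_clusters(
    wm: WindowMask, min_run: int = 5, frac_gt: float = 0.05
) -> pd.DataFrame:
    """Call repeat clusters as runs of consecutive qualifying windows.

    A window qualifies when its masked fraction is strictly > ``frac_gt``;
    maximal runs of >= ``min_run`` consecutive qualifying windows become
    clusters spanning [first window start, last window end).
    """
    ok = wm.fraction > frac_gt
    d = np.diff(ok.astype(np.int8), prepend=0, append=0)
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive window index
    rows = []
    for rs, re in zip(run_starts, run_ends):
        if re - rs >= min_run:
            rows.append(
                {
                    "chrom": wm.chrom,
                    "start": int(wm.starts[rs]),
                    "end": int(wm.ends[re - 1]),
                    "n_windows": int(re - rs),
                    "max_fraction": float(wm.fraction[rs:re].max()),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows", "max_fraction"])


def detect_repeat_clusters(
    genome: dict[str, str],
    query: str,
    k: int = 20,
    window: int = 5000,
    step: int = 200,
    min_run: int = 5,
    frac_gt: float = 0.05,
) -> pd.DataFrame:
    """End-to-end: mask with query k-mers, window, and call clusters (BED-like)."""
    masks = kmer_mask(genome, query, k)
    out = []
    for name, mask in masks.items():
        wm = window_masked_fraction(mask, name, window, step)
        out.append(call_clusters(wm, min_run, frac_gt))
    return pd.concat(out, ignore_index=True) if out else call_clusters(
        WindowMask("", np.empty(0, int), np.empty(0, int), np.empty(0)), min_run, frac_gt
    )
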