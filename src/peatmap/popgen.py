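"""Population-genomic statistics on haploid SNP matrices.

Sliding-window nucleotide diversity (pi), between-group divergence (Dxy) and
Hudson FST for contrasting diverged U/V haplogroups against autosomal
structure; LD pruning and classical multidimensional scaling for panel
structure; and ABBA-BABA D statistics with the topology-minimised D_min and
block-jackknife significance for introgression.

Calls are int8 matrices over {0, 1, -1 = missing} (sites x samples); all
sites are assumed biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import norm, false_discovery_control
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

MISSING = -1


# ------------------------------------------------------------------ pruning


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 1.0 if (vx == 0 and vy == 0) else 0.0
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_prune(
    sites: pd.DataFrame,
    calls: np.ndarray,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Windowed greedy LD pruning (PLINK --indep-pairwise semantics).

    Within each sliding window of ``window`` variants, any pair with
    haploid r^2 > ``r2_max`` loses its later site; the window advances by
    ``step``. Returns the indices of surviving sites.
    """
    n = len(sites)
    removed = np.zeros(n, dtype=bool)
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, n)) if not removed[i]]
        for a_pos in range(len(idx)):
            if removed[idx[a_pos]]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                i, j = idx[a_pos], idx[b_pos]
                if removed[j]:
                    continue
                if _r2(calls[i], calls[j]) > r2_max:
                    removed[j] = True
        if start + window >= n:
            break
        start += step
    return np.flatnonzero(~removed)


# --------------------------------------------------------------------- MDS


def allele_sharing_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise mismatch fraction over pairwise-complete sites."""
    n = calls.shape[1]
    d = np.zeros((n, n))
    valid = calls != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[:, i] & valid[:, j]
            if ok.sum() == 0:
                continue
            d[i, j] = d[j, i] = np.mean(calls[ok, i] != calls[ok, j])
    return d


def mds(calls: np.ndarray, n_axes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling of the allele-sharing distance matrix.

    Double-centres the squared distances and eigendecomposes; axes are
    ordered by eigenvalue and variance fractions are eigenvalue shares of
    the positive spectrum. Degenerate (all-identical) input raises.
    """
    if calls.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    d = allele_sharing_distance(calls)
    if np.allclose(d, 0):
        raise ValueError("all samples identical; MDS degenerate")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    w, v = eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w[w > 1e-12]
    coords = v[:, :n_axes] * np.sqrt(np.maximum(w[:n_axes], 0.0))
    varfrac = np.maximum(w[:n_axes], 0.0) / pos.sum()
    return coords, varfrac


def split_clusters_chr(
    calls: np.ndarray, min_silhouette: float = 0.3
) -> tuple[np.ndarray | None, float]:
    """Two-means split on MDS axis 1, used to define U-like vs V-like carriers.

    Separation is scored by the silhouette of the split under the full
    allele-sharing distance matrix (scoring on axis 1 alone would reward any
    k-means split of even structureless data). Returns (labels, silhouette);
    labels is None when separation is poor (silhouette < ``min_silhouette``).
    """
    if calls.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    coords, _ = mds(calls, n_axes=1)
    axis1 = coords[:, 0]
    init = np.array([[axis1.min()], [axis1.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1).fit(axis1[:, None])
    labels = km.labels_
    if len(np.unique(labels)) < 2:
        return None, 0.0
    sil = float(
        silhouette_score(allele_sharing_distance(calls), labels, metric="precomputed")
    )
    if sil < min_silhouette:
        return None, sil
    return labels, sil


# ---------------------------------------------------------- window statistics


def _site_components(calls: np.ndarray, groups: np.ndarray):
    """Per-site pi within each group, Dxy between, for biallelic haploid calls."""
    stats = {}
    freqs, sizes = {}, {}
    for gidx in (0, 1):
        sub = calls[:, groups == gidx]
        valid = sub != MISSING
        n = valid.sum(axis=1)
        cnt = ((sub == 1) & valid).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, cnt / np.maximum(n, 1), np.nan)
            # unbiased mean pairwise difference among n haplotypes
            pi = np.where(n > 1, 2 * p * (1 - p) * n / np.maximum(n - 1, 1), np.nan)
        freqs[gidx], sizes[gidx] = p, n
        stats[f"pi{gidx}"] = pi
    p0, p1 = freqs[0], freqs[1]
    stats["dxy"] = p0 * (1 - p1) + p1 * (1 - p0)
    stats["usable"] = (sizes[0] > 1) & (sizes[1] > 1)
    return stats


@dataclass
class WindowStats:
    table: pd.DataFrame  # chrom, start, end, n_sites, pi0, pi1, dxy, fst


def window_stats(
    sites: pd.DataFrame,
    calls: np.ndarray,
    groups: np.ndarray,
    window: int = 100_000,
    jump: int = 10_000,
    min_sites: int = 10,
    denominator: str = "window",
) -> WindowStats:
    """Sliding-window pi / Dxy / Hudson FST between two haploid groups.

    pi within a group is the mean pairwise difference per accessible site;
    Dxy the mean between-group pairwise difference per site; FST the Hudson
    Hw/Hb form, 1 - mean(pi within) / Dxy, computed from per-window sums.
    ``denominator`` 'window' divides per-site sums by window length
    (assumes non-variant positions are invariant); 'variant' divides by the
    number of usable variant sites. Windows with fewer than ``min_sites``
    usable sites get NaN statistics.
    """
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be coded 0/1")
    comp = _site_components(calls, groups)
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        usable = comp["usable"][idx]
        last = int(pos.max())
        for start in range(0, last + 1, jump):
            end = start + window
            in_win = (pos > start) & (pos <= end) & usable
            n_sites = int(in_win.sum())
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": n_sites,
            }
            if n_sites < min_sites:
                row.update(pi0=np.nan, pi1=np.nan, dxy=np.nan, fst=np.nan)
            else:
                sel = idx[in_win]
                denom = float(window) if denominator == "window" else float(n_sites)
                pi0 = np.nansum(comp["pi0"][sel]) / denom
                pi1 = np.nansum(comp["pi1"][sel]) / denom
                dxy = np.nansum(comp["dxy"][sel]) / denom
                hw = 0.5 * (np.nansum(comp["pi0"][sel]) + np.nansum(comp["pi1"][sel]))
                hb = np.nansum(comp["dxy"][sel])
                fst = 1.0 - hw / hb if hb > 0 else np.nan
                row.update(pi0=pi0, pi1=pi1, dxy=dxy, fst=fst)
            rows.append(row)
            if end > last:
                break
    return WindowStats(table=pd.DataFrame(rows))


# ------------------------------------------------------------- D statistics


@dataclass
class TrioCounts:
    abba: float
    baba: float
    d: float
    d_min: float
    d_min_arrangement: tuple[int, int, int]
    se: float
    z: float
    p: float


def _abba_baba(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted ABBA/BABA per site; freqs is (sites, 3) derived freqs."""
    p1, p2, p3 = freqs[:, 0], freqs[:, 1], freqs[:, 2]
    return (1 - p1) * p2 * p3, p1 * (1 - p2) * p3


def _d_from_freqs(freqs: np.ndarray) -> float:
    abba, baba = _abba_baba(freqs)
    tot = abba.sum() + baba.sum()
    if tot == 0:
        return np.nan
    return float((abba.sum() - baba.sum()) / tot)


def d_statistics(
    calls: np.ndarray,
    trio_groups: tuple[np.ndarray, np.ndarray, np.ndarray],
    outgroup: np.ndarray,
    n_blocks: int = 100,
) -> TrioCounts:
    """ABBA-BABA D and topology-minimised D_min with block-jackknife inference.

    Sites are polarised by the outgroup (sites where the outgroup is not
    fixed are dropped); derived-allele frequencies in the three populations
    weight the ABBA and BABA patterns. D_min is the minimum |D| over the
    three arrangements of the trio and bounds introgression from below when
    the true topology is unknown. The jackknife drops each of ``n_blocks``
    contiguous equal-site blocks to get SE, Z and a two-sided normal p.
    """
    pops = list(trio_groups) + [outgroup]
    freqs = []
    for idx in pops:
        sub = calls[:, idx]
        valid = sub != MISSING
        n = valid.sum(axis=1)
        cnt = ((sub == 1) & valid).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs.append(np.where(n > 0, cnt / np.maximum(n, 1), np.nan))
    freqs = np.column_stack(freqs)
    anc_fixed = np.isin(freqs[:, 3], (0.0, 1.0)) & ~np.isnan(freqs).any(axis=1)
    f = freqs[anc_fixed]
    # polarise: derived = allele absent from the outgroup
    flip = f[:, 3] == 1.0
    f = np.abs(f - flip[:, None].astype(float))[:, :3]
    informative = (f > 0).any(axis=1)
    f = f[informative]
    if f.shape[0] == 0:
        raise ValueError("no informative sites")

    abba, baba = _abba_baba(f)
    d = _d_from_freqs(f)

    arrangements = [(0, 1, 2), (0, 2, 1), (1, 2, 0)]
    d_by_arr = [_d_from_freqs(f[:, list(a)]) for a in arrangements]
    k = int(np.argmin([abs(x) for x in d_by_arr]))
    d_min = abs(d_by_arr[k])

    blocks = np.array_split(np.arange(f.shape[0]), min(n_blocks, f.shape[0]))
    jack = []
    for b in blocks:
        keep = np.ones(f.shape[0], dtype=bool)
        keep[b] = False
        jack.append(_d_from_freqs(f[keep]))
    jack = np.asarray(jack)
    g = len(jack)
    se = float(np.sqrt((g - 1) / g * np.sum((jack - jack.mean()) ** 2)))
    z = d / se if se > 0 else np.inf
    p = float(2 * norm.sf(abs(z)))
    return TrioCounts(
        abba=float(abba.sum()),
        baba=float(baba.sum()),
        d=d,
        d_min=d_min,
        d_min_arrangement=arrangements[k],
        se=se,
        z=float(z),
        p=p,
    )


def d_from_pattern_sums(abba: float, baba: float) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA) from site-pattern sums."""
    tot = abba + baba
    if tot == 0:
        raise ValueError("no informative site patterns")
    return (abba - baba) / tot


def adjust_trio_pvalues(p_values: list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjustment across trios."""
    return false_discovery_control(np.asarray(p_values), method="bh")
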