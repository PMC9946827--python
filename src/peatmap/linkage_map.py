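"""Haploid linkage-map construction.

The cascade mirrors dense F1-haploid map building from a single sporophyte:
missingness filters, maternal phasing, segregation/LD filters, collapse of
co-segregating markers, pairwise recombination fractions and LOD scores,
single-linkage grouping, travelling-salesman marker ordering, map-function
distances, and 1-cM thinning.

Genotype calls are int8 matrices over {0 = A (maternal), 1 = B (paternal),
-1 = missing}, markers in rows, individuals in columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

MISSING = -1
LOG10_2 = np.log10(2.0)


@dataclass
class HaploidGenotypes:
    """Marker x individual haploid call matrix with genomic coordinates."""

    markers: pd.DataFrame          # columns: chrom, pos (1-based), id
    samples: list[str]
    calls: np.ndarray              # int8 (n_markers, n_samples), {0,1,-1}

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError("calls shape inconsistent with markers/samples")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("marker positions must increase within chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def marker_missing_frac(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def subset(self, marker_idx=None, sample_idx=None) -> "HaploidGenotypes":
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return HaploidGenotypes(
            markers=self.markers.iloc[mi].reset_index(drop=True),
            samples=[self.samples[j] for j in si],
            calls=self.calls[np.ix_(mi, si)].copy(),
        )


@dataclass
class PairwiseLinkage:
    """Pairwise recombination fractions, LOD scores and informative counts."""

    r_hat: np.ndarray      # (m, m) in [0, 0.5]; NaN where undefined
    lod: np.ndarray        # (m, m), 0 on the diagonal of undefined pairs
    n_inf: np.ndarray      # (m, m) informative sample counts


@dataclass
class LinkageMap:
    """Ordered markers per linkage group with cM positions (0 at group start)."""

    groups: list[pd.DataFrame]     # each: chrom, pos, id, cM
    map_function: str = "kosambi"

    @property
    def total_length_cM(self) -> float:
        return float(sum(g["cM"].iloc[-1] for g in self.groups if len(g)))

    @property
    def n_markers(self) -> int:
        return sum(len(g) for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        out = []
        for i, g in enumerate(self.groups):
            d = g.copy()
            d.insert(0, "group", i + 1)
            out.append(d)
        return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------- filtering


def filter_samples_markers(
    g: HaploidGenotypes, sample_miss_max: float = 0.70, marker_miss_max: float = 0.02
) -> HaploidGenotypes:
    """Two-stage missingness filter: samples first, then markers.

    Samples with missing fraction > ``sample_miss_max`` are dropped; marker
    missingness is then recomputed on the retained samples and markers above
    ``marker_miss_max`` are dropped.
    """
    smiss = (g.calls == MISSING).mean(axis=0)
    keep_s = np.flatnonzero(smiss <= sample_miss_max)
    if keep_s.size == 0:
        raise ValueError("all samples removed by missingness filter")
    sub = g.calls[:, keep_s]
    mmiss = (sub == MISSING).mean(axis=1)
    keep_m = np.flatnonzero(mmiss <= marker_miss_max)
    if keep_m.size == 0:
        raise ValueError("all markers removed by missingness filter")
    return g.subset(keep_m, keep_s)


def phase_by_maternal(
    g: HaploidGenotypes, maternal: np.ndarray, allele_calls: np.ndarray | None = None
) -> HaploidGenotypes:
    """Phase raw allele calls against the maternal haplotype.

    A call matching the maternal allele becomes A (0), a mismatch B (1).
    Markers whose maternal allele is unknown (coded -1) are dropped.
    ``allele_calls`` defaults to ``g.calls``.
    """
    alleles = g.calls if allele_calls is None else allele_calls
    known = np.flatnonzero(maternal != MISSING)
    a = alleles[known]
    m = maternal[known][:, None]
    phased = np.where(a == MISSING, MISSING, (a != m).astype(np.int8)).astype(np.int8)
    out = g.subset(known)
    out.calls = phased
    return out


def filter_representation_ld(
    g: HaploidGenotypes,
    rep_range: tuple[float, float] = (0.35, 0.65),
    concordance_max: float = 0.999,
) -> HaploidGenotypes:
    """Retain balanced markers and break near-perfect LD duplicates.

    Keeps markers whose B-allele fraction among non-missing calls lies inside
    ``rep_range`` (balanced 1:1 segregation expected in a haploid F1). Then,
    among marker pairs with genotype concordance > ``concordance_max``
    (haploid concordance and r^2 coincide at this extreme), only the one with
    less missing data survives (tie: lower genomic coordinate).
    """
    nonmiss = g.calls != MISSING
    nb = ((g.calls == 1) & nonmiss).sum(axis=1)
    nn = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        bfrac = np.where(nn > 0, nb / np.maximum(nn, 1), np.nan)
    keep = np.flatnonzero((bfrac >= rep_range[0]) & (bfrac <= rep_range[1]))
    g = g.subset(keep)

    pl = pairwise_rf_lod(g)
    conc = 1.0 - pl.r_hat
    dup = (conc > concordance_max) & (pl.n_inf > 0)
    np.fill_diagonal(dup, False)
    keep = _component_representatives(dup, g)
    return g.subset(keep)


def _component_representatives(adj: np.ndarray, g: HaploidGenotypes) -> np.ndarray:
    """One marker per connected component: least missing, tie lowest coordinate."""
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    miss = g.marker_missing_frac()
    order = np.lexsort((g.markers["pos"].to_numpy(), miss))  # best first
    chosen = np.full(n_comp, -1)
    for idx in order:
        if chosen[labels[idx]] < 0:
            chosen[labels[idx]] = idx
    return np.sort(chosen)


def collapse_cosegregating(g: HaploidGenotypes, rf_min: float = 0.01) -> HaploidGenotypes:
    """Collapse groups of markers with pairwise RF below ``rf_min``.

    Connected components of the RF < rf_min graph are reduced to a single
    representative (least missing data, tie: lowest genomic coordinate).
    """
    pl = pairwise_rf_lod(g)
    adj = (pl.r_hat < rf_min) & (pl.n_inf > 0)
    np.fill_diagonal(adj, False)
    keep = _component_representatives(adj, g)
    return g.subset(keep)


# ------------------------------------------------------------- linkage core


def pairwise_rf_lod(g: HaploidGenotypes) -> PairwiseLinkage:
    """All-pairs recombination fraction and linkage LOD for haploid calls.

    r_hat = R / n_inf with R the discordant-call count over informative
    (both non-missing) individuals; LOD = R*log10(r) + (n_inf-R)*log10(1-r)
    + n_inf*log10(2), with the limits LOD = n_inf*log10(2) at r = 0 and
    LOD = 0 at r = 0.5. Pairs with n_inf = 0 get r_hat = NaN, LOD = 0.
    """
    a = g.calls
    valid = (a != MISSING).astype(np.float32)
    one = (a == 1).astype(np.float32) * valid
    zero = (a == 0).astype(np.float32) * valid
    n_inf = (valid @ valid.T).astype(np.int64)
    disc = (one @ zero.T) + (zero @ one.T)
    R = np.rint(disc).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n_inf > 0, R / np.maximum(n_inf, 1), np.nan)
        lod = (
            np.where(R > 0, R * np.log10(np.maximum(r, 1e-300)), 0.0)
            + np.where(n_inf - R > 0, (n_inf - R) * np.log10(np.maximum(1 - r, 1e-300)), 0.0)
            + n_inf * LOG10_2
        )
    lod = np.where(n_inf > 0, np.maximum(lod, 0.0), 0.0)
    return PairwiseLinkage(r_hat=r, lod=lod, n_inf=n_inf)


def form_linkage_groups(
    pl: PairwiseLinkage, rf_max: float = 0.23, lod_min: float = 3.0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Single-linkage grouping on the (RF <= rf_max AND LOD >= lod_min) graph.

    Returns (groups, singletons): groups are marker-index arrays with >= 2
    members, sorted by size descending then by lowest member index; markers
    linked to nothing are reported separately.
    """
    with np.errstate(invalid="ignore"):
        adj = (pl.r_hat <= rf_max) & (pl.lod >= lod_min) & (pl.n_inf > 0)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups, singles = [], []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        (groups if members.size > 1 else singles).append(members)
    groups.sort(key=lambda m: (-m.size, m[0]))
    singletons = np.concatenate(singles) if singles else np.empty(0, dtype=int)
    return groups, singletons


def _path_cost(order: np.ndarray, R: np.ndarray) -> float:
    return float(R[order[:-1], order[1:]].sum())


def order_markers_tsp(
    group: np.ndarray, pl: PairwiseLinkage, g: HaploidGenotypes
) -> tuple[np.ndarray, float]:
    """Order a linkage group by minimising total adjacent crossover count.

    Open-path TSP on the discordant-count matrix: nearest-neighbour
    construction from every start, then best-improvement 2-opt to a local
    optimum. Deterministic; ties broken by genomic coordinate. The returned
    order is canonicalised so its first marker has the lower coordinate, and
    is reported with the objective value.
    """
    m = group.size
    if m < 2:
        return group.copy(), 0.0
    R = (pl.r_hat[np.ix_(group, group)] * pl.n_inf[np.ix_(group, group)])
    R = np.where(np.isnan(R), np.inf, R)
    np.fill_diagonal(R, np.inf)
    pos = g.markers["pos"].to_numpy()[group].astype(float)
    # deterministic argmin tie-break by coordinate: add an epsilon ramp
    eps = np.argsort(np.argsort(pos)) * 1e-9

    best_order, best_cost = None, np.inf
    for start in range(m):
        order = np.empty(m, dtype=int)
        order[0] = start
        used = np.zeros(m, dtype=bool)
        used[start] = True
        cost = 0.0
        cur = start
        for step in range(1, m):
            row = np.where(used, np.inf, R[cur] + eps)
            nxt = int(np.argmin(row))
            cost += R[cur, nxt]
            order[step] = nxt
            used[nxt] = True
            cur = nxt
        if cost < best_cost - 1e-12:
            best_order, best_cost = order, cost

    order = _two_opt(best_order, np.where(np.isinf(R), 1e9, R))
    cost = _path_cost(order, np.where(np.isinf(R), 1e9, R))
    if pos[order[0]] > pos[order[-1]]:
        order = order[::-1]
    return group[order], float(cost)


def _two_opt(order: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Best-improvement 2-opt for an open path; vectorised move search."""
    order = order.copy()
    m = order.size
    while True:
        p = order
        # reversing p[i..j] (1 <= i <= j <= m-1, open path): delta uses edges
        # (i-1, i) and (j, j+1); treat the virtual end edge cost as 0.
        d_in = R[p[:-1], p[1:]]                      # edge k: (p[k], p[k+1])
        best_delta, best_move = -1e-9, None
        # reversing p[i..j]: replaces edges (i-1, i) and (j, j+1) with
        # (i-1, j) and (i, j+1); for an open path the virtual edges before
        # p[0] and after p[m-1] cost 0, so prefix/suffix reversals are moves too
        Rj = R[p][:, p]
        for i in range(0, m - 1):
            js = np.arange(max(i, 1), m)
            left_old = d_in[i - 1] if i > 0 else 0.0
            left_new = Rj[i - 1, js] if i > 0 else 0.0
            old = left_old + np.where(js < m - 1, d_in[np.minimum(js, m - 2)], 0.0)
            new = left_new + np.where(
                js < m - 1, Rj[i, np.minimum(js + 1, m - 1)], 0.0
            )
            delta = new - old
            k = int(np.argmin(delta))
            if delta[k] < best_delta:
                best_delta, best_move = float(delta[k]), (int(i), int(js[k]))
        if best_move is None:
            return order
        i, j = best_move
        order[i : j + 1] = order[i : j + 1][::-1]


# -------------------------------------------------------------- map distance


def haldane_cM(r: np.ndarray | float) -> np.ndarray | float:
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def kosambi_cM(r: np.ndarray | float) -> np.ndarray | float:
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


MAP_FUNCTIONS = {"haldane": haldane_cM, "kosambi": kosambi_cM}


def haldane_r(d_cM: np.ndarray | float):
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def kosambi_r(d_cM: np.ndarray | float):
    return 0.5 * np.tanh(np.asarray(d_cM, dtype=float) / 50.0)


INVERSE_MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


def estimate_positions(
    ordered: np.ndarray,
    pl: PairwiseLinkage,
    g: HaploidGenotypes,
    map_function: str = "kosambi",
) -> pd.DataFrame:
    """Cumulative cM positions along an ordered group from adjacent RFs.

    Adjacent r >= 0.5 is clamped to 0.49 (with a warning) before applying the
    map function; positions start at 0.
    """
    import warnings

    fn = MAP_FUNCTIONS[map_function]
    r_adj = pl.r_hat[ordered[:-1], ordered[1:]]
    if np.any(r_adj >= 0.5):
        warnings.warn("adjacent recombination fraction >= 0.5 clamped to 0.49")
        r_adj = np.minimum(r_adj, 0.49)
    steps = fn(np.nan_to_num(r_adj, nan=0.49))
    cm = np.concatenate([[0.0], np.cumsum(steps)])
    out = g.markers.iloc[ordered].reset_index(drop=True).copy()
    out["cM"] = cm
    return out


def thin_markers(group: pd.DataFrame, min_cM: float = 1.0) -> pd.DataFrame:
    """Greedy left-to-right thinning: keep a marker only >= min_cM past the last kept."""
    keep = []
    last = -np.inf
    for i, c in enumerate(group["cM"].to_numpy()):
        if c - last >= min_cM:
            keep.append(i)
            last = c
    return group.iloc[keep].reset_index(drop=True)


# --------------------------------------------------- error-robust refinement


def correct_singletons(g: HaploidGenotypes, ordered: np.ndarray) -> HaploidGenotypes:
    """Mask calls that disagree with both flanking markers along an order.

    In a dense map an isolated call flanked on both sides by the opposite
    allele implies two crossovers within a short interval, which is far more
    likely a genotyping error; such calls are set missing before distance
    estimation so that per-interval map inflation (~2 x error rate) is
    removed. Standard cleaning step for dense F1 maps.
    """
    calls = g.calls.copy()
    sub = calls[ordered]
    left, mid, right = sub[:-2], sub[1:-1], sub[2:]
    bad = (mid != MISSING) & (left == right) & (left != MISSING) & (mid != left)
    sub[1:-1][bad] = MISSING
    calls[ordered] = sub
    out = g.subset()
    out.calls = calls
    return out


def drop_distorted(
    g: HaploidGenotypes, alpha: float = 0.001
) -> HaploidGenotypes:
    """Drop markers whose A:B segregation departs from 1:1 (chi-square test)."""
    from scipy.stats import chi2

    nonmiss = g.calls != MISSING
    nb = ((g.calls == 1) & nonmiss).sum(axis=1)
    nn = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        stat = (2 * nb - nn) ** 2 / np.maximum(nn, 1)
    p = chi2.sf(stat, df=1)
    return g.subset(np.flatnonzero(p >= alpha))


def drop_high_leverage(
    group: pd.DataFrame,
    pl: PairwiseLinkage,
    g: HaploidGenotypes,
    ordered: np.ndarray,
    map_function: str = "kosambi",
    max_shrink_cM: float = 5.0,
) -> np.ndarray:
    """Iteratively drop markers whose removal shrinks the group > max_shrink_cM.

    Targets map expansion from error-prone markers. Returns the surviving
    ordered index array.
    """
    fn = MAP_FUNCTIONS[map_function]

    def length(idx: np.ndarray) -> float:
        r = np.nan_to_num(pl.r_hat[idx[:-1], idx[1:]], nan=0.49)
        return float(fn(np.minimum(r, 0.49)).sum())

    idx = ordered.copy()
    while idx.size > 2:
        L = length(idx)
        shrink = np.array(
            [L - length(np.delete(idx, k)) for k in range(idx.size)]
        )
        k = int(np.argmax(shrink))
        if shrink[k] <= max_shrink_cM:
            break
        idx = np.delete(idx, k)
    return idx


# ---------------------------------------------------------------- pipeline


@dataclass
class MapBuildResult:
    map: LinkageMap
    ordered_full: list[np.ndarray] = field(default_factory=list)  # pre-thinning orders
    singletons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    genotypes: HaploidGenotypes | None = None


def build_map(
    g: HaploidGenotypes,
    maternal: np.ndarray | None = None,
    sample_miss_max: float = 0.70,
    marker_miss_max: float = 0.02,
    rep_range: tuple[float, float] = (0.35, 0.65),
    concordance_max: float = 0.999,
    rf_collapse: float = 0.01,
    rf_max: float = 0.23,
    lod_min: float = 3.0,
    map_function: str = "kosambi",
    thin_cM: float = 1.0,
    distortion_alpha: float = 0.001,
    leverage_shrink_cM: float = 5.0,
    singleton_correction: bool = True,
) -> MapBuildResult:
    """Run the full map-construction cascade and return the thinned map."""
    g = filter_samples_markers(g, sample_miss_max, marker_miss_max)
    if maternal is not None:
        g = phase_by_maternal(g, maternal)
    g = filter_representation_ld(g, rep_range, concordance_max)
    if distortion_alpha is not None:
        g = drop_distorted(g, distortion_alpha)
    g = collapse_cosegregating(g, rf_collapse)

    pl = pairwise_rf_lod(g)
    groups, singletons = form_linkage_groups(pl, rf_max, lod_min)

    ordered_groups = []
    for members in groups:
        ordered, _ = order_markers_tsp(members, pl, g)
        ordered_groups.append(ordered)

    if singleton_correction:
        for ordered in ordered_groups:
            g = correct_singletons(g, ordered)
        pl = pairwise_rf_lod(g)

    final_groups, ordered_full = [], []
    for ordered in ordered_groups:
        if leverage_shrink_cM is not None:
            ordered = drop_high_leverage(
                None, pl, g, ordered, map_function, leverage_shrink_cM
            )
        positioned = estimate_positions(ordered, pl, g, map_function)
        ordered_full.append(ordered)
        final_groups.append(thin_markers(positioned, thin_cM))

    return MapBuildResult(
        map=LinkageMap(groups=final_groups, map_function=map_function),
        ordered_full=ordered_full,
        singletons=singletons,
        genotypes=g,
    )
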