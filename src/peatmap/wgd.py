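"""Synonymous-rate (Ks) estimation and Gaussian-mixture peak inference.

Whole-genome duplications leave clusters of paralogue pairs with similar
synonymous divergence; the Ks distribution of syntenic paralogues is
modelled as a univariate Gaussian mixture, the number of components chosen
by BIC, and pairs assigned to peaks by posterior probability.

Ks per pair is computed with the Nei-Gojobori (1986) counting method and
Jukes-Cantor correction: synonymous/nonsynonymous site counts averaged over
both sequences, multi-difference codons averaged over equal-weight minimal
mutational pathways, Ks = -(3/4) ln(1 - (4/3) pS).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
NUCS = "ACGT"


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (of its 3 positions)."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for n in NUCS:
            if n == codon[i]:
                continue
            alt = codon[:i] + n + codon[i + 1 :]
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all are used (degenerate but defined).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    kept = [(s, n) for s, n, stop in results if not stop] or [
        (s, n) for s, n, _ in results
    ]
    sd = sum(s for s, _ in kept) / len(kept)
    nd = sum(n for _, n in kept) / len(kept)
    return sd, nd


@dataclass
class KsPair:
    s_sites: float      # synonymous sites (averaged over the two sequences)
    n_sites: float
    sd: float           # synonymous differences
    nd: float
    ps: float           # proportion of synonymous differences, Sd/S
    pn: float
    ks: float           # Jukes-Cantor corrected; NaN when saturated
    ka: float
    n_codons: int       # codons actually compared


def ng86_ks(seq1: str, seq2: str) -> KsPair:
    """Nei-Gojobori Ks/Ka for one codon-aligned sequence pair.

    Codons containing gaps, ambiguity codes, or stops (in either sequence)
    are excluded pairwise. pS >= 0.75 (or S = 0) leaves Ks as NaN
    (Jukes-Cantor saturation).
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be codon-aligned with equal length")
    s = n = sd = nd = 0.0
    used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in GENETIC_CODE or c2 not in GENETIC_CODE:
            continue
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            continue
        s += (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        dsd, dnd = _pathway_counts(c1, c2)
        sd += dsd
        nd += dnd
        used += 1
    n = 3.0 * used - s

    def _jc(p: float) -> float:
        if p >= 0.75:
            return float("nan")
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    ps = sd / s if s > 0 else float("nan")
    pn = nd / n if n > 0 else float("nan")
    ks = _jc(ps) if s > 0 else float("nan")
    ka = _jc(pn) if n > 0 else float("nan")
    return KsPair(
        s_sites=s, n_sites=n, sd=sd, nd=nd, ps=ps, pn=pn, ks=ks, ka=ka, n_codons=used
    )


# ----------------------------------------------------------------- mixtures


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    bic_by_k: dict[int, float]
    fits_by_k: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, float]]
    degenerate: bool = False


def _em_fit(
    x: np.ndarray, k: int, tol: float = 1e-8, max_iter: int = 500, perturb=None
):
    """EM for a univariate Gaussian mixture with deterministic quantile init."""
    n = x.size
    order = np.sort(x)
    groups = np.array_split(order, k)
    means = np.array([g.mean() for g in groups])
    sds = np.array([max(g.std(), 1e-3) for g in groups])
    weights = np.full(k, 1.0 / k)
    if perturb is not None:
        means = means * (1.0 + 0.05 * perturb)
        sds = np.maximum(sds, x.std() / (2 * k))

    prev_ll = -np.inf
    for _ in range(max_iter):
        logpdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(weights[None, :])
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = float(lse.sum())
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        gamma = np.exp(logpdf - lse[:, None])
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        nk = gamma.sum(axis=0)
        weights = nk / n
        means = (gamma * x[:, None]).sum(axis=0) / nk
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, 1e-12))
    return weights, means, sds, prev_ll


def fit_mixture(
    ks: np.ndarray, k_max: int = 5, ks_ceiling: float | None = 2.0, seed: int = 0
) -> MixtureFit:
    """Fit Gaussian mixtures for k = 1..k_max and select k by minimum BIC.

    BIC = -2 logL + (3k - 1) ln n. Values above ``ks_ceiling`` (saturation
    guard) and NaNs are excluded before fitting. A fit with a collapsed
    component (sd < 1e-4) is restarted once from a perturbed initialisation
    and flagged if still degenerate. Deterministic.
    """
    x = np.asarray(ks, dtype=float)
    x = x[np.isfinite(x)]
    if ks_ceiling is not None:
        x = x[x <= ks_ceiling]
    if x.size < 10 * k_max:
        raise ValueError(f"need >= {10 * k_max} Ks values")

    fits, bics = {}, {}
    degenerate = False
    for k in range(1, k_max + 1):
        w, mu, sd, ll = _em_fit(x, k)
        if (sd < 1e-4).any():
            w, mu, sd, ll = _em_fit(x, k, perturb=np.linspace(-1, 1, k))
            if (sd < 1e-4).any():
                degenerate = True
        fits[k] = (w, mu, sd, ll)
        bics[k] = -2.0 * ll + (3 * k - 1) * np.log(x.size)
    best = min(bics, key=lambda k: bics[k])
    w, mu, sd, ll = fits[best]
    order = np.argsort(mu)
    return MixtureFit(
        k=best,
        weights=w[order],
        means=mu[order],
        sds=sd[order],
        log_likelihood=ll,
        bic=bics[best],
        bic_by_k=bics,
        fits_by_k=fits,
        degenerate=degenerate,
    )


def assign_peaks(
    fit: MixtureFit, ks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each Ks value to its maximum-posterior component.

    Ties go to the lower-mean component (components are mean-ordered).
    Returns (assignments, posteriors (n, k), per-peak medians).
    """
    x = np.asarray(ks, dtype=float)
    logpdf = (
        -0.5 * ((x[:, None] - fit.means[None, :]) / fit.sds[None, :]) ** 2
        - np.log(fit.sds[None, :])
        + np.log(fit.weights[None, :])
    )
    m = logpdf.max(axis=1, keepdims=True)
    post = np.exp(logpdf - m)
    post /= post.sum(axis=1, keepdims=True)
    # argmax takes the first (lower-mean) component on exact ties
    assign = np.argmax(np.isclose(post, post.max(axis=1, keepdims=True)), axis=1)
    medians = np.array(
        [np.median(x[assign == c]) if (assign == c).any() else np.nan
         for c in range(fit.k)]
    )
    return assign, post, medians
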