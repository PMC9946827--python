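"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design of a haploid-dominant peat moss: an F1-haploid
pedigree of gametophytes germinated from a single sporophyte, a small
non-recombining U/V sex chromosome transmitted whole, genomes with planted
tandem-repeat arrays, competitive-mapping read counts, two-haplogroup SNP
panels, two-component Ks mixtures, and phenotypes with sex-dependent QTL
effects.

Every stochastic operation derives an independent child generator from the
single integer seed in :class:`SimConfig`, so a fixed seed yields
bit-identical outputs regardless of which operations are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Simulation knobs standing in for the study design.

    Defaults follow the reference pedigree: 184 haploid gametophytes from a
    single sporophyte, genome-wide map density 13.7 cM/Mb (73 kb/cM), the
    last chromosome segregating whole as U or V.
    """

    seed: int = 0
    n_individuals: int = 184
    chrom_lengths_bp: tuple[int, ...] = tuple([20_000_000] * 5)
    marker_spacing_bp: int = 100_000
    map_density_cM_per_Mb: float = 13.7
    genotyping_error: float = 0.0
    missing_rate: float = 0.0
    uv_chrom_index: int | None = None
    cross_mapping_rate: float = 0.02
    qtl_spec: tuple = ()           # (chrom, pos_bp, beta_add, beta_sex, beta_env)
    ks_mixture: tuple = ((0.5, 0.406, 0.06), (0.5, 0.643, 0.06))
    repeat_plants: tuple = ()      # (chrom, start, array_length)

    def __post_init__(self) -> None:
        for p in (self.genotyping_error, self.missing_rate, self.cross_mapping_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        w = sum(w for w, _, _ in self.ks_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("Ks mixture weights must sum to 1")
        if self.uv_chrom_index is not None and not (
            0 <= self.uv_chrom_index < len(self.chrom_lengths_bp)
        ):
            raise ValueError("uv_chrom_index out of range")

_STREAMS = {
    "pedigree": 1, "genome": 2, "readcounts": 3, "ks": 4,
    "phenotypes": 5, "panel": 6,
}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    # hash() is salted per-process; a fixed stream table keeps runs reproducible
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass
class TruthSet:
    """Ground truth retained by the simulators, for scoring downstream calls."""

    marker_chrom: np.ndarray          # chromosome index per marker
    marker_bp: np.ndarray             # 1-based position per marker
    marker_cM: np.ndarray             # true map position per marker
    maternal_allele: np.ndarray       # allele (0/1) on the maternal haplotype
    crossovers: list                  # per individual: list per chromosome of bp positions
    sex: np.ndarray | None            # 'F' (U) / 'M' (V) per individual, if uv chrom set
    uv_chrom_index: int | None
    repeat_intervals: list = field(default_factory=list)   # (chrom, start, end) 0-based half-open
    qtl_params: tuple = ()
    mixture_params: tuple = ()

    def chrom_map_length_cM(self, c: int) -> float:
        sel = self.marker_chrom == c
        return float(self.marker_cM[sel].max() - self.marker_cM[sel].min())


def sim_pedigree(config: SimConfig) -> tuple["pd.DataFrame", np.ndarray, TruthSet]:
    """Simulate an F1-haploid pedigree from one sporophyte.

    Each gamete is a mosaic of the sporophyte's two parental haplotypes with
    crossover counts per chromosome drawn Poisson(map length in Morgans), no
    interference (Haldane). The U/V chromosome, if configured, carries no
    crossovers and is transmitted whole as U (maternal) or V (paternal) with
    probability 1/2; that choice defines the individual's sex. Calls are
    flipped with probability ``genotyping_error`` and masked at
    ``missing_rate``.

    Returns
    -------
    markers : DataFrame with columns chrom, pos, id
    calls : int8 array (n_markers, n_individuals), values {0, 1, -1=missing}
            coding which parental haplotype was inherited (before phasing,
            0 = maternal allele, 1 = paternal allele, relative to
            ``TruthSet.maternal_allele``; the emitted allele is
            ``maternal_allele ^ inherited``)
    truth : TruthSet
    """
    rng = _child_rng(config.seed, "pedigree")
    density = config.map_density_cM_per_Mb
    chrom_idx, bp, cm = [], [], []
    for c, L in enumerate(config.chrom_lengths_bp):
        n = max(2, int(L // config.marker_spacing_bp))
        pos = np.linspace(config.marker_spacing_bp // 2, L - 1, n).astype(np.int64)
        chrom_idx.append(np.full(n, c))
        bp.append(pos)
        cm.append(pos / 1e6 * density)
    chrom_idx = np.concatenate(chrom_idx)
    bp = np.concatenate(bp)
    cm = np.concatenate(cm)
    n_mark, n_ind = len(bp), config.n_individuals

    maternal = rng.integers(0, 2, n_mark).astype(np.int8)

    inherited = np.empty((n_mark, n_ind), dtype=np.int8)
    crossovers: list[list[np.ndarray]] = []
    sex = None
    if config.uv_chrom_index is not None:
        sex = np.where(rng.random(n_ind) < 0.5, "F", "M")
    for i in range(n_ind):
        xo_per_chrom = []
        for c, L in enumerate(config.chrom_lengths_bp):
            sel = chrom_idx == c
            if c == config.uv_chrom_index:
                # whole-chromosome U/V transmission, no recombination
                hap = 0 if sex[i] == "F" else 1
                inherited[sel, i] = hap
                xo_per_chrom.append(np.empty(0, dtype=np.int64))
                continue
            length_morgan = (L / 1e6 * density) / 100.0
            n_xo = rng.poisson(length_morgan)
            xo_bp = np.sort(rng.integers(1, L, n_xo))
            start_hap = rng.integers(0, 2)
            # haplotype at marker = start_hap + number of crossovers to its left
            hap = (start_hap + np.searchsorted(xo_bp, bp[sel])) % 2
            inherited[sel, i] = hap
            xo_per_chrom.append(xo_bp)
        crossovers.append(xo_per_chrom)

    calls = inherited.copy()
    if config.genotyping_error > 0:
        flips = rng.random(calls.shape) < config.genotyping_error
        calls[flips] ^= 1
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1

    markers = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": bp,
            "id": [f"chr{c + 1}_{p}" for c, p in zip(chrom_idx, bp)],
        }
    )
    truth = TruthSet(
        marker_chrom=chrom_idx,
        marker_bp=bp,
        marker_cM=cm,
        maternal_allele=maternal,
        crossovers=crossovers,
        sex=sex,
        uv_chrom_index=config.uv_chrom_index,
        qtl_params=config.qtl_spec,
        mixture_params=config.ks_mixture,
    )
    return markers, calls, truth


def truth_linkage_map(markers: pd.DataFrame, calls: np.ndarray, truth: TruthSet):
    """True-order linkage map plus per-group calls, for scans against truth.

    Autosomes only (the U/V chromosome, if any, is excluded: it does not
    recombine and carries no map). Returns (LinkageMap, calls_by_group).
    """
    from .linkage_map import LinkageMap

    groups, calls_by_group = [], []
    for c in np.unique(truth.marker_chrom):
        if c == truth.uv_chrom_index:
            continue
        sel = truth.marker_chrom == c
        grp = markers[sel].reset_index(drop=True).copy()
        grp["cM"] = truth.marker_cM[sel] - truth.marker_cM[sel].min()
        groups.append(grp)
        calls_by_group.append(calls[sel])
    return LinkageMap(groups=groups), calls_by_group


def alleles_from_inheritance(calls: np.ndarray, truth: TruthSet) -> np.ndarray:
    """Convert inherited-haplotype codes to observed alleles (0/1, -1 missing)."""
    out = calls.copy()
    ok = out >= 0
    out[ok] = (truth.maternal_allele[:, None] ^ calls)[ok]
    return out


def sim_genome_with_repeats(
    config: SimConfig, monomer: str
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Uniform-random A/C/G/T chromosomes with planted tandem monomer arrays.

    Each entry of ``config.repeat_plants`` is (chrom index, start, array
    length): the monomer is tiled (truncated at the end) over that 0-based
    half-open interval. Planted intervals must not overlap.

    Returns the genome as {name: sequence} plus the truth intervals as BED-style
    (chrom name, start, end) tuples.
    """
    rng = _child_rng(config.seed, "genome")
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for c, start, length in config.repeat_plants:
        if start < 0 or start + length > config.chrom_lengths_bp[c]:
            raise ValueError("planted interval outside chromosome")
        by_chrom.setdefault(c, []).append((start, start + length))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("planted repeat intervals overlap")

    genome: dict[str, str] = {}
    truth: list[tuple[str, int, int]] = []
    for c, L in enumerate(config.chrom_lengths_bp):
        seq = rng.choice(BASES, L)
        name = f"chr{c + 1}"
        for start, end in by_chrom.get(c, []):
            array = (monomer * (-(-(end - start) // len(monomer))))[: end - start]
            seq[start:end] = np.frombuffer(array.encode(), dtype="S1")
            truth.append((name, start, end))
        genome[name] = seq.tobytes().decode()
    return genome, truth


def sim_readcounts(
    truth: TruthSet,
    reads_per_sample: int,
    delta: float,
    seed: int | None = None,
    n_autosomal_windows: int = 200,
) -> pd.DataFrame:
    """Competitive-mapping read counts to the paired U and V targets.

    A true male's reads hit the V target Binomial(N, 1-delta); the remainder
    leak to U via cross-mapping (mirrored for females). A set of autosomal
    control windows receives Binomial(N, 0.5) counts for the empirical null.
    """
    if reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    if truth.sex is None:
        raise ValueError("truth has no sex labels (no U/V chromosome simulated)")
    rng = _child_rng(seed if seed is not None else 0, "readcounts")
    n = len(truth.sex)
    p_v = np.where(truth.sex == "M", 1.0 - delta, delta)
    count_v = rng.binomial(reads_per_sample, p_v)
    count_u = reads_per_sample - count_v
    df = pd.DataFrame(
        {
            "sample": [f"ind{i:03d}" for i in range(n)],
            "count_V": count_v,
            "count_U": count_u,
            "true_sex": truth.sex,
        }
    )
    df.attrs["autosomal_window_counts"] = rng.binomial(
        reads_per_sample, 0.5, n_autosomal_windows
    )
    return df


def sim_ks_mixture(
    params: tuple[tuple[float, float, float], ...], n: int, seed: int = 0
) -> np.ndarray:
    """Draw n Ks values from a Gaussian mixture, redrawing any negatives.

    ``params`` is a sequence of (weight, mean, sd); weights must sum to 1.
    """
    if any(sd <= 0 for _, _, sd in params):
        raise ValueError("component sds must be positive")
    rng = _child_rng(seed, "ks")
    w = np.array([p[0] for p in params])
    comp = rng.choice(len(params), n, p=w / w.sum())
    mu = np.array([p[1] for p in params])[comp]
    sd = np.array([p[2] for p in params])[comp]
    x = rng.normal(mu, sd)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mu[bad], sd[bad])
        bad = x < 0
    return x


def sim_phenotypes(
    truth: TruthSet,
    calls: np.ndarray,
    qtl_spec,
    environments=("control", "low"),
    sigma: float = 1.0,
    mu_env: dict[str, float] | None = None,
    beta_sex: float = 0.0,
    seed: int = 0,
    antagonistic: bool = False,
) -> pd.DataFrame:
    """Log-scale growth phenotypes with sex-dependent QTL effects.

    Per environment: y = mu_env + beta_sex*sex + sum_q [beta*g + gamma*g*sex
    + eta*g*sex*env] + N(0, sigma^2), with sex coded 0 (female) / 1 (male) and
    env coded 0/1.. by position in ``environments``. With ``antagonistic``
    the male genotype effect flips sign between successive environments,
    the rank-change pattern of antagonistic pleiotropy.
    """
    rng = _child_rng(seed, "phenotypes")
    n = calls.shape[1]
    sex01 = (truth.sex == "M").astype(float) if truth.sex is not None else np.zeros(n)
    mu_env = mu_env or {}
    rows = []
    for e_idx, env in enumerate(environments):
        y = np.full(n, mu_env.get(env, 0.0)) + beta_sex * sex01
        for chrom, pos_bp, beta, gamma, eta in qtl_spec:
            m = int(
                np.argmin(
                    np.where(truth.marker_chrom == chrom, 0, np.inf)
                    + np.abs(truth.marker_bp - pos_bp)
                )
            )
            g = calls[m].astype(float)
            g[g < 0] = 0.5  # missing at the QTL: average over alleles
            if antagonistic:
                sgn = 1.0 if e_idx == 0 else -1.0
                y += beta * g + sgn * gamma * g * sex01
            else:
                y += beta * g + gamma * g * sex01 + eta * g * sex01 * e_idx
        y += rng.normal(0.0, sigma, n)
        rows.append(
            pd.DataFrame(
                {
                    "sample": [f"ind{i:03d}" for i in range(n)],
                    "environment": env,
                    "growth": y,
                    "sex": np.where(sex01 > 0, "M", "F"),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sim_popgen_panel(
    n_per_group: int = 5,
    n_sites_sex: int = 500,
    n_sites_auto: int = 500,
    p_fix: float = 0.95,
    sex_chrom: str = "chr20",
    sex_chrom_len: int = 4_700_000,
    auto_chrom: str = "chr1",
    auto_chrom_len: int = 20_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two-haplogroup haploid SNP panel emulating a diverged U/V chromosome.

    Sex-chromosome sites are fixed-different between the two haplogroups with
    probability ``p_fix`` and shared-polymorphic otherwise; autosomal sites
    follow a smooth allele-frequency gradient across samples so that autosomal
    structure does not mirror the sex-linked split.

    Returns (sites DataFrame, calls matrix {0,1}, group labels).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per haplogroup")
    rng = _child_rng(seed, "panel")
    n = 2 * n_per_group
    groups = np.array([0] * n_per_group + [1] * n_per_group)

    pos_sex = np.sort(rng.choice(sex_chrom_len, n_sites_sex, replace=False)) + 1
    fixed = rng.random(n_sites_sex) < p_fix
    calls_sex = np.empty((n_sites_sex, n), dtype=np.int8)
    calls_sex[fixed] = groups[None, :]
    shared = ~fixed
    freq = rng.uniform(0.1, 0.9, shared.sum())
    calls_sex[shared] = (rng.random((shared.sum(), n)) < freq[:, None]).astype(np.int8)

    pos_auto = np.sort(rng.choice(auto_chrom_len, n_sites_auto, replace=False)) + 1
    grad = np.linspace(0.2, 0.8, n)[rng.permutation(n)]
    base = rng.uniform(0.1, 0.9, n_sites_auto)
    p_site = np.clip(base[:, None] * grad[None, :] * 2, 0.02, 0.98)
    calls_auto = (rng.random((n_sites_auto, n)) < p_site).astype(np.int8)

    sites = pd.DataFrame(
        {
            "chrom": [auto_chrom] * n_sites_auto + [sex_chrom] * n_sites_sex,
            "pos": np.concatenate([pos_auto, pos_sex]),
            "ref": "A",
            "alt": "T",
        }
    )
    calls = np.vstack([calls_auto, calls_sex])
    return sites, calls, groups
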