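"""Haley-Knott QTL mapping on haploid genotype probabilities.

Genotype probabilities along each linkage group come from a two-state
(A/B parental haplotype) hidden Markov model with genotyping-error emissions
and map-function transitions. Scans regress the phenotype on P(B) at each
evaluation position with sex as an additive covariate; the interaction scan
adds a genotype-by-sex term, capturing sex-chromosome-by-autosome epistasis.
Genome-wide significance thresholds come from stratified permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage_map import INVERSE_MAP_FUNCTIONS

MISSING = -1
LOD_RSS_FLOOR = 1e-10  # relative floor so a perfect fit yields a finite LOD


@dataclass
class GenotypeProbs:
    """P(B allele) per evaluation position per individual, by linkage group."""

    positions: pd.DataFrame        # group, pos_cM, is_marker
    p_b: np.ndarray                # (n_positions, n_individuals)
    samples: list[str] = field(default_factory=list)


def hmm_probs(
    group_cM: np.ndarray,
    calls: np.ndarray,
    error: float = 0.001,
    grid_cM: float | None = 1.0,
    map_function: str = "kosambi",
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-backward genotype probabilities along one ordered group.

    ``group_cM``: marker positions in cM (non-decreasing); ``calls``:
    (n_markers, n_individuals) over {0 (A), 1 (B), -1 missing}. Evaluation
    positions are the markers plus pseudomarkers every ``grid_cM`` (None for
    markers only). The transition probability across an interval is the
    inverse map function of its cM span; emissions are correct with
    probability 1 - error.

    Returns (positions_cM, P(B) array of shape (n_positions, n_individuals)).
    """
    inv = INVERSE_MAP_FUNCTIONS[map_function]
    marker_cM = np.asarray(group_cM, dtype=float)
    n_mark, n_ind = calls.shape
    if marker_cM.size != n_mark:
        raise ValueError("positions/calls mismatch")

    if grid_cM is not None and marker_cM[-1] > marker_cM[0]:
        grid = np.arange(marker_cM[0], marker_cM[-1], grid_cM)
        pos = np.unique(np.concatenate([marker_cM, grid]))
    else:
        pos = np.unique(marker_cM)
    # map markers onto evaluation positions (first match wins for duplicates)
    marker_at = np.full(pos.size, -1, dtype=int)
    idx = np.searchsorted(pos, marker_cM)
    for m in range(n_mark - 1, -1, -1):
        marker_at[idx[m]] = m

    emis = np.ones((pos.size, n_ind, 2))
    for p_i in range(pos.size):
        m = marker_at[p_i]
        if m < 0:
            continue
        obs = calls[m]
        e = np.ones((n_ind, 2))
        e[obs == 0] = [1.0 - error, error]
        e[obs == 1] = [error, 1.0 - error]
        emis[p_i] = e

    r = inv(np.diff(pos))
    r = np.clip(r, 1e-12, 0.5)

    # forward
    alpha = np.empty((pos.size, n_ind, 2))
    alpha[0] = 0.5 * emis[0]
    alpha[0] /= alpha[0].sum(axis=1, keepdims=True)
    for t in range(1, pos.size):
        stay, move = 1.0 - r[t - 1], r[t - 1]
        pred = np.empty_like(alpha[t - 1])
        pred[:, 0] = alpha[t - 1, :, 0] * stay + alpha[t - 1, :, 1] * move
        pred[:, 1] = alpha[t - 1, :, 0] * move + alpha[t - 1, :, 1] * stay
        a = pred * emis[t]
        alpha[t] = a / a.sum(axis=1, keepdims=True)
    # backward
    beta = np.ones((pos.size, n_ind, 2))
    for t in range(pos.size - 2, -1, -1):
        stay, move = 1.0 - r[t], r[t]
        nb = beta[t + 1] * emis[t + 1]
        beta[t, :, 0] = nb[:, 0] * stay + nb[:, 1] * move
        beta[t, :, 1] = nb[:, 0] * move + nb[:, 1] * stay
        beta[t] /= beta[t].sum(axis=1, keepdims=True)

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return pos, post[:, :, 1]


def probs_from_map(
    lmap, calls_by_group: list[np.ndarray], error: float = 0.001,
    grid_cM: float | None = 1.0, samples: list[str] | None = None,
) -> GenotypeProbs:
    """Genotype probabilities for every group of a linkage map."""
    frames, mats = [], []
    for gi, (grp, calls) in enumerate(zip(lmap.groups, calls_by_group)):
        pos, pb = hmm_probs(
            grp["cM"].to_numpy(), calls, error, grid_cM, lmap.map_function
        )
        frames.append(
            pd.DataFrame(
                {"group": gi + 1, "pos_cM": pos,
                 "is_marker": np.isin(pos, grp["cM"].to_numpy())}
            )
        )
        mats.append(pb)
    return GenotypeProbs(
        positions=pd.concat(frames, ignore_index=True),
        p_b=np.vstack(mats),
        samples=samples or [],
    )


# -------------------------------------------------------------------- scans


@dataclass
class ScanResult:
    positions: pd.DataFrame        # group, pos_cM, lod_add, lod_int (optional)
    threshold_add: float | None = None
    threshold_int: float | None = None

    def peaks(self, which: str = "lod_add", drop: float = 1.5) -> pd.DataFrame:
        """Per-group peak positions with 1.5-LOD support intervals."""
        rows = []
        for g, grp in self.positions.groupby("group"):
            lod = grp[which].to_numpy()
            if np.all(np.isnan(lod)):
                continue
            k = int(np.nanargmax(lod))
            lo = lod[k] - drop
            inside = np.flatnonzero(np.nan_to_num(lod, nan=-np.inf) >= lo)
            rows.append(
                {
                    "group": g,
                    "pos_cM": grp["pos_cM"].iloc[k],
                    "lod": lod[k],
                    "ci_lo_cM": grp["pos_cM"].iloc[inside[0]],
                    "ci_hi_cM": grp["pos_cM"].iloc[inside[-1]],
                }
            )
        return pd.DataFrame(rows)


def _residualize(y: np.ndarray, sex01: np.ndarray):
    """Residuals of y (and a basis) after removing intercept + sex."""
    n = y.shape[0]
    X0 = np.column_stack([np.ones(n), sex01])
    Q, _ = np.linalg.qr(X0)
    return y - Q @ (Q.T @ y), Q


def _lod_from_rss(rss0, rss1, n, scale=None):
    """(n/2) log10(RSS0/RSS1) with floors for perfect fits and null phenotypes.

    ``scale`` is the total phenotype sum of squares; when the null RSS is
    already negligible against it (constant phenotype after covariates) the
    LOD is 0 by definition rather than a ratio of rounding errors.
    """
    rss1 = np.maximum(rss1, LOD_RSS_FLOOR * np.maximum(rss0, 1e-300))
    lod = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
    if scale is not None:
        lod = np.where(rss0 <= 1e-12 * np.maximum(scale, 1e-300), 0.0, lod)
    return lod


def _scan_components(probs: GenotypeProbs, sex01: np.ndarray):
    """Residualized genotype and genotype-by-sex design columns."""
    n = sex01.size
    G = probs.p_b.T                         # (n, P)
    H = G * sex01[:, None]
    X0 = np.column_stack([np.ones(n), sex01])
    Q, _ = np.linalg.qr(X0)
    Eg = G - Q @ (Q.T @ G)
    Eh = H - Q @ (Q.T @ H)
    return Q, Eg, Eh


def scan_additive(
    probs: GenotypeProbs, phenotype: np.ndarray, sex01: np.ndarray
) -> ScanResult:
    """Additive Haley-Knott scan: y ~ 1 + sex + P(B) vs y ~ 1 + sex."""
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    Q, Eg, _ = _scan_components(probs, sex01)
    ey = y - Q @ (Q.T @ y)
    rss0 = float(ey @ ey)
    a = (Eg * Eg).sum(axis=0)
    u = Eg.T @ ey
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = rss0 - np.where(a > 1e-12, u * u / np.maximum(a, 1e-12), 0.0)
    lod = _lod_from_rss(rss0, rss1, n, scale=float(y @ y))
    lod[a <= 1e-12] = np.nan  # rank-deficient positions flagged
    out = probs.positions.copy()
    out["lod_add"] = lod
    return ScanResult(positions=out)


def scan_interaction(
    probs: GenotypeProbs, phenotype: np.ndarray, sex01: np.ndarray
) -> ScanResult:
    """Interaction scan: adds P(B) x sex over the additive model.

    LOD_int compares y ~ 1 + sex + g + g:sex against y ~ 1 + sex + g;
    LOD_add is reported alongside.
    """
    sex01 = np.asarray(sex01, dtype=float)
    if len(np.unique(sex01)) < 2:
        raise ValueError("interaction scan requires both sexes")
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    Q, Eg, Eh = _scan_components(probs, sex01)
    ey = y - Q @ (Q.T @ y)
    rss0 = float(ey @ ey)
    a = (Eg * Eg).sum(axis=0)
    b = (Eg * Eh).sum(axis=0)
    c = (Eh * Eh).sum(axis=0)
    u = Eg.T @ ey
    v = Eh.T @ ey
    det = a * c - b * b
    ok = det > 1e-12 * np.maximum(a * c, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        quad_full = np.where(ok, (c * u * u - 2 * b * u * v + a * v * v) / det, np.nan)
        rss_add = rss0 - np.where(a > 1e-12, u * u / np.maximum(a, 1e-12), 0.0)
        rss_full = rss0 - quad_full
    scale = float(y @ y)
    lod_add = _lod_from_rss(rss0, rss_add, n, scale=scale)
    lod_int = _lod_from_rss(rss_add, rss_full, n, scale=scale)
    lod_int[~ok] = np.nan
    out = probs.positions.copy()
    out["lod_add"] = lod_add
    out["lod_int"] = lod_int
    return ScanResult(positions=out)


def permute_thresholds(
    probs: GenotypeProbs,
    phenotype: np.ndarray,
    sex01: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    interaction: bool = True,
) -> tuple[float, float | None, np.ndarray, np.ndarray | None]:
    """Genome-wide permutation thresholds for the additive/interaction scans.

    Phenotypes are permuted within sex strata (sex is a model covariate);
    the genome-wide maximum LOD is recorded per permutation and the
    threshold is its (1 - alpha) quantile. Because stratified permutation
    commutes with projection on {1, sex}, the phenotype residuals are
    permuted directly.

    Returns (threshold_add, threshold_int, max_add, max_int).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    sex01 = np.asarray(sex01, dtype=float)
    Q, Eg, Eh = _scan_components(probs, sex01)
    ey = y - Q @ (Q.T @ y)

    perms = np.empty((n, n_perm))
    strata = [np.flatnonzero(sex01 == s) for s in np.unique(sex01)]
    for b in range(n_perm):
        col = ey.copy()
        for s in strata:
            col[s] = col[s][rng.permutation(s.size)]
        perms[:, b] = col

    rss0 = (perms * perms).sum(axis=0)                     # (B,)
    a = (Eg * Eg).sum(axis=0)                              # (P,)
    U = Eg.T @ perms                                       # (P, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss_add = rss0[None, :] - np.where(
            a[:, None] > 1e-12, U * U / np.maximum(a[:, None], 1e-12), 0.0
        )
    lod_add = _lod_from_rss(rss0[None, :], rss_add, n, scale=float(y @ y))
    max_add = np.nanmax(lod_add, axis=0)
    thr_add = float(np.quantile(max_add, 1.0 - alpha))

    thr_int, max_int = None, None
    if interaction:
        b_ = (Eg * Eh).sum(axis=0)
        c = (Eh * Eh).sum(axis=0)
        V = Eh.T @ perms
        det = a * c - b_ * b_
        ok = det > 1e-12 * np.maximum(a * c, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            quad = (
                c[:, None] * U * U - 2 * b_[:, None] * U * V + a[:, None] * V * V
            ) / det[:, None]
        rss_full = rss0[None, :] - np.where(ok[:, None], quad, np.nan)
        lod_int = _lod_from_rss(rss_add, rss_full, n, scale=float(y @ y))
        max_int = np.nanmax(lod_int, axis=0)
        thr_int = float(np.quantile(max_int, 1.0 - alpha))
    return thr_add, thr_int, max_add, max_int


# ------------------------------------------------------------ effect models


def effect_models(
    phenotypes: pd.DataFrame,
    genotype: pd.Series,
    control: str = "control",
    treatment: str = "low",
):
    """Genotype / sex / environment effect models at a QTL peak.

    ``phenotypes`` holds columns (sample, environment, growth, sex);
    ``genotype`` maps sample id to the A/B call (0/1) at the peak.

    Fits (i) the difference-score model response ~ genotype * sex by least
    squares, where response = treatment - control growth per individual
    (pairing absorbs the per-individual random effect, so the genotype x sex
    t-test matches a paired mixed model); (ii) per-sex models
    growth ~ genotype * environment with an F-test on the interaction; and
    (iii) an effect table of mean +/- s.e. per (sex, allele, environment)
    (s.e. NaN where a cell has < 2 observations).

    Returns (difference-model results, {sex: anova table}, effect table).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    wide = phenotypes.pivot_table(
        index=["sample", "sex"], columns="environment", values="growth"
    ).reset_index()
    if control not in wide or treatment not in wide:
        raise ValueError("both environments must be measured")
    wide = wide.dropna(subset=[control, treatment]).copy()
    wide["response"] = wide[treatment] - wide[control]
    wide["g"] = wide["sample"].map(genotype).astype(float)
    wide["s"] = (wide["sex"] == "M").astype(float)
    wide = wide.dropna(subset=["g"])
    diff_model = smf.ols("response ~ g * s", data=wide).fit()

    per_sex = {}
    long = phenotypes.copy()
    long["g"] = long["sample"].map(genotype).astype(float)
    long = long.dropna(subset=["g"])
    for sex, sub in long.groupby("sex"):
        if sub["environment"].nunique() < 2 or sub["g"].nunique() < 2:
            continue
        fit = smf.ols("growth ~ g * C(environment)", data=sub).fit()
        if fit.df_resid <= 0:
            continue  # saturated: no residual df for an F-test
        per_sex[sex] = anova_lm(fit, typ=2)

    eff = (
        long.groupby(["sex", "g", "environment"])["growth"]
        .agg(mean="mean", n="size", sd="std")
        .reset_index()
    )
    eff["se"] = np.where(eff["n"] >= 2, eff["sd"] / np.sqrt(eff["n"]), np.nan)
    return diff_model, per_sex, eff
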