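# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Pedigree simulation

`simdata.sim_pedigree` draws an F1-haploid pedigree: every gametophyte is a
mosaic of the two parental haplotypes of a single sporophyte. Crossover
counts per chromosome are Poisson with mean equal to the chromosome's map
length in Morgans and positions uniform along the chromosome — the Haldane
(no-interference) model. Interference is deliberately not modelled: it is
the simplest model consistent with what is known about these crosses, and
adding it would only make recovered maps easier (positive interference
reduces double crossovers, the main ordering noise). The U/V chromosome, if
configured, carries no crossovers and is transmitted whole — U (maternal)
or V (paternal) with probability 1/2 — which defines the individual's sex.

Defaults mirror the reference study design: 184 individuals, map density
13.7 cM/Mb (equivalently ~73 kb/cM). Genotyping errors are independent
allele flips at rate ε_g; missingness is completely at random (only rates,
not mechanisms, are known for the real data). All markers are assumed
informative (the parents differ); real pedigrees would first drop
uninformative sites, which this generator simply never creates.

Every generator derives an independent child RNG from the one configured
seed through a fixed stream table, so outputs are bit-identical for a fixed
seed regardless of call order.

What the generator does *not* emulate: read-level sequencing noise (counts
and calls are drawn directly), linked-error structure (e.g. reference-bias
errors correlated along haplotypes), segregation distortion, and
chromosome-scale coverage variation. Tests passing on this truth therefore
demonstrate the estimators' correctness and calibration under the stated
noise model, not robustness to every artefact of real short-read data.

## Map construction

Haploid F1 data make two-point linkage simple: with R discordant calls among
n informative individuals, r̂ = R/n and
LOD = R·log₁₀ r̂ + (n−R)·log₁₀(1−r̂) + n·log₁₀ 2, with the limits
LOD = n·log₁₀ 2 at r̂ = 0 and LOD = 0 at r̂ = 0.5.

The cascade applies, in order: (1) sample then marker missingness filters
(70% / 2%); (2) maternal phasing (match → A, mismatch → B); (3) retention of
markers with 35–65% B-representation — read as a *retention* rule, since
removing balanced markers would contradict the 1:1 segregation expected of
a haploid F1 — plus collapse of >99.9%-concordant duplicates (haploid
concordance and r² coincide at that extreme); (4) a chi-square segregation
test against 1:1 at α = 0.001; (5) collapse of co-segregating groups
(pairwise RF < 0.01) to the least-missing representative; (6) single-linkage
grouping with edges where r̂ ≤ 0.23 and LOD ≥ 3 (the standard direction:
an RF ceiling and a LOD floor); (7) ordering; (8) distances; (9) 1-cM
thinning. Ties anywhere break deterministically by (missingness, genomic
coordinate).

**Ordering** is an open-path travelling-salesman problem on the matrix of
discordant counts: nearest-neighbour construction from every start, then
best-improvement 2-opt including prefix/suffix reversals (virtual zero-cost
end edges). Prefix reversals matter: a nearest-neighbour tour that starts
mid-chromosome runs to one telomere and jumps back, and interior-only 2-opt
cannot repair it. The result is deterministic and canonicalised so the
lower genomic coordinate comes first.

**Error control.** With per-call error ε, every adjacent interval's apparent
RF inflates by ≈2ε, which at dense spacing would inflate the whole map by
tens of percent. Two mechanisms counter this: isolated calls that disagree
with both flanking markers (apparent double crossovers in a short interval,
overwhelmingly errors) are masked before distance estimation — the standard
cleaning step for dense maps — and markers whose removal shrinks the group
by more than 5 cM (high leverage) are dropped. Under the study conditions
(ε = 0.005, 1% missing, 184 gametes) the rebuilt map length lands within a
few percent of truth; the residual bias is slightly *downward* because
singleton masking also removes the rare genuine double crossover.

**Distances** use Kosambi by default (d = 25·ln((1+2r)/(1−2r))); Haldane
(d = −50·ln(1−2r)) is available. The choice is conventional, not inferred:
two-point haploid data cannot distinguish map functions. Adjacent r̂ ≥ 0.5
is clamped to 0.49 with a warning.

## Recombination landscape

Windowed rates interpolate cM linearly between flanking markers (monotone by
construction) and differentiate: rate = ΔcM/Δbp·10⁶, zero beyond terminal
markers; window 500 kb, non-overlapping (the plotting window of the original
analysis is not stated; any window integrates back to the same total).
A chromosome is flagged recombination-suppressed when its observed map
length is below 25% of the expectation from its physical size and the
genome-average kb/cM — a fraction chosen so a ~4.7 Mb chromosome with ~2 cM
observed versus ~60 cM expected flags decisively while noisy ordinary
chromosomes do not. Both the fraction and the window are configurable.

## Repeat-cluster detection

The genome is masked at every position covered by an exact match to any
20-mer of the query repeat. Both strands are searched (query k-mers plus
their reverse complements); ambiguous-base k-mers are skipped. k-mers are
encoded as base-4 integers with a rolling construction, so masking a 10-Mb
genome takes seconds. Masked fractions are computed in 5 kb windows stepped
by 200 bp; terminal partial windows use their true length as denominator.
Clusters are maximal runs of at least five consecutive windows with masked
fraction strictly above 5%; every qualifying run is reported (satellite
clusters are not distinguished from primary ones). On simulated genomes,
a uniform-random background makes a chance exact 20-mer match essentially
impossible (L·4⁻²⁰ ≈ 10⁻⁶ per megabase), so planted arrays ≥1 kb are
recovered with precision = recall = 1.

## Sex assignment

The competitive-mapping assay counts reads hitting the homologous V-region
and U-region targets. Calls use ratio = count_V/(count_V+count_U): V at
ratio ≥ 0.9, U at ≤ 0.1, NA otherwise or below 20 total reads. The
thresholds are conservative defaults (the real assay left 2 of 174
individuals ambiguous); with 200 reads and 2% cross-mapping the
misclassification probability is below 10⁻⁶ per individual. The autosomal
null samples random equal-length window pairs and reports the fraction of
null ratios at least as extreme (max(r, 1−r)) as an observation. The
coverage classifier is a deterministic 1-D two-means (initialised at the
min and max) that only declares two modes when the cluster means differ at
least two-fold. The sex-ratio test is the exact binomial two-sided
(2·min-tail, capped at 1) against 0.5.

## Population genomics

π within a group uses the unbiased per-site estimator 2p(1−p)·n/(n−1);
D_xy is p₁(1−p₂)+p₂(1−p₁); F_ST is Hudson's H_w/H_b form,
1 − mean(π within)/D_xy, computed from per-window sums (a ratio of sums,
not a mean of ratios). The per-site denominator defaults to the full window
length, i.e. positions absent from the matrix are assumed invariant — the
appropriate convention for a variants-only matrix accompanied by dense
coverage; a variant-only denominator is available and changes units.
Windows default to 100 kb with a 10 kb jump; windows with fewer than 10
usable sites are undefined.

The haplogroup split on a candidate sex chromosome clusters samples by
two-means on the first classical-MDS axis of allele-sharing distances.
Separation is scored by the silhouette of that split under the *full*
distance matrix — scoring on the clustered axis alone would award ~0.5 to
any split of structureless data, whereas full-distance silhouettes are
~0.05 for homogeneous panels and >0.9 for genuinely diverged ones; the
declare-split threshold is 0.3.

D statistics use frequency-weighted patterns on outgroup-polarised sites:
ABBA = (1−p₁)p₂p₃, BABA = p₁(1−p₂)p₃, D = (ΣABBA−ΣBABA)/(ΣABBA+ΣBABA).
D_min is the minimum |D| over the three arrangements of the trio — a lower
bound on introgression when the true topology is unknown. Significance is a
delete-one block jackknife over 100 contiguous equal-site blocks with a
normal approximation, and Benjamini–Hochberg across trios. LD pruning
follows the windowed greedy rule (50-variant windows, step 10, remove the
later site of any pair with r² > 0.5); the same pruner stands in for
variance-inflation-based pruning, which differs only in its pair criterion.

## Ks and mixture inference

Ks uses Nei–Gojobori (1986) counting: synonymous site counts per codon
(fraction of the three single-base changes per position that preserve the
amino acid), averaged over both sequences; differences in multi-hit codons
averaged over all minimal mutational pathways with equal weight, excluding
pathways through stop codons (unless all pass through one); Jukes–Cantor
correction Ks = −(3/4)·ln(1−(4/3)p_S), undefined at p_S ≥ 0.75. Codons with
gaps, ambiguity or stops are excluded pairwise. The implementation is
validated against an independent exhaustive-pathway oracle on short
alignments.

Mixtures are univariate Gaussians fitted by EM with deterministic quantile
initialisation, tolerance 10⁻⁸ on the log-likelihood, 500 iterations
maximum, and a monotonicity assertion every iteration. k is chosen by
minimum BIC = −2·logL + (3k−1)·ln n over k = 1..5. A collapsed component
(sd < 10⁻⁴) triggers one perturbed restart, then a degeneracy flag. Ks
values above 2 are excluded before fitting as a saturation guard
(configurable). Values are assigned to the maximum-posterior component,
ties to the lower mean. On 5,094 draws from an equal mixture of
N(0.406, 0.06²) and N(0.643, 0.06²) — the two-WGD configuration — BIC
selects k = 2 and recovers both means within 0.02.

## QTL mapping

Genotype probabilities come from a two-state forward–backward HMM per
linkage group: transition probability over an interval is the inverse map
function of its cM span (matching the map function of the map), emission is
the observed allele with probability 1−ε (ε default 0.001; the data's error
rate is rarely known, and the scans are insensitive to it within an order
of magnitude), missing calls are uninformative. Pseudomarkers can be placed
every 1 cM.

Scans are Haley–Knott regressions on P(B): the additive scan compares
y ~ 1 + sex + g against y ~ 1 + sex; the interaction scan compares
y ~ 1 + sex + g + g·sex against the additive model. LOD =
(n/2)·log₁₀(RSS_reduced/RSS_full). A perfect fit is capped at a finite LOD
via a relative RSS floor, and a phenotype fully explained by the covariates
yields LOD 0 rather than a ratio of rounding errors. Rank-deficient
positions are flagged NaN.

Permutation thresholds shuffle the phenotype *within sex strata* — sex is a
model covariate, and unstratified shuffling would push a real sex effect
into the null, inflating thresholds. Because stratified permutation
commutes with projection on {1, sex}, residuals are permuted directly,
which makes 100–1,000 permutations a vectorised matrix product. Thresholds
are the 95th percentile of the genome-wide max LOD. Calibration measured on
null simulations (5 chromosomes × 20 markers, 174 individuals, 100
permutations, 200 simulations — sizes chosen to make repeated calibration
cheap) gives genome-wide type-I error ≈0.05 for the additive and ≈0.06 for
the interaction scan.

A male-only QTL contributes to *both* scans (its sex-averaged half to the
additive, the remainder to the interaction term), so the package's
detection rule for a locus is that either scan exceeds its own genome-wide
threshold. For an antagonistic-pleiotropy effect (±1σ in males across two
environments, zero in females) scanned on the relative response
(treatment − control), either-scan power at n = 174 is ≥95%; the
interaction scan alone sits near 85% because its expected peak LOD (~4.7)
is only moderately above the threshold (~2.4).

Effect models at a peak use the difference score (treatment − control) per
individual, which absorbs the per-individual random effect of a paired
mixed model exactly when each individual is measured once per environment;
response ~ genotype × sex is then ordinary least squares with t-tests.
Per-sex models growth ~ genotype × environment give the interaction F-tests,
and the effect table reports mean ± s.e. per (sex, allele, environment)
cell, with s.e. undefined below two observations. Peak support intervals
are 1.5-LOD drops, the conventional choice.

## Known limitations

- Two-point distances cannot separate map-function choice from interference;
  total lengths are comparable only under a fixed convention.
- The singleton-masking error control assumes errors are isolated; bursty
  or haplotype-correlated errors would leak through.
- The D-statistics block jackknife assumes blocks of equal site counts
  approximate independent loci; very uneven SNP density would argue for
  coordinate-based blocks.
- The mixture model treats Ks values as independent draws; in real paralog
  sets, shared gene families induce correlation the BIC does not see.
- `effect_models`' difference-score trick requires exactly two environments;
  more environments need the full mixed model, which is out of scope here.
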