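# Methods

`parashore` re-implements, as a tested library, the population-genomic
workflow used to study parallel ecotype divergence in replicated rocky-shore
snail populations: SNP QC, multi-method FST outlier scanning with consensus
calling, quantification of outlier sharing across replicate sites against a
resampling null, hierarchical AMOVA, chord-distance neighbor-joining trees,
and supervised admixture estimation for phenotypically intermediate
mid-shore individuals. Everything runs end-to-end on synthetic data with
known truth; this note records the models, the defaults and why, the
numerical choices, and the known limitations.

## Study design emulated by the generator

The synthetic generator (`parashore.synthetic`) emulates a hierarchical
sampling design: two glacial refugia (south and north), three sites (two
southern, one northern), and within each site three tidal levels sampled
along replicate transects. The upper shore holds the crab-adapted ecotype,
the lower shore the wave-adapted ecotype, and the mid shore a contact-zone
class that is predominantly wave-like with a small minority of true
hybrids.

Neutral allele frequencies follow a hierarchical Balding–Nichols (BN)
model. An ancestral frequency `p0 ~ Uniform(0.05, 0.95)` is drawn per
locus; each level of the hierarchy then draws a daughter frequency from
`Beta(p(1-F)/F, (1-p)(1-F)/F)` around its parent, so the drift parameter
`F` at that level is the expected FST it introduces. `F = 0` is an exact
copy. Frequencies are clamped to `[0.01, 0.99]` before genotype draws so
loci do not drift to fixation (where the MAF filter would remove them in
expectation).

Defaults and their basis:

| parameter | default | rationale |
|---|---|---|
| sites / refugia | 3 sites, S1+S2 south, S3 north | replicated-sites design |
| individuals | 30 per site per tidal level, 2 transects | typical RAD sample sizes |
| `n_loci` | 4,256 | size of the filtered SNP panel the analysis targets |
| `f_refugium` | 0.20 | deep north–south split dominates genome-wide structure |
| `f_site` | 0.05 | moderate site differentiation within a refugium |
| `f_ecotype_neutral` | 0.15 | neutral between-ecotype FST within sites of 0.12–0.24 reported for this system |
| divergent loci | 10 shared by all sites + 35 shared by the southern pair + 75 private per site (~6% of loci) | reproduces the magnitudes of per-site outlier lists (~100–150) and the strong southern-pair sharing vs weak north–south sharing |
| `delta` | 0.8 | ecotype allele-frequency differential at divergent loci; gives per-locus between-ecotype FST ~0.6–0.7, as reported for outlier loci |
| `n_balancing` | 100 | small lower-tail class; all demes share `p0` |
| `missing_rate` | 0.10 | typical RAD missingness (MCAR) |
| `hybrid_fraction` | 0.02 | mid-shore is predominantly wave-like; roughly 2% true hybrids (Q ~ Uniform(0.2, 0.8)) mirrors the handful of admixed individuals found among ~166 mid-shore snails |

Divergent loci get deterministic shifts in their member sites only:
`crab = clip(p_site + delta/2)`, `wave = clip(p_site - delta/2)`; in
non-member sites they behave neutrally. Mid-shore individuals with
admixture proportion `Q` draw genotypes from the per-locus mixture
`Q * p_wave + (1-Q) * p_crab`. Genotypes are `Binomial(2, p)`;
missingness is MCAR. Same seed, same config: byte-identical output (the
frequency and genotype stages consume separate spawned child seeds).

What the generator does **not** emulate: linkage and recombination maps
(loci are exchangeable and independent), genotyping-error structure
(missingness is MCAR, not coverage-driven), selection dynamics through
time, and — importantly — genealogical (coalescent) variance in locus-wise
differentiation: under BN the latent per-locus FST is essentially constant
across neutral loci. Passing tests therefore demonstrate correct recovery
of *planted* structure under a clean frequency model, not robustness to
every property of real RAD data.

## SNP filtering

Pipeline order: first-SNP-per-RAD-fragment selection (smallest read
offset; ties by input order), then call-rate >= 70% and pooled MAF
strictly > 1%, then per-population Hardy–Weinberg exact tests (full
enumeration of heterozygote counts conditional on allele counts) with a
per-population Bonferroni threshold `alpha / n_loci_tested`. HWE-deviant
loci are flagged, never removed — departures can be biological. Linkage
flags use composite (dosage-correlation) r² over complete cases, and a
locus is called linked only if it is in at least one pair with r² > 0.2 in
*every* site; the finer site-by-shore grouping is available as an option.

## Weir–Cockerham FST and pairwise tests

The two-level Weir & Cockerham (1984) moment estimator is used throughout.
Multilocus values combine variance components as a ratio of sums, never a
mean of per-locus ratios; negative per-locus estimates are retained in
averages (a truncation flag exists for comparison with conventions that
clip at zero). Loci monomorphic in a comparison are excluded from the
sums. Pairwise significance permutes individuals between the two groups
with the `+1` small-sample correction, `p = (1 + #{theta* >= theta}) /
(n_perm + 1)`.

## FDIST outlier scan

The neutral null is a finite island model: `n_demes = 100` demes, samples
taken from two focal demes, scaled migration rate `M` solved from
`FST = 1 / (1 + M (d/(d-1))^2)`. Genealogies are generated by a dedicated
Gillespie simulation of the structured coalescent (within-deme pair
coalescence rate 1, per-lineage migration `M/2`, time in units of 2N
generations); when every lineage sits in its own deme the wait until two
lineages co-occur is drawn in one geometric jump, which makes 20,000
simulations tractable on one CPU. An independent msprime implementation of
the same island model is kept as a cross-check engine and is compared
distributionally in the test suite.

Mutations follow a symmetric two-allele model with `1 + Poisson(1)`
allele-flipping mutations placed uniformly on the total branch length
(monomorphic samples redrawn). The recurrent component matters: with a
single mutation, every low-heterozygosity simulated locus is a young,
deme-private allele with high differentiation, whereas at mutation-drift
equilibrium low-He loci also include old alleles segregating across demes.

Calibration: the target neutral FST is the 5%-trimmed mean of observed
per-locus theta (one re-estimation round after removing provisional
outliers, as in standard FDIST practice). Because the sampling expectation
of single-SNP theta sits below the parametric island FST, a short pilot
loop adjusts `M` until the simulated trimmed-mean theta matches the
target; the calibration statistic weights simulated loci to the observed
He distribution so the null is centred where the data live rather than
where the simulated site-frequency spectrum is dense.

P-values are empirical tail counts conditional on He, using for each
observed locus the 500 simulated loci nearest in He (a sliding window on
the He-sorted cloud, minimum 200). Upper tail = divergent candidates,
lower tail = balancing candidates; both raw and SGoF-corrected lower-tail
sets are reported. An optional empirical conditional recentering exists
(`recenter=True` on `FdistNull.pvalues`) but is off in the pipeline: in
testing it proved sensitive to conditional skewness and did not improve
calibration.

Known limitation (documented deliberately): the island-model null and
BN-generated data differ in conditional law at low He — the coalescent
cloud has fatter conditional tails (genealogical variance) than BN data,
which concentrate near a constant latent FST — so the scan is
conservative in the low-He stratum. With the equilibrium mutation model
and He-matched calibration the overall neutral upper-tail rate measures
close to nominal (~4.5% at a nominal 5% on 2,000 generator loci), and
p-values over the mid/high-He stratum (He > 0.2, where the informative
loci sit) are uniform by KS test. Any residual miscalibration is in the
conservative direction and does not compromise recovery of strongly
divergent loci.

## SGoF correction

Sequential Goodness-of-Fit: with `R` p-values at or below `gamma = 0.05`,
walk `r = R, R-1, ..., 1` and count those for which the one-tailed
binomial excess probability `P(X >= r | n, gamma)` is at most
`alpha = 0.05`, stopping at the first failure; flag that many smallest
p-values. Binomial metatest, one-tailed, no continuity correction; the
G-test variant is not implemented. Verified against an independent
brute-force binomial-tail implementation.

## PC-association scan

pcadapt-style: missing dosages imputed by locus means, loci standardized
by `sqrt(2p(1-p))`, top-K principal axes from an SVD (per-site scans use
K = 1: within one site the leading axis is the ecotype axis), per-locus
statistic = squared standardized association with the retained axes
(Mahalanobis form for K > 1), rescaled by the genomic inflation factor
(median statistic over the chi-square median), chi-square(K) p-values,
Benjamini–Hochberg q-values, flags at q <= 0.05.

## Bayesian F-model scan

A fixed-dimension spike-and-slab reimplementation of the BayeScan-style
logistic F-decomposition: allele counts `a_ij ~ BetaBinomial(n_ij,
theta_ij pi_i, theta_ij (1 - pi_i))` with `theta_ij = 1/F_ij - 1` and
`logit(F_ij) = alpha_i + beta_j` (the per-population sampling layer
`p_ij` is integrated out analytically, which the beta-binomial form makes
exact). The locus effect `alpha_i` carries a spike-and-slab prior with
prior inclusion `1/(1 + prior_odds)`, slab `N(0, 2^2)`;
`beta_j ~ N(-1, 1.8^2)`. Inclusion indicators are Gibbs-sampled with a
Carlin–Chib pseudo-prior centred on the empirical per-locus effect (so
loci needing a large `alpha` can switch on), with the pseudo-prior
correction in the inclusion odds; `pi`, `alpha` and `beta` move by
random-walk Metropolis with pilot-tuned step sizes. Defaults mirror
standard practice for this sampler family (20 pilot runs of 5,000
iterations, 100,000 burn-in, 5,000 samples at thinning 10); tests and the
acceptance script use shorter chains and state so. The q-value of a locus
is the cumulative mean of `(1 - inclusion)` down the inclusion ranking;
flags at q <= 0.05 are additionally restricted to loci above the median
theta (divergent direction). A split-half inclusion discrepancy > 0.1
records a non-convergence warning. Agreement with BayeScan is assessed by
calibration and planted-truth recovery, not numerical identity.

## Consensus and sharing

Consensus divergent loci are those flagged by at least two of the three
methods, computed per site over the site's polymorphic loci (loci
monomorphic within a site are dropped from that site's scan, which is why
per-site polymorphic counts differ). Sharing between sites is reported
under both denominators: shared/union (per-method tables convention) and
shared/per-site-list (headline-percentage convention) — published
accounts mix the two, so both are always present. The null: each
replicate draws, per site, a uniform random subset of the observed list
size from that site's pool of tested loci; the 2.5th/97.5th percentiles
over 1,000 replicates give the 95% band, with the analytic hypergeometric
mean `|S1||S2||P1 n P2| / (|P1||P2|)` as a cross-check.

## Hierarchical AMOVA

Locus-by-locus, allele-based: each genotyped individual contributes two
allele draws, so the squared-difference AMOVA reduces to a nested ANOVA on
allele indicators with Excoffier's unequal-size coefficients. Components
are estimated per locus, summed over loci ("averaged over all loci" as a
ratio of sums), negative estimates retained, and loci with an empty
population cell or monomorphic in the compared subset excluded (the count
is reported). Permutation schemes follow the standard hierarchy: whole
populations among groups for F_CT, individuals among populations within
groups for F_SC, individuals among all populations for F_ST.

Populations default to site x tidal-level. Because F_CT permutes whole
populations, its attainable p-value is floored by the number of distinct
population-to-group assignments (with 6 populations in 3 groups the floor
is ~1/15); when replicate transects exist, `pop_by='site_level_transect'`
uses transect-level populations and removes the floor. Mid-shore admixed
individuals are excluded by default. Exact conservation of the total
variance under a nesting swap does not hold for these moment estimators
with unbalanced per-locus sample sizes; the within-population component is
invariant and the total is stable to a few percent.

## Chord distances, NJ, bootstrap, rooting

Individuals are treated as two-allele frequency profiles per locus,
`(g/2, 1 - g/2)`; the per-locus squared chord term is
`c_l = 1 - sum_a sqrt(x_a y_a)` and distances aggregate as
`D = (2/pi) sqrt((2/L_pair) sum c_l)` over the loci genotyped in both
individuals (pairwise-complete). The `2/pi` normalization is a dialect of
the classical chord distance; it rescales all pairs equally, so topology
and bootstrap support are unaffected — acceptance is topology-level.

Neighbor joining uses the Studier–Keppler Q-criterion with deterministic
smallest-index tie-breaking; negative branch-length estimates are clamped
to zero for display with the raw value kept on the node. NJ exactly
inverts additive matrices (tested against random additive trees and
scikit-bio's implementation). Bootstrap resamples loci with replacement;
support on each internal bipartition of the point tree is the count of
replicates containing it (1,000 by default; scaled runs state their
count). Midpoint rooting roots at the midpoint of the longest
leaf-to-leaf path; an all-zero-length tree is left as-is with a warning.
Neutral-tree runs default to 2,000 randomly chosen neutral loci.

## Supervised admixture (Q)

For a mid-shore individual against its site's upper-shore (crab, source
A) and lower-shore (wave, source B) panels, Q maximizes
`sum_l log Binom(g_l | 2, Q p_Bl + (1-Q) p_Al)` over `[0, 1]` by bounded
1-D optimization (the likelihood is unimodal in the mixture frequency;
tolerance 1e-8, deterministic). Panel frequencies carry a 0.5 pseudocount
per allele. Individuals with `0.20 <= Q <= 0.80` (inclusive at both ends;
configurable) are putative recent hybrids or backcrosses. A fully
supervised estimator was chosen over an unsupervised clustering sampler
because the inference of interest — the ancestry fraction of mid-shore
individuals against known ecotype backgrounds — is exactly the supervised
problem, is deterministic, and admits parameter-recovery testing
(RMSE(Q) <= 0.05 at 2,000 informative loci). HWE within the mixture is
assumed. If the two panels are identical at every locus the likelihood is
flat and Q is reported undefined.

## Pipeline and reproducibility

`run_pipeline` chains simulate/load -> filter -> per-site scans ->
consensus -> sharing -> AMOVA -> trees -> ancestry. One global seed fans
out to per-stage child seeds (stable when stages are added), every summary
number is also written as a TSV artifact, and a rerun with the same
configuration is byte-identical. The CLI (`parashore simulate | filter |
scan | share | amova | tree | ancestry | run`) is a thin layer over these
functions.

Problem sizes used by the shipped checks: the test suite and
`scripts/acceptance.py` run the generator at 250–2,600 loci, FDIST nulls
at 250–5,000 simulations, AMOVA at up to 200 permutations, bootstraps at
10–100 replicates, and short F-model chains; library defaults remain the
full-size settings quoted above.
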