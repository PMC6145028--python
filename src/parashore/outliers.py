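"""FST outlier detection: three independent methods plus consensus calling.

* FDIST: a finite island-model coalescent null.  Loci are simulated as
  single mutations dropped uniformly on genealogies of samples from two of
  ``n_demes`` demes exchanging migrants at a rate solved from the
  island-model expectation ``FST = 1 / (1 + M (d/(d-1))^2)``; empirical
  p-values for observed loci are taken from the simulated (He, theta) cloud
  conditional on heterozygosity.  The upper tail flags divergent loci, the
  lower tail candidates for balancing selection.
* PCA scan: association of each locus with the leading principal
  component(s), chi-square calibrated through the genomic inflation factor,
  Benjamini-Hochberg corrected (pcadapt-style).
* Bayesian F-model: a spike-and-slab logistic decomposition of
  population-locus FST into locus effects alpha_i and population effects
  beta_j (BayeScan-style), sampled by Metropolis-within-Gibbs on the
  beta-binomial marginal likelihood.

Multiple testing is handled by SGoF (binomial metatest) for FDIST and by
FDR for the other two; the consensus set keeps loci flagged by at least two
methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, logit

from .datamodel import MISSING, GenotypeMatrix, SampleHierarchy
from .popgen import _wc_components
from .synthetic import CRAB_LEVEL, WAVE_LEVEL


# ------------------------------------------------------------------ FDIST

@dataclass
class FdistNull:
    """Simulated island-model null cloud of (He, theta) pairs.

    Conditioning on heterozygosity uses, for each observed locus, the
    ``neighborhood`` simulated loci nearest in He (a sliding window on the
    He-sorted cloud), so resolution adapts to where the observed loci fall
    rather than to where the simulated site-frequency spectrum is dense.
    """

    target_fst: float
    n_demes: int
    he: np.ndarray
    theta: np.ndarray
    neighborhood: int = 500
    _he_sorted: np.ndarray = field(default=None, repr=False)    # type: ignore[assignment]
    _th_by_he: np.ndarray = field(default=None, repr=False)     # type: ignore[assignment]

    def __post_init__(self) -> None:
        order = np.argsort(self.he, kind="stable")
        self._he_sorted = self.he[order]
        self._th_by_he = self.theta[order]
        self.neighborhood = int(min(max(self.neighborhood, 200), len(self.he)))

    def pvalues(self, obs_he, obs_theta, recenter: bool = True) -> pd.DataFrame:
        """Upper- and lower-tail empirical p-values conditional on He.

        With ``recenter`` (default), the bulk of the observed loci is used
        as an empirical null for conditional location: within each He
        window the trimmed-mean offset between observed and simulated
        theta is subtracted before the tail counts (the FDIST analogue of
        genomic-control rescaling; robust to a minority of true outliers).
        """
        obs_he = np.asarray(obs_he, dtype=float)
        obs_theta = np.asarray(obs_theta, dtype=float)
        n = len(self._he_sorted)
        k = self.neighborhood
        p_up = np.full(len(obs_he), np.nan)
        p_lo = np.full(len(obs_he), np.nan)
        pos = np.searchsorted(self._he_sorted, obs_he)
        lo = np.clip(pos - k // 2, 0, n - k)
        shift = np.zeros(len(obs_he))
        if recenter:
            ok = ~(np.isnan(obs_theta) | np.isnan(obs_he))
            if ok.sum() >= 50:
                order = np.argsort(obs_he[ok], kind="stable")
                he_o = obs_he[ok][order]
                th_o = obs_theta[ok][order]
                k_obs = min(max(ok.sum() // 5, 50), 300)
                pos_o = np.searchsorted(he_o, obs_he)
                lo_o = np.clip(pos_o - k_obs // 2, 0, len(he_o) - k_obs)
                for i in np.flatnonzero(ok):
                    w_obs = th_o[lo_o[i]: lo_o[i] + k_obs]
                    w_sim = self._th_by_he[lo[i]: lo[i] + k]
                    shift[i] = stats.trim_mean(w_obs, 0.1) - stats.trim_mean(
                        w_sim, 0.1
                    )
        for i in range(len(obs_he)):
            if np.isnan(obs_theta[i]) or np.isnan(obs_he[i]):
                continue
            window = self._th_by_he[lo[i]: lo[i] + k]
            t = obs_theta[i] - shift[i]
            p_up[i] = (1 + (window >= t).sum()) / (k + 1)
            p_lo[i] = (1 + (window <= t).sum()) / (k + 1)
        return pd.DataFrame({"p_upper": p_up, "p_lower": p_lo})


def island_migration_rate(target_fst: float, n_demes: int) -> float:
    """Scaled migration rate M with island-model expectation ``target_fst``."""
    if not (0.0 < target_fst < 0.9):
        raise ValueError("target_fst must be in (0, 0.9)")
    return (1.0 / target_fst - 1.0) * ((n_demes - 1) / n_demes) ** 2


def _island_locus(rng: np.random.Generator, M: float, n_demes: int,
                  n1: int, n2: int, mutation: str = "equilibrium",
                  mut_lambda: float = 1.0) -> np.ndarray:
    """One island-model coalescent genealogy -> diploid dosages.

    Gillespie simulation of the structured coalescent: within-deme lineage
    pairs coalesce at rate 1, each lineage migrates to a uniformly chosen
    other deme at rate M/2 (time in units of 2N generations, so the
    classical expectation FST = 1/(1 + M (d/(d-1))^2) holds).

    Mutations follow a symmetric two-allele model: ``equilibrium`` places
    1 + Poisson(mut_lambda) allele-flipping mutations uniformly on the
    total branch length (so low-heterozygosity loci include old alleles
    segregating across demes, as at mutation-drift equilibrium, not only
    young deme-private ones); ``single`` places exactly one mutation.
    Monomorphic samples are redrawn.
    """
    n_leaves = 2 * (n1 + n2)
    t_node = np.zeros(2 * n_leaves - 1)
    children: list[tuple[int, int] | None] = [None] * (2 * n_leaves - 1)
    # occupancy bookkeeping: only occupied demes are tracked
    occ: dict[int, list[int]] = {0: list(range(2 * n1)),
                                 1: list(range(2 * n1, n_leaves))}
    deme_of = {v: 0 for v in range(2 * n1)}
    deme_of.update({v: 1 for v in range(2 * n1, n_leaves)})
    nxt = n_leaves
    t = 0.0
    mig = M / 2.0
    randint = rng.integers

    def move(v, dest):
        src = deme_of[v]
        occ[src].remove(v)
        if not occ[src]:
            del occ[src]
        occ.setdefault(dest, []).append(v)
        deme_of[v] = dest

    k = n_leaves
    while k > 1:
        n_pairs = sum(len(g) * (len(g) - 1) for g in occ.values()) // 2
        if n_pairs == 0:
            # all singletons: skip migrations into empty demes in one jump
            p_join = (k - 1) / (n_demes - 1)
            g = rng.geometric(p_join)
            t += rng.gamma(g, 1.0 / (k * mig))
            lineages = list(deme_of)
            mover = lineages[randint(k)]
            others = [v for v in lineages if v != mover]
            target = others[randint(k - 1)]
            move(mover, deme_of[target])
            continue
        coal_rate = float(n_pairs)
        total = coal_rate + k * mig
        t += rng.exponential(1.0 / total)
        if rng.random() * total < coal_rate:
            # coalescence: choose deme weighted by its pair count
            u = randint(n_pairs)
            for d_pick, g in occ.items():
                c = len(g) * (len(g) - 1) // 2
                if u < c:
                    break
                u -= c
            i = randint(len(g))
            j = randint(len(g) - 1)
            if j >= i:
                j += 1
            a, b = g[i], g[j]
            t_node[nxt] = t
            children[nxt] = (a, b)
            occ[d_pick] = [v for v in g if v not in (a, b)]
            if not occ[d_pick]:
                del occ[d_pick]
            del deme_of[a], deme_of[b]
            occ.setdefault(d_pick, []).append(nxt)
            deme_of[nxt] = d_pick
            nxt += 1
            k -= 1
        else:
            lineages = list(deme_of)
            v = lineages[randint(k)]
            dest = (deme_of[v] + randint(1, n_demes)) % n_demes
            move(v, dest)
    # mutation placement on the genealogy
    n_nodes = nxt
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for p in range(n_leaves, n_nodes):
        a, b = children[p]
        parent[a] = parent[b] = p
    bl = np.zeros(n_nodes)
    has_parent = parent >= 0
    bl[has_parent] = t_node[parent[has_parent]] - t_node[np.flatnonzero(has_parent)]
    w = bl / bl.sum()
    for _ in range(50):
        if mutation == "single":
            hits = np.zeros(n_nodes, dtype=np.int64)
            hits[int(rng.choice(n_nodes, p=w))] = 1
        elif mutation == "equilibrium":
            m = 1 + rng.poisson(mut_lambda)
            hits = np.bincount(rng.choice(n_nodes, size=m, p=w),
                               minlength=n_nodes)
        else:
            raise ValueError(f"unknown mutation model {mutation!r}")
        # symmetric two-allele model: state flips at every mutation
        state = np.zeros(n_nodes, dtype=np.int8)
        for p in range(n_nodes - 1, n_leaves - 1, -1):  # parent index > child
            a, b = children[p]
            state[a] = state[p] ^ (hits[a] & 1)
            state[b] = state[p] ^ (hits[b] & 1)
        leaf = state[:n_leaves]
        dosage = leaf[0::2] + leaf[1::2]
        if 0 < leaf.sum() < n_leaves:
            return dosage.astype(np.int8)
    # could not obtain a polymorphic sample on this genealogy
    return dosage.astype(np.int8)


def _msprime_locus_batch(M, n_demes, n_sims, n1, n2, seed):
    """Island-model loci via msprime (slower; used as a cross-check engine)."""
    N = 1000.0
    m_pair = M / (4.0 * N) / (n_demes - 1)
    demography = msprime.Demography.island_model([N] * n_demes,
                                                 migration_rate=m_pair)
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples={0: n1, 1: n2}, demography=demography, ploidy=2,
        num_replicates=n_sims, random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    out = []
    for ts in reps:
        tree = ts.first()
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        bl = np.array([tree.branch_length(u) for u in nodes])
        pick = nodes[rng.choice(len(nodes), p=bl / bl.sum())]
        carriers = np.zeros(2 * (n1 + n2), dtype=bool)
        carriers[list(tree.samples(pick))] = True
        out.append(carriers[0::2].astype(np.int8) + carriers[1::2])
    return out


def _dosage_stats(dosage: np.ndarray, n1: int):
    a, b, c = _wc_components(dosage[:n1, None], dosage[n1:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = float(a[0] / (a[0] + b[0] + c[0]))
    p = dosage.sum() / float(len(dosage) * 2)
    return 2.0 * p * (1.0 - p), theta


def _weighted_trim_mean(x: np.ndarray, w: np.ndarray, trim: float = 0.05) -> float:
    """Trimmed mean of x under weights w (trims ``trim`` weight each side)."""
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    keep = (cw > trim * total) & (cw - w < (1 - trim) * total)
    if not keep.any() or total == 0:
        return float(np.mean(x))
    return float(np.average(x[keep], weights=w[keep]))


def _he_match_weights(sim_he: np.ndarray, obs_he: np.ndarray) -> np.ndarray:
    """Per-sim weights matching the simulated He distribution to the data's."""
    edges = np.linspace(0.0, 0.5, 21)
    obs_counts, _ = np.histogram(obs_he[~np.isnan(obs_he)], bins=edges)
    sim_counts, _ = np.histogram(sim_he, bins=edges)
    ratio = np.where(sim_counts > 0, obs_counts / np.maximum(sim_counts, 1), 0.0)
    idx = np.clip(np.digitize(sim_he, edges) - 1, 0, 19)
    return ratio[idx]


def fdist_simulate_null(
    target_fst: float,
    n_demes: int = 100,
    n_sims: int = 20000,
    sample_sizes: tuple[int, int] = (30, 30),
    seed: int = 1,
    calibrate: bool = True,
    engine: str = "gillespie",
    match_he: np.ndarray | None = None,
    mutation: str = "equilibrium",
    mut_lambda: float = 1.0,
) -> FdistNull:
    """Simulate the neutral joint (He, theta) distribution.

    Each simulated locus is one coalescent genealogy of diploid samples
    from two focal demes of an ``n_demes``-deme island model with a single
    uniformly placed mutation; the Weir-Cockerham theta between the two
    deme samples and the pooled expected heterozygosity are recorded.

    The migration rate starts at the closed-form island-model solution;
    because the sampling expectation of single-SNP theta sits below the
    parametric FST, a short pilot calibration then adjusts M so that the
    simulated trimmed-mean theta matches ``target_fst`` (disable with
    ``calibrate=False`` to use the closed form exactly).  When ``match_he``
    (the observed per-locus He values) is given, the calibration statistic
    weights the simulated loci to the observed He distribution, so the
    null is centred where the data actually live rather than where the
    simulated site-frequency spectrum is dense.
    """
    n1, n2 = sample_sizes
    if min(n1, n2) < 2:
        raise ValueError("need at least two diploid samples per focal deme")
    M = island_migration_rate(target_fst, n_demes)
    rng = np.random.default_rng(seed)

    def batch(M_val, k, child_seed):
        if engine == "msprime":
            ds = _msprime_locus_batch(M_val, n_demes, k, n1, n2, child_seed)
        elif engine == "gillespie":
            r = np.random.default_rng(child_seed)
            ds = [_island_locus(r, M_val, n_demes, n1, n2, mutation, mut_lambda)
                  for _ in range(k)]
        else:
            raise ValueError(f"unknown engine {engine!r}")
        stats_ = np.array([_dosage_stats(d, n1) for d in ds])
        return stats_[:, 0], stats_[:, 1]

    if calibrate:
        pilot = min(max(n_sims // 4, 200), 1000)
        for _ in range(5):
            he_p, th = batch(M, pilot, int(rng.integers(2**31 - 1)))
            ok_p = ~np.isnan(th)
            if match_he is not None:
                w = _he_match_weights(he_p[ok_p], np.asarray(match_he, float))
                realized = _weighted_trim_mean(th[ok_p], np.maximum(w, 1e-12))
            else:
                realized = float(stats.trim_mean(th[ok_p], 0.05))
            if realized <= 0 or abs(realized - target_fst) < 0.005:
                break
            # map realized theta back through the island-model formula
            # (damped multiplicative update; realized is monotone decreasing
            # in M, so the fixed point is stable)
            ratio = island_migration_rate(min(target_fst, 0.89), n_demes) / \
                island_migration_rate(min(max(realized, 1e-3), 0.89), n_demes)
            M *= ratio**0.8
    he, theta = batch(M, n_sims, int(rng.integers(2**31 - 1)))
    ok = ~np.isnan(theta)
    return FdistNull(target_fst, n_demes, he[ok], theta[ok])


def _sample_stats(gm: GenotypeMatrix, idx_a, idx_b) -> pd.DataFrame:
    """Observed per-locus He (pooled over both groups) and WC theta."""
    d = gm.dosages[np.concatenate([np.asarray(idx_a), np.asarray(idx_b)])]
    ok = d != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, d, 0).sum(axis=0) / (2.0 * n)
    a, b, c = _wc_components(gm.dosages[np.asarray(idx_a)], gm.dosages[np.asarray(idx_b)])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return pd.DataFrame(
        {"he": 2 * p * (1 - p), "theta": theta}, index=gm.locus_names
    )


def fdist_pvalues(obs: pd.DataFrame, null: FdistNull) -> pd.DataFrame:
    """Empirical conditional p-values for an observed (He, theta) table."""
    out = null.pvalues(obs["he"].to_numpy(), obs["theta"].to_numpy())
    out.index = obs.index
    return out


def fdist_target_fst(theta: np.ndarray, trim: float = 0.05) -> float:
    """Neutral-FST calibration target: two-sided trimmed mean of theta."""
    th = np.asarray(theta, dtype=float)
    th = th[~np.isnan(th)]
    t = float(stats.trim_mean(th, trim))
    return float(np.clip(t, 0.005, 0.89))


# ------------------------------------------------------------------- SGoF

def sgof(pvalues, gamma: float = 0.05, alpha: float = 0.05):
    """Sequential Goodness-of-Fit multiple-testing correction.

    With ``R`` p-values at or below ``gamma``, rejections are counted by
    walking r = R, R-1, ..., 1 and keeping those r for which the one-tailed
    binomial excess probability P(X >= r | n, gamma) is at most ``alpha``,
    stopping at the first failure; the resulting number of smallest p-values
    is flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return 0, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    big_r = int((p <= gamma).sum())
    s = 0
    for r in range(big_r, 0, -1):
        if stats.binom.sf(r - 1, n, gamma) <= alpha:
            s = big_r - r + 1
        else:
            break
    flags = np.zeros(n, dtype=bool)
    if s > 0:
        flags[np.argsort(p, kind="stable")[:s]] = True
    return s, flags


# --------------------------------------------------------------- PCA scan

def pca_scan(
    gm: GenotypeMatrix, K: int = 1, fdr: float = 0.05
) -> pd.DataFrame:
    """Principal-component association scan (pcadapt-style).

    Missing dosages are imputed by the locus mean; loci are standardized by
    2p(1-p); the per-locus statistic is the squared standardized association
    with the top-K axes (Mahalanobis form), rescaled by the genomic
    inflation factor, with chi-square(K) p-values and BH q-values.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least two samples")
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    p_hat = mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    informative = scale > 0
    informative &= np.nanstd(d, axis=0) > 0
    x = (d[:, informative] - mean[informative]) / scale[informative]
    n = x.shape[0]
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    K = min(K, u.shape[1])
    axes = u[:, :K]
    coef = axes.T @ x                                   # K x L
    rss = (x * x).sum(axis=0) - (coef**2).sum(axis=0)
    dof = max(n - K - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.maximum(rss, 0.0) / dof
        stat = (coef**2).sum(axis=0) / sigma2
    stat[~np.isfinite(stat)] = np.nan
    gif = np.nanmedian(stat) / stats.chi2.ppf(0.5, K)
    pvals = stats.chi2.sf(stat / gif, K)
    out = pd.DataFrame(
        {"stat": np.nan, "p": np.nan, "q": np.nan, "flag": False},
        index=gm.locus_names,
    )
    out.loc[np.asarray(gm.locus_names)[informative], "stat"] = stat
    out.loc[np.asarray(gm.locus_names)[informative], "p"] = pvals
    ok = ~np.isnan(pvals)
    q = np.full(pvals.shape, np.nan)
    q[ok] = _bh_qvalues(pvals[ok])
    out.loc[np.asarray(gm.locus_names)[informative], "q"] = q
    out["flag"] = out["q"] <= fdr
    return out


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    q[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(q, 1.0)


# --------------------------------------------------------- Bayesian F-model

@dataclass
class FModelPosterior:
    """Posterior summaries of the spike-and-slab F-model scan."""

    inclusion: pd.Series      # posterior probability the locus effect is on
    alpha_mean: pd.Series
    beta_mean: np.ndarray     # per-population effects
    q: pd.Series
    flags: pd.Series
    converged: bool


def _betabinom_loglik(a, n, f, pi):
    """Beta-binomial log-likelihood (binomial constant dropped)."""
    f = np.clip(f, 1e-9, 1 - 1e-9)
    theta = 1.0 / f - 1.0
    u = theta * np.clip(pi, 1e-9, 1 - 1e-9)
    v = theta - u
    return betaln(a + u, n - a + v) - betaln(u, v)


def fmodel_scan(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    site: str,
    prior_odds: float = 10.0,
    pilot_runs: int = 20,
    pilot_len: int = 5000,
    burn_in: int = 100000,
    thin: int = 10,
    n_samples: int = 5000,
    fdr: float = 0.05,
    seed: int = 1,
    slab_sd: float = 2.0,
) -> FModelPosterior:
    """Spike-and-slab F-model scan between the two ecotype samples of a site.

    Allele counts per locus and ecotype population follow a beta-binomial
    with logit(F_ij) = alpha_i + beta_j; alpha_i carries a spike-and-slab
    prior with prior inclusion 1/(1+prior_odds).  Inclusion indicators are
    Gibbs-sampled with a Carlin–Chib pseudo-prior centred on the empirical
    per-locus effect (so loci needing a large alpha can switch on); pi,
    alpha and beta move by random-walk Metropolis with pilot-tuned step
    sizes.  The q-value of a locus is the mean local false-discovery rate
    (1 - inclusion) over all loci with inclusion at least its own.
    """
    idx_a = hierarchy.indices_for(gm, site=site, tidal_level=CRAB_LEVEL)
    idx_b = hierarchy.indices_for(gm, site=site, tidal_level=WAVE_LEVEL)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"site {site!r} lacks one of the two ecotype samples")
    counts, totals = [], []
    for idx in (idx_a, idx_b):
        d = gm.dosages[np.asarray(idx)]
        ok = d != MISSING
        counts.append(np.where(ok, d, 0).sum(axis=0).astype(float))
        totals.append((2 * ok.sum(axis=0)).astype(float))
    a = np.column_stack(counts)        # L x 2 alt-allele counts
    n = np.column_stack(totals)
    L = a.shape[0]
    rng = np.random.default_rng(seed)

    pi = np.clip(a.sum(axis=1) / np.maximum(n.sum(axis=1), 1), 0.05, 0.95)
    beta = np.full(2, -1.0)
    # empirical per-locus effect for the pseudo-prior: logit of the
    # method-of-moments FST between the two samples, relative to beta
    p1, p2 = a[:, 0] / np.maximum(n[:, 0], 1), a[:, 1] / np.maximum(n[:, 1], 1)
    pbar = (a.sum(axis=1)) / np.maximum(n.sum(axis=1), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = ((p1 - p2) ** 2) / np.maximum(2 * pbar * (1 - pbar), 1e-6)
    f_hat = np.clip(np.nan_to_num(f_hat), 1e-3, 0.95)
    pseudo_mu = np.clip(logit(f_hat) - beta.mean(), -3.0, 8.0)
    pseudo_sd = 1.0
    alpha = pseudo_mu.copy()
    delta = np.zeros(L, dtype=bool)
    p_incl = 1.0 / (1.0 + prior_odds)
    step_pi, step_alpha, step_beta = 0.5, 0.8, 0.1

    def loglik_rows(alpha_vec, pi_vec):
        f = expit(alpha_vec[:, None] + beta[None, :])
        return _betabinom_loglik(a, n, f, pi_vec[:, None]).sum(axis=1)

    def tune(rate, step):
        if rate < 0.20:
            return step * 0.7
        if rate > 0.45:
            return step * 1.4
        return step

    ll = loglik_rows(np.where(delta, alpha, 0.0), pi)

    def sweep(iters, adapt):
        nonlocal pi, alpha, delta, beta, ll, step_pi, step_alpha, step_beta
        acc = np.zeros(3)
        for _ in range(iters):
            # pi update (random walk on logit scale, Jacobian included)
            lp = logit(np.clip(pi, 1e-6, 1 - 1e-6))
            prop = lp + rng.normal(0, step_pi, L)
            pi_new = expit(prop)
            ll_new = loglik_rows(np.where(delta, alpha, 0.0), pi_new)
            log_acc = (ll_new + np.log(pi_new * (1 - pi_new))) - (
                ll + np.log(pi * (1 - pi))
            )
            accept = np.log(rng.random(L)) < log_acc
            pi = np.where(accept, pi_new, pi)
            ll = np.where(accept, ll_new, ll)
            acc[0] += accept.mean()
            # alpha update: MH (slab prior) if on, pseudo-prior Gibbs if off
            a_prop = np.where(
                delta,
                alpha + rng.normal(0, step_alpha, L),
                rng.normal(pseudo_mu, pseudo_sd, L),
            )
            ll_prop = loglik_rows(np.where(delta, a_prop, 0.0), pi)
            log_acc = (ll_prop - ll) + 0.5 * (alpha**2 - a_prop**2) / slab_sd**2
            accept = np.log(rng.random(L)) < log_acc
            accept |= ~delta                       # pseudo-prior draw: Gibbs
            alpha = np.where(accept, a_prop, alpha)
            ll = np.where(accept, ll_prop, ll)
            acc[1] += accept[delta].mean() if delta.any() else 0.25
            # delta update (Gibbs with Carlin-Chib pseudo-prior correction)
            ll_on = loglik_rows(alpha, pi)
            ll_off = loglik_rows(np.zeros(L), pi)
            log_prior_ratio = (
                -0.5 * alpha**2 / slab_sd**2 - np.log(slab_sd)
                + 0.5 * (alpha - pseudo_mu) ** 2 / pseudo_sd**2 + np.log(pseudo_sd)
            )
            logit_post = (
                np.log(p_incl / (1 - p_incl)) + ll_on - ll_off + log_prior_ratio
            )
            delta = rng.random(L) < expit(logit_post)
            ll = np.where(delta, ll_on, ll_off)
            # beta update, one population at a time
            for j in range(2):
                b_prop = beta.copy()
                b_prop[j] += rng.normal(0, step_beta)
                f = expit(np.where(delta, alpha, 0.0)[:, None] + b_prop[None, :])
                ll_prop = _betabinom_loglik(a, n, f, pi[:, None]).sum(axis=1)
                log_acc = (ll_prop.sum() - ll.sum()) + (
                    (beta[j] + 1) ** 2 - (b_prop[j] + 1) ** 2
                ) / (2 * 1.8**2)
                if np.log(rng.random()) < log_acc:
                    beta = b_prop
                    ll = ll_prop
                    acc[2] += 0.5
        if adapt and iters:
            rates = acc / iters
            step_pi = tune(rates[0], step_pi)
            step_alpha = tune(rates[1], step_alpha)
            step_beta = tune(rates[2], step_beta)

    for _ in range(pilot_runs):
        sweep(pilot_len, adapt=True)
    sweep(burn_in, adapt=False)
    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    beta_sum = np.zeros(2)
    halves = np.zeros((2, L))
    for k in range(n_samples):
        sweep(thin, adapt=False)
        incl_sum += delta
        alpha_sum += np.where(delta, alpha, 0.0)
        beta_sum += beta
        halves[k * 2 // n_samples if n_samples > 1 else 0] += delta
    inclusion = incl_sum / n_samples
    half_n = n_samples / 2
    disc = float(np.max(np.abs(halves[0] - halves[1]) / half_n)) if n_samples > 1 else 0.0
    converged = disc <= 0.1
    if not converged:
        warnings.warn(
            f"F-model chain may not have converged (split-half inclusion "
            f"discrepancy {disc:.2f} > 0.1)"
        )
    order = np.argsort(-inclusion, kind="stable")
    qv = np.empty(L)
    qv[order] = np.cumsum(1.0 - inclusion[order]) / np.arange(1, L + 1)
    names = gm.locus_names
    q = pd.Series(qv, index=names)
    return FModelPosterior(
        inclusion=pd.Series(inclusion, index=names),
        alpha_mean=pd.Series(alpha_sum / n_samples, index=names),
        beta_mean=beta_sum / n_samples,
        q=q,
        flags=q <= fdr,
        converged=converged,
    )


# -------------------------------------------------------------- consensus

@dataclass
class OutlierSet:
    """Per-method divergent sets for one site comparison plus consensus."""

    comparison: str
    method_sets: dict
    balancing_sets: dict = field(default_factory=dict)
    consensus: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.consensus:
            self.consensus = consensus_loci(self.method_sets)


def consensus_loci(method_sets: dict) -> set:
    """Loci flagged by at least two methods."""
    if len(method_sets) < 2:
        raise ValueError("need at least two method sets")
    tally: dict = {}
    for s in method_sets.values():
        for locus in s:
            tally[locus] = tally.get(locus, 0) + 1
    return {locus for locus, k in tally.items() if k >= 2}


# --------------------------------------------------------- site-level scan

@dataclass
class SiteScanResult:
    site: str
    stats: pd.DataFrame          # he, theta, per-method p/q, flags
    outliers: OutlierSet
    n_polymorphic: int
    balancing_raw: set
    balancing_sgof: set


def scan_site(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    site: str,
    n_demes: int = 100,
    n_sims: int = 20000,
    sgof_alpha: float = 0.05,
    fdr: float = 0.05,
    seed: int = 1,
    recalibrate: bool = True,
    fmodel_kwargs: dict | None = None,
    run_fmodel: bool = True,
) -> SiteScanResult:
    """Run all outlier methods between the two ecotypes of one site.

    Loci monomorphic in the pooled site sample are dropped before scanning,
    so reported fractions are over the site's polymorphic loci.
    """
    idx_a = hierarchy.indices_for(gm, site=site, tidal_level=CRAB_LEVEL)
    idx_b = hierarchy.indices_for(gm, site=site, tidal_level=WAVE_LEVEL)
    sub = gm.subset_individuals(np.concatenate([idx_a, idx_b]))
    d = sub.dosages
    ok = d != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, d, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))
    poly = (p > 0) & (p < 1)
    sub = sub.subset_loci(poly)
    ia = np.arange(len(idx_a))
    ib = np.arange(len(idx_a), len(idx_a) + len(idx_b))

    obs = _sample_stats(sub, ia, ib)
    rng = np.random.default_rng(seed)
    target = fdist_target_fst(obs["theta"].to_numpy())
    obs_he = obs["he"].to_numpy()
    null = fdist_simulate_null(
        target, n_demes, n_sims, (len(ia), len(ib)),
        seed=int(rng.integers(2**31 - 1)), match_he=obs_he,
    )
    pv = fdist_pvalues(obs, null)
    if recalibrate:
        provisional = (pv["p_upper"] < 0.05) | (pv["p_lower"] < 0.05)
        neutral = obs.loc[~provisional]
        target = fdist_target_fst(neutral["theta"].to_numpy())
        null = fdist_simulate_null(
            target, n_demes, n_sims, (len(ia), len(ib)),
            seed=int(rng.integers(2**31 - 1)), match_he=neutral["he"].to_numpy(),
        )
        pv = fdist_pvalues(obs, null)

    tested = pv["p_upper"].notna()
    names_tested = pv.index[tested]
    _, up_flags = sgof(pv.loc[tested, "p_upper"].to_numpy(), alpha=sgof_alpha)
    # divergent = upper-tail SGoF rejections that actually sit above the median
    fdist_set = set(names_tested[up_flags])
    _, lo_flags = sgof(pv.loc[tested, "p_lower"].to_numpy(), alpha=sgof_alpha)
    balancing_sgof = set(names_tested[lo_flags])
    balancing_raw = set(names_tested[pv.loc[tested, "p_lower"].to_numpy() <= 0.05])

    pca = pca_scan(sub, K=1, fdr=fdr)
    pca_set = set(pca.index[pca["flag"]])

    stats_tbl = obs.join(pv.add_prefix("fdist_")).join(pca.add_prefix("pca_"))
    method_sets = {"fdist": fdist_set, "pcadapt": pca_set}
    if run_fmodel:
        fm = fmodel_scan(
            sub, hierarchy.subset(sub.sample_ids), site,
            seed=int(rng.integers(2**31 - 1)), fdr=fdr,
            **(fmodel_kwargs or {}),
        )
        med = np.nanmedian(obs["theta"])
        fm_set = {
            loc for loc in fm.flags.index[fm.flags]
            if obs.loc[loc, "theta"] > med
        }
        method_sets["fmodel"] = fm_set
        stats_tbl = stats_tbl.join(
            pd.DataFrame({"fmodel_incl": fm.inclusion, "fmodel_q": fm.q})
        )
    outliers = OutlierSet(site, method_sets, {"fdist": balancing_sgof})
    stats_tbl["consensus"] = [n in outliers.consensus for n in stats_tbl.index]
    cls = np.where(
        stats_tbl["consensus"], "divergent",
        np.where(stats_tbl.index.isin(balancing_sgof), "balancing", "neutral"),
    )
    stats_tbl["class"] = cls
    return SiteScanResult(
        site, stats_tbl, outliers, int(poly.sum()), balancing_raw, balancing_sgof
    )
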