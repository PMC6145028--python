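"""Locus-by-locus hierarchical AMOVA (groups / populations / alleles).

Each genotyped individual contributes two allele draws per biallelic locus,
so the squared-difference allele distance reduces to a nested analysis of
variance on allele indicators — the standard SNP treatment.  Variance
components are estimated per locus with unequal-sample-size coefficients,
summed over loci, and the fixation indices formed from the summed
components ("averaged over all loci" as a ratio of sums, not a mean of
ratios):

    F_CT = sa / (sa + sb + sc)        among groups
    F_SC = sb / (sb + sc)             among populations within groups
    F_ST = (sa + sb) / (sa + sb + sc)

Negative component estimates are retained.  Significance is assessed by
permutation: whole populations among groups for F_CT, individuals among
populations within groups for F_SC, and individuals among all populations
for F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, SampleHierarchy


@dataclass
class AmovaResult:
    """Summed variance components, fixation indices and permutation p-values."""

    sigma_a: float
    sigma_b: float
    sigma_c: float
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None
    p_sc: float | None
    p_st: float | None
    n_loci_used: int
    grouping: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": ["among_groups", "among_pops_within_groups",
                              "within_pops"],
                "sigma2": [self.sigma_a, self.sigma_b, self.sigma_c],
                "F": [self.f_ct, self.f_sc, self.f_st],
                "F_name": ["F_CT", "F_SC", "F_ST"],
                "p": [self.p_ct, self.p_sc, self.p_st],
            }
        )


def _pop_allele_counts(dosages: np.ndarray, pop_of_ind: np.ndarray, n_pops: int):
    """Alt-allele counts s and total allele counts n per population x locus."""
    z = np.zeros((n_pops, dosages.shape[0]))
    z[pop_of_ind, np.arange(dosages.shape[0])] = 1.0
    ok = (dosages != MISSING).astype(float)
    s = z @ np.where(dosages == MISSING, 0, dosages).astype(float)
    n = 2.0 * (z @ ok)
    return s, n


def _components(s: np.ndarray, n: np.ndarray, group_of_pop: np.ndarray):
    """Per-locus variance components (sa, sb, sc) and a validity mask.

    ``s``/``n`` are populations x loci alt and total allele counts;
    ``group_of_pop`` assigns each population to a group.  Loci with an
    empty population cell or monomorphic in the compared subset are masked.
    """
    n_pops, n_loci = s.shape
    groups = np.unique(group_of_pop)
    n_groups = len(groups)
    gz = np.zeros((n_groups, n_pops))
    for gi, g in enumerate(groups):
        gz[gi, group_of_pop == g] = 1.0

    n_tot = n.sum(axis=0)
    s_tot = s.sum(axis=0)
    valid = (n > 0).all(axis=0) & (s_tot > 0) & (s_tot < n_tot)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = s / n
        n_g = gz @ n
        s_g = gz @ s
        p_g = s_g / n_g
        p_bar = s_tot / n_tot

        ss_wp = (s * (n - s) / n).sum(axis=0)
        ss_ap = (n * (p - gz.T @ p_g) ** 2).sum(axis=0)
        ss_ag = (n_g * (p_g - p_bar) ** 2).sum(axis=0)

        sum_n2_over_ng = ((gz @ (n**2)) / n_g).sum(axis=0)
        n_prime = (n_tot - sum_n2_over_ng) / (n_pops - n_groups)
        n_dprime = (sum_n2_over_ng - (n**2).sum(axis=0) / n_tot) / (n_groups - 1) \
            if n_groups > 1 else np.full(n_loci, np.nan)
        n_tprime = (n_tot - (n_g**2).sum(axis=0) / n_tot) / (n_groups - 1) \
            if n_groups > 1 else np.full(n_loci, np.nan)

        sc = ss_wp / (n_tot - n_pops)
        sb = (ss_ap / (n_pops - n_groups) - sc) / n_prime
        sa = (ss_ag / (n_groups - 1) - sc - n_dprime * sb) / n_tprime \
            if n_groups > 1 else np.zeros(n_loci)
    return sa, sb, sc, valid


def _f_stats(sa: float, sb: float, sc: float):
    total = sa + sb + sc
    f_ct = sa / total if total else float("nan")
    f_sc = sb / (sb + sc) if (sb + sc) else float("nan")
    f_st = (sa + sb) / total if total else float("nan")
    return f_ct, f_sc, f_st


def hierarchical_amova(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    group_by: str = "site",
    n_perm: int = 1000,
    seed: int = 0,
    exclude_mid: bool = True,
    pop_by: str = "site_level",
) -> AmovaResult:
    """Locus-by-locus AMOVA of (site x tidal-level) populations.

    ``group_by='site'`` asks how much variance geography explains (ecotype
    populations nested in sites); ``group_by='tidal_level'`` asks the same
    of ecotype (site samples nested in shore levels).  Mid-shore admixed
    individuals are excluded by default.

    ``pop_by='site_level_transect'`` splits populations by transect as
    well.  Because F_CT significance permutes whole populations among
    groups, its achievable p-value is floored by the number of distinct
    population-to-group assignments; transect-level populations (4 per
    site instead of 2) remove that floor when replicate transects exist.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be non-negative")
    tbl = hierarchy.table.loc[gm.sample_ids]
    keep = np.ones(gm.n_individuals, dtype=bool)
    if exclude_mid:
        keep = (tbl["tidal_level"] != "mid").to_numpy()
    sub = gm.subset_individuals(keep)
    tbl = tbl.loc[keep]

    if pop_by == "site_level":
        pop_labels = (tbl["site"] + ":" + tbl["tidal_level"]).to_numpy()
    elif pop_by == "site_level_transect":
        pop_labels = (
            tbl["site"] + ":" + tbl["tidal_level"] + ":" + tbl["transect"]
        ).to_numpy()
    else:
        raise ValueError("pop_by must be 'site_level' or 'site_level_transect'")
    pops, pop_of_ind = np.unique(pop_labels, return_inverse=True)
    group_label_of_pop = np.array(
        [p.split(":")[0] if group_by == "site" else p.split(":")[1] for p in pops]
    )
    if group_by not in ("site", "tidal_level"):
        raise ValueError("group_by must be 'site' or 'tidal_level'")
    if len(np.unique(group_label_of_pop)) < 2:
        raise ValueError("F_CT undefined with a single group")

    rng = np.random.default_rng(seed)
    s, n = _pop_allele_counts(sub.dosages, pop_of_ind, len(pops))
    sa, sb, sc, valid = _components(s, n, group_label_of_pop)

    def summed(sa, sb, sc, valid):
        return sa[valid].sum(), sb[valid].sum(), sc[valid].sum()

    A, B, C = summed(sa, sb, sc, valid)
    f_ct, f_sc, f_st = _f_stats(A, B, C)

    p_ct = p_sc = p_st = None
    if n_perm > 0:
        # F_CT: permute whole populations among groups
        exceed = 0
        for _ in range(n_perm):
            perm_groups = rng.permutation(group_label_of_pop)
            psa, psb, psc, pv = _components(s, n, perm_groups)
            pf = _f_stats(*summed(psa, psb, psc, pv))[0]
            if pf >= f_ct:
                exceed += 1
        p_ct = (1 + exceed) / (n_perm + 1)

        # F_SC: permute individuals among populations within their group
        group_of_ind = group_label_of_pop[pop_of_ind]
        exceed = 0
        for _ in range(n_perm):
            perm = pop_of_ind.copy()
            for g in np.unique(group_of_ind):
                idx = np.flatnonzero(group_of_ind == g)
                perm[idx] = pop_of_ind[idx][rng.permutation(len(idx))]
            ps, pn = _pop_allele_counts(sub.dosages, perm, len(pops))
            psa, psb, psc, pv = _components(ps, pn, group_label_of_pop)
            pf = _f_stats(*summed(psa, psb, psc, pv))[1]
            if pf >= f_sc:
                exceed += 1
        p_sc = (1 + exceed) / (n_perm + 1)

        # F_ST: permute individuals among all populations
        exceed = 0
        for _ in range(n_perm):
            perm = pop_of_ind[rng.permutation(len(pop_of_ind))]
            ps, pn = _pop_allele_counts(sub.dosages, perm, len(pops))
            psa, psb, psc, pv = _components(ps, pn, group_label_of_pop)
            pf = _f_stats(*summed(psa, psb, psc, pv))[2]
            if pf >= f_st:
                exceed += 1
        p_st = (1 + exceed) / (n_perm + 1)

    return AmovaResult(
        A, B, C, f_ct, f_sc, f_st, p_ct, p_sc, p_st,
        int(valid.sum()), f"group_by={group_by}",
    )
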