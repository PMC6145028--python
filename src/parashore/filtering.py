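"""SNP retention rules and QC statistics.

Pipeline order is: first-SNP-per-RAD-locus selection, then the call-rate /
minor-allele-frequency thresholds, then HWE and LD *flagging*.  HWE and LD
flags never remove loci — departures can have biological causes — they are
carried in the report for downstream interpretation.

Thresholds follow the conventions of RADseq population pipelines: a locus is
retained when >= 70% of individuals are genotyped AND the pooled minor
allele frequency is strictly greater than 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import MISSING, GenotypeMatrix, SampleHierarchy


@dataclass
class FilterReport:
    """Per-locus QC bookkeeping.

    ``loci`` has one row per input locus: call_rate, maf, retained, reason
    (empty when retained; otherwise the first failing rule).  ``hwe`` is a
    populations x loci table of exact-test p-values with per-population
    Bonferroni flags in ``hwe_flagged``; ``ld_linked`` marks loci in at least
    one pair with r-squared above threshold in every site.
    """

    loci: pd.DataFrame
    hwe: pd.DataFrame | None = None
    hwe_flagged: pd.DataFrame | None = None
    ld_linked: pd.Series | None = None
    ld_pairs: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        out = self.loci.copy()
        if self.hwe_flagged is not None:
            out["hwe_flagged_any"] = self.hwe_flagged.any(axis=0).reindex(out.index)
        if self.ld_linked is not None:
            out["ld_linked"] = self.ld_linked.reindex(out.index)
        out.to_csv(path, sep="\t")


def filter_loci(
    gm: GenotypeMatrix, call_rate_min: float = 0.70, maf_min: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci below the call-rate or MAF thresholds.

    Call rate is compared inclusively (a locus at exactly the threshold is
    retained); MAF strictly (a locus at exactly ``maf_min`` is removed).
    MAF is pooled over all genotyped samples.
    """
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if gm.n_loci == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    ok = gm.dosages != MISSING
    n = ok.sum(axis=0)
    call_rate = n / gm.n_individuals
    alt = np.where(ok, gm.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    maf = np.fmin(p, 1.0 - p)
    reason = np.array([""] * gm.n_loci, dtype=object)
    fail_cr = call_rate < call_rate_min
    fail_maf = ~fail_cr & (~(maf > maf_min) | np.isnan(maf))
    reason[fail_cr] = "call_rate"
    reason[fail_maf] = "maf"
    retained = reason == ""
    report = FilterReport(
        pd.DataFrame(
            {"call_rate": call_rate, "maf": maf, "retained": retained, "reason": reason},
            index=gm.locus_names,
        )
    )
    return gm.subset_loci(retained), report


def first_snp_per_rad_locus(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep, per RAD locus, the SNP with the smallest read offset.

    Ties in offset are broken by input order.  This minimizes short-range
    physical linkage between SNPs on the same sequenced fragment.
    """
    best: dict[int, int] = {}
    for i, (rad, off) in enumerate(gm.locus_ids):
        j = best.get(rad)
        if j is None or off < gm.locus_ids[j][1]:
            best[rad] = i
    keep = sorted(best.values())
    return gm.subset_loci(keep)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test for one biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one (Wigginton-style SNP-HWE).  Monomorphic input
    returns 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("genotype counts all zero")
    n_a = 2 * n_hom_ref + n_het           # allele-A count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def hwe_flag(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    alpha: float = 0.05,
    report: FilterReport | None = None,
) -> FilterReport:
    """Per-population HWE exact tests with per-population Bonferroni flags.

    A locus is flagged in a population when its exact p-value falls below
    ``alpha`` divided by the number of loci tested in that population.
    Flagged loci are reported, never removed.
    """
    pops = hierarchy.population_labels()
    pvals, flags = {}, {}
    for pop in dict.fromkeys(pops.loc[gm.sample_ids]):
        idx = [i for i, s in enumerate(gm.sample_ids) if pops.loc[s] == pop]
        d = gm.dosages[idx]
        genotyped = (d != MISSING).sum(axis=0)
        if (genotyped >= 2).sum() == 0 or len(idx) < 2:
            warnings.warn(f"population {pop!r} has <2 genotyped individuals; skipped")
            continue
        row = np.ones(gm.n_loci)
        tested = 0
        for j in range(gm.n_loci):
            if genotyped[j] < 2:
                row[j] = np.nan
                continue
            col = d[:, j]
            col = col[col != MISSING]
            row[j] = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            tested += 1
        pvals[pop] = row
        flags[pop] = row < (alpha / tested if tested else np.inf)
    if report is None:
        report = FilterReport(pd.DataFrame(index=gm.locus_names))
    report.hwe = pd.DataFrame(pvals, index=gm.locus_names).T
    report.hwe_flagged = pd.DataFrame(flags, index=gm.locus_names).T
    return report


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns over complete cases."""
    x = d.astype(np.float64)
    m = (d != MISSING).astype(np.float64)
    x = np.where(d == MISSING, 0.0, x)
    n = m.T @ m
    sx = x.T @ m          # sum of x over cases shared with each partner
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        r2 = (cov * cov) / (varx * varx.T)
    r2[(varx <= 0) | (varx.T <= 0) | (n < 2)] = np.nan
    return r2


def ld_flag(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    r2_min: float = 0.2,
    by: str = "site",
    report: FilterReport | None = None,
) -> FilterReport:
    """Flag loci in at least one pair with r-squared > ``r2_min`` in every group.

    Groups default to sites; ``by='site_level'`` uses the finer site x
    tidal-level grouping.  A pair lacking a defined correlation in a group
    (zero variance there) does not satisfy the rule for that group.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least two loci")
    if by == "site":
        groups = hierarchy.table.loc[gm.sample_ids, "site"]
    elif by == "site_level":
        groups = hierarchy.population_labels().loc[gm.sample_ids]
    else:
        raise ValueError("by must be 'site' or 'site_level'")
    exceeds = np.ones((gm.n_loci, gm.n_loci), dtype=bool)
    for g in dict.fromkeys(groups):
        idx = np.flatnonzero((groups == g).to_numpy())
        r2 = _pairwise_r2(gm.dosages[idx])
        with np.errstate(invalid="ignore"):
            exceeds &= r2 > r2_min
    np.fill_diagonal(exceeds, False)
    linked = exceeds.any(axis=1)
    ii, jj = np.nonzero(np.triu(exceeds, 1))
    names = gm.locus_names
    if report is None:
        report = FilterReport(pd.DataFrame(index=names))
    report.ld_linked = pd.Series(linked, index=names, name="ld_linked")
    report.ld_pairs = pd.DataFrame(
        {"locus_a": [names[i] for i in ii], "locus_b": [names[j] for j in jj]}
    )
    return report
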