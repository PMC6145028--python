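"""Allele frequencies, heterozygosity and Weir–Cockerham FST.

The two-level Weir & Cockerham (1984) theta is the workhorse differentiation
estimator: per-locus variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed from
sample sizes, allele frequencies and observed heterozygosities, and the
multilocus estimate is the ratio of summed components sum(a)/sum(a+b+c) —
not the mean of per-locus ratios.  Negative per-locus estimates are retained.
Pairwise significance comes from permuting individuals between the two
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix


def expected_het(p):
    """He = 2p(1-p) for a biallelic locus."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return 2.0 * p * (1.0 - p)


def allele_frequencies(gm: GenotypeMatrix, grouping) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group per-locus alt-allele frequency and genotyped counts.

    ``grouping`` maps group label -> row indices into ``gm``.  Cells with no
    genotyped individual are NaN.
    """
    freqs, counts = {}, {}
    for label, idx in grouping.items():
        if len(idx) == 0:
            raise ValueError(f"group {label!r} is empty")
        d = gm.dosages[np.asarray(idx)]
        ok = d != MISSING
        n = ok.sum(axis=0)
        s = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[label] = np.where(n > 0, s / (2.0 * n), np.nan)
        counts[label] = n
    names = gm.locus_names
    return (
        pd.DataFrame(freqs, index=names).T,
        pd.DataFrame(counts, index=names).T,
    )


def _wc_components(d_a: np.ndarray, d_b: np.ndarray):
    """Per-locus W&C (1984) components a, b, c for two groups of dosages."""
    comps = []
    for d in (d_a, d_b):
        ok = d != MISSING
        n = ok.sum(axis=0).astype(float)
        s = np.where(ok, d, 0).sum(axis=0)
        het = np.where(ok, d == 1, False).sum(axis=0)
        comps.append((n, s, het))
    (n1, s1, h1), (n2, s2, h2) = comps
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = s1 / (2 * n1), s2 / (2 * n2)
        hf1, hf2 = h1 / n1, h2 / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2v = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * hf1 + n2 * hf2) / (r * nbar)
        a = (nbar / nc) * (
            s2v - (pbar * (1 - pbar) - s2v * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2v * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    # monomorphic across both groups: no information
    poly = valid & ~((pbar <= 0) | (pbar >= 1)) | (valid & (s2v > 0))
    for arr in (a, b, c):
        arr[~poly] = np.nan
    return a, b, c


def wc_theta(gm: GenotypeMatrix, idx_a, idx_b) -> tuple[pd.Series, float]:
    """Per-locus Weir–Cockerham theta and the ratio-of-sums multilocus value."""
    a, b, c = _wc_components(gm.dosages[np.asarray(idx_a)], gm.dosages[np.asarray(idx_b)])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    ok = ~np.isnan(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    multi = float(np.nansum(a[ok]) / denom) if denom != 0 else float("nan")
    return pd.Series(theta, index=gm.locus_names, name="theta"), multi


def pairwise_fst_test(
    gm: GenotypeMatrix, grouping: dict, n_perm: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multilocus theta between all group pairs with permutation p-values.

    p = (1 + #{permuted theta >= observed}) / (n_perm + 1), permuting
    individuals between the two groups.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(grouping) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    labels = list(grouping)
    theta_m = pd.DataFrame(np.nan, index=labels, columns=labels)
    p_m = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ia = np.asarray(grouping[la])
            ib = np.asarray(grouping[lb])
            _, obs = wc_theta(gm, ia, ib)
            pool = np.concatenate([ia, ib])
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                _, t = wc_theta(gm, perm[: len(ia)], perm[len(ia):])
                if t >= obs:
                    exceed += 1
            p = (1 + exceed) / (n_perm + 1)
            theta_m.loc[la, lb] = theta_m.loc[lb, la] = obs
            p_m.loc[la, lb] = p_m.loc[lb, la] = p
    return theta_m, p_m
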