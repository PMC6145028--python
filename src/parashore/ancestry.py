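"""Supervised two-source admixture estimation and hybrid classification.

For a focal individual and two reference panels A (crab ecotype) and B
(wave ecotype), the admixture proportion Q — the fraction of the genome
drawn from panel B — maximizes the binomial genotype likelihood

    sum_l log Binom(g_l | 2, Q * p_Bl + (1 - Q) * p_Al)

over Q in [0, 1], assuming Hardy-Weinberg proportions within the mixture.
The likelihood is unimodal in the mixture frequency, so a bounded 1-D
optimization is exact and deterministic.  Panel frequencies carry a 0.5
pseudocount per allele to avoid 0/1 singularities.  Individuals with
0.20 <= Q <= 0.80 (inclusive, configurable) are classified as putative
recent hybrids or backcrosses; others as crab-like or wave-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datamodel import MISSING, GenotypeMatrix, SampleHierarchy
from .synthetic import CRAB_LEVEL, WAVE_LEVEL


@dataclass
class AncestryEstimate:
    """Per-individual Q (wave-ancestry fraction), likelihood and label."""

    table: pd.DataFrame  # columns: q, loglik, n_loci, label

    def hybrid_count(self) -> int:
        return int((self.table["label"] == "putative-hybrid").sum())


def reference_freqs(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    ref_a: tuple[str, str],
    ref_b: tuple[str, str],
) -> pd.DataFrame:
    """Pseudocounted allele frequencies of the two reference populations.

    ``ref_a``/``ref_b`` are (site, tidal_level) population selectors.  Loci
    untyped in either panel are excluded.  Each panel frequency gets a 0.5
    pseudocount per allele class.
    """
    freqs = {}
    for name, (site, level) in (("A", ref_a), ("B", ref_b)):
        idx = hierarchy.indices_for(gm, site=site, tidal_level=level)
        if len(idx) == 0:
            raise ValueError(f"reference population {site}:{level} is empty")
        d = gm.dosages[idx]
        ok = d != MISSING
        n = 2.0 * ok.sum(axis=0)
        alt = np.where(ok, d, 0).sum(axis=0)
        freqs[name] = np.where(n > 0, (alt + 0.5) / (n + 1.0), np.nan)
        freqs[f"n_{name}"] = n
    out = pd.DataFrame(
        {"p_a": freqs["A"], "p_b": freqs["B"]}, index=gm.locus_names
    )
    return out.dropna()


def estimate_q(
    dosages: np.ndarray, p_a: np.ndarray, p_b: np.ndarray, min_loci: int = 20
) -> tuple[float, float]:
    """Maximum-likelihood Q for one individual; returns (q, loglik).

    Returns (nan, nan) when no locus is informative (p_a == p_b
    everywhere), which callers should treat as undefined.
    """
    g = np.asarray(dosages, dtype=float)
    ok = g != MISSING
    g, pa, pb = g[ok], np.asarray(p_a)[ok], np.asarray(p_b)[ok]
    if g.size < min_loci:
        raise ValueError(f"only {g.size} genotyped loci; need >= {min_loci}")
    informative = pa != pb
    if not informative.any():
        return float("nan"), float("nan")

    def nll(q):
        p = np.clip(q * pb + (1 - q) * pa, 1e-9, 1 - 1e-9)
        return -(g * np.log(p) + (2 - g) * np.log(1 - p)).sum()

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x), float(-res.fun)


def estimate_q_all(
    gm: GenotypeMatrix,
    hierarchy: SampleHierarchy,
    site: str,
    individuals=None,
) -> pd.DataFrame:
    """Q for the given individuals against the site's two ecotype panels.

    Defaults to the site's mid-shore individuals scored against its
    upper-shore (crab, A) and lower-shore (wave, B) panels.
    """
    panel = reference_freqs(
        gm, hierarchy, (site, CRAB_LEVEL), (site, WAVE_LEVEL)
    )
    sub = gm.loci_by_name(panel.index)
    if individuals is None:
        idx = hierarchy.indices_for(gm, site=site, tidal_level="mid")
        individuals = [gm.sample_ids[i] for i in idx]
    pos = {s: i for i, s in enumerate(sub.sample_ids)}
    rows = []
    for ind in individuals:
        q, ll = estimate_q(
            sub.dosages[pos[ind]], panel["p_a"].to_numpy(), panel["p_b"].to_numpy()
        )
        rows.append({"sample": ind, "q": q, "loglik": ll,
                     "n_loci": int((sub.dosages[pos[ind]] != MISSING).sum())})
    return pd.DataFrame(rows).set_index("sample")


def classify_hybrids(
    q_table: pd.DataFrame, lo: float = 0.20, hi: float = 0.80
) -> AncestryEstimate:
    """Label individuals by the Q window: putative hybrids inside [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    q = q_table["q"]
    label = np.where(
        q.isna(), "undefined",
        np.where((q >= lo) & (q <= hi), "putative-hybrid",
                 np.where(q > hi, "wave-like", "crab-like")),
    )
    out = q_table.copy()
    out["label"] = label
    return AncestryEstimate(out)
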