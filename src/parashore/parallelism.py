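"""Outlier sharing across replicate sites with a random-resampling null.

The headline question of a parallel-divergence study is how many divergent
loci replicate sites have in common.  Two percentage conventions are in
circulation and both are always reported:

* ``percentage_union`` — 100 * |intersection| / |union of the compared
  lists| (the convention of per-method sharing tables);
* ``percentage_list`` — 100 * |intersection| / |each site's own list|
  (the convention behind headline "X% of loci shared" statements).

Significance comes from a resampling null: each replicate draws, per site,
a uniform random subset of the observed list size from that site's pool of
tested loci, recomputes the sharing statistics, and the 2.5th/97.5th
percentiles across replicates give the 95% null band.  The analytic
hypergeometric mean pairwise intersection |S1||S2||P1 ∩ P2| / (|P1||P2|) is
reported alongside as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


def sharing_percentages(shared: int, union: int, list_sizes=()) -> dict:
    """Both percentage conventions from raw counts."""
    out = {
        "percentage_union": 100.0 * shared / union if union else 0.0,
    }
    for k, size in enumerate(list_sizes):
        out[f"percentage_list_{k}"] = 100.0 * shared / size if size else 0.0
    return out


@dataclass
class SharingResult:
    """Observed sharing counts/percentages plus (optionally) the null band."""

    observed: pd.DataFrame                 # one row per comparison
    null: pd.DataFrame | None = None       # null mean + CI per comparison
    n_reps: int = 0
    seed: int | None = None


def sharing_stats(sets: dict) -> pd.DataFrame:
    """Pairwise and k-way shared-locus counts and percentages.

    ``sets`` maps site label -> set of locus names (a global namespace).
    Returns one row per pairwise comparison plus one ``all`` row for the
    k-way intersection.
    """
    if len(sets) < 2:
        raise ValueError("need at least two locus sets")
    labels = list(sets)
    rows = []
    for la, lb in combinations(labels, 2):
        a, b = sets[la], sets[lb]
        if not a or not b:
            warnings.warn(f"empty outlier list in comparison {la}-{lb}")
        inter, union = len(a & b), len(a | b)
        row = {
            "comparison": f"{la}-{lb}",
            "shared": inter,
            "union": union,
            f"n_{la}": len(a),
            f"n_{lb}": len(b),
            "percentage_union": 100.0 * inter / union if union else 0.0,
            f"percentage_of_{la}": 100.0 * inter / len(a) if a else 0.0,
            f"percentage_of_{lb}": 100.0 * inter / len(b) if b else 0.0,
        }
        rows.append(row)
    inter_all = set.intersection(*(set(s) for s in sets.values()))
    union_all = set.union(*(set(s) for s in sets.values()))
    row = {
        "comparison": "all",
        "shared": len(inter_all),
        "union": len(union_all),
        "percentage_union": 100.0 * len(inter_all) / len(union_all)
        if union_all else 0.0,
    }
    for lab in labels:
        row[f"n_{lab}"] = len(sets[lab])
        row[f"percentage_of_{lab}"] = (
            100.0 * len(inter_all) / len(sets[lab]) if sets[lab] else 0.0
        )
    rows.append(row)
    return pd.DataFrame(rows).set_index("comparison")


def hypergeometric_mean_intersection(
    n_a: int, n_b: int, pool_a: set, pool_b: set
) -> float:
    """Expected |A ∩ B| for uniform draws of sizes n_a, n_b from the pools."""
    shared_pool = len(set(pool_a) & set(pool_b))
    if len(pool_a) == 0 or len(pool_b) == 0:
        return 0.0
    return n_a * n_b * shared_pool / (len(pool_a) * len(pool_b))


def resample_null(
    list_sizes: dict,
    pools: dict,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Null distribution of sharing under random list draws from the pools.

    ``list_sizes`` maps site -> observed list size; ``pools`` maps site ->
    the site's tested-locus set.  Returns, per comparison and statistic,
    the null mean and the 2.5/97.5 percentile band, plus the analytic
    hypergeometric mean intersection for pairwise comparisons.
    """
    if n_reps < 100:
        warnings.warn("n_reps < 100: null confidence band will be unstable")
    labels = list(list_sizes)
    pool_arrays = {}
    for lab in labels:
        pool = np.asarray(sorted(pools[lab]))
        if list_sizes[lab] > len(pool):
            raise ValueError(f"list size exceeds pool size for {lab!r}")
        pool_arrays[lab] = pool
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        draw = {
            lab: set(
                rng.choice(pool_arrays[lab], size=list_sizes[lab], replace=False)
            )
            for lab in labels
        }
        reps.append(sharing_stats(draw))
    stacked = pd.concat(reps, keys=range(n_reps))
    stat_cols = [
        c for c in stacked.columns
        if c.startswith(("shared", "percentage"))
    ]
    grouped = stacked[stat_cols].groupby(level=1)
    out = pd.concat(
        {
            "null_mean": grouped.mean(),
            "null_lo": grouped.quantile(0.025),
            "null_hi": grouped.quantile(0.975),
        },
        axis=1,
    )
    out.columns = [f"{stat}_{which}" for which, stat in out.columns]
    hyper = {}
    for la, lb in combinations(labels, 2):
        hyper[f"{la}-{lb}"] = hypergeometric_mean_intersection(
            list_sizes[la], list_sizes[lb], pools[la], pools[lb]
        )
    out["hypergeom_mean_shared"] = pd.Series(hyper)
    return out


def sharing_analysis(
    sets: dict,
    pools: dict,
    n_reps: int = 1000,
    seed: int = 0,
) -> SharingResult:
    """Observed sharing plus the resampled null for the same list sizes."""
    observed = sharing_stats(sets)
    null = resample_null(
        {lab: len(s) for lab, s in sets.items()}, pools, n_reps, seed
    )
    return SharingResult(observed, null, n_reps, seed)
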