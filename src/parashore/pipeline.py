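"""Configuration-driven orchestration of the full analysis.

simulate (or load) -> filter -> per-site outlier scans -> consensus ->
cross-site sharing with resampling null -> hierarchical AMOVA -> NJ trees
-> mid-shore ancestry.  A single global seed fans out to per-stage child
seeds, so reruns with the same configuration are byte-identical and adding
a stage does not disturb the seeds of the others.  Every table the summary
reports is also written as a TSV artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amova as amova_mod
from . import ancestry as ancestry_mod
from . import filtering, io, parallelism, phylo
from .outliers import scan_site
from .synthetic import SimConfig, simulate_dataset

log = logging.getLogger("parashore")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the study's settings."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    genotypes_path: str | None = None     # if set, load instead of simulate
    genotypes_format: str = "genepop"
    popmap_path: str | None = None
    call_rate_min: float = 0.70
    maf_min: float = 0.01
    hwe_alpha: float = 0.05
    ld_r2: float = 0.2
    run_ld: bool = True
    fdist_n_demes: int = 100
    fdist_n_sims: int = 20000
    fdist_recalibrate: bool = True
    sgof_alpha: float = 0.05
    fdr: float = 0.05
    run_fmodel: bool = True
    fmodel_kwargs: dict = field(default_factory=dict)
    n_perm: int = 1000
    n_boot: int = 1000
    n_resample: int = 1000
    n_neutral_tree_loci: int = 2000
    run_trees: bool = True
    q_lo: float = 0.20
    q_hi: float = 0.80

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if isinstance(sim.sites, list):
            sim.sites = tuple(sim.sites)
        return cls(sim=sim, **raw)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage and return (and write) the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    summary: dict = {"seed": cfg.seed, "thresholds": {
        "call_rate_min": cfg.call_rate_min, "maf_min": cfg.maf_min,
        "hwe_alpha": cfg.hwe_alpha, "ld_r2": cfg.ld_r2,
        "fdist": [cfg.fdist_n_sims, cfg.fdist_n_demes],
        "sgof_alpha": cfg.sgof_alpha, "fdr": cfg.fdr,
        "n_perm": cfg.n_perm, "n_boot": cfg.n_boot,
        "q_window": [cfg.q_lo, cfg.q_hi],
    }}

    # ------------------------------------------------------------ data
    truth = None
    if cfg.genotypes_path:
        log.info("loading genotypes from %s", cfg.genotypes_path)
        gm, hierarchy = io.load_genotypes(
            cfg.genotypes_path, cfg.genotypes_format, cfg.popmap_path
        )
    else:
        sim_cfg = cfg.sim
        sim_cfg.seed = seeds[0]
        log.info("simulating dataset (seed %d)", sim_cfg.seed)
        gm, hierarchy, truth = simulate_dataset(sim_cfg)
        truth.to_frame(gm.locus_names).to_csv(
            outdir / "truth.tsv", sep="\t", index=False
        )
        io.save_popmap(hierarchy, outdir / "popmap.tsv")
    summary["n_individuals"] = gm.n_individuals
    summary["n_loci_input"] = gm.n_loci

    # ---------------------------------------------------------- filter
    gm = filtering.first_snp_per_rad_locus(gm)
    gm, report = filtering.filter_loci(gm, cfg.call_rate_min, cfg.maf_min)
    report = filtering.hwe_flag(gm, hierarchy, cfg.hwe_alpha, report)
    if cfg.run_ld:
        report = filtering.ld_flag(gm, hierarchy, cfg.ld_r2, report=report)
        summary["n_ld_linked"] = int(report.ld_linked.sum())
    report.to_tsv(outdir / "filter_report.tsv")
    summary["n_loci_retained"] = gm.n_loci
    summary["n_hwe_flagged"] = (
        int(report.hwe_flagged.any(axis=0).sum())
        if report.hwe_flagged is not None else 0
    )
    log.info("%d loci retained after filtering", gm.n_loci)

    # --------------------------------------------------- per-site scans
    sites = hierarchy.sites
    scan_seed_rng = np.random.default_rng(seeds[1])
    scans = {}
    sets, pools = {}, {}
    per_site = {}
    for site in sites:
        res = scan_site(
            gm, hierarchy, site,
            n_demes=cfg.fdist_n_demes, n_sims=cfg.fdist_n_sims,
            sgof_alpha=cfg.sgof_alpha, fdr=cfg.fdr,
            seed=int(scan_seed_rng.integers(2**31 - 1)),
            recalibrate=cfg.fdist_recalibrate,
            run_fmodel=cfg.run_fmodel, fmodel_kwargs=cfg.fmodel_kwargs,
        )
        scans[site] = res
        res.stats.to_csv(outdir / f"scan_{site}.tsv", sep="\t")
        sets[site] = res.outliers.consensus
        pools[site] = set(res.stats.index[res.stats["fdist_p_upper"].notna()])
        per_site[site] = {
            "polymorphic": res.n_polymorphic,
            "consensus_divergent": len(res.outliers.consensus),
            "balancing_sgof": len(res.balancing_sgof),
            **{
                f"{m}_divergent": len(s)
                for m, s in res.outliers.method_sets.items()
            },
            **{
                f"{m}_pct": round(100 * len(s) / res.n_polymorphic, 2)
                for m, s in res.outliers.method_sets.items()
            },
        }
        log.info("site %s: %d consensus divergent of %d polymorphic",
                 site, len(sets[site]), res.n_polymorphic)
    summary["per_site"] = per_site

    # --------------------------------------------------------- sharing
    sharing = parallelism.sharing_analysis(
        sets, pools, n_reps=cfg.n_resample, seed=seeds[2]
    )
    sharing.observed.to_csv(outdir / "sharing_observed.tsv", sep="\t")
    sharing.null.to_csv(outdir / "sharing_null.tsv", sep="\t")
    summary["sharing"] = json.loads(
        sharing.observed.round(4).to_json(orient="index")
    )
    summary["sharing_null"] = json.loads(
        sharing.null.round(4).to_json(orient="index")
    )

    # ----------------------------------------------------------- AMOVA
    amova_rows = []
    southern = [s for s in sites
                if cfg.sim.refugium_of.get(s) == "south"] if truth is not None else sites[:2]
    runs = [("all", None, "site"), ("all", None, "tidal_level")]
    if len(southern) >= 2:
        runs += [("southern", southern, "tidal_level")]
    amova_summary = {}
    for label, site_subset, group_by in runs:
        g, h = gm, hierarchy
        if site_subset is not None:
            idx = np.concatenate(
                [h.indices_for(g, site=s) for s in site_subset]
            )
            g = g.subset_individuals(sorted(idx))
            h = h.subset(g.sample_ids)
        res = amova_mod.hierarchical_amova(
            g, h, group_by=group_by, n_perm=cfg.n_perm, seed=seeds[3]
        )
        frame = res.to_frame()
        frame.insert(0, "run", f"{label}:{group_by}")
        amova_rows.append(frame)
        amova_summary[f"{label}:{group_by}"] = {
            "F_CT": round(res.f_ct, 4), "F_SC": round(res.f_sc, 4),
            "F_ST": round(res.f_st, 4), "p_CT": res.p_ct, "p_SC": res.p_sc,
            "n_loci": res.n_loci_used,
        }
    pd.concat(amova_rows).to_csv(outdir / "amova.tsv", sep="\t", index=False)
    summary["amova"] = amova_summary

    # ----------------------------------------------------------- trees
    if cfg.run_trees:
        rng = np.random.default_rng(seeds[4])
        union_div = sorted(set.union(*sets.values())) if any(sets.values()) else []
        classes = {}
        for site, res in scans.items():
            for loc, cl in res.stats["class"].items():
                if cl != "neutral":
                    classes[loc] = cl
        neutral_pool = [n for n in gm.locus_names if n not in classes]
        k = min(cfg.n_neutral_tree_loci, len(neutral_pool))
        neutral_panel = sorted(
            rng.choice(np.asarray(neutral_pool), size=k, replace=False)
        )
        t_neutral = phylo.bootstrap_support(
            gm, neutral_panel, n_boot=cfg.n_boot, seed=seeds[5]
        )
        io.write_newick(phylo.midpoint_root(t_neutral), outdir / "tree_neutral.nwk")
        summary["tree_neutral_loci"] = k
        if len(union_div) >= 10:
            t_div = phylo.bootstrap_support(
                gm, union_div, n_boot=cfg.n_boot, seed=seeds[6]
            )
            io.write_newick(
                phylo.midpoint_root(t_div), outdir / "tree_divergent.nwk"
            )
            summary["tree_divergent_loci"] = len(union_div)

    # -------------------------------------------------------- ancestry
    anc_rows, hybrid_counts = [], {}
    for site in sites:
        q_tbl = ancestry_mod.estimate_q_all(gm, hierarchy, site)
        est = ancestry_mod.classify_hybrids(q_tbl, cfg.q_lo, cfg.q_hi)
        tbl = est.table.copy()
        tbl.insert(0, "site", site)
        anc_rows.append(tbl)
        hybrid_counts[site] = est.hybrid_count()
    anc = pd.concat(anc_rows)
    anc.to_csv(outdir / "ancestry.tsv", sep="\t")
    summary["hybrid_counts"] = hybrid_counts
    summary["n_mid_shore"] = int(len(anc))

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary
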