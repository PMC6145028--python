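"""Synthetic genotype datasets with planted truth.

The generator emulates the sampling design of a replicated shore-ecotype
study: three sites colonized from two glacial refugia (two southern sites,
one northern), each sampled at three tidal levels — upper shore (crab
ecotype), lower shore (wave ecotype) and a mid-shore contact zone that is
predominantly wave-like with a small fraction of true hybrids.

Neutral allele frequencies follow a hierarchical Balding–Nichols model:
ancestral ``p0 ~ Uniform(0.05, 0.95)``, then at each level of the hierarchy
(refugium, site, ecotype) the daughter frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around its parent, so ``F`` is the expected
FST introduced at that level.  Divergent loci get a deterministic
between-ecotype differential ``delta`` in their member sites only; balancing
loci share the ancestral frequency across all demes.  Genotypes are
``Binomial(2, p_deme)`` draws; mid-shore individuals with admixture
proportion ``Q`` draw from the mixture ``Q*p_wave + (1-Q)*p_crab``.

The beta hierarchy (rather than an explicit coalescent) keeps closed-form
FST expectations for recovery tests and is generatively independent of the
island-model coalescent used by the FDIST null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .datamodel import MISSING, GenotypeMatrix, SampleHierarchy

CRAB_LEVEL = "upper"   # crab-adapted ecotype occupies the upper shore
WAVE_LEVEL = "lower"
ECOTYPES = ("crab", "wave")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the magnitudes of the motivating study: 3 sites x 3
    tidal levels x 30 individuals, 4,256 SNPs of which ~6% are divergent
    (partitioned into loci shared by all sites, shared by the two southern
    sites, and private to each site), a strong between-ecotype differential
    at divergent loci, ~10% missing calls, and a mid-shore class that is
    wave-like except for a ~2% minority of true hybrids.
    """

    seed: int = 0
    sites: tuple = ("S1", "S2", "S3")
    refugium_of: dict = field(
        default_factory=lambda: {"S1": "south", "S2": "south", "S3": "north"}
    )
    n_per_level: int = 30
    n_loci: int = 4256
    f_refugium: float = 0.20
    f_site: float = 0.05
    f_ecotype_neutral: float = 0.05
    n_divergent_shared_all: int = 10
    n_divergent_shared_southern: int = 35
    n_divergent_private: int = 75          # per site
    delta: float = 0.80                    # ecotype allele-frequency differential
    n_balancing: int = 100
    missing_rate: float = 0.10
    hybrid_fraction: float = 0.02          # mid-shore true hybrids, Q ~ U(0.2, 0.8)

    def validate(self) -> None:
        for name in ("f_refugium", "f_site", "f_ecotype_neutral"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must be in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.hybrid_fraction <= 1.0):
            raise ValueError("hybrid_fraction must be in [0, 1]")
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be positive")
        if self.n_divergent + self.n_balancing > self.n_loci:
            raise ValueError("planted locus counts exceed n_loci")
        missing_sites = set(self.sites) - set(self.refugium_of)
        if missing_sites:
            raise ValueError(f"sites without refugium assignment: {missing_sites}")

    @property
    def southern_sites(self) -> list:
        return [s for s in self.sites if self.refugium_of[s] == "south"]

    @property
    def n_divergent(self) -> int:
        return (
            self.n_divergent_shared_all
            + self.n_divergent_shared_southern
            + self.n_divergent_private * len(self.sites)
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.sites, list):
            cfg.sites = tuple(cfg.sites)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sites"] = list(d["sites"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    locus_class: np.ndarray          # 'neutral' | 'divergent' | 'balancing'
    divergent_sites: list            # per locus: frozenset of member sites
    true_q: pd.Series                # per sample: wave-ancestry fraction
    deme_freqs: pd.DataFrame         # rows (site, ecotype), columns loci

    def divergent_loci_for(self, site: str, locus_names) -> set:
        names = np.asarray(locus_names)
        idx = [i for i, s in enumerate(self.divergent_sites) if site in s]
        return set(names[idx])

    def to_frame(self, locus_names) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": locus_names,
                "class": self.locus_class,
                "divergent_sites": [
                    ",".join(sorted(s)) for s in self.divergent_sites
                ],
            }
        )


def _bn_draw(rng: np.random.Generator, parent: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols daughter frequencies; F=0 is an exact copy."""
    if f == 0.0:
        return parent.copy()
    scale = (1.0 - f) / f
    p = np.clip(parent, 1e-3, 1.0 - 1e-3)  # guard against absorbed frequencies
    return rng.beta(p * scale, (1.0 - p) * scale)


def _clamp(p: np.ndarray) -> np.ndarray:
    # keeps loci from drifting to fixation, where the MAF filter would
    # remove them in expectation
    return np.clip(p, 0.01, 0.99)


def simulate_frequencies(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Per-deme allele-frequency table plus the planted truth (no genotypes)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci

    # locus classes: divergent first, then balancing, rest neutral
    locus_class = np.array(["neutral"] * L, dtype=object)
    divergent_sites: list = [frozenset()] * L
    k = 0
    for _ in range(cfg.n_divergent_shared_all):
        divergent_sites[k] = frozenset(cfg.sites)
        k += 1
    for _ in range(cfg.n_divergent_shared_southern):
        divergent_sites[k] = frozenset(cfg.southern_sites)
        k += 1
    for site in cfg.sites:
        for _ in range(cfg.n_divergent_private):
            divergent_sites[k] = frozenset({site})
            k += 1
    locus_class[:k] = "divergent"
    locus_class[k:k + cfg.n_balancing] = "balancing"

    p0 = rng.uniform(0.05, 0.95, size=L)
    refugia = sorted(set(cfg.refugium_of.values()))
    p_ref = {r: _bn_draw(rng, p0, cfg.f_refugium) for r in refugia}
    rows, index = [], []
    for site in cfg.sites:
        p_site = _bn_draw(rng, p_ref[cfg.refugium_of[site]], cfg.f_site)
        freqs = {}
        for eco in ECOTYPES:
            freqs[eco] = _bn_draw(rng, p_site, cfg.f_ecotype_neutral)
        for j in range(L):
            if locus_class[j] == "balancing":
                for eco in ECOTYPES:
                    freqs[eco][j] = p0[j]
            elif locus_class[j] == "divergent" and site in divergent_sites[j]:
                freqs["crab"][j] = p_site[j] + cfg.delta / 2.0
                freqs["wave"][j] = p_site[j] - cfg.delta / 2.0
        for eco in ECOTYPES:
            rows.append(_clamp(freqs[eco]))
            index.append((site, eco))
    deme_freqs = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["site", "ecotype"])
    )
    truth = SimTruth(locus_class, divergent_sites, pd.Series(dtype=float), deme_freqs)
    return deme_freqs, truth


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, SampleHierarchy, SimTruth]:
    """Full dataset: genotype matrix, sample hierarchy and planted truth.

    Deterministic given ``cfg`` (including its seed): the frequency and
    genotype stages consume independent child seeds of ``cfg.seed``.
    """
    deme_freqs, truth = simulate_frequencies(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    L = cfg.n_loci

    level_of_ecotype = {"crab": CRAB_LEVEL, "wave": WAVE_LEVEL}
    sample_ids, records, dosage_rows, true_q = [], [], [], {}
    for site in cfg.sites:
        p_crab = deme_freqs.loc[(site, "crab")].to_numpy()
        p_wave = deme_freqs.loc[(site, "wave")].to_numpy()
        for level in ("upper", "mid", "lower"):
            for i in range(cfg.n_per_level):
                sid = f"{site}_{level[0].upper()}{i + 1:03d}"
                transect = f"T{1 + (i % 2)}"
                if level == CRAB_LEVEL:
                    q, p = 0.0, p_crab
                elif level == WAVE_LEVEL:
                    q, p = 1.0, p_wave
                else:
                    if rng.random() < cfg.hybrid_fraction:
                        q = rng.uniform(0.2, 0.8)
                    else:
                        q = 1.0
                    p = q * p_wave + (1.0 - q) * p_crab
                dosage_rows.append(rng.binomial(2, p).astype(np.int8))
                sample_ids.append(sid)
                records.append((sid, site, transect, level))
                true_q[sid] = q
    dosages = np.vstack(dosage_rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    offsets = rng.integers(0, 85, size=L)
    locus_ids = [(j + 1, int(offsets[j])) for j in range(L)]
    gm = GenotypeMatrix(dosages, sample_ids, locus_ids)
    hierarchy = SampleHierarchy.from_records(records)
    truth.true_q = pd.Series(true_q)
    truth.deme_freqs.columns = gm.locus_names
    return gm, hierarchy, truth
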