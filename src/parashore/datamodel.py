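"""Core genotype containers.

Genotypes are stored as alt-allele dosages in an ``n_individuals x n_loci``
integer matrix with ``-1`` marking missing calls.  Loci are identified by a
``(rad_locus_id, snp_offset)`` pair — the RAD fragment the SNP sits on and its
0-based position within the 85 bp read — rendered as the global string name
``rad<id>_<offset>`` so that outlier lists from different sites live in one
namespace and can be intersected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
READ_LENGTH = 85

TIDAL_LEVELS = ("upper", "mid", "lower")


def locus_name(rad_locus_id: int, snp_offset: int) -> str:
    return f"rad{rad_locus_id}_{snp_offset}"


def parse_locus_name(name: str) -> tuple[int, int]:
    """Invert :func:`locus_name`; raises ValueError on malformed names."""
    if not name.startswith("rad") or "_" not in name:
        raise ValueError(f"not a locus name: {name!r}")
    rad, off = name[3:].split("_", 1)
    return int(rad), int(off)


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alt-allele dosages.

    Parameters
    ----------
    dosages
        ``(n_ind, n_loci)`` integer array with entries in ``{0, 1, 2, -1}``.
    sample_ids
        Individual labels, in file order.
    locus_ids
        One ``(rad_locus_id, snp_offset)`` pair per locus; unique.
    alleles
        One ``(ref, alt)`` pair of single characters per locus.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    locus_ids: list[tuple[int, int]]
    alleles: list[tuple[str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        n_ind, n_loci = self.dosages.shape
        if len(self.sample_ids) != n_ind:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus_ids length does not match dosage columns")
        if len(set(self.locus_ids)) != n_loci:
            raise ValueError("locus_ids must be unique")
        if self.alleles is None:
            self.alleles = [("A", "T")] * n_loci
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, missing}")
        for rad, off in self.locus_ids:
            if not (0 <= off < READ_LENGTH):
                raise ValueError(
                    f"snp_offset {off} outside [0, {READ_LENGTH}) for rad locus {rad}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_names(self) -> list[str]:
        return [locus_name(r, o) for r, o in self.locus_ids]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_loci(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(int)
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.sample_ids),
            [self.locus_ids[i] for i in index],
            [self.alleles[i] for i in index],
        )

    def subset_individuals(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(int)
        return GenotypeMatrix(
            self.dosages[index],
            [self.sample_ids[i] for i in index],
            list(self.locus_ids),
            list(self.alleles),
        )

    def loci_by_name(self, names) -> "GenotypeMatrix":
        pos = {n: i for i, n in enumerate(self.locus_names)}
        return self.subset_loci([pos[n] for n in names])


@dataclass
class SampleHierarchy:
    """Per-sample site / transect / tidal-level assignment.

    The derived *population* label is ``site:tidal_level`` (the unit the
    shore-ecotype comparisons operate on); the *group* label for hierarchical
    analyses is either the site or the tidal level.
    """

    table: pd.DataFrame  # index: sample id; columns: site, transect, tidal_level

    def __post_init__(self) -> None:
        required = {"site", "transect", "tidal_level"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"hierarchy table needs columns {sorted(required)}")
        bad = set(self.table["tidal_level"]) - set(TIDAL_LEVELS)
        if bad:
            raise ValueError(f"unknown tidal levels: {sorted(bad)}")

    @classmethod
    def from_records(cls, records) -> "SampleHierarchy":
        df = pd.DataFrame(records, columns=["sample", "site", "transect", "tidal_level"])
        return cls(df.set_index("sample"))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site"]))

    def population_labels(self) -> pd.Series:
        return self.table["site"] + ":" + self.table["tidal_level"]

    def group_labels(self, group_by: str) -> pd.Series:
        if group_by not in ("site", "tidal_level"):
            raise ValueError("group_by must be 'site' or 'tidal_level'")
        return self.table[group_by]

    def indices_for(self, gm: GenotypeMatrix, site: str | None = None,
                    tidal_level: str | None = None) -> np.ndarray:
        """Row indices of gm whose samples match the given labels."""
        sel = pd.Series(True, index=self.table.index)
        if site is not None:
            sel &= self.table["site"] == site
        if tidal_level is not None:
            sel &= self.table["tidal_level"] == tidal_level
        keep = set(self.table.index[sel])
        return np.array([i for i, s in enumerate(gm.sample_ids) if s in keep], dtype=int)

    def subset(self, sample_ids) -> "SampleHierarchy":
        return SampleHierarchy(self.table.loc[list(sample_ids)])
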