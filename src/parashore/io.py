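"""Readers and writers: Genepop, minimal VCF (GT-only), popmaps, Newick.

The VCF dialect is VCFv4.2 restricted to biallelic SNP records with a GT
field; multiallelic records are rejected.  Genepop files may use two- or
three-digit allele coding, detected per file from the genotype token width
and never mixed.  A popmap is a tab-separated table
``sample  site  transect  tidal_level``.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    SampleHierarchy,
    locus_name,
    parse_locus_name,
)


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


class MetadataError(ValueError):
    """Sample present in a genotype file but absent from the popmap."""


# ---------------------------------------------------------------- popmap

def load_popmap(path) -> SampleHierarchy:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=["sample", "site", "transect", "tidal_level"])
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path}: duplicate sample {dup!r}")
    return SampleHierarchy(df.set_index("sample"))


def save_popmap(hierarchy: SampleHierarchy, path) -> None:
    hierarchy.table.to_csv(path, sep="\t", header=False)


def _check_popmap_covers(sample_ids, hierarchy: SampleHierarchy, path) -> None:
    missing = [s for s in sample_ids if s not in hierarchy.table.index]
    if missing:
        raise MetadataError(
            f"{path}: samples absent from popmap: {', '.join(missing[:5])}"
        )


# ---------------------------------------------------------------- Genepop

_ALLELE_CHARS = "ACGT"


def _genepop_code(dosage: int, width: int) -> str:
    """Diploid two- or three-digit Genepop genotype; 0-run = missing."""
    if dosage == MISSING:
        return "0" * (2 * width)
    a1 = 2 if dosage >= 1 else 1  # allele 1 = ref, 2 = alt
    a2 = 2 if dosage == 2 else 1
    return f"{a1:0{width}d}{a2:0{width}d}"


def save_genepop(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path,
                 digits: int = 2) -> None:
    """Write Genepop with one POP block per (site, tidal_level) population."""
    if gm.n_loci == 0 or gm.n_individuals == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    pops = hierarchy.population_labels()
    lines = ["parashore genotype export"]
    lines.extend(gm.locus_names)
    order = []
    for pop in dict.fromkeys(pops.loc[gm.sample_ids]):
        lines.append("POP")
        for i, s in enumerate(gm.sample_ids):
            if pops.loc[s] != pop:
                continue
            order.append(i)
            codes = " ".join(
                _genepop_code(int(d), digits) for d in gm.dosages[i]
            )
            lines.append(f"{s} ,  {codes}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_genepop(path, popmap_path) -> tuple[GenotypeMatrix, SampleHierarchy]:
    hierarchy = load_popmap(popmap_path)
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise ParseError(f"{path}: too short for a Genepop file")
    # locus names: either one comma-separated line or one per line up to POP
    body_start = None
    for i, line in enumerate(text[1:], 1):
        if line.strip().lower() == "pop":
            body_start = i
            break
    if body_start is None:
        raise ParseError(f"{path}: no POP line found")
    locus_field = [ln.strip() for ln in text[1:body_start]]
    names: list[str] = []
    for ln in locus_field:
        names.extend(n.strip() for n in ln.split(",") if n.strip())
    locus_ids = [parse_locus_name(n) for n in names]

    sample_ids: list[str] = []
    rows: list[list[int]] = []
    width: int | None = None
    for lineno, line in enumerate(text[body_start:], body_start + 1):
        if line.strip().lower() == "pop" or not line.strip():
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(names):
            raise ParseError(
                f"{path}:{lineno}: {len(tokens)} genotypes for {len(names)} loci"
            )
        row = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise ParseError(f"{path}:{lineno}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}:{lineno}: mixed {2 * width}- and {2 * w}-digit coding"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if a1 == 0 or a2 == 0:
                row.append(MISSING)
            else:
                if a1 not in (1, 2) or a2 not in (1, 2):
                    raise ParseError(f"{path}:{lineno}: allele code out of range in {tok!r}")
                row.append((a1 - 1) + (a2 - 1))
        sample_ids.append(name.strip())
        rows.append(row)
    _check_popmap_covers(sample_ids, hierarchy, path)
    gm = GenotypeMatrix(np.array(rows, dtype=np.int8), sample_ids, locus_ids)
    return gm, hierarchy.subset(sample_ids)


# ---------------------------------------------------------------- VCF

def save_vcf(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path) -> None:
    """Write a minimal VCFv4.2: biallelic SNPs, GT field only, POS 1-based."""
    if gm.n_loci == 0 or gm.n_individuals == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for rad in dict.fromkeys(r for r, _ in gm.locus_ids):
        header.contigs.add(f"rad{rad}")
    for s in gm.sample_ids:
        header.add_sample(s)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, (rad, off) in enumerate(gm.locus_ids):
            ref, alt = gm.alleles[j]
            rec = out.new_record(
                contig=f"rad{rad}", start=off, stop=off + 1,
                alleles=(ref, alt), id=locus_name(rad, off),
            )
            for i, s in enumerate(gm.sample_ids):
                rec.samples[s]["GT"] = gt_of[int(gm.dosages[i, j])]
            out.write(rec)


def load_vcf(path, popmap_path) -> tuple[GenotypeMatrix, SampleHierarchy]:
    hierarchy = load_popmap(popmap_path)
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        _check_popmap_covers(sample_ids, hierarchy, path)
        cols, locus_ids, alleles = [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic"
                )
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise ParseError(f"{path}: record {rec.chrom}:{rec.pos} is not a SNP")
            if rec.id and rec.id.startswith("rad"):
                rid = parse_locus_name(rec.id)
            elif rec.chrom.startswith("rad"):
                rid = (int(rec.chrom[3:]), rec.pos - 1)
            else:
                raise ParseError(f"{path}: cannot derive locus id at {rec.chrom}:{rec.pos}")
            col = []
            for s in sample_ids:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                else:
                    col.append(int(sum(gt)))
            cols.append(col)
            locus_ids.append(rid)
            alleles.append((rec.ref, rec.alts[0]))
    gm = GenotypeMatrix(
        np.array(cols, dtype=np.int8).T, sample_ids, locus_ids, alleles
    )
    return gm, hierarchy.subset(sample_ids)


# ---------------------------------------------------------------- dispatch

def load_genotypes(path, fmt: str, popmap_path) -> tuple[GenotypeMatrix, SampleHierarchy]:
    if fmt == "genepop":
        return load_genepop(path, popmap_path)
    if fmt == "vcf":
        return load_vcf(path, popmap_path)
    raise ValueError(f"unknown format {fmt!r}; use 'genepop' or 'vcf'")


def save_genotypes(gm, hierarchy, path, fmt: str) -> None:
    if fmt == "genepop":
        save_genepop(gm, hierarchy, path)
    elif fmt == "vcf":
        save_vcf(gm, hierarchy, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'genepop' or 'vcf'")


# ---------------------------------------------------------------- Newick

def write_newick(tree: dendropy.Tree, path) -> None:
    """Newick with branch lengths and integer bootstrap labels on internals."""
    t = tree.clone(depth=1)
    for nd in t.internal_nodes():
        if nd.parent_node is not None and getattr(nd, "support", None) is not None:
            nd.label = str(int(nd.support))
    t.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
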