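"""Individual-level chord distances, neighbor-joining and bootstrap support.

The Cavalli-Sforza & Edwards chord distance treats each individual as a
two-allele frequency profile per locus, (dosage/2, 1 - dosage/2); the
per-locus squared chord term is ``c_l = 1 - sum_a sqrt(x_a y_a)`` and the
distance aggregates as ``D = (2/pi) * sqrt((2/L) * sum_l c_l)`` over the L
loci genotyped in both individuals (pairwise-complete handling of missing
data).  The (2/pi) normalization is a dialect of the classical chord
distance; it rescales all distances equally and does not affect topology
or bootstrap support.

Neighbor joining uses the Studier–Keppler Q-criterion with deterministic
smallest-index tie-breaking; negative branch lengths are clamped to zero
for display with the raw estimate retained on the node.  Bootstrap support
for each internal bipartition of the point-estimate tree counts the
replicate trees (loci resampled with replacement) containing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-pair locus counts."""

    values: np.ndarray
    labels: list[str]
    pair_loci: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _chord_from_dosages(dosages: np.ndarray, labels) -> DistanceMatrix:
    present = dosages != MISSING
    x = np.where(present, dosages / 2.0, 0.0)
    a = np.sqrt(x)
    b = np.sqrt(np.where(present, 1.0 - dosages / 2.0, 0.0))
    m = present.astype(float)
    shared = m @ m.T
    if np.any(shared[~np.eye(len(shared), dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(len(shared), dtype=bool))[0]
        raise ValueError(
            f"no shared genotyped loci between {labels[i]!r} and {labels[j]!r}"
        )
    s = a @ a.T + b @ b.T
    c_sum = np.maximum(shared - s, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (2.0 / np.pi) * np.sqrt(2.0 * c_sum / shared)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(dist, list(labels), shared.astype(int))


def chord_distance(gm: GenotypeMatrix, subset_loci=None) -> DistanceMatrix:
    """Pairwise chord distances between all individuals.

    ``subset_loci`` optionally restricts to a list of locus names (e.g. a
    random neutral panel or the divergent consensus set).
    """
    if subset_loci is not None:
        gm = gm.loci_by_name(subset_loci)
    return _chord_from_dosages(gm.dosages.astype(float), gm.sample_ids)


def nj_tree(dm: DistanceMatrix, taxon_namespace=None) -> dendropy.Tree:
    """Neighbor-joining (Saitou–Nei via the Studier–Keppler criterion).

    Deterministic: among tied Q minima the lexicographically smallest node
    index pair is joined.  Negative branch lengths are clamped at zero with
    the raw estimate stored as ``node.raw_length``.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    d = np.asarray(dm.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    tree.seed_node.raw_length = None
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nd.raw_length = None
        nodes.append(nd)
    active = list(range(n))
    d = d.copy()

    def set_edge(node, length):
        node.raw_length = float(length)
        node.edge.length = max(float(length), 0.0)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))         # first minimum = smallest index pair
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.raw_length = None
        set_edge(nodes[i], li)
        set_edge(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining actives
        knew = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            knew[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.vstack([d, knew[None, :]])
        d = np.hstack([d, np.append(knew, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    # final edge: attach both under the seed node, splitting the length
    root = tree.seed_node
    set_edge(nodes[i], d[i, j] / 2.0)
    set_edge(nodes[j], d[i, j] / 2.0)
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    return tree


def _bipartitions(tree: dendropy.Tree) -> set:
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        out.add(edge.bipartition.split_bitmask)
    return out


def bootstrap_support(
    gm: GenotypeMatrix,
    subset_loci=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """Point-estimate NJ tree with per-bipartition bootstrap counts.

    Loci are resampled with replacement ``n_boot`` times; each internal
    node of the point tree gets ``node.support`` = the number of replicate
    trees containing its bipartition (so support <= n_boot).
    """
    if subset_loci is not None:
        gm = gm.loci_by_name(subset_loci)
    if gm.n_loci < 10:
        raise ValueError("need at least 10 loci for a bootstrap")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(gm.sample_ids)
    point = nj_tree(chord_distance(gm), taxon_namespace=tns)
    counts: dict[int, int] = {}
    dos = gm.dosages.astype(float)
    for _ in range(n_boot):
        idx = rng.integers(0, gm.n_loci, size=gm.n_loci)
        rep = nj_tree(
            _chord_from_dosages(dos[:, idx], gm.sample_ids),
            taxon_namespace=tns,
        )
        for split in _bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    point.encode_bipartitions()
    for edge in point.preorder_edge_iter():
        node = edge.head_node
        if node is point.seed_node or node.is_leaf():
            continue
        node.support = counts.get(edge.bipartition.split_bitmask, 0)
    return point


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    t = tree.clone(depth=1)
    pdm = t.phylogenetic_distance_matrix()
    if max(
        (pdm.patristic_distance(a, b)
         for a, b in pdm.distinct_taxon_pair_iter()),
        default=0.0,
    ) == 0.0:
        warnings.warn("all path lengths zero; tree left rooted as-is")
        t.is_rooted = True
        return t
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t
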