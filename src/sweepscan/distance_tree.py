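"""Genetic distance matrices and neighbor-joining trees.

Individual-level distance is the allele-sharing p-distance: per site
|dosage_i - dosage_j| / 2 averaged over pairwise-complete sites, so two
identical genotypes score 0 and opposite homozygotes score 1. The
whole-genome identity score is its complement, IS = 1 - p-distance. A
population-level Nei (1972) standard distance over group allele frequencies
is available as an alternative metric.

Trees are built with canonical Saitou–Nei neighbor joining: repeatedly join
the pair minimizing Q(i,j) = (r-2)·d(i,j) - S_i - S_j, attach with the
standard closed-form branch lengths, and reduce the matrix, until three
nodes remain and form the central trifurcation. On an additive (tree-like)
matrix this recovers the generating tree and its branch lengths exactly.
Negative branch lengths (possible on non-additive input) are clamped to
zero and the total deficit recorded. Newick output uses a deterministic
child ordering (smallest leaf label first), so equal trees serialize
byte-identically. Branch support comes from bootstrap resampling of sites.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix

from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger("sweepscan")

__all__ = [
    "PhyloTree", "p_distance", "p_distance_matrix", "identity_score_matrix",
    "nei_distance_matrix", "nj_tree", "to_newick", "bootstrap_support",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def p_distance(gm: GenotypeMatrix, i: str | int, j: str | int) -> float:
    """Allele-sharing dissimilarity of two samples over pairwise-complete
    sites; raises if the pair shares no called site."""
    ii = gm.sample_ids.index(i) if isinstance(i, str) else i
    jj = gm.sample_ids.index(j) if isinstance(j, str) else j
    di, dj = gm.dosage[ii], gm.dosage[jj]
    ok = (di != MISSING) & (dj != MISSING)
    if not ok.any():
        raise ValueError(
            f"samples {gm.sample_ids[ii]!r} and {gm.sample_ids[jj]!r} share "
            "no non-missing site"
        )
    return float(np.abs(di[ok].astype(float) - dj[ok]).mean() / 2.0)


def _p_distance_from_dosage(dosage: np.ndarray,
                            sample_ids: list[str]) -> DistanceMatrix:
    n = len(sample_ids)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            da, db = dosage[a], dosage[b]
            ok = (da != MISSING) & (db != MISSING)
            if not ok.any():
                raise ValueError(
                    f"samples {sample_ids[a]!r} and {sample_ids[b]!r} share "
                    "no non-missing site"
                )
            d[a, b] = d[b, a] = float(
                np.abs(da[ok].astype(float) - db[ok]).mean() / 2.0)
    return DistanceMatrix(d, ids=sample_ids)


def p_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Symmetric sample × sample p-distance matrix."""
    return _p_distance_from_dosage(gm.dosage, gm.sample_ids)


def identity_score_matrix(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Whole-genome identity score IS = 1 - p-distance (unit diagonal)."""
    pd = p_distance_matrix(gm)
    return list(pd.ids), 1.0 - pd.data


def nei_distance_matrix(gm: GenotypeMatrix,
                        groups: dict[str, Sequence[str]]) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between population groups.

    D = -ln( J_xy / sqrt(J_x · J_y) ) with the gene-identity terms averaged
    over loci where both groups have a defined frequency.
    """
    from .popgen_stats import group_frequencies

    labels = list(groups)
    freqs = {}
    for g in labels:
        p, _ = group_frequencies(gm, gm.sample_index(groups[g]))
        freqs[g] = p
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            p, q = freqs[labels[a]], freqs[labels[b]]
            ok = ~(np.isnan(p) | np.isnan(q))
            if not ok.any():
                raise ValueError(f"groups {labels[a]!r}/{labels[b]!r} share "
                                 "no informative locus")
            p, q = p[ok], q[ok]
            jxy = (p * q + (1 - p) * (1 - q)).mean()
            jx = (p * p + (1 - p) ** 2).mean()
            jy = (q * q + (1 - q) ** 2).mean()
            d[a, b] = d[b, a] = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("name", "children", "min_leaf", "support")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children: list[tuple["_Node", float]] = children or []
        self.support: float | None = None
        if name is not None:
            self.min_leaf = name
        else:
            self.min_leaf = min(c.min_leaf for c, _ in self.children)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree stored rooted at the central join (trifurcation for
    ≥ 3 taxa). ``clamped_deficit`` is the total negative branch length set
    to zero during construction."""

    def __init__(self, root: _Node, clamped_deficit: float = 0.0):
        self.root = root
        self.clamped_deficit = clamped_deficit

    # -- inspection ---------------------------------------------------------

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: _Node):
            if n.is_leaf:
                out.append(n.name)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return sorted(out)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side not containing
        the lexicographically smallest leaf."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset] = set()

        def walk(n: _Node) -> set:
            if n.is_leaf:
                return {n.name}
            below = set()
            for c, _ in n.children:
                sub = walk(c)
                if 2 <= len(sub) <= len(all_leaves) - 2:
                    side = all_leaves - sub if anchor in sub else sub
                    splits.add(frozenset(side))
                below |= sub
            return below

        walk(self.root)
        return splits

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along tree edges."""
        leaves = self.leaf_names()
        idx = {name: k for k, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: _Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            seen: dict[str, float] = {}
            for child, length in node.children:
                sub = {leaf: dist + length for leaf, dist in walk(child).items()}
                for la, da in seen.items():
                    for lb, db in sub.items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
                seen.update(sub)
            return seen

        walk(self.root)
        return DistanceMatrix(d, ids=leaves)

    # -- serialization ------------------------------------------------------

    def to_newick(self, include_support: bool = False) -> str:
        return to_newick(self, include_support=include_support)

    def write(self, path, include_support: bool = False) -> None:
        from .variant_io import _open_text
        with _open_text(path, "wt") as fh:
            fh.write(self.to_newick(include_support=include_support) + "\n")


def _fmt_len(x: float) -> str:
    return format(float(x), ".10g")


def to_newick(tree: PhyloTree, include_support: bool = False) -> str:
    """Deterministic Newick: children ordered by smallest contained leaf
    label; optional bootstrap support as internal-node labels."""

    def render(node: _Node) -> str:
        if node.is_leaf:
            return node.name
        parts = []
        for child, length in sorted(node.children, key=lambda cl: cl[0].min_leaf):
            label = ""
            if include_support and not child.is_leaf and child.support is not None:
                label = format(child.support, "g")
            parts.append(f"{render(child)}{label}:{_fmt_len(length)}")
        return "(" + ",".join(parts) + ")"

    return render(tree.root) + ";"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining of a distance matrix.

    The matrix must be symmetric with zero diagonal and non-negative entries
    (``skbio.DistanceMatrix`` enforces the first two). Taxa are processed in
    sorted-label order so the result is independent of input order.
    """
    if (dm.data < 0).any():
        raise ValueError("distance matrix has negative entries")
    ids = sorted(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    order = [list(dm.ids).index(t) for t in ids]
    D = dm.data[np.ix_(order, order)].astype(float)
    nodes = [_Node(name=t) for t in ids]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        S = D.sum(axis=1)
        Q = (r - 2) * D - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = clamp(dij / 2.0 + (S[i] - S[j]) / (2.0 * (r - 2)))
        lj = clamp(dij - (dij / 2.0 + (S[i] - S[j]) / (2.0 * (r - 2))))
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        # canonical ordering keeps every later argmin order-invariant
        reorder = sorted(range(len(nodes)), key=lambda k: nodes[k].min_leaf)
        nodes = [nodes[k] for k in reorder]
        D = D[np.ix_(reorder, reorder)]

    if len(nodes) == 2:
        half = clamp(D[0, 1] / 2.0)
        root = _Node(children=[(nodes[0], half), (nodes[1], half)])
    else:
        dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
        root = _Node(children=[
            (nodes[0], clamp((dab + dac - dbc) / 2.0)),
            (nodes[1], clamp((dab + dbc - dac) / 2.0)),
            (nodes[2], clamp((dac + dbc - dab) / 2.0)),
        ])
    if deficit:
        logger.info("nj_tree: clamped %.3g of negative branch length", deficit)
    return PhyloTree(root, clamped_deficit=deficit)


def bootstrap_support(gm: GenotypeMatrix, n_replicates: int = 100,
                      seed: int | None = None) -> PhyloTree:
    """NJ tree from the full data with bootstrap branch support.

    Sites are resampled with replacement ``n_replicates`` times; each
    replicate's p-distance NJ tree votes for the bipartitions it contains,
    and support (percent of replicates) is attached to the main tree's
    internal nodes.
    """
    main = nj_tree(p_distance_matrix(gm))
    if gm.n_sites == 0:
        return main
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        sites = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep = nj_tree(_p_distance_from_dosage(gm.dosage[:, sites],
                                              gm.sample_ids))
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    all_leaves = set(main.leaf_names())
    anchor = min(all_leaves)

    def annotate(n: _Node) -> set:
        if n.is_leaf:
            return {n.name}
        below = set()
        for c, _ in n.children:
            below |= annotate(c)
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if anchor in below else below
            n.support = 100.0 * counts.get(frozenset(side), 0) / n_replicates
        return below

    annotate(main.root)
    return main


def write_distance_matrix(dm: DistanceMatrix, path, fmt: str = "tsv",
                          header_comments=()) -> None:
    """Write a distance (or IS) matrix as TSV or square PHYLIP."""
    from .variant_io import _open_text
    with _open_text(path, "wt") as fh:
        if fmt == "phylip":
            fh.write(f"{len(dm.ids)}\n")
            for i, name in enumerate(dm.ids):
                row = " ".join(f"{x:.6f}" for x in dm.data[i])
                fh.write(f"{name:<10s} {row}\n")
            return
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("sample\t" + "\t".join(dm.ids) + "\n")
        for i, name in enumerate(dm.ids):
            fh.write(name + "\t" + "\t".join(f"{x:.6g}" for x in dm.data[i]) + "\n")
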