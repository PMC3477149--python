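"""Neighbor-joining trees from synonymous distances, codon bootstrap,
clade queries and the 4-OTU informative-site topology partition.

The NJ implementation is Saitou & Nei's agglomeration with the
Studier-Keppler Q criterion.  It is deterministic: when several pairs tie
for the minimal Q, the lexicographically smallest pair of current node
indices (in input order) is joined.  Negative branch lengths are clamped to
zero with the deficit transferred to the sister branch so path lengths are
preserved; every clamping event is counted.

Trees are stored as an undirected adjacency structure (leaves keep their
taxon labels) and serialised to newick with branch lengths and integer
percent bootstrap supports as internal node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence, Union

import numpy as np

from .alignment_io import CodonAlignment, TaxonTag
from .divergence import (SATURATION_P, SYN_DIFFS, SYN_SITES, DivergenceError,
                         encode_codons)


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named taxa.

    Saturated / undefined entries are NaN; NJ refuses to run on them and
    reports the offending pairs.
    """

    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise PhylogenyError("matrix shape does not match taxon count")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise PhylogenyError("distance matrix must be symmetric")
        np.fill_diagonal(self.d, 0.0)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        bad = []
        n = len(self.names)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.d[i, j]):
                    bad.append((self.names[i], self.names[j]))
        return bad


def ps_distance_matrix(aln: CodonAlignment) -> DistanceMatrix:
    """Pairwise p_S matrix of a codon alignment (NaN where undefined)."""
    idx = [encode_codons(r) for r in aln.rows]
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _ps_or_nan(idx[i], idx[j])
    return DistanceMatrix(names=list(aln.ids), d=d)


def _ps_or_nan(i1: np.ndarray, i2: np.ndarray) -> float:
    valid = (i1 >= 0) & (i2 >= 0)
    if not valid.any():
        return math.nan
    a, b = i1[valid], i2[valid]
    S = (SYN_SITES[a].sum() + SYN_SITES[b].sum()) / 2.0
    if S <= 0:
        return math.nan
    return float(SYN_DIFFS[a, b].sum() / S)


@dataclass
class PhyloTree:
    """Unrooted tree: leaves are taxon names, internal nodes integers."""

    adj: dict[Hashable, list[tuple[Hashable, float]]]
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_clamped: int = 0

    def neighbors(self, node: Hashable) -> list[tuple[Hashable, float]]:
        return self.adj[node]

    # -- bipartitions ------------------------------------------------------
    def _side(self, u: Hashable, v: Hashable) -> frozenset:
        """Leaves reachable from v without crossing edge (u, v)."""
        seen, stack, out = {u, v}, [v], []
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.append(node)
            for nbr, _ in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge splits, canonicalised as the side NOT containing
        the lexicographically smallest leaf."""
        ref = min(self.leaves)
        splits = set()
        for u in self.adj:
            if isinstance(u, str):
                continue
            for v, _ in self.adj[u]:
                if isinstance(v, str):
                    continue
                side = self._side(u, v)
                if ref in side:
                    side = frozenset(self.leaves) - side
                if 1 < len(side) < len(self.leaves) - 1:
                    splits.add(side)
        return splits

    # -- queries -----------------------------------------------------------
    def terminal_branch_length(self, leaf: str) -> float:
        if leaf not in self.adj:
            raise PhylogenyError(f"leaf {leaf!r} not in tree")
        (_, length), = self.adj[leaf][:1] or [(None, math.nan)]
        return length

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique a-b path."""
        prev = {a: None}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nbr, w in self.adj[node]:
                if nbr not in prev:
                    prev[nbr] = (node, w)
                    stack.append(nbr)
        if b not in prev:
            raise PhylogenyError(f"no path {a!r} -> {b!r}")
        total, node = 0.0, b
        while prev[node] is not None:
            parent, w = prev[node]
            total += w
            node = parent
        return total

    # -- newick ------------------------------------------------------------
    def to_newick(self, root: Optional[str] = None) -> str:
        """Newick string; rooted at the given leaf (outgroup) if supplied,
        otherwise at an arbitrary internal node."""
        if root is not None and root not in self.adj:
            raise PhylogenyError(f"outgroup {root!r} not in tree")

        ref = min(self.leaves)
        all_leaves = frozenset(self.leaves)

        def support_label(node: Hashable, parent: Hashable) -> str:
            side = self._side(parent, node)
            if ref in side:
                side = all_leaves - side
            if side in self.supports:
                return str(int(round(self.supports[side])))
            return ""

        def fmt(node: Hashable, parent: Hashable) -> str:
            children = [(c, w) for c, w in self.adj[node] if c != parent]
            if not children:
                return f"{node}"
            inner = ",".join(f"{fmt(c, node)}:{w:.6g}" for c, w in children)
            label = support_label(node, parent) if parent is not None else ""
            return f"({inner}){label}"

        if root is None:
            start = next(n for n in self.adj if not isinstance(n, str))
            return fmt(start, None) + ";"
        # root on the outgroup's pendant edge: outgroup first, its neighbour's
        # other subtrees as siblings
        (nbr, w), = self.adj[root]
        rest = ",".join(f"{fmt(c, nbr)}:{cw:.6g}"
                        for c, cw in self.adj[nbr] if c != root)
        return f"({root}:{w:.6g},{rest});"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices."""
    n = len(dm.names)
    if n < 3:
        raise PhylogenyError("NJ needs at least 3 taxa")
    bad = dm.undefined_pairs()
    if bad:
        raise PhylogenyError(f"undefined (saturated) distances for pairs: {bad}")

    nodes: list[Hashable] = list(dm.names)
    D = dm.d.astype(float).copy()
    adj: dict[Hashable, list[tuple[Hashable, float]]] = {name: [] for name in dm.names}
    next_internal = 0
    n_clamped = 0

    def add_edge(a, b, w):
        nonlocal n_clamped
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q criterion; scan in index order so ties resolve to the smallest pair
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
            n_clamped += 1
        if lj < 0:
            li += lj
            lj = 0.0
            n_clamped += 1
        new = next_internal
        next_internal += 1
        add_edge(nodes[i], new, li)
        add_edge(nodes[j], new, lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    # closing star for the final three nodes
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    center = next_internal
    lens = []
    for L in (la, lb, lc):
        if L < 0:
            n_clamped += 1
            L = 0.0
        lens.append(L)
    add_edge(a, center, lens[0])
    add_edge(b, center, lens[1])
    add_edge(c, center, lens[2])

    return PhyloTree(adj=adj, leaves=list(dm.names), n_clamped=n_clamped)


def bootstrap_nj(
    aln: CodonAlignment, reps: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree from the full alignment with codon-bootstrap supports.

    Codon columns (not single sites) are resampled with replacement so each
    replicate keeps valid codon structure for p_S.  Replicates in which any
    pair has an undefined p_S are redrawn, up to 10x ``reps`` draws.
    """
    if aln.mode != "codon":
        raise PhylogenyError("bootstrap_nj requires a codon-mode alignment")
    rng = np.random.default_rng(seed)
    idx = np.array([encode_codons(r) for r in aln.rows])
    n_taxa, n_codons = idx.shape

    main = nj_tree(_dm_from_indices(aln.ids, idx))
    target_splits = main.bipartitions()
    counts = {s: 0 for s in target_splits}

    done = 0
    draws = 0
    cap = 10 * reps
    while done < reps:
        if draws >= cap:
            raise PhylogenyError(
                f"exceeded {cap} bootstrap draws with valid p_S for all pairs"
            )
        draws += 1
        cols = rng.integers(0, n_codons, size=n_codons)
        sub = idx[:, cols]
        try:
            dm = _dm_from_indices(aln.ids, sub)
            if dm.undefined_pairs():
                continue
            tree = nj_tree(dm)
        except (PhylogenyError, DivergenceError):
            continue
        splits = tree.bipartitions()
        for s in counts:
            if s in splits:
                counts[s] += 1
        done += 1

    main.supports = {s: 100.0 * c / reps for s, c in counts.items()}
    return main


def _dm_from_indices(names: Sequence[str], idx: np.ndarray) -> DistanceMatrix:
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _ps_or_nan(idx[i], idx[j])
    return DistanceMatrix(names=list(names), d=d)


def is_monophyletic(
    tree: PhyloTree, taxa: Iterable[str], outgroup: str
) -> bool:
    """True iff ``taxa`` form a clade on the tree rooted at ``outgroup``."""
    subset = frozenset(taxa)
    leaves = frozenset(tree.leaves)
    if outgroup not in leaves:
        raise PhylogenyError(f"outgroup {outgroup!r} not in tree")
    missing = subset - leaves
    if missing:
        raise PhylogenyError(f"taxa not in tree: {sorted(missing)}")
    if len(subset) <= 1 or subset == leaves:
        return True
    if outgroup in subset:
        return False
    if subset == leaves - {outgroup}:
        return True
    # subset is a clade iff some edge splits it off on the far side from the root
    for u in tree.adj:
        for v, _ in tree.adj[u]:
            side = tree._side(u, v)
            if side == subset and outgroup not in side:
                return True
    return False


def terminal_branch_ratio(tree: PhyloTree, taxon1: str, taxon2: str) -> float:
    """Ratio of the two terminal branch lengths taxon1 / taxon2."""
    b1 = tree.terminal_branch_length(taxon1)
    b2 = tree.terminal_branch_length(taxon2)
    if b2 == 0:
        raise PhylogenyError(f"terminal branch of {taxon2!r} has zero length")
    return b1 / b2


@dataclass
class SitePartitionCounts:
    """Informative-site support for the three unrooted quartet topologies.

    Topology A pairs X with X across clades — ([EX, MX], [EY, MY]) — the
    signature of gametolog differentiation before the clades split.
    Topology B pairs within clades — ([EX, EY], [MX, MY]) — differentiation
    after the split, or lineage-specific gene conversion.  Topology C is the
    remaining pairing, expected only by chance.
    """

    nA: int = 0
    nB: int = 0
    nC: int = 0
    positions: dict[str, list[int]] = field(default_factory=lambda: {"A": [], "B": [], "C": []})
    n_skipped: int = 0

    @property
    def n_informative(self) -> int:
        return self.nA + self.nB + self.nC


def classify_informative_sites(
    sites: Sequence[tuple[int, tuple[str, str, str, str]]]
) -> SitePartitionCounts:
    """Partition 4-OTU sites (ordered EX, EY, MX, MY) into topologies A/B/C.

    A site is informative iff exactly two distinct states each occur exactly
    twice; everything else is skipped and tallied.
    """
    out = SitePartitionCounts()
    for col, (ex, ey, mx, my) in sites:
        states = {ex, ey, mx, my}
        if len(states) != 2 or any((ex, ey, mx, my).count(s) != 2 for s in states):
            out.n_skipped += 1
            continue
        if ex == mx and ey == my:
            out.nA += 1
            out.positions["A"].append(col)
        elif ex == ey and mx == my:
            out.nB += 1
            out.positions["B"].append(col)
        else:  # ex == my and ey == mx
            out.nC += 1
            out.positions["C"].append(col)
    return out
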