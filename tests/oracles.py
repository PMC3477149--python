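"""Independent brute-force oracles used only by the test suite.

These deliberately share no code (and no genetic-code table) with the
package: the code table below is written out from the standard code, and
every quantity is computed by direct enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

# standard genetic code, written out independently ('*' = stop)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
BASES = "ACGT"
SENSE_CODONS = [c for c, a in GENETIC_CODE.items() if a != "*"]


def brute_syn_sites(codon: str) -> float:
    """Synonymous site count by direct enumeration of all 9 single changes."""
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = denom = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] == "*":
                continue
            denom += 1
            if GENETIC_CODE[mut] == aa:
                syn += 1
        if denom:
            total += syn / denom
    return total


def brute_codon_syn_diffs(c1: str, c2: str) -> float:
    """Synonymous differences between two codons by pathway enumeration."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0
    ok_paths, blocked_paths = [], []
    for order in itertools.permutations(diffs):
        cur, nsyn, stopped = c1, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                stopped = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                nsyn += 1
            cur = nxt
        (blocked_paths if stopped else ok_paths).append(nsyn)
    pool = ok_paths or blocked_paths
    return sum(pool) / len(pool)


def brute_pairwise_syn(seq1: str, seq2: str) -> tuple[float, float, float]:
    """(S, Sd, pS) for two in-frame sequences, by enumeration.

    Codons containing anything but ACGT, or a stop, in either sequence are
    dropped pairwise.
    """
    S1 = S2 = Sd = 0.0
    for j in range(len(seq1) // 3):
        a, b = seq1[3 * j: 3 * j + 3], seq2[3 * j: 3 * j + 3]
        if any(ch not in BASES for ch in a + b):
            continue
        if GENETIC_CODE[a] == "*" or GENETIC_CODE[b] == "*":
            continue
        S1 += brute_syn_sites(a)
        S2 += brute_syn_sites(b)
        Sd += brute_codon_syn_diffs(a, b)
    S = (S1 + S2) / 2.0
    return S, Sd, Sd / S if S else float("nan")


def brute_runs_p(labels: list, r_obs: int) -> float:
    """P(runs <= r_obs) by literal enumeration of all arrangements."""
    n = len(labels)
    n1 = sum(1 for x in labels if x == sorted(set(labels), key=str)[0])
    hits = total = 0
    for pos in itertools.combinations(range(n), n1):
        arr = ["B"] * n
        for p in pos:
            arr[p] = "A"
        runs = 1 + sum(1 for a, b in zip(arr, arr[1:]) if a != b)
        total += 1
        if runs <= r_obs:
            hits += 1
    return hits / total


def random_additive_tree(n_leaves: int, rng):
    """Random binary tree with positive branch lengths.

    Returns (names, distance matrix as dict-of-dict, set of non-trivial
    bipartitions as frozensets of leaf names canonicalised on the side not
    containing the smallest name).
    """
    import numpy as np

    names = [f"t{i}" for i in range(n_leaves)]
    # build by sequential leaf attachment onto a random existing edge
    # nodes: ints; edges: dict (u,v)->length with u<v on an arbitrary order
    next_id = n_leaves
    edges = {}

    def add_edge(a, b, w):
        edges[frozenset((a, b))] = w

    # start with a 2-leaf tree (single edge), then attach the rest
    add_edge(0, 1, rng.uniform(0.05, 1.0))
    for leaf in range(2, n_leaves):
        u, v = tuple(list(edges)[rng.integers(len(edges))])
        w = edges.pop(frozenset((u, v)))
        mid = next_id
        next_id += 1
        split = rng.uniform(0.2, 0.8) * w
        add_edge(u, mid, split)
        add_edge(v, mid, w - split)
        add_edge(leaf, mid, rng.uniform(0.05, 1.0))

    # adjacency
    adj = {}
    for e, w in edges.items():
        a, b = tuple(e)
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def leaf_dist(a, b):
        stack = [(a, 0.0, None)]
        while stack:
            node, d, par = stack.pop()
            if node == b:
                return d
            for nbr, w in adj[node]:
                if nbr != par:
                    stack.append((nbr, d + w, node))
        raise RuntimeError

    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = leaf_dist(i, j)

    def side(u, v):
        out, stack = [], [(v, u)]
        seen = {u, v}
        while stack:
            node, par = stack.pop()
            if node < n_leaves:
                out.append(names[node])
            for nbr, _ in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, node))
        return frozenset(out)

    ref = min(names)
    splits = set()
    for e in edges:
        a, b = tuple(e)
        if a >= n_leaves and b >= n_leaves:
            s = side(a, b)
            if ref in s:
                s = frozenset(names) - s
            if 1 < len(s) < n_leaves - 1:
                splits.add(s)
    return names, D, splits
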