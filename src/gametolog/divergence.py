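"""Synonymous divergence between gametologs.

Implements the unweighted Nei–Gojobori (1986) estimator of synonymous sites
and differences (the transition/transversion-unbiased case, R = 1), the
Jukes–Cantor multiple-hit correction

    K_S = -(3/4) * ln(1 - (4/3) * p_S),

binomial / delta-method standard errors, normal-deviate (Z) comparisons of
two divergence estimates, and non-overlapping sliding-window nucleotide
divergence profiles for genomic alignments.

Synonymous sites per codon are the sum over the three positions of the
fraction of single-nucleotide changes that are synonymous, with changes to
stop codons excluded from the denominator.  Synonymous differences between
two codons average, with equal weight, over all minimal substitution
pathways between them that avoid stop-codon intermediates.  Both quantities
are precomputed for all 64x64 codon pairs at import, so per-pair estimation
and codon bootstrapping reduce to table lookups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

from .alignment_io import CodonAlignment

_BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)

SATURATION_P = 0.75  # JC correction undefined at or above this

class DivergenceError(ValueError):
    pass


class SaturationError(DivergenceError):
    """p >= 3/4: the Jukes-Cantor log has no real value."""


def _aa(codon: str) -> Optional[str]:
    """Amino acid, or None for a stop codon."""
    return _AA.get(codon)


def syn_sites_of_codon(codon: str) -> float:
    """Nei-Gojobori synonymous site count of one codon (R = 1).

    For each position, the fraction of the single-nucleotide changes that
    preserve the amino acid, counting only changes that do not create a stop
    codon in the denominator.  Summed over the three positions; ranges from
    0 (e.g. TGG) to 3 (none in the standard code; CTN gives 1).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise DivergenceError(f"degenerate or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise DivergenceError(f"stop codon {codon}")
    aa0 = _aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            denom += 1
            if _aa(mut) == aa0:
                syn += 1
        if denom:
            total += syn / denom
    return total


def _pathway_syn_diffs(c1: str, c2: str) -> float:
    """Mean synonymous differences between two codons over minimal pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are discarded.  If every pathway is blocked
    (possible only for some stop-adjacent pairs) all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0
    valid: list[int] = []
    blocked: list[int] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        nsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if _aa(nxt) == _aa(cur):
                nsyn += 1
            cur = nxt
        (blocked if hit_stop else valid).append(nsyn)
    pool = valid if valid else blocked
    return sum(pool) / len(pool)


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    """64-vector of synonymous sites and 64x64 matrix of synonymous diffs.

    Entries involving stop codons are NaN.
    """
    sites = np.full(64, np.nan)
    for c in CODONS:
        if c not in STOP_CODONS:
            sites[CODON_INDEX[c]] = syn_sites_of_codon(c)
    sd = np.full((64, 64), np.nan)
    for c1 in CODONS:
        if c1 in STOP_CODONS:
            continue
        for c2 in CODONS:
            if c2 in STOP_CODONS:
                continue
            sd[CODON_INDEX[c1], CODON_INDEX[c2]] = _pathway_syn_diffs(c1, c2)
    return sites, sd

SYN_SITES, SYN_DIFFS = _build_tables()


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame sequence; -1 marks codons that are
    incomplete (gap/N) or stops and must be pairwise-deleted."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        codon = seq[3 * j : 3 * j + 3]
        idx = CODON_INDEX.get(codon)
        if idx is not None and codon not in STOP_CODONS:
            out[j] = idx
    return out


@dataclass(frozen=True)
class SynDivergence:
    """Synonymous divergence of one sequence pair."""

    S: float
    Sd: float
    pS: float
    KS: Optional[float]
    se_pS: float
    se_KS: Optional[float]
    n_codons: int
    n_excluded: int = 0

    def __str__(self) -> str:  # Table-1-style presentation
        ks = "undef" if self.KS is None else f"{self.KS:.2f}±{self.se_KS:.3f}"
        return f"pS={self.pS:.2f}±{self.se_pS:.3f} (KS={ks})"


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a proportion of differences."""
    if not 0.0 <= p < SATURATION_P:
        raise SaturationError(f"p={p} outside [0, 0.75): JC distance undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _se_pair(pS: float, S: float) -> tuple[float, Optional[float]]:
    """Binomial SE of p_S over S sites; delta-method SE of K_S."""
    se_p = math.sqrt(max(pS * (1.0 - pS), 0.0) / S)
    if pS < SATURATION_P:
        return se_p, se_p / (1.0 - 4.0 * pS / 3.0)
    return se_p, None


def pairwise_syn_indices(idx1: np.ndarray, idx2: np.ndarray) -> SynDivergence:
    """Nei-Gojobori estimate from two codon-index arrays (fast path)."""
    if idx1.shape != idx2.shape:
        raise DivergenceError("sequences differ in codon count")
    valid = (idx1 >= 0) & (idx2 >= 0)
    n = int(valid.sum())
    n_excl = idx1.size - n
    if n == 0:
        raise DivergenceError("no complete codons shared by the pair")
    i1, i2 = idx1[valid], idx2[valid]
    S = float(SYN_SITES[i1].sum() + SYN_SITES[i2].sum()) / 2.0
    Sd = float(SYN_DIFFS[i1, i2].sum())
    if S <= 0:
        raise DivergenceError("zero synonymous sites: divergence undefined")
    pS = Sd / S
    KS = jc_correct(pS) if pS < SATURATION_P else None
    se_p, se_k = _se_pair(pS, S)
    return SynDivergence(S=S, Sd=Sd, pS=pS, KS=KS, se_pS=se_p, se_KS=se_k,
                         n_codons=n, n_excluded=n_excl)


def pairwise_syn(seq1: str, seq2: str) -> SynDivergence:
    """Synonymous divergence between two equal-length in-frame sequences.

    Codons containing a gap, ``N`` or a stop in either sequence are excluded
    pairwise before counting.
    """
    if len(seq1) != len(seq2):
        raise DivergenceError("sequences must be equal length")
    if len(seq1) % 3:
        raise DivergenceError("sequence length must be a multiple of 3")
    return pairwise_syn_indices(encode_codons(seq1.upper()), encode_codons(seq2.upper()))


def mean_pairwise_syn(results: Sequence[SynDivergence]) -> SynDivergence:
    """Arithmetic mean over several X-copy x Y-copy pairs (multi-copy genes).

    pS and KS (where defined) are averaged; SEs are combined as the SE of
    the mean of independent estimates.
    """
    if not results:
        raise DivergenceError("no pair results to average")
    k = len(results)
    pS = sum(r.pS for r in results) / k
    se_p = math.sqrt(sum(r.se_pS ** 2 for r in results)) / k
    ks_vals = [r.KS for r in results if r.KS is not None]
    if len(ks_vals) == k:
        KS = sum(ks_vals) / k
        se_k = math.sqrt(sum(r.se_KS ** 2 for r in results)) / k
    else:
        KS, se_k = None, None
    return SynDivergence(
        S=sum(r.S for r in results) / k,
        Sd=sum(r.Sd for r in results) / k,
        pS=pS, KS=KS, se_pS=se_p, se_KS=se_k,
        n_codons=min(r.n_codons for r in results),
        n_excluded=max(r.n_excluded for r in results),
    )


def z_compare(d1: float, se1: float, d2: float, se2: float) -> tuple[float, float]:
    """Normal-deviate test of two divergence estimates.

    Z = |d1 - d2| / sqrt(se1^2 + se2^2), two-tailed p from the standard
    normal.  Used e.g. to compare a marsupial gametolog's p_S with the
    eutherian one.
    """
    if se1 < 0 or se2 < 0 or (se1 == 0 and se2 == 0):
        raise DivergenceError("standard errors must be >= 0 and not both zero")
    z = abs(d1 - d2) / math.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(z)
    return z, p


@dataclass
class WindowProfile:
    """Non-overlapping sliding-window nucleotide divergence of one pair."""

    window_size: int
    starts: list[int]
    p: list[float]
    n_sites: list[int]
    n_diff: list[int]
    reliable: list[bool]
    length: int

    def __len__(self) -> int:
        return len(self.starts)

    def end(self, i: int) -> int:
        return min(self.starts[i] + self.window_size, self.length)


def window_profile(seq1: str, seq2: str, window_size: int = 500) -> WindowProfile:
    """Per-window p-distance with pairwise deletion of gap/N columns.

    Windows with fewer than ``window_size / 2`` compared sites (and any
    trailing partial window failing that bar) are flagged unreliable.
    """
    if window_size < 1:
        raise DivergenceError("window_size must be >= 1")
    if len(seq1) != len(seq2):
        raise DivergenceError("sequences must be equal length")
    s1 = np.frombuffer(seq1.upper().encode(), dtype="S1")
    s2 = np.frombuffer(seq2.upper().encode(), dtype="S1")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    ok = np.isin(s1, acgt) & np.isin(s2, acgt)
    diff = ok & (s1 != s2)
    starts, ps, ns, nd, rel = [], [], [], [], []
    for start in range(0, len(seq1), window_size):
        stop = min(start + window_size, len(seq1))
        n = int(ok[start:stop].sum())
        d = int(diff[start:stop].sum())
        starts.append(start)
        ns.append(n)
        nd.append(d)
        ps.append(d / n if n else 0.0)
        rel.append(n >= window_size / 2)
    return WindowProfile(window_size=window_size, starts=starts, p=ps,
                         n_sites=ns, n_diff=nd, reliable=rel, length=len(seq1))


def alignment_pairwise_syn(aln: CodonAlignment, key1, key2) -> SynDivergence:
    """Convenience wrapper: pairwise_syn between two records of an alignment."""
    return pairwise_syn(aln.row(key1), aln.row(key2))
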