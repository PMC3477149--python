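"""Statistical evidence for ectopic gene conversion between gametologs.

Three complementary detectors:

* :func:`runs_test` — a two-sample (Wald–Wolfowitz) runs test on the spatial
  ordering of informative sites along the alignment.  Gene conversion
  homogenises a tract, so sites supporting the "within-clade" quartet
  topology cluster instead of interleaving with "across-clade" sites; too
  few runs is the one-tailed alternative.
* :func:`fragment_permutation_test` — a global permutation test in the
  spirit of GENECONV's global fragment test: condense the alignment to its
  polymorphic columns, score every sequence pair by its longest run of
  consecutive identical condensed columns, take the maximum over pairs, and
  compare with the same statistic under random column orderings.
* :func:`detect_low_divergence` — delineate runs of consecutive sliding
  windows whose pooled divergence is significantly below the rest of the
  profile (two-proportion Z test).

The fragment test deliberately simplifies GENECONV: mismatch-free inner
fragments only, scored by length in polymorphic sites, with the
column-permutation maximum statistic providing multiplicity control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .alignment_io import CodonAlignment
from .divergence import WindowProfile


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class RunsTestResult:
    n1: int
    n2: int
    runs_observed: int
    p_one_tailed: float
    method: str  # "exact" | "normal"


def _count_runs(labels: Sequence) -> int:
    runs = 1
    for a, b in zip(labels, labels[1:]):
        if a != b:
            runs += 1
    return runs


def runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact run-count distribution for n1 + n2 exchangeable binary labels."""
    total = comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for k in range(1, min(n1, n2) + 1):
        pmf[2 * k] = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1) / total
        odd = (comb(n1 - 1, k - 1) * comb(n2 - 1, k)
               + comb(n1 - 1, k) * comb(n2 - 1, k - 1))
        if odd:
            pmf[2 * k + 1] = odd / total
    return pmf


def runs_test(labels: Sequence, exact_limit: int = 20) -> RunsTestResult:
    """One-tailed runs test for clustering (fewer runs than expected).

    ``labels`` is the ordered two-class sequence of informative sites (in
    alignment order).  Exact p by the combinatorial run-count distribution
    when n1 + n2 <= ``exact_limit``, otherwise a normal approximation with
    continuity correction.
    """
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ConversionError(f"need exactly 2 label classes, got {classes}")
    n1 = sum(1 for x in labels if x == classes[0])
    n2 = len(labels) - n1
    r = _count_runs(labels)
    n = n1 + n2
    if n <= exact_limit:
        pmf = runs_pmf(n1, n2)
        p = sum(v for k, v in pmf.items() if k <= r)
        method = "exact"
    else:
        mean = 1.0 + 2.0 * n1 * n2 / n
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
        z = (r + 0.5 - mean) / math.sqrt(var)
        p = float(stats.norm.cdf(z))
        method = "normal"
    return RunsTestResult(n1=n1, n2=n2, runs_observed=r,
                          p_one_tailed=min(p, 1.0), method=method)


@dataclass(frozen=True)
class Fragment:
    pair: tuple[str, str]
    start: int   # condensed (polymorphic-site) coordinates, inclusive
    end: int     # exclusive
    score: int   # length in polymorphic sites


@dataclass
class FragmentResult:
    fragments: list[Fragment]
    observed_statistic: int
    p_global: float
    n_perm: int
    seed: int
    n_polymorphic: int


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(length, start) of the longest run of True; (0, -1) if none."""
    best_len = best_start = cur = 0
    start = -1
    run_start = 0
    for i, v in enumerate(mask):
        if v:
            if cur == 0:
                run_start = i
            cur += 1
            if cur > best_len:
                best_len, best_start = cur, run_start
        else:
            cur = 0
    return (best_len, best_start if best_len else -1)


def _max_run_rows(eq: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a boolean matrix (vectorised).

    cumsum minus its running maximum at False positions gives the current
    run length at every column.
    """
    cs = np.cumsum(eq, axis=1)
    reset = np.where(~eq, cs, 0)
    base = np.maximum.accumulate(reset, axis=1)
    return (cs - base).max(axis=1)


def fragment_permutation_test(
    aln: CodonAlignment, n_perm: int = 10_000, seed: int = 0
) -> FragmentResult:
    """Global permutation test for conversion fragments.

    Columns with any gap/N are ignored; a column is polymorphic if >= 2
    states occur among the sequences.  Pair score = longest run of
    consecutive polymorphic columns at which the pair is identical; the
    global statistic is the maximum score over pairs.  Significance from
    ``n_perm`` random orderings of the polymorphic columns, with the
    add-one estimator p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    if len(aln) < 3:
        raise ConversionError("fragment test needs >= 3 sequences")
    mat = np.array([list(r) for r in aln.rows])
    clean = ~np.any((mat == "-") | (mat == "N"), axis=0)
    mat = mat[:, clean]
    poly = np.array([len(set(mat[:, j])) > 1 for j in range(mat.shape[1])])
    cond = mat[:, poly]
    m = cond.shape[1]
    if m == 0:
        return FragmentResult(fragments=[], observed_statistic=0, p_global=1.0,
                              n_perm=n_perm, seed=seed, n_polymorphic=0)

    pairs = list(itertools.combinations(range(len(aln)), 2))
    eq = np.array([cond[i] == cond[j] for i, j in pairs])  # (n_pairs, m)

    fragments = []
    observed = 0
    for (i, j), row in zip(pairs, eq):
        score, start = _longest_true_run(row)
        if score > 0:
            fragments.append(Fragment(pair=(aln.ids[i], aln.ids[j]),
                                      start=start, end=start + score, score=score))
        observed = max(observed, score)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if _max_run_rows(eq[:, perm]).max() >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    fragments.sort(key=lambda f: -f.score)
    return FragmentResult(fragments=fragments, observed_statistic=observed,
                          p_global=p, n_perm=n_perm, seed=seed, n_polymorphic=m)


@dataclass(frozen=True)
class LowDivergenceRegion:
    start: int          # alignment bp, inclusive
    end: int            # exclusive
    window_indices: tuple[int, ...]
    p_inside: float
    p_outside: float
    z: float
    p_value: float


def _two_proportion_z(d1: int, n1: int, d2: int, n2: int) -> tuple[float, float]:
    """Z for proportion d1/n1 below d2/n2; one-tailed p for a reduction."""
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    p1, p2 = d1 / n1, d2 / n2
    pp = (d1 + d2) / (n1 + n2)
    denom = math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    if denom == 0:
        return 0.0, 1.0
    z = (p2 - p1) / denom
    return z, float(stats.norm.sf(z))


def detect_low_divergence(
    profile: WindowProfile,
    min_windows: int = 2,
    alpha: float = 0.001,
) -> list[LowDivergenceRegion]:
    """Maximal runs of low-divergence windows that are significant at alpha.

    Candidate runs are maximal stretches of consecutive reliable windows
    whose p lies below the pooled p of all reliable windows; a run of at
    least ``min_windows`` windows is reported when the pooled proportion
    inside is below the pooled proportion of all other reliable windows
    with a one-tailed two-proportion Z test p < alpha (default 0.001).
    """
    rel = [i for i in range(len(profile)) if profile.reliable[i]]
    if len(rel) < 4:
        raise ConversionError("need at least 4 reliable windows")
    tot_d = sum(profile.n_diff[i] for i in rel)
    tot_n = sum(profile.n_sites[i] for i in rel)
    if tot_n == 0:
        return []
    pooled = tot_d / tot_n

    regions: list[LowDivergenceRegion] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) < min_windows:
            return
        d_in = sum(profile.n_diff[i] for i in run)
        n_in = sum(profile.n_sites[i] for i in run)
        d_out, n_out = tot_d - d_in, tot_n - n_in
        z, p = _two_proportion_z(d_in, n_in, d_out, n_out)
        if p < alpha:
            regions.append(LowDivergenceRegion(
                start=profile.starts[run[0]],
                end=profile.end(run[-1]),
                window_indices=tuple(run),
                p_inside=d_in / n_in if n_in else 0.0,
                p_outside=d_out / n_out if n_out else 0.0,
                z=z, p_value=p,
            ))

    prev = None
    for i in rel:
        below = profile.p[i] < pooled
        contiguous = prev is not None and i == prev + 1
        if below and (not run or contiguous):
            run.append(i)
        else:
            flush(run)
            run = [i] if below else []
        prev = i
    flush(run)
    return regions


def regions_to_bed(regions: Sequence[LowDivergenceRegion], name: str = "low_divergence") -> str:
    """BED (0-based half-open) text for the detected regions."""
    lines = [
        f"aln\t{r.start}\t{r.end}\t{name}\t{r.z:.3f}" for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
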