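# Methods

This note records the models implemented by `gametolog`, the parameter
choices that matter, and the limits of what the synthetic-data tests can
show.

## Synonymous divergence

Synonymous sites follow the Nei–Gojobori (1986) counting scheme without
transition/transversion weighting (the R = 1 case): for each codon
position, the synonymous fraction of the three possible single-nucleotide
changes, with changes that create a stop codon removed from the
denominator. The per-pair site total *S* is the mean of the two sequences'
sums. Synonymous differences *S*<sub>d</sub> between two codons average,
with equal weight, over all minimal substitution pathways that avoid stop
intermediates; in the rare case where every pathway crosses a stop, all
pathways are used rather than dropping the codon pair. Both quantities are
tabulated for all 64 × 64 codon pairs at import time, so pairwise
estimation and bootstrapping are table lookups.

Codon columns containing a gap, an ambiguity symbol or a stop in either
sequence are deleted pairwise; lower-case input is upper-cased and every
IUPAC ambiguity other than N is collapsed to N on reading, so downstream
code handles a single degenerate symbol.

Multiple-hit correction uses the Jukes–Cantor one-parameter model,
*K*<sub>S</sub> = −(3/4) ln(1 − (4/3) *p*<sub>S</sub>), undefined at
*p*<sub>S</sub> ≥ 0.75 (reported as such, not raised, in batch paths).
Standard errors are binomial over synonymous sites,
se(*p*<sub>S</sub>) = √(*p*<sub>S</sub>(1 − *p*<sub>S</sub>)/*S*), with the
delta method for *K*<sub>S</sub>:
se(*K*<sub>S</sub>) = se(*p*<sub>S</sub>)/(1 − 4*p*<sub>S</sub>/3). These
are the standard first-order formulas; published tables computed with
other ("maximum-variance") estimators will not match them exactly, so no
test asserts equality with any externally printed standard error. For
multi-copy genes, the divergence of a gene pair is the arithmetic mean of
*p*<sub>S</sub> (and *K*<sub>S</sub>) over all X-copy × Y-copy pairs.

Two divergence estimates are compared with the normal deviate
Z = |d₁ − d₂|/√(se₁² + se₂²), two-tailed.

## Trees

Neighbor joining follows Saitou & Nei with the Studier–Keppler Q
criterion. Determinism is guaranteed by joining the lexicographically
smallest pair of current node indices on Q ties. Negative branch lengths
are clamped to zero with the deficit moved to the sister branch (path
lengths preserved); clamp events are counted on the tree object. On an
additive matrix the implementation is exact, which the test suite checks
against randomly generated trees of up to 8 leaves and against dendropy's
independent NJ.

Bootstrap resampling draws codon columns (not individual sites) with
replacement so every replicate remains a valid codon alignment for
*p*<sub>S</sub>; replicates in which any pair's *p*<sub>S</sub> is
undefined are redrawn, capped at 10 × the requested replicates. Support
for an internal edge is the percentage of replicate NJ trees containing
the same leaf bipartition. Trees are built unrooted; monophyly queries
root at a user-designated outgroup.

Whether published bootstrap analyses of this kind resampled codons or
nucleotides is generally unstated; codon resampling was chosen because it
preserves the unit on which the distance is defined.

## Informative sites and conversion tests

For a quartet with roles EX, EY (one clade's X and Y) and MX, MY (the
other clade's), an alignment column is phylogenetically informative iff
exactly two states each occur exactly twice. The pairing that shares
states assigns topology A ([EX, MX], [EY, MY]: differentiation before the
clades split), B ([EX, EY], [MX, MY]: differentiation after the split, or
lineage-specific gene conversion) or C (the remaining pairing, expected
only by chance). Second codon positions are the default substrate because
they saturate slowest; the codon position is configurable (the simulator's
four-fold scaffold only varies at third positions, so its tests read
position 3).

The runs test asks whether topology-A and topology-B sites interleave
randomly along the alignment: conversion produces clustered B sites, i.e.
fewer runs. The one-tailed p is exact — the closed-form Wald–Wolfowitz
run-count distribution — for n₁ + n₂ ≤ 20, else a normal approximation
with continuity correction (the two agree within 0.02 at n₁ = n₂ = 10,
kept as a regression bound). Which two site classes enter is configurable;
A vs B with C discarded is the default.

The global fragment test condenses the alignment to polymorphic columns
(gap/N columns removed), scores each sequence pair by its longest run of
consecutive identical condensed columns, and takes the maximum over pairs.
Significance comes from random permutations of column order (default
10,000), with the add-one estimator p = (1 + hits)/(1 + n). This is a
deliberate simplification of GENECONV's global test: mismatch-free inner
fragments only, length scored in polymorphic sites, multiplicity handled
by the max statistic. It trades GENECONV's mismatch penalties and outer
fragments for a fully specified null.

Low-divergence regions are delineated on non-overlapping 500-bp window
profiles (pairwise gap deletion; windows with fewer than half the window
size of compared sites flagged unreliable). Maximal runs of at least 2
consecutive reliable windows below the pooled divergence are tested by a
one-tailed two-proportion Z on pooled difference counts, inside vs all
other reliable windows, and reported when p < 0.001. Pooling (rather than
per-window testing) matches the granularity of the question — is this
*region* converted — and the 0.001 threshold keeps the false-positive rate
on null simulations near 4% (measured by the acceptance script at 500
replicates). The minimum of 2 windows suppresses single-window artifacts.

Direction of conversion is never tested statistically; it is read
descriptively from which gametolog clusters with the other clade's copies
in the region tree.

## Dating

With male/female mutation-rate ratio α and a 1:1 sex ratio, the X spends
2/3 of its history in the female germ line, so
m_f = 2 m_A/(1 + α), m_m = α m_f, m_X = (2/3) m_f + (1/3) m_m,
m_Y = m_m, and an X/Y pair diverges at m_XY = m_X + m_Y per year. The
autosomal rate is calibrated as m_A = K/(2T) from a neutral divergence K
between species with a split-time window [T_lo, T_hi]; the younger bound
gives the faster rate and hence the younger date T = K_S/m_XY. α defaults
to 2, the conservative end of mammalian estimates (2–6); the 1:1 sex ratio
is hard-coded.

Two rounding modes exist because chained published estimates are
conventionally reported with each intermediate rounded to 3 significant
figures, and sums such as 2.38 + 3.57 = 5.95 (×10⁻⁹) only reproduce under
that convention. `printed-chain` (3 s.f. intermediates, dates rounded
half-up to integer Myr) reproduces such chains; `full-precision` defers
all rounding and is the scientific default for new analyses. In
full-precision mode the chain is exactly invertible (dating K = m_XY·T
returns T), which is under test.

## The simulator

`simulate_gametologs` evolves one ancestral sequence down the fixed tree
(outgroup split, recombination arrest at `T_arrest`, speciation of the two
clades at `T_split`), drawing Poisson substitution counts per branch at
per-year rates m_X (X branches), m_Y (Y branches) and m_A (pre-arrest and
outgroup branches), with Jukes–Cantor base changes. Multiple hits at one
site compose additively mod 4, which is distributionally identical to
sequential application. Conversion events replace the recipient's tract
with the donor's current sequence instantaneously at `t_event`; inside a
converted tract the X/Y coalescence time is t_event, not T_arrest, and the
truth ledger records the implied per-region expected divergence.

Two scaffolds are provided. The default four-fold-degenerate codon
scaffold freezes positions 1–2 using only codon families (GTN, TCN, CCN,
ACN, GCN, GGN) whose first two positions admit no synonymous change, so
every substitution is synonymous and the Nei–Gojobori *S* equals the codon
count exactly — estimator tests decouple from simulator complexity. The
`nucleotide` scaffold frees every position (raw Jukes–Cantor sequences)
for window-profile and conversion analyses.

Default study conditions: T_arrest = 180 Myr, T_split = 160 Myr,
m_f = 2 × 10⁻⁹ per site per year, α = 2 (hence m_A = 3 × 10⁻⁹,
m_X ≈ 2.67 × 10⁻⁹, m_Y = 4 × 10⁻⁹), matching the therian scenario the
dating chain infers. The outgroup split time is not constrained by that
scenario beyond preceding the arrest; 1.3 × T_arrest (≈ 234 Myr) was
chosen to sit near the monotreme divergence and is configurable. Tests of
topology-dependent signals (bootstrap support, informative-site polarity,
monophyly) use a strong-signal variant with T_split = 50 Myr, since with
arrest only 20 Myr before speciation the internal branches are short
relative to saturated terminal branches and any method's signal is
legitimately weak.

What the simulator does *not* emulate: codon-usage bias, selection,
indels and alignment error, among-site rate heterogeneity, partial or
patchy conversion tracts, and coalescent polymorphism at the arrest time.
Passing tests therefore demonstrate correctness of the estimators and
detectors under their own model assumptions, not robustness to real-data
violations of them.

## Problem sizes and numerical choices

The statistical calibration summaries are computed at: 100 replicates of
10,000 codons for dating coverage (2-SE interval, delta-method SE), 1,000
label shuffles for the runs-test type-I error, 50 random additive trees
(≤ 8 leaves, exactness to 1e-9) for NJ, 25 high-signal and 500 null
replicates of ~10-kb genomic pairs for conversion-region detection. These
sizes give binomial uncertainties comfortably inside the asserted bands.

Degenerate inputs are errors, not silent results: alignments with fewer
than 2 rows, codon-mode lengths not divisible by 3, pairs with no shared
complete codon, S = 0 pairs (e.g. all-Met/Trp), both-zero standard errors
in Z comparisons, absent label classes in the runs test, and fewer than 4
reliable windows in region detection. Saturated distances (p_S ≥ 0.75)
propagate as undefined values and NJ refuses to run while naming the
offending pairs.
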