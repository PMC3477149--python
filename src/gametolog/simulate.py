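"""Forward simulator of gametolog evolution.

Generates 4-OTU (optionally 5 with an outgroup) alignments of X- and
Y-linked gametologs from two clades ("eutherian" and "marsupial") that stop
recombining at ``T_arrest`` and speciate at ``T_split``, under sex-biased
substitution rates, with optional ectopic gene-conversion tracts.  Every
stage of the analysis pipeline is exercisable from these fixtures alone.

Tree (ages in years before present)::

    T_out ──┬── outgroup (autosomal rate)
            └─ T_arrest ──┬── X ancestor ── T_split ──┬── EX
                          │      (m_X)                └── MX
                          └── Y ancestor ── T_split ──┬── EY
                                 (m_Y)                └── MY

Rates: m_X = (2/3 + alpha/3) m_f, m_Y = alpha m_f, autosomal
m_A = (1 + alpha)/2 m_f.  Substitution counts on each branch are Poisson
with mean rate x time x sites; each hit moves the site to one of the three
other bases uniformly (Jukes-Cantor).

Two sequence scaffolds:

* ``fourfold`` (default) — codons with frozen first two positions drawn from
  the eight 4-fold-degenerate codon families, third position free.  Every
  change is synonymous, so the Nei-Gojobori S equals the codon count exactly
  and estimator tests decouple from simulator complexity.
* ``nucleotide`` — every position free (raw Jukes-Cantor sequences), for
  window-profile and conversion tests on "genomic" alignments.

Conversion is instantaneous, complete tract replacement: at ``t_event`` the
recipient's region is overwritten by the donor's current sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .alignment_io import CodonAlignment, TaxonTag, write_alignment, write_tag_map

# 4-fold-degenerate codon families whose first two positions admit no
# synonymous change (CTN and CGN are excluded: their first position can
# change synonymously, e.g. CTA->TTA), so Nei-Gojobori S == codon count
FOURFOLD_PREFIXES = ("GT", "TC", "CC", "AC", "GC", "GG")
_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionEvent:
    """Instantaneous tract replacement between gametologs of one clade."""

    clade: Literal["eutherian", "marsupial"]
    direction: Literal["Y->X", "X->Y"]
    start_codon: int
    end_codon: int            # exclusive
    t_event: float            # years before present

    def __post_init__(self) -> None:
        if self.clade not in ("eutherian", "marsupial"):
            raise SimulationError(f"unknown clade {self.clade!r}")
        if self.direction not in ("Y->X", "X->Y"):
            raise SimulationError(f"unknown direction {self.direction!r}")
        if not 0 <= self.start_codon < self.end_codon:
            raise SimulationError("invalid conversion region")
        if self.t_event < 0:
            raise SimulationError("t_event must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for one simulated gametolog pair.

    Defaults mirror the inferred therian scenario: recombination arrest
    ~180 Myr ago, eutherian/marsupial speciation ~160 Myr ago, a female
    rate consistent with autosomal m_A ~3e-9 at alpha = 2.
    """

    n_codons: int = 2000
    T_split: float = 1.6e8
    T_arrest: float = 1.8e8
    m_f: float = 2.0e-9
    alpha: float = 2.0
    conversion_events: list[ConversionEvent] = field(default_factory=list)
    include_outgroup: bool = True
    T_outgroup: Optional[float] = None   # default: 1.3 x T_arrest
    scaffold: Literal["fourfold", "nucleotide"] = "fourfold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise SimulationError("n_codons must be >= 1")
        if not self.T_arrest >= self.T_split > 0:
            raise SimulationError("require T_arrest >= T_split > 0")
        if self.m_f < 0 or self.alpha <= 0:
            raise SimulationError("require m_f >= 0 and alpha > 0")
        if self.T_outgroup is None:
            self.T_outgroup = 1.3 * self.T_arrest
        if self.include_outgroup and self.T_outgroup < self.T_arrest:
            raise SimulationError("outgroup must split before recombination arrest")
        for ev in self.conversion_events:
            if ev.t_event >= self.T_split:
                raise SimulationError("conversion events must postdate T_split")
            if ev.end_codon > self.n_codons:
                raise SimulationError("conversion region outside [0, n_codons)")

    # rates ---------------------------------------------------------------
    @property
    def m_m(self) -> float:
        return self.alpha * self.m_f

    @property
    def m_X(self) -> float:
        return (2.0 / 3.0) * self.m_f + (1.0 / 3.0) * self.m_m

    @property
    def m_Y(self) -> float:
        return self.m_m

    @property
    def m_A(self) -> float:
        return 0.5 * (self.m_f + self.m_m)

    @property
    def n_sites(self) -> int:
        """Free (mutable) sites: third positions, or all positions."""
        return self.n_codons if self.scaffold == "fourfold" else 3 * self.n_codons


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated alignment."""

    branch_substitutions: dict[str, int]
    converted_regions: list[dict]
    expected_divergence: dict[str, float]      # per free site, whole gene
    expected_p: dict[str, float]               # JC expectation of observed p
    region_expected_p: list[dict]
    config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def jc_expected_p(d: float) -> float:
    """Expected observed proportion of differences at true distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _evolve(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator) -> int:
    """JC69 evolution in place over time t; returns the substitution count."""
    L = seq.size
    n = rng.poisson(rate * t * L)
    if n:
        sites = rng.integers(0, L, size=n)
        steps = rng.integers(1, 4, size=n)
        # hits at the same site compose additively mod 4 under JC
        delta = np.zeros(L, dtype=np.int64)
        np.add.at(delta, sites, steps)
        seq += delta
        seq %= 4
    return int(n)


def simulate_gametologs(cfg: SimConfig) -> tuple[CodonAlignment, SimTruth]:
    """Run the forward simulation; returns the alignment and its truth ledger.

    Taxa are named EX, EY (eutherian X/Y), MX, MY (marsupial X/Y) and OUT.
    Reproducible bit-for-bit from ``cfg.seed``: branches are evolved in a
    fixed traversal order (outgroup, proto-XY, X then Y ancestor, then
    EX, MX, EY, MY with clade events sorted oldest first).
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_sites
    root = rng.integers(0, 4, size=L)
    subs: dict[str, int] = {}

    # outgroup branch (autosomal rate throughout)
    out_seq = None
    if cfg.include_outgroup:
        out_seq = root.copy()
        subs["outgroup"] = _evolve(out_seq, cfg.m_A, cfg.T_outgroup, rng)
        proto = root.copy()
        subs["proto_XY"] = _evolve(proto, cfg.m_A, cfg.T_outgroup - cfg.T_arrest, rng)
    else:
        proto = root.copy()
        subs["proto_XY"] = 0

    # ancestral X and Y between arrest and speciation
    x_anc = proto.copy()
    subs["X_ancestor"] = _evolve(x_anc, cfg.m_X, cfg.T_arrest - cfg.T_split, rng)
    y_anc = proto.copy()
    subs["Y_ancestor"] = _evolve(y_anc, cfg.m_Y, cfg.T_arrest - cfg.T_split, rng)

    # terminal branches, pausing at conversion events
    def site_slice(ev: ConversionEvent) -> slice:
        if cfg.scaffold == "fourfold":
            return slice(ev.start_codon, ev.end_codon)
        return slice(3 * ev.start_codon, 3 * ev.end_codon)

    terminals: dict[str, np.ndarray] = {}
    for clade, xname, yname in (("eutherian", "EX", "EY"), ("marsupial", "MX", "MY")):
        x = x_anc.copy()
        y = y_anc.copy()
        t_now = cfg.T_split
        events = sorted((e for e in cfg.conversion_events if e.clade == clade),
                        key=lambda e: -e.t_event)
        nx = ny = 0
        for ev in events:
            nx += _evolve(x, cfg.m_X, t_now - ev.t_event, rng)
            ny += _evolve(y, cfg.m_Y, t_now - ev.t_event, rng)
            sl = site_slice(ev)
            if ev.direction == "Y->X":
                x[sl] = y[sl]
            else:
                y[sl] = x[sl]
            t_now = ev.t_event
        nx += _evolve(x, cfg.m_X, t_now, rng)
        ny += _evolve(y, cfg.m_Y, t_now, rng)
        subs[xname] = nx
        subs[yname] = ny
        terminals[xname] = x
        terminals[yname] = y

    # assemble sequence strings
    if cfg.scaffold == "fourfold":
        prefixes = rng.integers(0, len(FOURFOLD_PREFIXES), size=cfg.n_codons)

        def to_str(third: np.ndarray) -> str:
            return "".join(
                FOURFOLD_PREFIXES[p] + _BASES[b] for p, b in zip(prefixes, third)
            )
    else:
        def to_str(seq: np.ndarray) -> str:
            return "".join(_BASES[b] for b in seq)

    order = ["EX", "EY", "MX", "MY"]
    tags = {
        "EX": TaxonTag("eut", "X", "eutherian"),
        "EY": TaxonTag("eut", "Y", "eutherian"),
        "MX": TaxonTag("mar", "X", "marsupial"),
        "MY": TaxonTag("mar", "Y", "marsupial"),
    }
    rows = [to_str(terminals[k]) for k in order]
    if cfg.include_outgroup:
        order.append("OUT")
        tags["OUT"] = TaxonTag("out", "autosome", "outgroup")
        rows.append(to_str(out_seq))

    aln = CodonAlignment(
        ids=order,
        taxa=[tags[k] for k in order],
        rows=rows,
        mode="codon" if cfg.scaffold == "fourfold" else "genomic",
    )

    truth = _build_truth(cfg, subs)
    return aln, truth


def _pair_distance(cfg: SimConfig, a: str, b: str) -> float:
    """Expected substitutions per free site between two taxa, no conversion."""
    mX, mY, mA = cfg.m_X, cfg.m_Y, cfg.m_A
    if {a, b} == {"EX", "EY"} or {a, b} == {"MX", "MY"}:
        return (mX + mY) * cfg.T_arrest
    if {a, b} == {"EX", "MX"}:
        return 2 * mX * cfg.T_split
    if {a, b} == {"EY", "MY"}:
        return 2 * mY * cfg.T_split
    if {a, b} in ({"EX", "MY"}, {"EY", "MX"}):
        return (mX + mY) * cfg.T_split + (mX + mY) * (cfg.T_arrest - cfg.T_split)
    if "OUT" in (a, b):
        other = b if a == "OUT" else a
        m = mX if other.endswith("X") else mY
        return (mA * cfg.T_outgroup
                + mA * (cfg.T_outgroup - cfg.T_arrest)
                + m * cfg.T_arrest)
    raise SimulationError(f"unknown pair {a}, {b}")


def _build_truth(cfg: SimConfig, subs: dict[str, int]) -> SimTruth:
    taxa = ["EX", "EY", "MX", "MY"] + (["OUT"] if cfg.include_outgroup else [])
    exp_d, exp_p = {}, {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = _pair_distance(cfg, a, b)
            exp_d[f"{a}-{b}"] = d
            exp_p[f"{a}-{b}"] = jc_expected_p(d)

    converted = []
    region_p = []
    for ev in cfg.conversion_events:
        recipient = (("EX" if ev.clade == "eutherian" else "MX")
                     if ev.direction == "Y->X"
                     else ("EY" if ev.clade == "eutherian" else "MY"))
        scale = 1 if cfg.scaffold == "fourfold" else 3
        converted.append({
            "clade": ev.clade, "direction": ev.direction,
            "recipient": recipient,
            "start_codon": ev.start_codon, "end_codon": ev.end_codon,
            "start_bp": 3 * ev.start_codon, "end_bp": 3 * ev.end_codon,
            "start_site": scale * ev.start_codon, "end_site": scale * ev.end_codon,
            "t_event": ev.t_event,
        })
        # within the tract the X/Y pair of that clade coalesces at t_event
        pair = ("EX-EY" if ev.clade == "eutherian" else "MX-MY")
        d_conv = (cfg.m_X + cfg.m_Y) * ev.t_event
        region_p.append({"pair": pair, "start_codon": ev.start_codon,
                         "end_codon": ev.end_codon,
                         "expected_d": d_conv, "expected_p": jc_expected_p(d_conv)})

    return SimTruth(branch_substitutions=subs, converted_regions=converted,
                    expected_divergence=exp_d, expected_p=exp_p,
                    region_expected_p=region_p, config=asdict(cfg))


def write_fixture(aln: CodonAlignment, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write FASTA + taxon TSV + truth JSON; enough input for every stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "alignment.fasta",
        "tags": outdir / "taxa.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(aln, paths["fasta"])
    write_tag_map(dict(zip(aln.ids, aln.taxa)), paths["tags"])
    paths["truth"].write_text(truth.to_json())
    return paths
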