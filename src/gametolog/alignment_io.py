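"""Reading, validating, tagging and slicing of gametolog alignments.

All coordinate conventions live here: internally every interval is 0-based,
half-open; the user-facing helpers accept the 1-based inclusive "start-end"
strings conventional in the literature (e.g. "1-1000") and convert.

Alignments are plain in-memory objects: an ordered list of taxa (each with a
:class:`TaxonTag` describing species, chromosome of origin and clade) plus
equal-length upper-case rows over the alphabet ``A C G T N -``.  Lower-case
input is upper-cased and any IUPAC ambiguity code other than ``N`` is mapped
to ``N`` so that downstream pairwise-deletion logic only ever has to treat a
single degenerate symbol.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

CHROMOSOMES = frozenset({"X", "Y", "autosome", "unknown"})
CLADES = frozenset({"eutherian", "marsupial", "monotreme", "outgroup"})

_VALID = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Rows of unequal length or too few records."""


class FrameError(AlignmentError):
    """Codon-mode alignment whose length is not a multiple of 3."""


class RegionError(ValueError):
    """Region outside alignment bounds or malformed."""


@dataclass(frozen=True)
class TaxonTag:
    """Identity of one aligned sequence: species, chromosome and clade."""

    species_code: str
    chromosome: str = "unknown"
    clade: str = "outgroup"

    def __post_init__(self) -> None:
        if not self.species_code:
            raise ValueError("species_code must be non-empty")
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"chromosome must be one of {sorted(CHROMOSOMES)}")
        if self.clade not in CLADES:
            raise ValueError(f"clade must be one of {sorted(CLADES)}")


@dataclass(frozen=True)
class Region:
    """Half-open column interval [start, end) with a free-text label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def parse_region(text: str, label: str = "") -> Region:
    """Convert a 1-based inclusive ``"start-end"`` string to a :class:`Region`.

    ``"1-1000"`` becomes ``Region(0, 1000)``.  En-dashes are accepted.
    """
    cleaned = text.strip().replace("–", "-").replace("—", "-")
    try:
        lo_s, hi_s = cleaned.split("-")
        lo, hi = int(lo_s), int(hi_s)
    except ValueError as exc:
        raise RegionError(f"cannot parse region {text!r}") from exc
    if lo < 1 or hi < lo:
        raise RegionError(f"1-based region must satisfy 1 <= start <= end: {text!r}")
    return Region(lo - 1, hi, label=label)


def _sanitize(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in _VALID:
            out.append(ch)
        elif ch.isalpha():
            out.append("N")  # IUPAC ambiguity collapsed to a single symbol
        else:
            raise AlignmentError(f"illegal alignment character {ch!r}")
    return "".join(out)


@dataclass
class CodonAlignment:
    """An aligned set of sequences with per-taxon tags.

    ``mode`` is ``"codon"`` for in-frame coding alignments (length divisible
    by 3, frame starting at column 0) or ``"genomic"`` for free nucleotide
    alignments used in sliding-window analyses.
    """

    ids: list[str]
    taxa: list[TaxonTag]
    rows: list[str]
    mode: str = "codon"

    def __post_init__(self) -> None:
        if self.mode not in ("codon", "genomic"):
            raise ValueError("mode must be 'codon' or 'genomic'")
        if len(self.rows) < 2:
            raise AlignmentError("alignment needs at least 2 records")
        if not (len(self.ids) == len(self.taxa) == len(self.rows)):
            raise AlignmentError("ids, taxa and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"rows have unequal lengths {sorted(lengths)}")
        if self.mode == "codon" and self.length % 3 != 0:
            raise FrameError(
                f"codon-mode alignment length {self.length} is not a multiple of 3"
            )
        self.rows = [_sanitize(r) for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        if self.mode != "codon":
            raise ValueError("n_codons only defined in codon mode")
        return self.length // 3

    def __len__(self) -> int:
        return len(self.rows)

    def index_of(self, key: Union[str, TaxonTag]) -> int:
        """Row index of a record id or an exactly matching :class:`TaxonTag`."""
        if isinstance(key, TaxonTag):
            try:
                return self.taxa.index(key)
            except ValueError:
                raise KeyError(f"taxon {key} not in alignment") from None
        try:
            return self.ids.index(key)
        except ValueError:
            raise KeyError(f"record id {key!r} not in alignment") from None

    def row(self, key: Union[str, TaxonTag]) -> str:
        return self.rows[self.index_of(key)]


def read_tag_map(path: Union[str, Path]) -> dict[str, TaxonTag]:
    """Read the sidecar taxon TSV: record_id, species_code, chromosome, clade."""
    tags: dict[str, TaxonTag] = {}
    with open(path, newline="") as fh:
        for line in csv.reader(fh, delimiter="\t"):
            if not line or line[0].startswith("#"):
                continue
            rec_id, species, chrom, clade = (f.strip() for f in line[:4])
            tags[rec_id] = TaxonTag(species, chrom, clade)
    return tags


def write_tag_map(tags: dict[str, TaxonTag], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec_id, tag in tags.items():
            w.writerow([rec_id, tag.species_code, tag.chromosome, tag.clade])


def read_alignment(
    path: Union[str, Path],
    mode: str = "codon",
    tag_map: dict[str, TaxonTag] | None = None,
) -> CodonAlignment:
    """Read an aligned multi-FASTA into a validated :class:`CodonAlignment`.

    Records absent from ``tag_map`` are tagged chromosome=unknown,
    clade=outgroup with the record id as species code.
    """
    tag_map = tag_map or {}
    ids: list[str] = []
    taxa: list[TaxonTag] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        taxa.append(tag_map.get(rec.id, TaxonTag(rec.id)))
        rows.append(str(rec.seq))
    if len(rows) < 2:
        raise AlignmentError(f"{path}: fewer than 2 FASTA records")
    return CodonAlignment(ids=ids, taxa=taxa, rows=rows, mode=mode)


def write_alignment(aln: CodonAlignment, path: Union[str, Path]) -> None:
    """Write unwrapped FASTA (one sequence per line; byte-stable round trip)."""
    with open(path, "w") as fh:
        for rec_id, row in zip(aln.ids, aln.rows):
            fh.write(f">{rec_id}\n{row}\n")


def slice_region(aln: CodonAlignment, region: Region) -> CodonAlignment:
    """Sub-alignment over the region's columns; mode is preserved."""
    if region.end > aln.length:
        raise RegionError(
            f"region [{region.start}, {region.end}) exceeds alignment length {aln.length}"
        )
    if aln.mode == "codon" and (region.start % 3 or region.end % 3):
        raise RegionError("codon-mode regions must start and end on codon boundaries")
    return CodonAlignment(
        ids=list(aln.ids),
        taxa=list(aln.taxa),
        rows=[r[region.start : region.end] for r in aln.rows],
        mode=aln.mode,
    )


def codon_position_sites(
    aln: CodonAlignment,
    taxa: Sequence[Union[str, TaxonTag]],
    position: int = 2,
) -> list[tuple[int, tuple[str, str, str, str]]]:
    """Residues at one codon position (1, 2 or 3) for 4 selected taxa.

    Returns ``(alignment column, residues)`` per codon; codons where any
    selected residue is a gap or ``N`` are dropped.
    """
    if aln.mode != "codon":
        raise ValueError("codon_position_sites requires a codon-mode alignment")
    if len(taxa) != 4:
        raise ValueError("exactly 4 taxa are required")
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    idx = [aln.index_of(t) for t in taxa]
    sites = []
    for j in range(aln.n_codons):
        col = 3 * j + position - 1
        residues = tuple(aln.rows[i][col] for i in idx)
        if any(ch in "N-" for ch in residues):
            continue
        sites.append((col, residues))
    return sites


def second_position_sites(
    aln: CodonAlignment, taxa: Sequence[Union[str, TaxonTag]]
) -> list[tuple[int, tuple[str, str, str, str]]]:
    """Second-codon-position residues for 4 selected taxa.

    Second positions are the slowest-saturating class of coding sites,
    which is why informative-site topology counting uses them.
    """
    return codon_position_sites(aln, taxa, position=2)
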