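"""Degenerate IUPAC motif scanning on both strands.

The default pattern is ``VGAATAW`` (V = {A,C,G}, W = {A,T}); its reverse
complement is ``WTATTCB``.  Minus-strand matches are reported in plus-strand
coordinates.  ``N`` bases in the scanned sequence never match.  All
overlapping occurrences are reported; region membership only needs one hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

from kanseek.errors import ValidationError
from kanseek.io_formats import BindingRegion

#: IUPAC nucleotide code -> set of concrete bases it allows.
IUPAC_CODES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items() if code != "X"
}

DEFAULT_MOTIF_PATTERN = "VGAATAW"


def expand_iupac(pattern: str) -> list[frozenset[str]]:
    """Expand an IUPAC pattern to one allowed-base set per position."""
    if len(pattern) < 1:
        raise ValidationError("motif pattern must have length >= 1")
    sets: list[frozenset[str]] = []
    for symbol in pattern.upper():
        if symbol not in IUPAC_CODES:
            raise ValidationError(f"unknown IUPAC symbol {symbol!r} in motif pattern {pattern!r}")
        sets.append(IUPAC_CODES[symbol])
    return sets


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate nucleotide motif over the 15 IUPAC codes."""

    pattern: str = DEFAULT_MOTIF_PATTERN

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        expand_iupac(self.pattern)  # validates

    @property
    def per_position_sets(self) -> list[frozenset[str]]:
        return expand_iupac(self.pattern)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One strand-aware motif match; offset/matched are in plus-strand coordinates."""

    region_id: str
    offset: int
    strand: str
    matched: str


def reverse_complement_motif(motif: IupacMotif) -> IupacMotif:
    """Reverse the pattern and complement each symbol under IUPAC rules."""
    comp = "".join(ambiguous_dna_complement[s] for s in motif.pattern)
    return IupacMotif(pattern=comp[::-1])


@lru_cache(maxsize=64)
def _compiled(pattern: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all reported.
    body = "".join("[%s]" % "".join(sorted(s)) for s in expand_iupac(pattern))
    return re.compile(f"(?=({body}))")


def scan_sequence(
    seq: str,
    motif: IupacMotif | str = DEFAULT_MOTIF_PATTERN,
    strands: str = "both",
    region_id: str = "",
) -> list[MotifHit]:
    """Report every motif occurrence in ``seq`` on the requested strands.

    Minus-strand hits are matches of the reverse-complement pattern on the
    given sequence, reported at their plus-strand offset.  Output is sorted
    by (offset, strand).
    """
    if strands not in {"plus", "minus", "both"}:
        raise ValidationError(f"strands must be plus/minus/both, got {strands!r}")
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    seq = seq.upper()
    k = len(motif)
    hits: list[MotifHit] = []
    if strands in {"plus", "both"}:
        for m in _compiled(motif.pattern).finditer(seq):
            hits.append(MotifHit(region_id=region_id, offset=m.start(), strand="+", matched=m.group(1)))
    if strands in {"minus", "both"}:
        rc = reverse_complement_motif(motif)
        for m in _compiled(rc.pattern).finditer(seq):
            hits.append(MotifHit(region_id=region_id, offset=m.start(), strand="-", matched=m.group(1)))
    assert all(h.offset + k <= len(seq) for h in hits)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def regions_with_motif(
    regions: Sequence[BindingRegion],
    genome: Mapping[str, str],
    motif: IupacMotif | str = DEFAULT_MOTIF_PATTERN,
    strands: str = "both",
) -> tuple[list[BindingRegion], list[BindingRegion], list[MotifHit]]:
    """Partition regions into motif-containing / motif-free subsets.

    Hit offsets are local to each region's scanned sequence.  Raises when a
    region's chromosome is missing or its span exceeds the sequence.
    """
    with_motif: list[BindingRegion] = []
    without_motif: list[BindingRegion] = []
    all_hits: list[MotifHit] = []
    for region in regions:
        if region.chrom not in genome:
            raise ValidationError(f"region {region.region_id}: chromosome {region.chrom!r} not in genome")
        seq = genome[region.chrom]
        if region.end > len(seq):
            raise ValidationError(
                f"region {region.region_id}: span [{region.start},{region.end}) exceeds "
                f"{region.chrom} length {len(seq)}"
            )
        hits = scan_sequence(seq[region.start : region.end], motif, strands, region_id=region.region_id)
        all_hits.extend(hits)
        (with_motif if hits else without_motif).append(region)
    return with_motif, without_motif, all_hits


def write_hit_table(hits: Iterable[MotifHit], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("region_id\toffset\tstrand\tmatched\n")
        for h in hits:
            handle.write(f"{h.region_id}\t{h.offset}\t{h.strand}\t{h.matched}\n")
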