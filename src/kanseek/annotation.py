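"""Assign binding regions to nearby gene models and summarize positions.

Each region is anchored at a single point (its summit; the interval midpoint
when no summit was called) and compared against the CDS span of every gene
on the same chromosome within a window (default 10500 bp, the smallest
round radius consistent with the largest printed target distance of
10052 bp).  A summit inside a gene body is labeled IN_CDS with distance 0;
otherwise the distance is measured to the nearer CDS boundary and the label
is UP on the gene's 5' side and DOWN on its 3' side, strand-aware.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from kanseek.errors import ConfigError, ValidationError
from kanseek.io_formats import BindingRegion, GeneModel

DEFAULT_WINDOW = 10500

LOCATION_UP = "UP"
LOCATION_DOWN = "DOWN"
LOCATION_IN_CDS = "IN_CDS"


@dataclass(frozen=True)
class GeneAssignment:
    region_id: str
    gene_id: str
    distance: int
    location: str
    is_nearest: bool = False

    def __post_init__(self) -> None:
        if (self.distance == 0) != (self.location == LOCATION_IN_CDS):
            raise ValidationError(
                f"assignment {self.region_id}->{self.gene_id}: distance 0 iff IN_CDS violated "
                f"(distance={self.distance}, location={self.location})"
            )


@dataclass(frozen=True)
class PositionBinSummary:
    """Counts and proportions of regions per positional bin."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    proportions: tuple[float, ...]

    def as_dict(self) -> dict[str, tuple[int, float]]:
        return {l: (c, p) for l, c, p in zip(self.labels, self.counts, self.proportions)}


def _locate(summit: int, gene: GeneModel) -> tuple[int, str]:
    """Distance to the CDS span and UP/DOWN/IN_CDS label for one summit."""
    if gene.body_start <= summit < gene.body_end:
        return 0, LOCATION_IN_CDS
    if summit < gene.cds_start:
        distance = gene.cds_start - summit
        side_is_low = True
    else:
        distance = summit - gene.cds_end
        if distance == 0:
            # Summit touching the half-open CDS end boundary counts as contained.
            return 0, LOCATION_IN_CDS
        side_is_low = False
    five_prime_is_low = gene.strand == "+"
    location = LOCATION_UP if side_is_low == five_prime_is_low else LOCATION_DOWN
    return distance, location


def assign_region(
    region: BindingRegion,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    anchor: str = "summit",
) -> list[GeneAssignment]:
    """Assign one region to every gene whose CDS lies within ``window`` of its anchor.

    Exactly one returned assignment carries ``is_nearest=True`` (smallest
    distance, ties broken by lexicographically smaller gene_id); the list is
    empty when no gene is in range.
    """
    if window <= 0:
        raise ConfigError(f"window must be > 0, got {window}")
    if anchor not in {"summit", "midpoint"}:
        raise ConfigError(f"anchor must be 'summit' or 'midpoint', got {anchor!r}")
    point = region.summit if anchor == "summit" else (region.start + region.end) // 2
    candidates: list[tuple[int, str, GeneAssignment]] = []
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        distance, location = _locate(point, gene)
        if distance <= window:
            assignment = GeneAssignment(
                region_id=region.region_id,
                gene_id=gene.gene_id,
                distance=distance,
                location=location,
            )
            candidates.append((distance, gene.gene_id, assignment))
    if not candidates:
        return []
    candidates.sort(key=lambda t: (t[0], t[1]))
    out = []
    for i, (_, _, a) in enumerate(candidates):
        out.append(GeneAssignment(a.region_id, a.gene_id, a.distance, a.location, is_nearest=(i == 0)))
    return out


def annotate_regions(
    regions: Sequence[BindingRegion],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    anchor: str = "summit",
) -> list[GeneAssignment]:
    """``assign_region`` over a region list, grouping genes per chromosome once."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for gene in genes:
        by_chrom[gene.chrom].append(gene)
    assignments: list[GeneAssignment] = []
    for region in regions:
        assignments.extend(assign_region(region, by_chrom.get(region.chrom, []), window, anchor))
    return assignments


DEFAULT_BIN_SCHEME = ("upstream_0_1kb", "gene_body", "downstream_0_1kb", "distal")


def _bin_label(assignment: GeneAssignment | None, near_limit: int = 1000) -> str:
    if assignment is None:
        return "distal"
    if assignment.location == LOCATION_IN_CDS:
        return "gene_body"
    if assignment.location == LOCATION_UP and assignment.distance <= near_limit:
        return "upstream_0_1kb"
    if assignment.location == LOCATION_DOWN and assignment.distance <= near_limit:
        return "downstream_0_1kb"
    return "distal"


def position_distribution(
    assignments: Sequence[GeneAssignment],
    regions: Sequence[BindingRegion] | None = None,
    bin_scheme: Sequence[str] = DEFAULT_BIN_SCHEME,
    near_limit: int = 1000,
) -> PositionBinSummary:
    """Summarize the positional distribution of regions via their nearest assignment.

    Each region counts once.  Regions present in ``regions`` but lacking any
    assignment fall in the ``distal`` bin; if the scheme has no distal bin
    such a region is an error.  Zero regions yield an empty summary.
    """
    nearest: dict[str, GeneAssignment] = {a.region_id: a for a in assignments if a.is_nearest}
    region_ids = [r.region_id for r in regions] if regions is not None else list(nearest)
    if not region_ids:
        return PositionBinSummary(labels=(), counts=(), proportions=())
    counts = {label: 0 for label in bin_scheme}
    for rid in region_ids:
        label = _bin_label(nearest.get(rid), near_limit)
        if label not in counts:
            raise ConfigError(f"region {rid}: bin {label!r} not in scheme {tuple(bin_scheme)} (no distal bin configured)")
        counts[label] += 1
    total = sum(counts.values())
    return PositionBinSummary(
        labels=tuple(bin_scheme),
        counts=tuple(counts[l] for l in bin_scheme),
        proportions=tuple(counts[l] / total for l in bin_scheme),
    )


def write_assignment_table(assignments: Sequence[GeneAssignment], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("region_id\tgene_id\tdistance\tlocation\tis_nearest\n")
        for a in assignments:
            handle.write(f"{a.region_id}\t{a.gene_id}\t{a.distance}\t{a.location}\t{'yes' if a.is_nearest else '-'}\n")


def write_distribution_table(summary: PositionBinSummary, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("bin\tcount\tproportion\n")
        for label, count, prop in zip(summary.labels, summary.counts, summary.proportions):
            handle.write(f"{label}\t{count}\t{prop:.6f}\n")
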