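"""Per-gene regulation calls from probe-level induction/control log-ratios.

A gene is called down-regulated at a timepoint when the response is
consistent along the transcript: at least ``min_fraction`` of its probes
(and at least ``min_probes`` probes overall) show a log2 ratio at or below
``-delta``.  Up-calls are symmetric.  The published thresholds were never
printed, so the defaults (delta=1.0 i.e. two-fold, min_fraction=0.9,
min_probes=4) are conservative, configurable stand-ins.  Replicate tracks
for one (gene, timepoint) are averaged probe-wise before calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from kanseek.errors import ConfigError, ValidationError
from kanseek.io_formats import RegulationTableRow

DEFAULT_TIMEPOINTS = (80, 160)


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probe positions and log2(induced/control) ratios for one gene/timepoint."""

    gene_id: str
    timepoint: int
    probe_positions: tuple[int, ...]
    log_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        positions = tuple(int(p) for p in self.probe_positions)
        ratios = tuple(float(r) for r in self.log_ratios)
        order = sorted(range(len(positions)), key=lambda i: positions[i])
        positions = tuple(positions[i] for i in order)
        ratios = tuple(ratios[i] for i in order)
        object.__setattr__(self, "probe_positions", positions)
        object.__setattr__(self, "log_ratios", ratios)
        if len(positions) < 1 or len(positions) != len(ratios):
            raise ValidationError(f"track {self.gene_id}@{self.timepoint}: need >=1 probe with matching ratios")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError(f"track {self.gene_id}@{self.timepoint}: probe positions must be strictly increasing")
        if not all(np.isfinite(ratios)):
            raise ValidationError(f"track {self.gene_id}@{self.timepoint}: log ratios must be finite")


@dataclass(frozen=True)
class TimepointCall:
    """Down/up decision for one gene at one timepoint, with a no-call reason."""

    gene_id: str
    timepoint: int
    down: bool
    up: bool
    reason: str = ""


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    down_80: bool = False
    down_160: bool = False
    up_80: bool = False
    up_160: bool = False

    def __post_init__(self) -> None:
        if (self.down_80 and self.up_80) or (self.down_160 and self.up_160):
            raise ValidationError(f"{self.gene_id}: down and up cannot both hold at one timepoint")

    @property
    def down_any(self) -> bool:
        return self.down_80 or self.down_160


def call_regulation(
    track: ProbeTrack,
    delta: float = 1.0,
    min_fraction: float = 0.9,
    min_probes: int = 4,
) -> TimepointCall:
    """Call down/up regulation for one probe track (see module docstring)."""
    if not delta > 0:
        raise ConfigError(f"delta must be > 0, got {delta}")
    if not (0 < min_fraction <= 1):
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if min_probes < 1:
        raise ConfigError(f"min_probes must be >= 1, got {min_probes}")
    ratios = np.asarray(track.log_ratios)
    if ratios.size < min_probes:
        return TimepointCall(track.gene_id, track.timepoint, False, False,
                             reason=f"only {ratios.size} probes < min_probes {min_probes}")
    frac_down = float(np.mean(ratios <= -delta))
    frac_up = float(np.mean(ratios >= delta))
    down = frac_down >= min_fraction
    up = frac_up >= min_fraction
    if down and up:  # only possible when min_fraction <= 0.5
        down = up = False
        return TimepointCall(track.gene_id, track.timepoint, False, False, reason="ambiguous: both directions pass")
    return TimepointCall(track.gene_id, track.timepoint, down, up)


def pool_replicates(tracks: Sequence[ProbeTrack]) -> ProbeTrack:
    """Average replicate tracks of one (gene, timepoint) probe-wise by position."""
    if not tracks:
        raise ValidationError("cannot pool zero tracks")
    keys = {(t.gene_id, t.timepoint) for t in tracks}
    if len(keys) != 1:
        raise ValidationError(f"cannot pool tracks from different genes/timepoints: {sorted(keys)}")
    positions = tracks[0].probe_positions
    if any(t.probe_positions != positions for t in tracks):
        raise ValidationError(f"replicate tracks for {tracks[0].gene_id}@{tracks[0].timepoint} disagree on probe positions")
    mean = np.mean([t.log_ratios for t in tracks], axis=0)
    return ProbeTrack(tracks[0].gene_id, tracks[0].timepoint, positions, tuple(float(x) for x in mean))


def merge_timepoints(
    calls: Iterable[TimepointCall],
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
) -> list[RegulationCall]:
    """Combine per-timepoint calls into one RegulationCall per gene.

    Genes absent at a timepoint get False there; duplicate (gene, timepoint)
    pairs are an error.  Output sorted by gene_id.
    """
    t80, t160 = timepoints
    per_gene: dict[str, dict[int, TimepointCall]] = {}
    for call in calls:
        slot = per_gene.setdefault(call.gene_id, {})
        if call.timepoint in slot:
            raise ValidationError(f"duplicate call for ({call.gene_id}, {call.timepoint})")
        slot[call.timepoint] = call
    merged = []
    for gene_id in sorted(per_gene):
        slot = per_gene[gene_id]
        c80 = slot.get(t80)
        c160 = slot.get(t160)
        merged.append(
            RegulationCall(
                gene_id=gene_id,
                down_80=bool(c80 and c80.down),
                down_160=bool(c160 and c160.down),
                up_80=bool(c80 and c80.up),
                up_160=bool(c160 and c160.up),
            )
        )
    return merged


def calls_from_table(rows: Iterable[RegulationTableRow]) -> list[RegulationCall]:
    """Adapt a pre-computed yes/- table to RegulationCalls (up flags unknown -> False)."""
    return [
        RegulationCall(gene_id=r.gene_id, down_80=r.down_80, down_160=r.down_160)
        for r in sorted(rows, key=lambda r: r.gene_id)
    ]


# ---------------------------------------------------------------------------
# Probe table I/O (TSV: gene_id, timepoint, position, log_ratio)
# ---------------------------------------------------------------------------


def read_probe_table(path: str) -> list[ProbeTrack]:
    """Read probe-level signals; replicate rows at one position are averaged."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "timepoint", "position", "log_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing probe-table columns {sorted(missing)}")
    tracks: list[ProbeTrack] = []
    for (gene_id, timepoint), group in df.groupby(["gene_id", "timepoint"], sort=True):
        pooled = group.groupby("position", sort=True)["log_ratio"].mean()
        tracks.append(
            ProbeTrack(
                gene_id=str(gene_id),
                timepoint=int(timepoint),
                probe_positions=tuple(int(p) for p in pooled.index),
                log_ratios=tuple(float(v) for v in pooled.values),
            )
        )
    return tracks


def write_probe_table(tracks: Sequence[ProbeTrack], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\ttimepoint\tposition\tlog_ratio\n")
        for t in tracks:
            for pos, ratio in zip(t.probe_positions, t.log_ratios):
                handle.write(f"{t.gene_id}\t{t.timepoint}\t{pos}\t{ratio:.6f}\n")


def write_call_table(calls: Sequence[RegulationCall], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tdown_80\tdown_160\tup_80\tup_160\n")
        for c in calls:
            flags = [c.down_80, c.down_160, c.up_80, c.up_160]
            handle.write(c.gene_id + "\t" + "\t".join("yes" if f else "-" for f in flags) + "\n")
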