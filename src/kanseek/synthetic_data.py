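"""Generate a fully specified synthetic study with recorded ground truth.

The generator emits a genome whose background is rejection-screened to be
motif-free on both strands, non-overlapping gene models, motif instances
planted at configurable positions around target genes (upstream/gene-body/
downstream/distal mixture), binding regions whose summits sit on planted
instances plus motif-free background regions, replicate enrichments drawn
from separated log-normal classes, and probe-level expression tracks with a
configurable down-shift for direct targets at both post-induction
timepoints.  Everything is deterministic given the seed; planted motif
counts are exact by construction.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from kanseek.errors import ConfigError
from kanseek.expression import ProbeTrack, write_probe_table
from kanseek.io_formats import (
    BindingRegion,
    GeneModel,
    fixture_path,
    write_fasta,
    write_gff3,
    write_region_table,
)
from kanseek.motif_scan import IupacMotif, expand_iupac, reverse_complement_motif, scan_sequence

PLACEMENT_BINS = ("upstream_1kb", "gene_body", "downstream_1kb", "distal")

#: planted-location label -> positional bin recovered by annotation
PLACEMENT_TO_POSITION_BIN = {
    "upstream_1kb": "upstream_0_1kb",
    "gene_body": "gene_body",
    "downstream_1kb": "downstream_0_1kb",
    "distal": "distal",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Knobs for one synthetic study; defaults mirror the printed positional
    mixture (~24% upstream-1kb, ~11% downstream-1kb) and enrichment ranges."""

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int | None = None
    n_genes: int = 300
    gene_length: tuple[int, int] = (1000, 3000)
    min_gap: int = 7000
    motif: str = "VGAATAW"
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "upstream_1kb": 0.24,
            "gene_body": 0.40,
            "downstream_1kb": 0.11,
            "distal": 0.25,
        }
    )
    n_target_genes: int = 60
    regions_per_target: int = 1
    n_background_regions: int = 120
    region_halfwidth: int = 150
    target_log_mu: float = math.log(6.0)
    target_log_sigma: float = 0.25
    background_log_mu: float = math.log(1.5)
    background_log_sigma: float = 0.3
    effect_size: float = 2.0
    noise_sigma: float = 0.3
    p_down_given_bound: float = 0.9
    p_down_background: float = 0.05
    probes_per_gene: int = 8
    timepoints: tuple[int, int] = (80, 160)

    def validate(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ConfigError(f"placement mixture must sum to 1, got {sum(self.mixture.values())}")
        if set(self.mixture) != set(PLACEMENT_BINS):
            raise ConfigError(f"mixture keys must be {PLACEMENT_BINS}")
        if self.n_target_genes > self.n_genes:
            raise ConfigError("n_target_genes must be <= n_genes")
        if math.exp(self.target_log_mu) < 3.0:
            raise ConfigError("target enrichment median must be >= the default filter threshold (3)")
        lo, hi = self.gene_length
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid gene_length range {self.gene_length}")
        if self.min_gap < 2 * 3000 + 2 * self.region_halfwidth:
            raise ConfigError("min_gap too small for unambiguous distal placements")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        cfg = cls(**raw)
        if isinstance(cfg.gene_length, list):
            cfg.gene_length = tuple(cfg.gene_length)
        if isinstance(cfg.timepoints, list):
            cfg.timepoints = tuple(cfg.timepoints)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["gene_length"] = list(self.gene_length)
        raw["timepoints"] = list(self.timepoints)
        with open(path, "w") as handle:
            yaml.safe_dump(raw, handle, sort_keys=True)


@dataclass
class TruthTable:
    """Recorded ground truth: per-gene flags and per-region planting facts."""

    genes: pd.DataFrame  # gene_id, is_bound, is_down, is_direct_target, n_planted_regions
    regions: pd.DataFrame  # region_id, chrom, gene_id, kind, planted_location, motif_start, motif_strand

    @property
    def direct_target_genes(self) -> set[str]:
        mask = self.genes["is_direct_target"]
        return set(self.genes.loc[mask, "gene_id"])

    @property
    def n_planted_instances(self) -> int:
        return int((self.regions["kind"] == "target").sum())


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    regions: list[BindingRegion]
    tracks: list[ProbeTrack]
    truth: TruthTable


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _auto_chrom_length(config: SyntheticConfig, n_per_chrom: int) -> int:
    return n_per_chrom * (config.gene_length[1] + config.min_gap + 1000) + 2 * config.min_gap


def _place_genes(config: SyntheticConfig, rng: np.random.Generator) -> tuple[list[GeneModel], dict[str, int]]:
    n_per = math.ceil(config.n_genes / config.n_chroms)
    lengths: dict[str, int] = {}
    genes: list[GeneModel] = []
    idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = min(n_per, config.n_genes - idx)
        length = config.chrom_length or _auto_chrom_length(config, n_here)
        pos = config.min_gap
        for _ in range(n_here):
            body_len = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            gap = config.min_gap + int(rng.integers(0, 1000))
            if pos + body_len + config.min_gap > length:
                raise ConfigError(
                    f"genes do not fit: {n_here} genes need more than {length} bp on {chrom}; "
                    "increase chrom_length or reduce n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    body_start=pos,
                    body_end=pos + body_len,
                    cds_start=pos,
                    cds_end=pos + body_len,
                )
            )
            pos += body_len + gap
        lengths[chrom] = length
    return genes, lengths


def _random_bases(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _overlaps(start: int, end: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in spans)


def _screen_motif_free(
    arr: np.ndarray,
    motif: IupacMotif,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int, str]] = (),
    max_rounds: int = 60,
) -> None:
    """Mutate the array in place until the only motif hits are the protected ones."""
    protected_spans = [(s, e) for s, e, _ in protected]
    expected = {(s, strand) for s, _, strand in protected}
    k = len(motif)
    for _ in range(max_rounds):
        hits = scan_sequence(_decode(arr), motif)
        unexpected = [h for h in hits if (h.offset, h.strand) not in expected]
        if not unexpected:
            found = {(h.offset, h.strand) for h in hits}
            if found != expected:
                raise RuntimeError("planted motif instance was destroyed during screening")
            return
        for h in unexpected:
            free = [p for p in range(h.offset, h.offset + k) if not _overlaps(p, p + 1, protected_spans)]
            if not free:
                raise RuntimeError(f"unexpected motif hit at {h.offset} lies entirely within planted instances")
            p = free[int(rng.integers(0, len(free)))]
            arr[p] = _BASES[int(rng.integers(0, 4))]
    raise RuntimeError("motif screening did not converge")


def _realize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(sorted(s)[int(rng.integers(0, len(s)))] for s in expand_iupac(pattern))


def _draw_summit(
    gene: GeneModel, placement: str, rng: np.random.Generator
) -> int:
    """Strand-aware summit position for one placement bin."""
    if placement == "gene_body":
        return int(rng.integers(gene.body_start + 25, gene.body_end - 25))
    if placement in {"upstream_1kb", "downstream_1kb"}:
        d = int(rng.integers(30, 951))
    else:  # distal: assigned to the gene but outside the 1 kb bins
        d = int(rng.integers(1500, 3001))
    upstream_side = placement in {"upstream_1kb", "distal"}
    low_side = upstream_side == (gene.strand == "+")
    return gene.cds_start - d if low_side else gene.cds_end + d


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def generate(config: SyntheticConfig) -> SyntheticStudy:
    """Build the full synthetic study (deterministic given ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    motif = IupacMotif(config.motif)
    k = len(motif)
    buffer = 5  # C-pad planted instances so junctions cannot re-create hits

    genes, chrom_lengths = _place_genes(config, rng)
    arrays = {chrom: _random_bases(rng, length) for chrom, length in chrom_lengths.items()}
    for chrom in arrays:
        _screen_motif_free(arrays[chrom], motif, rng)

    target_idx = sorted(int(i) for i in rng.choice(config.n_genes, size=config.n_target_genes, replace=False))
    target_genes = [genes[i] for i in target_idx]

    placements_by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in arrays}
    planted: list[dict] = []
    labels = list(PLACEMENT_BINS)
    probs = [config.mixture[l] for l in labels]
    rc_pattern = reverse_complement_motif(motif).pattern
    for gene in target_genes:
        for _ in range(config.regions_per_target):
            for _attempt in range(200):
                placement = labels[int(rng.choice(len(labels), p=probs))]
                summit = _draw_summit(gene, placement, rng)
                inst_start = summit - k // 2
                inst_end = inst_start + k
                lo, hi = inst_start - buffer - 10, inst_end + buffer + 10
                if lo < 0 or hi > chrom_lengths[gene.chrom]:
                    continue
                if _overlaps(lo, hi, [(s, e) for s, e, _ in placements_by_chrom[gene.chrom]]):
                    continue
                break
            else:
                raise ConfigError(f"could not place a motif instance near gene {gene.gene_id}")
            orientation = "+" if rng.random() < 0.5 else "-"
            word = _realize(motif.pattern if orientation == "+" else rc_pattern, rng)
            arr = arrays[gene.chrom]
            arr[inst_start:inst_end] = np.frombuffer(word.encode(), dtype=np.uint8)
            arr[inst_start - buffer : inst_start] = ord("C")
            arr[inst_end : inst_end + buffer] = ord("C")
            placements_by_chrom[gene.chrom].append((inst_start, inst_end, orientation))
            planted.append(
                {
                    "chrom": gene.chrom,
                    "gene_id": gene.gene_id,
                    "summit": summit,
                    "motif_start": inst_start,
                    "motif_strand": orientation,
                    "planted_location": placement,
                }
            )

    # Repair any junction artifacts; afterwards hit set == planted set exactly.
    for chrom in arrays:
        _screen_motif_free(arrays[chrom], motif, rng, protected=placements_by_chrom[chrom])
    genome = {chrom: _decode(arrays[chrom]) for chrom in sorted(arrays)}

    # Background regions: motif-free by construction of the screened genome;
    # keep their spans clear of planted instances.
    hw = config.region_halfwidth
    background: list[dict] = []
    chrom_names = sorted(arrays)
    planted_by_chrom = {c: sorted(s for s, _, _ in placements_by_chrom[c]) for c in chrom_names}
    for _ in range(config.n_background_regions):
        for _attempt in range(500):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            summit = int(rng.integers(hw + 1, chrom_lengths[chrom] - hw - 1))
            starts = planted_by_chrom[chrom]
            j = int(np.searchsorted(starts, summit))
            near = [starts[i] for i in (j - 1, j) if 0 <= i < len(starts)]
            if all(abs(summit - s) > hw + k + buffer + 2 for s in near):
                break
        else:
            raise ConfigError("could not place a background region away from planted instances")
        background.append({"chrom": chrom, "gene_id": "", "summit": summit,
                           "motif_start": -1, "motif_strand": ".", "planted_location": "background"})

    # Assemble regions with replicate enrichments/FDRs and ranks.
    records = [dict(p, kind="target") for p in planted] + [dict(b, kind="background") for b in background]
    for rec in records:
        if rec["kind"] == "target":
            enr = rng.lognormal(config.target_log_mu, config.target_log_sigma, size=2)
        else:
            enr = rng.lognormal(config.background_log_mu, config.background_log_sigma, size=2)
        rec["enrichment"] = tuple(round(float(e), 4) for e in enr)
        fdr = np.exp(-3.0 * enr + rng.normal(0.0, 0.5, size=2))
        rec["fdr"] = tuple(float(f"{float(x):.4g}") for x in fdr)
    order = sorted(range(len(records)), key=lambda i: (-records[i]["enrichment"][0], i))
    for rank, i in enumerate(order, start=1):
        records[i]["rank"] = rank
    regions: list[BindingRegion] = []
    for i, rec in enumerate(records):
        rec["region_id"] = f"R{i + 1:05d}"
        regions.append(
            BindingRegion(
                region_id=rec["region_id"],
                chrom=rec["chrom"],
                start=rec["summit"] - hw,
                end=rec["summit"] + hw,
                summit=rec["summit"],
                enrichment=rec["enrichment"],
                fdr=rec["fdr"],
                rank=rec["rank"],
            )
        )

    # Expression: direct targets (bound genes drawn down) shift by -effect at
    # both timepoints; a small background fraction is down without binding.
    bound_ids = {g.gene_id for g in target_genes}
    down_flags: dict[str, bool] = {}
    for gene in genes:
        p = config.p_down_given_bound if gene.gene_id in bound_ids else config.p_down_background
        down_flags[gene.gene_id] = bool(rng.random() < p)
    tracks: list[ProbeTrack] = []
    positions = tuple(range(0, config.probes_per_gene * 100, 100))
    for gene in genes:
        shift = -config.effect_size if down_flags[gene.gene_id] else 0.0
        for timepoint in config.timepoints:
            noise = rng.normal(0.0, config.noise_sigma, size=config.probes_per_gene)
            tracks.append(
                ProbeTrack(
                    gene_id=gene.gene_id,
                    timepoint=timepoint,
                    probe_positions=positions,
                    log_ratios=tuple(round(float(shift + n), 4) for n in noise),
                )
            )

    n_planted_per_gene = {g.gene_id: 0 for g in genes}
    for p in planted:
        n_planted_per_gene[p["gene_id"]] += 1
    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_bound": [g.gene_id in bound_ids for g in genes],
            "is_down": [down_flags[g.gene_id] for g in genes],
            "is_direct_target": [g.gene_id in bound_ids and down_flags[g.gene_id] for g in genes],
            "n_planted_regions": [n_planted_per_gene[g.gene_id] for g in genes],
        }
    )
    truth_regions = pd.DataFrame(
        [
            {
                "region_id": rec["region_id"],
                "chrom": rec["chrom"],
                "gene_id": rec["gene_id"],
                "kind": rec["kind"],
                "planted_location": rec["planted_location"],
                "motif_start": rec["motif_start"],
                "motif_strand": rec["motif_strand"],
            }
            for rec in records
        ]
    )
    return SyntheticStudy(
        config=config,
        genome=genome,
        genes=genes,
        regions=regions,
        tracks=tracks,
        truth=TruthTable(genes=truth_genes, regions=truth_regions),
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit every study artifact as deterministic plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "regions": outdir / "regions.tsv",
        "probes": outdir / "probes.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_regions": outdir / "truth_regions.tsv",
        "config": outdir / "config.yaml",
    }
    write_fasta(study.genome, paths["genome"])
    write_gff3(study.genes, paths["gff3"])
    write_region_table(study.regions, paths["regions"])
    write_probe_table(study.tracks, paths["probes"])
    study.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    study.truth.regions.to_csv(paths["truth_regions"], sep="\t", index=False)
    study.config.to_yaml(paths["config"])
    return paths


def write_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Copy the packaged verbatim transcriptions of the published target tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in ("table1", "table2", "table3"):
        dest = outdir / f"{name}.tsv"
        shutil.copyfile(fixture_path(name), dest)
        out[name] = dest
    return out
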